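# Methods

## The estimator

A pool of n seeds from one mother is a mixture of selfed and outcrossed
progeny. Every seed contributes one maternal allele; an outcrossed seed
(probability t) contributes one paternal allele drawn from the pollen
pool, a selfed seed another maternal allele. At an amplicon a, let q_a be
the combined frequency of the maternal haplotype(s) among pollen donors.
The expected fraction of non-parental alleles in the pooled DNA is then

    E[f_a] = (t / 2) · (1 − q_a),

so the estimator t̂ = 2 · mean_{a∈S} f_a converges to t(1 − q) under
uniform sampling of alleles into reads. Haplotype sharing therefore biases
t̂ downward and can never inflate it; with several amplicons the subset S
should favour amplicons where sharing is believed low. t̂ > 1 is reported
with a flag and never clamped — it indicates either f_a > 0.5 noise or a
violated assumption, and silent truncation would hide that.

Amplicon means weight amplicons equally, not by fragment counts: depth
varies by PCR efficiency, not by information content about t.

## Trimming arithmetic

Primer panels carry two variants per primer: plain, and with one A/T
heterogeneity base between adapter tail and gene-specific sequence. A
het-primed read loses `primer + 1` bases at its 5′ end; a plain-primed
read loses `primer` bases and then one base at its 3′ end, so both keep
exactly `read_length − primer_length − 1` bases and identical templates
yield identical haplotype strings regardless of primer variant. Reads of
any other kept length are rejected (`wrong_length`), which also disposes
of indel-containing primer matches — the reason matching is
substitution-only. The default `max_error_rate` of 0.1 allows
`floor(0.1 · match_length)` mismatches (2 for a 20-nt primer); N counts as
a mismatch. Ties between matching variants resolve to fewer mismatches,
then the longer (het) match, then panel order.

Mates are concatenated as sequenced, without reverse-complementing or
overlap merging: fragments only need to be *identical keys*, not
biological sequences, and 300–400 bp inserts do not reliably overlap at
2 × 150 bp.

## Filtering

Rule 1 removes haplotypes below `min_freq` (default 1%) of the cell's
**pre-filter** fragment total; rule 2 removes haplotypes that reach 1% in
fewer than `min_samples` (default 2) libraries at the same amplicon, leaf
libraries included. Downstream proportions use the **post-filter** totals
as baseline. A haplotype at exactly 1.0% is retained (the exclusion is of
haplotypes strictly below threshold). The cross-sample condition defaults
to "≥ 1% in ≥ 2 libraries"; `any_count` (nonzero count in ≥ 2 libraries)
ships as a documented, strictly more permissive alternative. Filtering is
idempotent and monotone, and setting `min_freq → 0`, `min_samples = 1`
returns the unfiltered table.

Parental haplotypes are the leaf library's retained haplotypes at
frequency ≥ `min_parent_freq` (default 5%). Near-homozygous lines leave a
wide margin between the real haplotype (≈100%) and the noise floor (<1%),
so the exact threshold is uncritical; 0 or >2 called haplotypes are
flagged. Where the declared parental lines differ at an amplicon, the
default (`auto`) counting switches to `exclude_all_parents`: only
haplotypes found in *neither* line enter the numerator (denominator
unchanged), which removes the confounding of genuine cross-line pollen
flow with differential haplotype sharing. Cross-line flow itself can be
examined with `parental_flow`, which shares fragments between the two
parental haplotype classes only.

## Statistics

Welch's t statistic and the Welch–Satterthwaite df are computed from their
defining formulas; the paired test is a one-sample t on differences with
df = n − 1. Tail probabilities use the exact Student t distribution
(scipy.stats.t), two-sided. Groups that are exactly constant are treated
as zero-variance degenerate cases (p = 1 when means agree, 0 otherwise,
flagged) — detected by value equality, not by a variance tolerance, so
that ordinary small-variance data never takes the degenerate path. Both
tests are scale-invariant, so results agree between outcrossing rates and
mean non-parental frequencies (factor 2). Raw p-values are reported; a
Bonferroni column is optional.

## Simulator

The generator draws, per amplicon, a random 260-nt insert for the maternal
line (inserts of that length fill both 150-nt reads beyond every primer of
the reference panel) and a donor pool of haplotypes mutated from it at
2–4 positions within the sequenced window. Seeds are drawn per the mixture
model above; reads sample alleles uniformly, choose het/plain primer
variants with equal probability, and acquire substitution errors at a
per-base rate e. Jackpot artifacts — one private haplotype per affected
(library × amplicon) cell at a nominal 1–5% of reads — emulate early-cycle
PCR errors. Outputs (FASTQ, sample sheet, truth table) are byte-identical
for identical configs, including under gzip (fixed mtime).

Defaults encode the emulated field trial: 300 seeds/pool, 2 × 150 bp
reads, 12 seed pools (2 lines × 2 treatments × 3 replicates) plus one leaf
library per line. The donor pool defaults to a **single** non-maternal
haplotype per amplicon, reflecting the genetically simple pollen
population of the emulated design (a few quasi-isogenic donor lines);
sharing of the maternal haplotype is modelled by q, not by pool
composition. This default also respects the method's detection floor: at
e = 0.005 only (1 − e)^258 ≈ 27% of fragments are error-free, so a donor
haplotype below ≈3.7% true frequency lands near the 1% filter threshold
and is stochastically truncated — with many rare donor haplotypes the
estimator measures only the detectable ones, which is a property of the
method, not of the implementation. The bias-sweep example shows this floor
emerging at q = 0.75.

What the simulator does not emulate: PCR amplification bias beyond an
optional per-haplotype lognormal efficiency multiplier (the panel was
designed to minimize it), chimeras, index hopping, quality-score
structure, read-length variation, and pollen-pool spatial structure
(collapsed into q_a). Passing recovery tests therefore show estimator
correctness under the model's assumptions, not robustness to all real-data
artifacts.

## Problem sizes

Recovery validation uses 20 replicate experiments of 2 seed pools + 1 leaf
library on the eight-amplicon subset at 2,000 reads/amplicon (leaf 1,000),
e = 0.005, t = 0.3, q ∈ {0, 0.5}; two pools are the minimum for shared
donor haplotypes to clear the single-sample rule, keeping that rule
honestly exercised. The mean t̂ is compared with t(1 − q) within three
empirical standard errors. Filter-efficacy runs inject jackpots into every
cell of three seeded two-pool experiments.

## Primer design

The design module is a strategy demonstrator: invariant-window detection
over a population alignment, GC screening at 0.4–0.6, Wallace-rule Tm
(2(A+T) + 4(G+C), adequate for ≤24-mers) at 55 ± 5 °C, and exhaustive
choice of the window pair enclosing the most polymorphic columns within a
300–400 nt variable region (ties to the leftmost pair). Nearest-neighbor
thermodynamics, dimer screening and single-copy vetting are out of scope;
coordinates are 1-based inclusive in reports, 0-based half-open
internally.

## Known limitations

- Biparental inbreeding (mating between relatives sharing haplotypes) is
  indistinguishable from selfing, as in any pooled single-locus approach.
- q is not estimable from a single pooled experiment; t̂ is a lower bound
  on t unless donors are genotyped.
- The single-sample rule assumes real alleles recur across libraries; a
  donor haplotype genuinely private to one pool (one rare father) is
  removed with the artifacts.
- Frequencies, not likelihoods: no joint mating-system model (MLTR-style
  inference is a non-goal).
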