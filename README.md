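# poolcross

Estimation of plant outcrossing rates from pooled-progeny amplicon
sequencing.

Many flowering plants have a mixed mating system: a fraction *t* of a
plant's seeds are sired by pollen from other individuals (outcrossing)
while the rest arise from self-fertilization. Classical estimates genotype
individual progeny one by one; this package implements the pooled
alternative: DNA is extracted from a pool of ~300 seeds per mother plant,
a panel of single-copy amplicons is PCR-amplified and sequenced in
2 × 150 bp paired-end mode, and outcrossing is read off the frequency of
haplotypes that do not belong to the maternal line. It is aimed at
population geneticists and breeders who need replicate-level outcrossing
estimates cheaply, and at anyone validating such a pipeline against
simulated data.

## Method

Per library and amplicon, each read pair is assigned by anchored matching
of the gene-specific primer at the 5′ end of read 1 (forward) and read 2
(reverse), substitutions only. Primers are trimmed — including the single
A/T "heterogeneity" base carried by half the primer pool — and reads from
plain primers are cut by one extra 3′ base so both primer versions yield
identical lengths (`read_length − primer_length − 1` per mate). Only
expected-length reads are kept, and the trimmed mates are concatenated
into one fragment treated as a haplotype. Haplotype counts are then
filtered by two rules:

1. haplotypes below 1% frequency in their (library × amplicon) cell are
   discarded as sequencing errors;
2. haplotypes above 1% but reaching that frequency in only one library
   are discarded as early-cycle PCR ("jackpot") artifacts.

Parental haplotypes are called per amplicon from the maternal line's leaf
library; the non-parental fragment frequency *f_a* of a seed pool is
computed over the retained baseline, and, because each outcrossed seed
contributes one maternal and one paternal allele to the pool,

  t̂ = 2 · mean_{a∈S} f_a

over the amplicon subset *S*. Outcrossing via pollen that shares the
maternal haplotype (combined pollen-pool frequency *q_a*) is undetectable,
so t̂ converges to *t*(1 − *q*): an underestimate, never an inflation.
Replicate-level comparisons use a Welch two-sample t-test across
treatments and paired t-tests between genotypes within a treatment.

The package also includes a full generative simulator of such experiments
(diploid seed pools, donor pools with configurable sharing *q*, per-base
sequencing error, jackpot artifacts) and a simplified conserved-window
primer-panel designer. The published 12-amplicon *Capsella* primer panel
ships as `load_reference_panel()`.

## Worked example

```bash
python examples/simulate_and_estimate.py
```

simulates the default design — 2 maternal lines × {open pollination (t =
0.3), insect exclusion (t = 0)} × 3 replicate pools of 300 seeds, plus two
leaf libraries — and runs the full pipeline:

```
per-library estimates (true rate: open 0.30, excluded 0.00):
    library_id treatment  outcrossing_rate
 CNL1_G_bird_1      bird          0.302853
 CNL1_G_bird_2      bird          0.320411
 ...
mean under open pollination:  0.298
mean under insect exclusion: 0.000

  test               comparison         t  df            p
paired   bird: CNL1_G vs CNL1_R  1.091867 2.0 3.888800e-01
paired insect: CNL1_G vs CNL1_R  0.000000 2.0 1.000000e+00
 welch           bird vs insect 48.696692 5.0 6.899956e-08
```

The per-library rates recover the simulated truth; the Welch test detects
the treatment effect, and the paired genotype tests are (correctly) null.
Other examples: `published_statistics.py` (the study's replicate table),
`haplotype_sharing_bias.py` (t̂ → t(1 − q)), `design_primer_panel.py`.

A `poolcross` console command exposes the same stages
(`simulate`, `assign`, `haplotypes`, `estimate`, `stats`, `design`).

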