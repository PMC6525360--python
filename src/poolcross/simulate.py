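"""Simulator of pooled-progeny amplicon sequencing experiments.

Each seed pool contains ``n_seeds`` diploid progeny of one maternal line.
Every seed carries one maternal allele; its paternal allele is maternal
again with probability 1 - t (selfing) or drawn from the pollen-donor pool
with probability t (outcrossing).  A donor allele is identical to the
maternal haplotype with probability q_a (haplotype sharing), which makes
that outcrossing event undetectable: the expected detectable non-parental
allele fraction is (t/2) * (1 - q_a).

Reads emulate the amplicon structure: read 1 starts with a forward primer
variant (heterogeneity and plain versions drawn with equal probability)
followed by the leading bases of the allele's insert; read 2 with a reverse
variant followed by the leading bases of the reverse-complemented insert.
Substitution errors are applied per base; optional sample-private "jackpot"
haplotypes emulate early-cycle PCR artifacts at 1-5% frequency.  Base
qualities are constant placeholders; the pipeline never interprets them.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .panel import (
    AmpliconPanel,
    Library,
    ROLE_PARENTAL_LEAF,
    ROLE_SEED_POOL,
    SampleSheet,
    load_reference_panel,
    write_sample_sheet,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = "ACGT"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class LibrarySpec:
    """One library of the simulated design."""

    library_id: str
    role: str  # seed_pool | parental_leaf
    maternal_line: str
    treatment: str = ""
    replicate: str = ""
    t: float = 0.0  # true outcrossing rate (ignored for leaf libraries)


@dataclass
class SimulationConfig:
    """Study conditions of a simulated experiment.

    Defaults encode the emulated field trial: pools of ~300 seeds sequenced
    2 x 150 bp, inserts of 260 nt giving ~300 bp amplicons once primers are
    included, and a pollen pool of a few distinct donor haplotypes per
    amplicon.
    """

    rng_seed: int = 0
    amplicon_ids: Optional[list[str]] = None  # None -> full reference panel
    read_length: int = 150
    insert_length: int = 260
    n_seeds: int = 300
    reads_per_amplicon: int = 2000
    leaf_reads_per_amplicon: Optional[int] = None  # None -> reads_per_amplicon
    error_rate: float = 0.0  # per-base substitution probability
    q: float | dict[str, float] = 0.0  # maternal-haplotype sharing per amplicon
    # the emulated pollen pool is genetically simple (quasi-isogenic donors):
    # one non-maternal haplotype per amplicon by default; with richer pools,
    # per-haplotype frequencies approach the 1% detection floor and real
    # alleles start falling to the frequency filter
    n_donor_haplotypes: int = 1
    jackpot_prob: float = 0.0  # per (library, amplicon)
    jackpot_freq_range: tuple[float, float] = (0.01, 0.05)
    amplification_bias: float = 0.0  # stdev of lognormal per-haplotype efficiency
    heterozygous_lines: bool = False
    polymorphic_amplicon: Optional[str] = None  # amplicon where the two lines differ
    libraries: Optional[list[LibrarySpec]] = None  # None -> default design
    compress: bool = False

    def q_for(self, amplicon_id: str) -> float:
        if isinstance(self.q, dict):
            return float(self.q.get(amplicon_id, 0.0))
        return float(self.q)

    def validate(self) -> None:
        probs = [self.error_rate, self.jackpot_prob, *self.jackpot_freq_range]
        if isinstance(self.q, dict):
            probs.extend(self.q.values())
        else:
            probs.append(self.q)
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        for spec in self.libraries or []:
            if not 0.0 <= spec.t <= 1.0:
                raise ValueError(f"{spec.library_id}: t={spec.t} out of [0,1]")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, default=str) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        d = json.loads(Path(path).read_text())
        if d.get("libraries"):
            d["libraries"] = [LibrarySpec(**ls) for ls in d["libraries"]]
        if d.get("jackpot_freq_range"):
            d["jackpot_freq_range"] = tuple(d["jackpot_freq_range"])
        return cls(**d)


def default_design(
    t_open: float = 0.3,
    t_excluded: float = 0.0,
    lines: Sequence[str] = ("CNL1_G", "CNL1_R"),
    treatments: Sequence[str] = ("bird", "insect"),
    n_replicates: int = 3,
) -> list[LibrarySpec]:
    """2 genotypes x {open, insect-excluded} x 3 replicates = 12 seed pools,
    plus one leaf library per maternal line."""
    specs = []
    t_by_treatment = {treatments[0]: t_open, treatments[1]: t_excluded}
    for line in lines:
        for treat in treatments:
            for rep in range(1, n_replicates + 1):
                specs.append(
                    LibrarySpec(
                        library_id=f"{line}_{treat}_{rep}",
                        role=ROLE_SEED_POOL,
                        maternal_line=line,
                        treatment=treat,
                        replicate=str(rep),
                        t=t_by_treatment[treat],
                    )
                )
    for line in lines:
        specs.append(
            LibrarySpec(
                library_id=f"{line}_leaf",
                role=ROLE_PARENTAL_LEAF,
                maternal_line=line,
                treatment="none",
                replicate="",
            )
        )
    return specs


@dataclass
class Genotypes:
    """True insert sequences: maternal haplotypes per (line, amplicon) and
    the donor pool per amplicon (haplotypes distinct from the maternal)."""

    maternal: dict[tuple[str, str], list[str]]  # (line, amplicon) -> 1-2 inserts
    donors: dict[str, list[str]]  # amplicon -> donor inserts

    def maternal_inserts(self, line: str, amplicon_id: str) -> list[str]:
        return self.maternal[(line, amplicon_id)]


def _random_insert(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _mutate(rng: np.random.Generator, seq: str, positions: Sequence[int]) -> str:
    chars = list(seq)
    for pos in positions:
        alternatives = [b for b in _BASES if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


# donor/jackpot mutations stay in this window so they always fall inside the
# sequenced part of the insert (>=126 leading bases are covered for every
# amplicon of the reference panel at 150 nt reads)
_MUTABLE_WINDOW = (20, 100)


def build_genotypes(
    config: SimulationConfig,
    panel: AmpliconPanel,
    lines: Sequence[str],
    rng: np.random.Generator,
) -> Genotypes:
    maternal: dict[tuple[str, str], list[str]] = {}
    donors: dict[str, list[str]] = {}
    for amp in panel.amplicon_ids:
        base = _random_insert(rng, config.insert_length)
        for i, line in enumerate(lines):
            inserts = [base]
            if config.polymorphic_amplicon == amp and i > 0:
                inserts = [_mutate(rng, base, [rng.integers(*_MUTABLE_WINDOW)])]
            if config.heterozygous_lines:
                inserts = inserts + [_mutate(rng, inserts[0], [rng.integers(*_MUTABLE_WINDOW)])]
            maternal[(line, amp)] = inserts
        pool = []
        for _ in range(config.n_donor_haplotypes):
            k = int(rng.integers(2, 5))
            positions = rng.choice(
                np.arange(*_MUTABLE_WINDOW), size=k, replace=False
            )
            pool.append(_mutate(rng, base, positions.tolist()))
        donors[amp] = pool
    return Genotypes(maternal, donors)


def simulate_seed_pool(
    config: SimulationConfig,
    genotypes: Genotypes,
    line: str,
    amplicon_id: str,
    t: float,
    rng: np.random.Generator,
) -> tuple[dict[str, int], float]:
    """Draw the 2*n_seeds alleles of one pool at one amplicon.

    Returns (allele counts, realized non-parental allele fraction).
    """
    maternal = genotypes.maternal_inserts(line, amplicon_id)
    donors = genotypes.donors[amplicon_id]
    q = config.q_for(amplicon_id)
    counts: dict[str, int] = {}
    nonparental = 0
    maternal_set = set(maternal)
    for _ in range(config.n_seeds):
        m_allele = maternal[rng.integers(0, len(maternal))]
        if rng.random() < t:  # outcrossed seed
            if rng.random() < q:  # donor shares the maternal haplotype
                p_allele = maternal[rng.integers(0, len(maternal))]
            else:
                p_allele = donors[rng.integers(0, len(donors))]
        else:  # selfed seed
            p_allele = maternal[rng.integers(0, len(maternal))]
        for allele in (m_allele, p_allele):
            counts[allele] = counts.get(allele, 0) + 1
            if allele not in maternal_set:
                nonparental += 1
    return counts, nonparental / (2 * config.n_seeds)


def true_fragment(insert: str, panel: AmpliconPanel, amplicon_id: str) -> str:
    """The haplotype string the pipeline recovers from an error-free read
    pair of this allele."""
    k1 = panel.trimmed_length(amplicon_id, "forward")
    k2 = panel.trimmed_length(amplicon_id, "reverse")
    rc = reverse_complement(insert)
    return insert[:k1] + rc[:k2]


def _apply_errors(
    rng: np.random.Generator, seq: str, n_errors: int
) -> str:
    if n_errors == 0:
        return seq
    positions = rng.choice(len(seq), size=n_errors, replace=False)
    return _mutate(rng, seq, positions.tolist())


def simulate_reads(
    allele_counts: dict[str, int],
    config: SimulationConfig,
    panel: AmpliconPanel,
    amplicon_id: str,
    rng: np.random.Generator,
    n_reads: Optional[int] = None,
    jackpot_insert: Optional[str] = None,
    jackpot_freq: float = 0.0,
) -> list[tuple[str, str]]:
    """Sequence one (library, amplicon) cell: uniform sampling of alleles
    (optionally skewed by per-haplotype amplification efficiencies),
    equal-probability choice of heterogeneity/plain primer on each mate,
    then per-base substitution errors.  Returns (seq1, seq2) tuples."""
    n_reads = config.reads_per_amplicon if n_reads is None else n_reads
    amp = panel[amplicon_id]
    fwd_plain = amp.plain("forward")
    rev_plain = amp.plain("reverse")
    fwd_het = next((v for v in amp.forward if v.is_het), None)
    rev_het = next((v for v in amp.reverse if v.is_het), None)

    alleles = sorted(allele_counts)
    weights = np.array([allele_counts[a] for a in alleles], dtype=float)
    if config.amplification_bias > 0:
        weights = weights * rng.lognormal(0.0, config.amplification_bias, len(alleles))
    probs = weights / weights.sum()
    if jackpot_insert is not None and jackpot_freq > 0:
        alleles = alleles + [jackpot_insert]
        probs = np.append(probs * (1.0 - jackpot_freq), jackpot_freq)

    min_insert = config.read_length - min(len(fwd_plain.gene_seq), len(rev_plain.gene_seq))
    if config.insert_length < min_insert:
        raise ValueError(
            f"insert length {config.insert_length} too short for amplicon "
            f"{amplicon_id} at read length {config.read_length}"
        )

    # per-allele read templates: (het?, mate) -> full read string, error-free
    templates = []
    for insert in alleles:
        rc = reverse_complement(insert)
        per_allele = {}
        for het, variant, source in (
            (False, fwd_plain, insert),
            (True, fwd_het, insert),
            (False, rev_plain, rc),
            (True, rev_het, rc),
        ):
            if variant is None:
                continue
            prefix = variant.match_seq
            fill = config.read_length - len(prefix)
            per_allele[(het, variant.direction)] = prefix + source[:fill]
        templates.append(per_allele)

    allele_idx = rng.choice(len(alleles), size=n_reads, p=probs)
    het1 = rng.random(n_reads) < 0.5
    het2 = rng.random(n_reads) < 0.5
    err1 = rng.binomial(config.read_length, config.error_rate, size=n_reads)
    err2 = rng.binomial(config.read_length, config.error_rate, size=n_reads)

    reads = []
    for i in range(n_reads):
        tmpl = templates[allele_idx[i]]
        use_het1 = het1[i] and (True, "forward") in tmpl
        use_het2 = het2[i] and (True, "reverse") in tmpl
        s1 = tmpl[(use_het1, "forward")]
        s2 = tmpl[(use_het2, "reverse")]
        reads.append(
            (_apply_errors(rng, s1, int(err1[i])), _apply_errors(rng, s2, int(err2[i])))
        )
    return reads


@dataclass
class SimulationTruth:
    """Ground truth of a simulated experiment."""

    genotypes: Genotypes
    per_library_t: dict[str, float] = field(default_factory=dict)
    q: dict[str, float] = field(default_factory=dict)  # amplicon -> q_a
    expected_detectable: dict[tuple[str, str], float] = field(default_factory=dict)
    realized_nonparental: dict[tuple[str, str], float] = field(default_factory=dict)
    jackpots: dict[tuple[str, str], str] = field(default_factory=dict)  # -> insert

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (lib, amp), realized in sorted(self.realized_nonparental.items()):
            rows.append(
                {
                    "library_id": lib,
                    "amplicon_id": amp,
                    "t": self.per_library_t.get(lib, 0.0),
                    "q": self.q.get(amp, 0.0),
                    "expected_detectable": self.expected_detectable[(lib, amp)],
                    "realized_nonparental": realized,
                    "jackpot": (lib, amp) in self.jackpots,
                }
            )
        return pd.DataFrame(rows)


def _fastq_bytes(records: list[tuple[str, str, str]]) -> bytes:
    return "".join(f"@{rid}\n{seq}\n+\n{qual}\n" for rid, seq, qual in records).encode()


def simulate_experiment(
    config: SimulationConfig,
    outdir: str | Path,
    panel: Optional[AmpliconPanel] = None,
) -> tuple[SampleSheet, SimulationTruth]:
    """Generate FASTQ pairs, a sample sheet and a truth table on disk.

    Deterministic: the same config (including rng_seed) yields byte-identical
    outputs.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if panel is None:
        panel = load_reference_panel(read_length=config.read_length)
    if config.amplicon_ids is not None:
        panel = panel.subset(config.amplicon_ids)
    specs = config.libraries if config.libraries is not None else default_design()
    lines = sorted({s.maternal_line for s in specs})
    rng = np.random.default_rng(config.rng_seed)
    genotypes = build_genotypes(config, panel, lines, rng)
    truth = SimulationTruth(
        genotypes=genotypes,
        q={amp: config.q_for(amp) for amp in panel.amplicon_ids},
    )

    libraries = []
    ext = ".fastq.gz" if config.compress else ".fastq"
    for spec in specs:
        is_leaf = spec.role == ROLE_PARENTAL_LEAF
        t = 0.0 if is_leaf else spec.t
        truth.per_library_t[spec.library_id] = t
        n_reads = (
            config.leaf_reads_per_amplicon
            if (is_leaf and config.leaf_reads_per_amplicon is not None)
            else config.reads_per_amplicon
        )
        r1_records: list[tuple[str, str, str]] = []
        r2_records: list[tuple[str, str, str]] = []
        for amp in panel.amplicon_ids:
            alleles, realized = simulate_seed_pool(
                config, genotypes, spec.maternal_line, amp, t, rng
            )
            q = config.q_for(amp)
            truth.expected_detectable[(spec.library_id, amp)] = (t / 2.0) * (1.0 - q)
            truth.realized_nonparental[(spec.library_id, amp)] = realized
            jackpot_insert = None
            jackpot_freq = 0.0
            if not is_leaf and config.jackpot_prob > 0 and rng.random() < config.jackpot_prob:
                maternal = genotypes.maternal_inserts(spec.maternal_line, amp)[0]
                positions = rng.choice(
                    np.arange(*_MUTABLE_WINDOW), size=2, replace=False
                )
                jackpot_insert = _mutate(rng, maternal, positions.tolist())
                lo, hi = config.jackpot_freq_range
                jackpot_freq = float(rng.uniform(lo, hi))
                truth.jackpots[(spec.library_id, amp)] = jackpot_insert
            for i, (s1, s2) in enumerate(
                simulate_reads(
                    alleles,
                    config,
                    panel,
                    amp,
                    rng,
                    n_reads=n_reads,
                    jackpot_insert=jackpot_insert,
                    jackpot_freq=jackpot_freq,
                )
            ):
                rid = f"{spec.library_id}:{amp}:{i}"
                r1_records.append((rid, s1, "I" * len(s1)))
                r2_records.append((rid, s2, "I" * len(s2)))
        fq1 = outdir / f"{spec.library_id}_R1{ext}"
        fq2 = outdir / f"{spec.library_id}_R2{ext}"
        for path, records in ((fq1, r1_records), (fq2, r2_records)):
            data = _fastq_bytes(records)
            if config.compress:
                # fixed mtime for byte-identical reruns
                with open(path, "wb") as raw:
                    with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
                        gz.write(data)
            else:
                path.write_bytes(data)
        libraries.append(
            Library(
                library_id=spec.library_id,
                fastq1=fq1.name,
                fastq2=fq2.name,
                role=spec.role,
                maternal_line=spec.maternal_line,
                treatment=spec.treatment,
                replicate=spec.replicate,
            )
        )

    sheet = SampleSheet(libraries)
    write_sample_sheet(sheet, outdir / "sample_sheet.tsv")
    truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return sheet, truth
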