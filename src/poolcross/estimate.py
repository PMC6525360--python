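"""Outcrossing-rate estimation from filtered haplotype tables.

Parental haplotypes are called per amplicon from the maternal line's leaf
library; any retained fragment in a seed pool whose haplotype is outside
that set is evidence of an outcrossed (paternal) allele.  Because each
outcrossed seed contributes one maternal and one paternal allele to the
pooled DNA, the non-parental fragment frequency is half the outcrossed-seed
fraction, so the estimator doubles the mean per-amplicon frequency:

    t_hat = 2 * mean_{a in S} f_a

Outcrossing by pollen that carries the maternal haplotype is invisible; if
the maternal haplotype(s) occur at combined frequency q_a in the pollen
pool, the detectable non-parental fraction is (t/2) * (1 - q_a) and t_hat
estimates t * (1 - q_a) — an underestimate whenever q_a > 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from statistics import median
from typing import Mapping, Optional, Sequence

import pandas as pd

from .filtering import HaplotypeTable
from .panel import SampleSheet

logger = logging.getLogger(__name__)

MODE_FOCAL_ONLY = "focal_only"
MODE_EXCLUDE_ALL_PARENTS = "exclude_all_parents"
MODE_AUTO = "auto"


class EstimationError(ValueError):
    pass


@dataclass
class ParentalHaplotypes:
    """Per (maternal_line, amplicon) sets of parental haplotype strings."""

    haplotypes: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    source_libraries: dict[str, str] = field(default_factory=dict)  # line -> library
    warnings: list[str] = field(default_factory=list)

    @property
    def lines(self) -> list[str]:
        return sorted({line for line, _ in self.haplotypes})

    def get(self, maternal_line: str, amplicon_id: str) -> set[str]:
        return self.haplotypes.get((maternal_line, amplicon_id), set())

    def union(self, amplicon_id: str) -> set[str]:
        """Haplotypes found in any parental line at one amplicon."""
        out: set[str] = set()
        for (line, amp), haps in self.haplotypes.items():
            if amp == amplicon_id:
                out |= haps
        return out

    def lines_differ(self, amplicon_id: str) -> bool:
        sets = [
            haps for (line, amp), haps in self.haplotypes.items() if amp == amplicon_id
        ]
        return len(sets) > 1 and any(s != sets[0] for s in sets[1:])


def call_parental_haplotypes(
    filtered: HaplotypeTable,
    sheet: SampleSheet,
    min_parent_freq: float = 0.05,
) -> ParentalHaplotypes:
    """Call each maternal line's haplotype set per amplicon from its leaf
    library: every retained haplotype at frequency >= min_parent_freq.

    A diploid line yields one (homozygous) or two (heterozygous) haplotypes;
    more than two, or none, is flagged.
    """
    leaves = sheet.leaf_libraries
    if not leaves:
        raise EstimationError(
            "no parental_leaf libraries in the sample sheet; supply parental "
            "haplotypes explicitly"
        )
    parents = ParentalHaplotypes()
    for leaf in leaves:
        parents.source_libraries[leaf.maternal_line] = leaf.library_id
        for amp in filtered.amplicons:
            freqs = filtered.frequencies(leaf.library_id, amp)
            called = {h for h, f in freqs.items() if f >= min_parent_freq}
            if not freqs:
                continue
            key = (leaf.maternal_line, amp)
            parents.haplotypes[key] = parents.haplotypes.get(key, set()) | called
    for (line, amp), haps in sorted(parents.haplotypes.items()):
        if len(haps) == 0:
            msg = f"line {line}, amplicon {amp}: no haplotype reached the parental threshold"
            parents.warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
        elif len(haps) > 2:
            msg = f"line {line}, amplicon {amp}: {len(haps)} haplotypes called (diploid expects <= 2)"
            parents.warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
    return parents


def nonparental_frequency(
    filtered: HaplotypeTable,
    parents: ParentalHaplotypes,
    library_id: str,
    amplicon_id: str,
    maternal_line: str,
    mode: str = MODE_FOCAL_ONLY,
) -> Optional[float]:
    """Fraction of retained fragments carrying a non-parental haplotype.

    ``focal_only`` counts fragments outside the focal maternal set;
    ``exclude_all_parents`` (for amplicons where the parental lines differ)
    additionally drops from the numerator haplotypes found in *any*
    parental line, leaving the denominator unchanged.  Returns None for an
    empty cell.
    """
    haps = filtered.cell(library_id, amplicon_id)
    total = sum(haps.values())
    if total == 0:
        return None
    focal = parents.get(maternal_line, amplicon_id)
    excluded = focal
    if mode == MODE_EXCLUDE_ALL_PARENTS:
        excluded = focal | parents.union(amplicon_id)
    elif mode != MODE_FOCAL_ONLY:
        raise ValueError(f"unknown mode {mode!r}")
    nonparental = sum(n for h, n in haps.items() if h not in excluded)
    return nonparental / total


@dataclass
class OutcrossingEstimate:
    library_id: str
    per_amplicon: dict[str, Optional[float]]  # f_a, None for empty cells
    subset: list[str]  # amplicons averaged (S)
    mean_frequency: float
    rate: float  # t_hat = 2 * mean
    flags: list[str] = field(default_factory=list)


def estimate_outcrossing(
    per_amplicon: Mapping[str, Optional[float]],
    subset: Sequence[str],
    library_id: str = "",
) -> OutcrossingEstimate:
    """Average per-amplicon non-parental frequencies over the subset and
    double the mean (diploid correction).  Rates above 1 are flagged, never
    clamped."""
    flags = []
    usable = [a for a in subset if per_amplicon.get(a) is not None]
    dropped = [a for a in subset if a not in usable]
    if dropped:
        flags.append(f"empty_amplicons:{','.join(dropped)}")
    if not usable:
        raise EstimationError(
            f"library {library_id or '<unnamed>'}: no amplicon in the subset has data"
        )
    m = sum(per_amplicon[a] for a in usable) / len(usable)
    rate = 2.0 * m
    if rate > 1.0:
        flags.append("rate_over_unity")
    return OutcrossingEstimate(
        library_id=library_id,
        per_amplicon=dict(per_amplicon),
        subset=list(usable),
        mean_frequency=m,
        rate=rate,
        flags=flags,
    )


def select_amplicons(
    per_library_freqs: Mapping[str, Mapping[str, Optional[float]]],
    method: str = "all",
    manual: Optional[Sequence[str]] = None,
    ratio: float = 0.5,
) -> list[str]:
    """Choose the amplicon subset used for averaging.

    ``all`` keeps every amplicon with data; ``manual`` returns the given
    list; ``low_outlier`` drops amplicons whose median non-parental
    frequency across the control libraries falls below ``ratio`` times the
    overall median — a stand-in for the judgment call of excluding amplicons
    depressed by haplotype sharing in the pollen pool.
    """
    amplicons = sorted({a for freqs in per_library_freqs.values() for a in freqs})
    if method == "manual":
        if manual is None:
            raise ValueError("manual selection requires a list of amplicons")
        unknown = [a for a in manual if a not in amplicons]
        if unknown:
            raise ValueError(f"unknown amplicon(s) in manual subset: {unknown}")
        return list(manual)
    if method == "all":
        return [
            a
            for a in amplicons
            if any(freqs.get(a) is not None for freqs in per_library_freqs.values())
        ]
    if method == "low_outlier":
        medians = {}
        for a in amplicons:
            vals = [
                freqs[a]
                for freqs in per_library_freqs.values()
                if freqs.get(a) is not None
            ]
            if vals:
                medians[a] = median(vals)
        overall = median(list(medians.values()))
        cutoff = ratio * overall
        kept = [a for a in amplicons if a in medians and medians[a] >= cutoff]
        excluded = [a for a in medians if a not in kept]
        if excluded:
            logger.info("low_outlier selection excluded amplicons %s", excluded)
        return kept
    raise ValueError(f"unknown selection method {method!r}")


def parental_flow(
    cell_counts: Mapping[str, int],
    p1: set[str],
    p2: set[str],
) -> tuple[Optional[float], Optional[float]]:
    """Shares of the two parental haplotype classes among fragments matching
    either parent (used at an amplicon where the two lines differ); other
    haplotypes are ignored.  Returns (None, None) with no parental fragments."""
    if p1 & p2:
        raise ValueError("parental haplotype sets overlap; flow shares undefined")
    n1 = sum(n for h, n in cell_counts.items() if h in p1)
    n2 = sum(n for h, n in cell_counts.items() if h in p2)
    total = n1 + n2
    if total == 0:
        return None, None
    return n1 / total, n2 / total


def estimate_all_libraries(
    filtered: HaplotypeTable,
    sheet: SampleSheet,
    parents: ParentalHaplotypes,
    subset: Optional[Sequence[str]] = None,
    mode: str = MODE_AUTO,
) -> list[OutcrossingEstimate]:
    """Per-seed-pool estimates; in ``auto`` mode, amplicons where the
    declared parental lines' haplotype sets differ switch to
    exclude_all_parents (logged)."""
    amplicons = filtered.amplicons
    modes = {}
    for amp in amplicons:
        if mode == MODE_AUTO:
            if parents.lines_differ(amp):
                modes[amp] = MODE_EXCLUDE_ALL_PARENTS
                logger.info(
                    "amplicon %s: parental lines differ; counting only haplotypes "
                    "absent from every parental line as non-parental",
                    amp,
                )
            else:
                modes[amp] = MODE_FOCAL_ONLY
        else:
            modes[amp] = mode
    estimates = []
    for lib in sheet.seed_pools:
        freqs = {
            amp: nonparental_frequency(
                filtered, parents, lib.library_id, amp, lib.maternal_line, modes[amp]
            )
            for amp in amplicons
        }
        use = list(subset) if subset is not None else [
            a for a in amplicons if freqs[a] is not None
        ]
        estimates.append(estimate_outcrossing(freqs, use, lib.library_id))
    return estimates


def estimates_to_frame(
    estimates: Sequence[OutcrossingEstimate], sheet: SampleSheet
) -> pd.DataFrame:
    """Results table in the published layout (genotype, net, replicate,
    outcrossing rate) plus per-amplicon frequency columns."""
    amplicons = sorted({a for e in estimates for a in e.per_amplicon})
    rows = []
    for e in estimates:
        lib = sheet[e.library_id]
        row: dict[str, object] = {
            "library_id": e.library_id,
            "genotype": lib.maternal_line,
            "treatment": lib.treatment,
            "replicate": lib.replicate,
            "mean_nonparental_freq": e.mean_frequency,
            "outcrossing_rate": e.rate,
            "amplicons_used": ",".join(e.subset),
            "flags": ";".join(e.flags),
        }
        for a in amplicons:
            row[f"freq_{a}"] = e.per_amplicon.get(a)
        rows.append(row)
    return pd.DataFrame(rows)
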