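"""Haplotype counting per (library x amplicon) and frequency filtering.

Two rules define the *major haplotypes* whose counts back all downstream
proportions:

1. frequency rule — a haplotype below ``min_freq`` (default 1%) of its
   cell's raw fragment total is discarded as likely sequencing error;
2. single-sample rule — a haplotype that clears 1% but does so in only one
   library for that amplicon is discarded as a likely early-cycle PCR
   artifact ("jackpot"), since genuine alleles recur across libraries.

Frequencies for filtering use pre-filter denominators; proportions reported
downstream use the post-filter totals as baseline.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .assign import AssignedFragment

Cell = tuple[str, str]  # (library_id, amplicon_id)

PRESENCE_AT_THRESHOLD = "at_threshold"
PRESENCE_ANY_COUNT = "any_count"


@dataclass
class HaplotypeTable:
    """Counts of haplotype fragments per (library, amplicon) cell.

    ``raw_totals`` are pre-filter fragment sums per cell and stay fixed
    through filtering; ``retained_totals`` track the surviving mass.
    """

    counts: dict[Cell, dict[str, int]] = field(default_factory=dict)
    raw_totals: dict[Cell, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cell, haps in self.counts.items():
            for hap, n in haps.items():
                if n < 0:
                    raise ValueError(f"negative count for {hap!r} in {cell}")
            self.raw_totals.setdefault(cell, sum(haps.values()))

    @property
    def retained_totals(self) -> dict[Cell, int]:
        return {cell: sum(haps.values()) for cell, haps in self.counts.items()}

    @property
    def cells(self) -> list[Cell]:
        return sorted(self.counts)

    @property
    def libraries(self) -> list[str]:
        return sorted({lib for lib, _ in self.counts})

    @property
    def amplicons(self) -> list[str]:
        return sorted({amp for _, amp in self.counts})

    def cell(self, library_id: str, amplicon_id: str) -> dict[str, int]:
        return self.counts.get((library_id, amplicon_id), {})

    def frequencies(self, library_id: str, amplicon_id: str) -> dict[str, float]:
        """Frequencies over the retained total of one cell."""
        haps = self.cell(library_id, amplicon_id)
        total = sum(haps.values())
        if total == 0:
            return {}
        return {h: n / total for h, n in haps.items()}

    def copy(self) -> "HaplotypeTable":
        return HaplotypeTable(
            {cell: dict(haps) for cell, haps in self.counts.items()},
            dict(self.raw_totals),
        )


def count_haplotypes(fragments: Iterable[AssignedFragment]) -> HaplotypeTable:
    """Exact multiset counting of fragments into an unfiltered table."""
    counts: dict[Cell, Counter] = defaultdict(Counter)
    for frag in fragments:
        counts[(frag.library_id, frag.amplicon_id)][frag.haplotype] += 1
    return HaplotypeTable({cell: dict(c) for cell, c in counts.items()})


def apply_frequency_filters(
    table: HaplotypeTable,
    min_freq: float = 0.01,
    presence_mode: str = PRESENCE_AT_THRESHOLD,
    min_samples: int = 2,
) -> HaplotypeTable:
    """Apply the 1% and single-sample rules; idempotent.

    A haplotype is retained in cell (library, amplicon) iff its frequency
    over the cell's raw total is >= min_freq (exactly-threshold haplotypes
    are kept: the exclusion is of haplotypes *below* the threshold), and it
    satisfies the cross-sample presence condition for that amplicon:
    ``at_threshold`` (default) requires frequency >= min_freq in at least
    ``min_samples`` distinct libraries, ``any_count`` requires a nonzero
    count in at least that many libraries.  Leaf libraries count as samples.
    """
    if not 0 < min_freq < 1:
        raise ValueError(f"min_freq must be in (0, 1), got {min_freq}")
    if presence_mode not in (PRESENCE_AT_THRESHOLD, PRESENCE_ANY_COUNT):
        raise ValueError(f"unknown presence_mode {presence_mode!r}")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")

    # libraries in which each (amplicon, haplotype) satisfies the presence test
    presence: dict[tuple[str, str], set[str]] = defaultdict(set)
    for (lib, amp), haps in table.counts.items():
        raw = table.raw_totals[(lib, amp)]
        if raw == 0:
            continue
        for hap, n in haps.items():
            if presence_mode == PRESENCE_ANY_COUNT:
                if n > 0:
                    presence[(amp, hap)].add(lib)
            elif n / raw >= min_freq:
                presence[(amp, hap)].add(lib)

    filtered: dict[Cell, dict[str, int]] = {}
    for (lib, amp), haps in table.counts.items():
        raw = table.raw_totals[(lib, amp)]
        kept = {
            hap: n
            for hap, n in haps.items()
            if raw > 0
            and n / raw >= min_freq
            and len(presence[(amp, hap)]) >= min_samples
        }
        filtered[(lib, amp)] = kept
    return HaplotypeTable(filtered, dict(table.raw_totals))


def filtering_summary(before: HaplotypeTable, after: HaplotypeTable) -> pd.DataFrame:
    """Per-cell retained fractions (fragments surviving the filters)."""
    rows = []
    for cell in before.cells:
        lib, amp = cell
        raw = before.raw_totals[cell]
        retained = sum(after.cell(lib, amp).values())
        rows.append(
            {
                "library_id": lib,
                "amplicon_id": amp,
                "raw_fragments": raw,
                "retained_fragments": retained,
                "retained_fraction": retained / raw if raw else 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "library_id",
            "amplicon_id",
            "raw_fragments",
            "retained_fragments",
            "retained_fraction",
        ],
    )


def table_to_frame(
    table: HaplotypeTable, retained: HaplotypeTable | None = None
) -> pd.DataFrame:
    """Long-format view: library, amplicon, haplotype, count, freq_raw and,
    when a filtered table is supplied, a retained flag."""
    rows = []
    for (lib, amp), haps in sorted(table.counts.items()):
        raw = table.raw_totals[(lib, amp)]
        for hap, n in sorted(haps.items(), key=lambda kv: (-kv[1], kv[0])):
            row = {
                "library_id": lib,
                "amplicon_id": amp,
                "haplotype": hap,
                "count": n,
                "freq_raw": n / raw if raw else 0.0,
            }
            if retained is not None:
                row["retained"] = hap in retained.cell(lib, amp)
            rows.append(row)
    cols = ["library_id", "amplicon_id", "haplotype", "count", "freq_raw"]
    if retained is not None:
        cols.append("retained")
    return pd.DataFrame(rows, columns=cols)


def write_haplotype_table(
    table: HaplotypeTable, path: str | Path, retained: HaplotypeTable | None = None
) -> None:
    table_to_frame(table, retained).to_csv(path, sep="\t", index=False)


def read_haplotype_table(path: str | Path) -> HaplotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"library_id": str, "amplicon_id": str})
    counts: dict[Cell, dict[str, int]] = defaultdict(dict)
    for lib, amp, hap, n in zip(
        df["library_id"], df["amplicon_id"], df["haplotype"], df["count"]
    ):
        counts[(lib, amp)][hap] = int(n)
    return HaplotypeTable(dict(counts))
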