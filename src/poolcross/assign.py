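"""Assignment of read pairs to amplicons by anchored primer matching.

Read 1 is probed for a forward primer variant at position 0, read 2 for a
reverse variant; both mates must name the same amplicon.  Matching is
substitution-only (no indels): the downstream exact-length filter would
discard indel-shifted reads anyway.  After primer removal, heterogeneity-
primed reads keep ``read_length - plain_len - 1`` bases directly; plain-
primed reads keep one base more and are cut by one nucleotide at the 3' end
so both primer versions yield identical lengths.  Any kept read whose length
differs from the expected value is rejected.  The trimmed mates are
concatenated (as sequenced, no reverse-complementing) into one fragment
treated as the haplotype.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, TextIO

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .panel import AmpliconPanel, PrimerVariant

REJECT_NO_FORWARD = "no_forward_match"
REJECT_NO_REVERSE = "no_reverse_match"
REJECT_CONFLICT = "amplicon_conflict"
REJECT_LENGTH = "wrong_length"
REJECT_REASONS = (REJECT_NO_FORWARD, REJECT_NO_REVERSE, REJECT_CONFLICT, REJECT_LENGTH)


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    seq2: str
    qual1: str = ""
    qual2: str = ""


@dataclass(frozen=True)
class AssignedFragment:
    library_id: str
    amplicon_id: str
    haplotype: str


@dataclass
class PrimerMatch:
    amplicon_id: str
    variant: PrimerVariant
    trim_length: int
    mismatches: int


@dataclass
class AssignmentStats:
    """Per-library accounting; rejection reasons partition rejected pairs."""

    library_id: str
    total_pairs: int = 0
    assigned: dict[str, int] = field(default_factory=dict)  # amplicon -> count
    rejected: dict[str, int] = field(default_factory=dict)  # reason -> count

    @property
    def n_assigned(self) -> int:
        return sum(self.assigned.values())

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())

    def check_conservation(self) -> None:
        if self.n_assigned + self.n_rejected != self.total_pairs:
            raise AssertionError(
                f"{self.library_id}: {self.n_assigned} assigned + "
                f"{self.n_rejected} rejected != {self.total_pairs} total"
            )


def _hamming_within(a: str, b: str, limit: int) -> int:
    """Mismatches between equal-length strings, or limit+1 once exceeded."""
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return mism
    return mism


def match_primer(
    read_seq: str,
    variants: Sequence[PrimerVariant],
    max_error_rate: float = 0.1,
) -> Optional[PrimerMatch]:
    """Best anchored primer match at the 5' end of a read.

    The match string (het_base + gene_seq, or gene_seq) is compared to the
    read prefix at position 0, substitutions only; a variant is a hit when
    its mismatch count is at most ``floor(max_error_rate * len(match))``.
    Among hits the fewest mismatches win; ties go to the longer match (het
    over plain), then to panel order.  N bases count as mismatches.
    """
    if not 0 <= max_error_rate < 0.5:
        raise ValueError(f"max_error_rate must be in [0, 0.5), got {max_error_rate}")
    best: Optional[PrimerMatch] = None
    for variant in variants:
        m = variant.match_seq
        if len(read_seq) < len(m):
            continue
        allowed = int(max_error_rate * len(m))
        mism = _hamming_within(read_seq[: len(m)], m, allowed)
        if mism > allowed:
            continue
        if (
            best is None
            or mism < best.mismatches
            or (mism == best.mismatches and len(m) > best.trim_length)
        ):
            best = PrimerMatch(variant.amplicon_id, variant, len(m), mism)
    return best


class _PrefixIndex:
    """Exact-prefix lookup accelerating the common error-free case.

    Keyed on every distinct match-string length present in the panel; a read
    whose prefix hits the dictionary exactly resolves without scanning.  Only
    usable directly when the exact hit is guaranteed to be the overall winner,
    i.e. when no longer variant could match with 0 mismatches too — handled by
    probing lengths longest-first.
    """

    def __init__(self, variants: Sequence[PrimerVariant]):
        self.variants = list(variants)
        self.by_len: dict[int, dict[str, PrimerMatch]] = {}
        for v in variants:
            m = v.match_seq
            self.by_len.setdefault(len(m), {})
            # first panel occurrence wins ties, as in the linear scan
            self.by_len[len(m)].setdefault(
                m, PrimerMatch(v.amplicon_id, v, len(m), 0)
            )
        self.lengths = sorted(self.by_len, reverse=True)

    def match(self, read_seq: str, max_error_rate: float) -> Optional[PrimerMatch]:
        for L in self.lengths:
            hit = self.by_len[L].get(read_seq[:L])
            if hit is not None:
                return hit
        return match_primer(read_seq, self.variants, max_error_rate)


def process_read_pair(
    pair: ReadPair,
    panel: AmpliconPanel,
    max_error_rate: float = 0.1,
    library_id: str = "",
    _fwd_index: Optional[_PrefixIndex] = None,
    _rev_index: Optional[_PrefixIndex] = None,
) -> tuple[Optional[AssignedFragment], Optional[str]]:
    """Assign one read pair; returns (fragment, None) or (None, reason)."""
    fwd = (
        _fwd_index.match(pair.seq1, max_error_rate)
        if _fwd_index
        else match_primer(pair.seq1, panel.variants("forward"), max_error_rate)
    )
    if fwd is None:
        return None, REJECT_NO_FORWARD
    rev = (
        _rev_index.match(pair.seq2, max_error_rate)
        if _rev_index
        else match_primer(pair.seq2, panel.variants("reverse"), max_error_rate)
    )
    if rev is None:
        return None, REJECT_NO_REVERSE
    if fwd.amplicon_id != rev.amplicon_id:
        return None, REJECT_CONFLICT

    amp = fwd.amplicon_id
    kept = []
    for match, seq, direction in ((fwd, pair.seq1, "forward"), (rev, pair.seq2, "reverse")):
        trimmed = seq[match.trim_length :]
        if not match.variant.is_het:
            trimmed = trimmed[:-1] if trimmed else trimmed  # equalize with het reads
        if len(trimmed) != panel.trimmed_length(amp, direction):
            return None, REJECT_LENGTH
        kept.append(trimmed)
    return AssignedFragment(library_id, amp, kept[0] + kept[1]), None


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_read_pairs(fastq1: str | Path, fastq2: str | Path) -> Iterator[ReadPair]:
    """Stream mate pairs from two FASTQ files in lockstep."""
    with _open_text(fastq1) as fh1, _open_text(fastq2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (id1, seq1, q1), (id2, seq2, q2) in zip(it1, it2, strict=True):
            base1 = id1.split()[0].removesuffix("/1")
            base2 = id2.split()[0].removesuffix("/2")
            if base1 != base2:
                raise ValueError(
                    f"desynchronized mates: {id1!r} vs {id2!r}"
                )
            yield ReadPair(base1, seq1.upper(), seq2.upper(), q1, q2)


def assign_library(
    fastq1: str | Path,
    fastq2: str | Path,
    panel: AmpliconPanel,
    library_id: str,
    max_error_rate: float = 0.1,
) -> tuple[list[AssignedFragment], AssignmentStats]:
    """Assign every read pair of one library; totals are conserved."""
    return assign_pairs(
        iter_read_pairs(fastq1, fastq2), panel, library_id, max_error_rate
    )


def assign_pairs(
    pairs: Iterator[ReadPair] | Sequence[ReadPair],
    panel: AmpliconPanel,
    library_id: str,
    max_error_rate: float = 0.1,
) -> tuple[list[AssignedFragment], AssignmentStats]:
    stats = AssignmentStats(library_id)
    fwd_index = _PrefixIndex(panel.variants("forward"))
    rev_index = _PrefixIndex(panel.variants("reverse"))
    fragments: list[AssignedFragment] = []
    for pair in pairs:
        stats.total_pairs += 1
        frag, reason = process_read_pair(
            pair,
            panel,
            max_error_rate,
            library_id,
            _fwd_index=fwd_index,
            _rev_index=rev_index,
        )
        if frag is not None:
            fragments.append(frag)
            stats.assigned[frag.amplicon_id] = stats.assigned.get(frag.amplicon_id, 0) + 1
        else:
            stats.rejected[reason] = stats.rejected.get(reason, 0) + 1
    stats.check_conservation()
    return fragments, stats


def write_assignment_stats(stats_list: Sequence[AssignmentStats], path: str | Path) -> None:
    """Tab-separated per-library report: totals, assigned and rejected counts."""
    import pandas as pd

    rows = []
    for s in stats_list:
        row: dict[str, object] = {
            "library_id": s.library_id,
            "total_pairs": s.total_pairs,
            "assigned": s.n_assigned,
            "assigned_pct": 100.0 * s.n_assigned / s.total_pairs if s.total_pairs else 0.0,
        }
        for reason in REJECT_REASONS:
            row[reason] = s.rejected.get(reason, 0)
        for amp, n in sorted(s.assigned.items()):
            row[f"amplicon_{amp}"] = n
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.2f")
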