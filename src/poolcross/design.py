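"""Conserved-primer panel design from population alignments.

A simplified rendition of the panel-design strategy: scan a multi-genome
alignment of a candidate single-copy gene for invariant windows (no
polymorphism, no gaps, no ambiguity codes) that can serve as primer sites,
screen them by GC content and a Wallace-rule melting temperature, and pick
the forward/reverse window pair that encloses the most polymorphic columns
within the allowed variable-region length.  Emitted primers carry the
adapter tails and alternating A/T heterogeneity variants of the panel
structure.  Wallace's rule (Tm = 2(A+T) + 4(G+C), valid for short
oligonucleotides) stands in for full thermodynamic models, which are out of
scope; single-copy vetting of the input genes is the caller's
responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO

from .panel import AmpliconPanel, PrimerVariant, build_panel
from .simulate import reverse_complement

FLAG_INVARIANT = "invariant"
FLAG_POLYMORPHIC = "polymorphic"
FLAG_GAP_OR_N = "gap_or_n"

# the study's adapter tails (forward 33 nt, reverse 34 nt)
DEFAULT_FORWARD_TAIL = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"
DEFAULT_REVERSE_TAIL = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"


class AlignmentError(ValueError):
    pass


@dataclass
class PopulationAlignment:
    gene_id: str
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise AlignmentError(f"{self.gene_id}: need at least 2 sequences")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"{self.gene_id}: ragged alignment (lengths {sorted(lengths)})")
        allowed = set("ACGT-N")
        for s in self.sequences:
            bad = set(s) - allowed
            if bad:
                raise AlignmentError(f"{self.gene_id}: invalid characters {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])


def read_alignment(path: str | Path, gene_id: Optional[str] = None) -> PopulationAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    return PopulationAlignment(
        gene_id or Path(path).stem, [str(r.seq) for r in records]
    )


def column_variability(alignment: PopulationAlignment) -> list[str]:
    """Per-column flag: invariant (all residues identical and ACGT),
    polymorphic, or gap/N."""
    flags = []
    for j in range(alignment.n_columns):
        column = {s[j] for s in alignment.sequences}
        if column & set("-N"):
            flags.append(FLAG_GAP_OR_N)
        elif len(column) == 1:
            flags.append(FLAG_INVARIANT)
        else:
            flags.append(FLAG_POLYMORPHIC)
    return flags


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature, 2(A+T) + 4(G+C)."""
    at = sum(seq.count(b) for b in "AT")
    gc = sum(seq.count(b) for b in "GC")
    return 2.0 * at + 4.0 * gc


@dataclass(frozen=True)
class PrimerWindow:
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    sequence: str
    tm: float
    gc: float

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        return self.end


def find_primer_windows(
    alignment: PopulationAlignment,
    flags: Optional[Sequence[str]] = None,
    window_len: int = 20,
    gc_bounds: tuple[float, float] = (0.4, 0.6),
    tm_target: float = 55.0,
    tm_tol: float = 5.0,
) -> list[PrimerWindow]:
    """All fully invariant windows of window_len columns whose GC fraction
    and Wallace Tm are within bounds."""
    if flags is None:
        flags = column_variability(alignment)
    ref = alignment.sequences[0]
    windows = []
    invariant_run = 0
    for j in range(alignment.n_columns):
        invariant_run = invariant_run + 1 if flags[j] == FLAG_INVARIANT else 0
        if invariant_run >= window_len:
            start = j - window_len + 1
            seq = ref[start : j + 1]
            gc = sum(seq.count(b) for b in "GC") / window_len
            tm = wallace_tm(seq)
            if gc_bounds[0] <= gc <= gc_bounds[1] and abs(tm - tm_target) <= tm_tol:
                windows.append(PrimerWindow(start, j + 1, seq, tm, gc))
    return windows


@dataclass
class PanelCandidate:
    gene_id: str
    forward_window: PrimerWindow
    reverse_window: PrimerWindow
    variable_region_length: int
    polymorphic_columns: int
    variants: list[PrimerVariant] = field(default_factory=list)


def design_panel(
    alignments: Sequence[PopulationAlignment],
    variable_region_bounds: tuple[int, int] = (300, 400),
    forward_tail: str = DEFAULT_FORWARD_TAIL,
    reverse_tail: str = DEFAULT_REVERSE_TAIL,
    het_bases: Sequence[str] = ("A", "T"),
    window_len: int = 20,
    gc_bounds: tuple[float, float] = (0.4, 0.6),
    tm_target: float = 55.0,
    tm_tol: float = 5.0,
) -> tuple[list[PanelCandidate], list[str]]:
    """For each gene pick the primer-window pair enclosing the most
    polymorphic columns subject to the variable-region length bounds.

    The variable region is the stretch strictly between the two windows.
    The reverse primer is the reverse complement of its window.  Genes with
    no feasible pair are returned in the undesignable list — design can
    fail, as it did for one target of the original panel.  Heterogeneity
    bases alternate A/T across emitted amplicons.
    """
    lo, hi = variable_region_bounds
    candidates: list[PanelCandidate] = []
    undesignable: list[str] = []
    for alignment in alignments:
        flags = column_variability(alignment)
        windows = find_primer_windows(
            alignment, flags, window_len, gc_bounds, tm_target, tm_tol
        )
        poly_prefix = [0]
        for f in flags:
            poly_prefix.append(poly_prefix[-1] + (f == FLAG_POLYMORPHIC))
        best: Optional[tuple[int, PrimerWindow, PrimerWindow, int]] = None
        for fw in windows:
            for rv in windows:
                region = rv.start - fw.end  # columns strictly between windows
                if not lo <= region <= hi:
                    continue
                n_poly = poly_prefix[rv.start] - poly_prefix[fw.end]
                if best is None or n_poly > best[0]:
                    best = (n_poly, fw, rv, region)
        if best is None:
            undesignable.append(alignment.gene_id)
            continue
        n_poly, fw, rv, region = best
        candidates.append(
            PanelCandidate(
                gene_id=alignment.gene_id,
                forward_window=fw,
                reverse_window=rv,
                variable_region_length=region,
                polymorphic_columns=n_poly,
            )
        )
    for i, cand in enumerate(candidates):
        het = het_bases[i % len(het_bases)]
        fwd_seq = cand.forward_window.sequence
        rev_seq = reverse_complement(cand.reverse_window.sequence)
        cand.variants = [
            PrimerVariant(cand.gene_id, "forward", fwd_seq, "", forward_tail),
            PrimerVariant(cand.gene_id, "reverse", rev_seq, "", reverse_tail),
            PrimerVariant(cand.gene_id, "forward", fwd_seq, het, forward_tail),
            PrimerVariant(cand.gene_id, "reverse", rev_seq, het, reverse_tail),
        ]
    return candidates, undesignable


def candidates_to_panel(
    candidates: Sequence[PanelCandidate], read_length: int = 150
) -> AmpliconPanel:
    rows = []
    for cand in candidates:
        for v in cand.variants:
            rows.append(
                {
                    "amplicon_id": v.amplicon_id,
                    "direction": v.direction,
                    "het_base": v.het_base,
                    "tail_seq": v.tail_seq,
                    "gene_seq": v.gene_seq,
                }
            )
    return build_panel(rows, read_length=read_length)
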