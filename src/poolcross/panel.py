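"""Amplicon primer panel and experiment sample sheet.

The panel describes, per amplicon, the gene-specific forward and reverse
primers together with their adapter tails and optional "heterogeneity"
variants — a second primer that carries a single extra A or T between the
tail and the gene-specific sequence, frame-shifting clusters to raise base
diversity during the first sequencing cycles.  The panel is the coordinate
system for read trimming: every read of an amplicon is trimmed back to
``read_length - len(plain gene primer) - 1`` bases regardless of which
primer variant produced it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")

PANEL_COLUMNS = ["amplicon_id", "direction", "het_base", "tail_seq", "gene_seq"]
SHEET_COLUMNS = [
    "library_id",
    "fastq1",
    "fastq2",
    "role",
    "maternal_line",
    "treatment",
    "replicate",
]

ROLE_SEED_POOL = "seed_pool"
ROLE_PARENTAL_LEAF = "parental_leaf"
VALID_ROLES = (ROLE_SEED_POOL, ROLE_PARENTAL_LEAF)


class PanelError(ValueError):
    """Structural problem in a primer panel."""


class SampleSheetError(ValueError):
    """Structural problem in a sample sheet."""


def _clean_seq(seq: str, what: str, allow_empty: bool = False) -> str:
    seq = (seq or "").strip()
    if seq != seq.upper():
        logger.info("upcasing lowercase sequence in %s", what)
        seq = seq.upper()
    if not seq:
        if allow_empty:
            return seq
        raise PanelError(f"{what}: empty sequence")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise PanelError(f"{what}: non-ACGT characters {sorted(bad)!r}")
    return seq


@dataclass(frozen=True)
class PrimerVariant:
    """One primer of the panel: plain, or with a heterogeneity base.

    ``match_seq`` is the string actually searched for at the 5' end of a
    read: the heterogeneity base (if any) followed by the gene-specific
    sequence.  The adapter tail is upstream of the sequencing primer and
    never appears in reads.
    """

    amplicon_id: str
    direction: str  # "forward" | "reverse"
    gene_seq: str
    het_base: str = ""  # "" | "A" | "T"
    tail_seq: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse"):
            raise PanelError(f"bad direction {self.direction!r}")
        object.__setattr__(
            self, "gene_seq", _clean_seq(self.gene_seq, f"{self.amplicon_id} gene_seq")
        )
        if self.het_base not in ("", "A", "T"):
            raise PanelError(
                f"{self.amplicon_id}: het_base must be empty, A or T, got {self.het_base!r}"
            )
        if self.tail_seq:
            object.__setattr__(
                self,
                "tail_seq",
                _clean_seq(self.tail_seq, f"{self.amplicon_id} tail_seq"),
            )

    @property
    def is_het(self) -> bool:
        return bool(self.het_base)

    @property
    def match_seq(self) -> str:
        return self.het_base + self.gene_seq

    @property
    def full_primer(self) -> str:
        """Tail + heterogeneity base + gene-specific sequence, as synthesized."""
        return self.tail_seq + self.het_base + self.gene_seq


@dataclass
class Amplicon:
    amplicon_id: str
    forward: list[PrimerVariant] = field(default_factory=list)
    reverse: list[PrimerVariant] = field(default_factory=list)

    def plain(self, direction: str) -> PrimerVariant:
        for v in getattr(self, direction):
            if not v.is_het:
                return v
        raise PanelError(f"amplicon {self.amplicon_id}: no plain {direction} primer")


@dataclass
class AmpliconPanel:
    """Ordered collection of amplicons with their primer variants."""

    amplicons: list[Amplicon]
    read_length: int = 150

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for amp in self.amplicons:
            if amp.amplicon_id in seen:
                raise PanelError(f"duplicate amplicon_id {amp.amplicon_id!r}")
            seen.add(amp.amplicon_id)
            for direction in ("forward", "reverse"):
                plain = amp.plain(direction)  # raises if absent
                if self.trimmed_length(amp.amplicon_id, direction) <= 0:
                    raise PanelError(
                        f"amplicon {amp.amplicon_id}: {direction} primer of length "
                        f"{len(plain.gene_seq)} leaves no sequence at read length "
                        f"{self.read_length}"
                    )
                keys = set()
                for v in getattr(amp, direction):
                    key = (v.amplicon_id, v.direction, v.het_base)
                    if key in keys:
                        raise PanelError(f"duplicate primer variant {key!r}")
                    keys.add(key)

    @property
    def amplicon_ids(self) -> list[str]:
        return [a.amplicon_id for a in self.amplicons]

    def __getitem__(self, amplicon_id: str) -> Amplicon:
        for a in self.amplicons:
            if a.amplicon_id == amplicon_id:
                return a
        raise KeyError(amplicon_id)

    def variants(self, direction: str) -> list[PrimerVariant]:
        """All variants of one direction, in panel order (het before plain ties
        are irrelevant here; matching resolves priority itself)."""
        out: list[PrimerVariant] = []
        for a in self.amplicons:
            out.extend(getattr(a, direction))
        return out

    def trimmed_length(self, amplicon_id: str, direction: str) -> int:
        """Bases kept per mate: read_length - plain primer length - 1.

        The -1 accounts for the heterogeneity base: a het-primed read loses
        one extra base at its 5' end, and a plain-primed read is cut by one
        base at its 3' end so both variants yield identical lengths.
        """
        plain = self[amplicon_id].plain(direction)
        return self.read_length - len(plain.gene_seq) - 1

    def fragment_length(self, amplicon_id: str) -> int:
        """Expected haplotype fragment length (trimmed read1 + trimmed read2)."""
        return self.trimmed_length(amplicon_id, "forward") + self.trimmed_length(
            amplicon_id, "reverse"
        )

    def subset(self, amplicon_ids: Sequence[str]) -> "AmpliconPanel":
        return AmpliconPanel(
            [self[a] for a in amplicon_ids], read_length=self.read_length
        )


def build_panel(
    rows: Iterable[Mapping[str, str]], read_length: int = 150
) -> AmpliconPanel:
    """Assemble a panel from row mappings with the PANEL_COLUMNS fields."""
    order: list[str] = []
    by_id: dict[str, Amplicon] = {}
    for row in rows:
        amp_id = str(row["amplicon_id"]).strip()
        direction = str(row["direction"]).strip().lower()
        if direction not in ("forward", "reverse"):
            raise PanelError(f"unknown direction {row['direction']!r}")
        het = str(row.get("het_base") or "").strip().upper()
        if het in ("NONE", "-", "."):
            het = ""
        variant = PrimerVariant(
            amplicon_id=amp_id,
            direction=direction,
            gene_seq=str(row["gene_seq"]),
            het_base=het,
            tail_seq=str(row.get("tail_seq") or "").strip(),
        )
        if amp_id not in by_id:
            by_id[amp_id] = Amplicon(amp_id)
            order.append(amp_id)
        bucket = getattr(by_id[amp_id], direction)
        if any(
            (v.amplicon_id, v.direction, v.het_base)
            == (variant.amplicon_id, variant.direction, variant.het_base)
            for v in bucket
        ):
            raise PanelError(
                f"duplicate primer row ({amp_id}, {direction}, het={het or 'none'})"
            )
        bucket.append(variant)
    return AmpliconPanel([by_id[a] for a in order], read_length=read_length)


def parse_primer_panel(path: str | Path, read_length: int = 150) -> AmpliconPanel:
    """Read a tab-separated panel table (columns: amplicon_id, direction,
    het_base, tail_seq, gene_seq)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"panel table missing columns {missing}")
    return build_panel(df.to_dict("records"), read_length=read_length)


def write_primer_panel(panel: AmpliconPanel, path: str | Path) -> None:
    rows = []
    for amp in panel.amplicons:
        for direction in ("forward", "reverse"):
            for v in getattr(amp, direction):
                rows.append(
                    {
                        "amplicon_id": v.amplicon_id,
                        "direction": v.direction,
                        "het_base": v.het_base,
                        "tail_seq": v.tail_seq,
                        "gene_seq": v.gene_seq,
                    }
                )
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def split_full_primer(
    full_primer: str, tail_seq: str, het_bases: Sequence[str] = ("A", "T")
) -> tuple[str, str]:
    """Split a synthesized primer string into (het_base, gene_seq) given the
    known adapter tail.  Returns ("", gene_seq) for a plain primer."""
    full_primer = full_primer.strip().upper()
    tail_seq = tail_seq.strip().upper()
    if not full_primer.startswith(tail_seq):
        raise PanelError("primer does not start with the given tail sequence")
    rest = full_primer[len(tail_seq) :]
    if not rest:
        raise PanelError("primer has no gene-specific part after the tail")
    return "", rest


def load_reference_panel(read_length: int = 150) -> AmpliconPanel:
    """The study's published 12-amplicon *Capsella* panel (plain primers for
    all 12 amplicons; heterogeneity variants for all but amplicon 10)."""
    path = Path(__file__).parent / "data" / "capsella_panel.tsv"
    return parse_primer_panel(path, read_length=read_length)


@dataclass(frozen=True)
class Library:
    library_id: str
    fastq1: str
    fastq2: str
    role: str
    maternal_line: str
    treatment: str = ""
    replicate: str = ""


@dataclass
class SampleSheet:
    libraries: list[Library]

    def __post_init__(self) -> None:
        ids = [lib.library_id for lib in self.libraries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SampleSheetError(f"duplicate library_ids {sorted(dupes)}")
        for lib in self.libraries:
            if lib.role not in VALID_ROLES:
                raise SampleSheetError(
                    f"library {lib.library_id}: unknown role {lib.role!r} "
                    f"(allowed: {', '.join(VALID_ROLES)})"
                )
        if not self.libraries:
            warnings.warn("sample sheet is empty", stacklevel=3)
        leaf_lines = {
            lib.maternal_line for lib in self.libraries if lib.role == ROLE_PARENTAL_LEAF
        }
        orphans = {
            lib.maternal_line
            for lib in self.libraries
            if lib.role == ROLE_SEED_POOL and lib.maternal_line not in leaf_lines
        }
        if orphans:
            warnings.warn(
                f"maternal line(s) {sorted(orphans)} have seed pools but no leaf "
                "library; estimation will require explicit parental haplotypes",
                stacklevel=3,
            )

    @property
    def seed_pools(self) -> list[Library]:
        return [l for l in self.libraries if l.role == ROLE_SEED_POOL]

    @property
    def leaf_libraries(self) -> list[Library]:
        return [l for l in self.libraries if l.role == ROLE_PARENTAL_LEAF]

    def __getitem__(self, library_id: str) -> Library:
        for lib in self.libraries:
            if lib.library_id == library_id:
                return lib
        raise KeyError(library_id)


def parse_sample_sheet(path: str | Path, check_paths: bool = True) -> SampleSheet:
    """Read a tab-separated sample sheet (columns: library_id, fastq1, fastq2,
    role, maternal_line, treatment, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise SampleSheetError(f"sample sheet missing columns {missing}")
    base = Path(path).parent
    libs = []
    for row in df.to_dict("records"):
        fq1, fq2 = row["fastq1"], row["fastq2"]
        if check_paths:
            for fq in (fq1, fq2):
                p = Path(fq)
                if not p.is_absolute():
                    p = base / p
                if not p.exists():
                    raise FileNotFoundError(
                        f"library {row['library_id']}: FASTQ not found: {fq}"
                    )
        libs.append(
            Library(
                library_id=row["library_id"],
                fastq1=fq1,
                fastq2=fq2,
                role=row["role"].strip(),
                maternal_line=row["maternal_line"],
                treatment=row.get("treatment", ""),
                replicate=row.get("replicate", ""),
            )
        )
    return SampleSheet(libs)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    rows = [
        {
            "library_id": l.library_id,
            "fastq1": l.fastq1,
            "fastq2": l.fastq2,
            "role": l.role,
            "maternal_line": l.maternal_line,
            "treatment": l.treatment,
            "replicate": l.replicate,
        }
        for l in sheet.libraries
    ]
    pd.DataFrame(rows, columns=SHEET_COLUMNS).to_csv(path, sep="\t", index=False)
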