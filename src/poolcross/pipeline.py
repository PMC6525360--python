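"""End-to-end orchestration: FASTQ -> haplotype tables -> estimates -> stats.

Every stage writes its intermediate as a tab-separated file so a run is
fully auditable; reruns on the same inputs are byte-identical (there is no
randomness outside the simulator's seeded generator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .assign import AssignmentStats, assign_library, write_assignment_stats
from .estimate import (
    MODE_AUTO,
    OutcrossingEstimate,
    ParentalHaplotypes,
    call_parental_haplotypes,
    estimate_all_libraries,
    estimates_to_frame,
    select_amplicons,
)
from .filtering import (
    HaplotypeTable,
    apply_frequency_filters,
    count_haplotypes,
    filtering_summary,
    write_haplotype_table,
)
from .panel import (
    AmpliconPanel,
    SampleSheet,
    parse_primer_panel,
    parse_sample_sheet,
)
from .stats import run_stats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    panel_path: str = ""
    sheet_path: str = ""
    output_dir: str = "poolcross_out"
    max_error_rate: float = 0.1
    min_freq: float = 0.01
    presence_mode: str = "at_threshold"
    min_samples: int = 2
    min_parent_freq: float = 0.05
    amplicon_subset: Optional[list[str]] = None  # None -> all with data
    selection_method: str = "all"  # all | manual | low_outlier
    nonparental_mode: str = MODE_AUTO
    bonferroni: bool = False

    def __post_init__(self) -> None:
        for name, value, lo, hi in (
            ("max_error_rate", self.max_error_rate, 0.0, 0.5),
            ("min_freq", self.min_freq, 0.0, 1.0),
            ("min_parent_freq", self.min_parent_freq, 0.0, 1.0),
        ):
            if not lo <= value < hi:
                raise ValueError(f"{name}={value} outside [{lo}, {hi})")


@dataclass
class RunResult:
    sheet: SampleSheet
    raw_table: HaplotypeTable
    filtered_table: HaplotypeTable
    parents: ParentalHaplotypes
    estimates: list[OutcrossingEstimate]
    estimates_frame: pd.DataFrame
    stats_report: pd.DataFrame
    assignment_stats: list[AssignmentStats] = field(default_factory=list)


def run_estimate(
    config: RunConfig,
    panel: Optional[AmpliconPanel] = None,
    sheet: Optional[SampleSheet] = None,
    fastq_dir: Optional[str | Path] = None,
) -> RunResult:
    """Run assignment, counting, filtering, parental calling, estimation and
    statistics; write every intermediate under ``config.output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if panel is None:
        panel = parse_primer_panel(config.panel_path)
    if sheet is None:
        sheet = parse_sample_sheet(config.sheet_path, check_paths=False)
    base = Path(fastq_dir) if fastq_dir is not None else Path(config.sheet_path or ".").parent

    fragments = []
    stats_list = []
    for lib in sheet.libraries:
        fq1, fq2 = Path(lib.fastq1), Path(lib.fastq2)
        if not fq1.is_absolute():
            fq1 = base / fq1
        if not fq2.is_absolute():
            fq2 = base / fq2
        frags, stats = assign_library(
            fq1, fq2, panel, lib.library_id, config.max_error_rate
        )
        logger.info(
            "library %s: %d/%d pairs assigned",
            lib.library_id,
            stats.n_assigned,
            stats.total_pairs,
        )
        fragments.extend(frags)
        stats_list.append(stats)
    write_assignment_stats(stats_list, outdir / "assignment_stats.tsv")

    raw = count_haplotypes(fragments)
    filtered = apply_frequency_filters(
        raw,
        min_freq=config.min_freq,
        presence_mode=config.presence_mode,
        min_samples=config.min_samples,
    )
    write_haplotype_table(raw, outdir / "haplotypes_raw.tsv", retained=filtered)
    filtering_summary(raw, filtered).to_csv(
        outdir / "filtering_summary.tsv", sep="\t", index=False
    )

    parents = call_parental_haplotypes(filtered, sheet, config.min_parent_freq)

    subset = config.amplicon_subset
    if subset is None and config.selection_method != "all":
        seed_ids = {l.library_id for l in sheet.seed_pools}
        per_lib = {}
        from .estimate import nonparental_frequency

        for lib in sheet.seed_pools:
            per_lib[lib.library_id] = {
                amp: nonparental_frequency(
                    filtered, parents, lib.library_id, amp, lib.maternal_line
                )
                for amp in filtered.amplicons
            }
        subset = select_amplicons(per_lib, method=config.selection_method)

    estimates = estimate_all_libraries(
        filtered, sheet, parents, subset=subset, mode=config.nonparental_mode
    )
    frame = estimates_to_frame(estimates, sheet)
    frame.to_csv(outdir / "estimates.tsv", sep="\t", index=False)

    report = run_stats(frame, bonferroni=config.bonferroni)
    report.to_csv(outdir / "stats_report.tsv", sep="\t", index=False)

    return RunResult(
        sheet=sheet,
        raw_table=raw,
        filtered_table=filtered,
        parents=parents,
        estimates=estimates,
        estimates_frame=frame,
        stats_report=report,
        assignment_stats=stats_list,
    )
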