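"""Multi-cohort locus selection and end-to-end pipeline orchestration.

A region-event passes selection when all gates hold:

1. primary-cohort Fisher p < ``p_primary`` (default 1e-5);
2. each case batch tested against the primary controls has p < ``p_batch``
   (default 0.05) with the same odds-ratio direction as the primary test;
3. a secondary-cohort region matched by reciprocal overlap > 0.5 has
   p < ``p_secondary`` (default 0.05), again with the same direction.

Direction concordance can be switched off.  Because breakpoint jitter
splits a real locus into a stack of contiguous atomic regions, selected
regions are additionally grouped by contiguity into loci for reporting.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .association import (
    AssociationResult,
    BurdenSummary,
    Direction,
    global_burden_summary,
    test_all_regions,
)
from .caller_filter import CnvnatorFilterParams, filter_calls
from .consensus import (
    AtomicRegion,
    ConsensusCnv,
    CopyState,
    CopyStateMatrix,
    assign_copy_states,
    build_atomic_regions,
    filter_regions_by_repeats,
    merge_all_samples,
)
from .errors import PipelineError, UsageError, ValidationError
from .intervals import GenomicInterval, reciprocal_overlap
from .io_formats import (
    CnvCall,
    Cohort,
    Group,
    SampleSheet,
    read_bed,
    read_calls_tsv,
    read_cnvnator,
    read_sample_sheet,
    write_results_tsv,
)


@dataclass(frozen=True)
class SelectionParams:
    p_primary: float = 1.0e-5
    p_batch: float = 0.05
    p_secondary: float = 0.05
    require_direction_concordance: bool = True
    match_overlap: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.p_secondary <= 1 and 0 < self.p_batch <= 1):
            raise ValidationError("p_secondary and p_batch must be in (0, 1]")
        if self.p_primary > self.p_batch:
            raise ValidationError("p_primary must be <= p_batch")


@dataclass(frozen=True)
class SelectedLocus:
    """One region-event that passed every selection gate."""

    region: AtomicRegion
    event_type: CopyState
    primary: AssociationResult
    batch1: AssociationResult
    batch2: AssociationResult
    secondary: AssociationResult


@dataclass(frozen=True)
class LocusGroup:
    """Contiguous run of selected regions reported as one locus."""

    interval: GenomicInterval
    event_type: CopyState
    members: tuple[SelectedLocus, ...]

    @property
    def min_primary_p(self) -> float:
        return min(m.primary.p_value for m in self.members)

    @property
    def representative(self) -> SelectedLocus:
        return min(self.members, key=lambda m: (m.primary.p_value, m.region.region_id))


def _index(results: Sequence[AssociationResult]):
    return {(r.region.region_id, r.event_type): r for r in results}


def _match_secondary(
    primary: AssociationResult,
    secondary_results: Sequence[AssociationResult],
    min_overlap: float,
) -> Optional[AssociationResult]:
    """Best secondary-cohort result whose region reciprocally overlaps the
    primary region by more than ``min_overlap`` (same event type)."""
    best: Optional[AssociationResult] = None
    best_ro = min_overlap
    for r in secondary_results:
        if r.event_type is not primary.event_type:
            continue
        ro = reciprocal_overlap(primary.region.interval, r.region.interval)
        if ro > best_ro or (
            best is not None
            and ro == best_ro
            and r.region.region_id < best.region.region_id
        ):
            best, best_ro = r, ro
    return best


def _concordant(a: AssociationResult, b: AssociationResult) -> bool:
    return (
        a.direction is not Direction.NULL
        and a.direction is b.direction
    )


def select_loci(
    primary_results: Sequence[AssociationResult],
    batch1_results: Sequence[AssociationResult],
    batch2_results: Sequence[AssociationResult],
    secondary_results: Sequence[AssociationResult],
    params: SelectionParams = SelectionParams(),
) -> list[SelectedLocus]:
    """Apply the multi-cohort gate to every primary result.

    Returns the selected region-events sorted by primary p-value.  A
    primary region with no matching secondary region simply fails the
    validation gate.
    """
    b1 = _index(batch1_results)
    b2 = _index(batch2_results)
    selected: list[SelectedLocus] = []
    for pr in primary_results:
        if not pr.p_value < params.p_primary:
            continue
        key = (pr.region.region_id, pr.event_type)
        r1, r2 = b1.get(key), b2.get(key)
        if r1 is None or r2 is None:
            continue
        if not (r1.p_value < params.p_batch and r2.p_value < params.p_batch):
            continue
        if params.require_direction_concordance and not (
            _concordant(pr, r1) and _concordant(pr, r2)
        ):
            continue
        sec = _match_secondary(pr, secondary_results, params.match_overlap)
        if sec is None or not sec.p_value < params.p_secondary:
            continue
        if params.require_direction_concordance and not _concordant(pr, sec):
            continue
        selected.append(
            SelectedLocus(
                region=pr.region,
                event_type=pr.event_type,
                primary=pr,
                batch1=r1,
                batch2=r2,
                secondary=sec,
            )
        )
    selected.sort(key=lambda s: (s.primary.p_value, s.region.region_id))
    return selected


def group_selected_loci(
    selected: Sequence[SelectedLocus], max_gap: int = 0
) -> list[LocusGroup]:
    """Collapse contiguous selected regions into loci.

    Adjacent atomic regions of the same event type on the same chromosome
    whose gap is <= ``max_gap`` bp are one locus (breakpoint jitter slices
    one true CNV into a stack of touching regions).  Groups are sorted by
    their best primary p-value.
    """
    by_key: dict[tuple[str, CopyState], list[SelectedLocus]] = {}
    for s in selected:
        by_key.setdefault((s.region.interval.chrom, s.event_type), []).append(s)
    groups: list[LocusGroup] = []
    for (chrom, et), items in by_key.items():
        items.sort(key=lambda s: s.region.interval.start)
        run: list[SelectedLocus] = []
        for s in items:
            if run and s.region.interval.start > run[-1].region.interval.end + max_gap:
                groups.append(_make_group(chrom, et, run))
                run = []
            run.append(s)
        if run:
            groups.append(_make_group(chrom, et, run))
    groups.sort(key=lambda g: (g.min_primary_p, g.interval))
    return groups


def _make_group(chrom: str, et: CopyState, run: list[SelectedLocus]) -> LocusGroup:
    return LocusGroup(
        interval=GenomicInterval(
            chrom,
            min(s.region.interval.start for s in run),
            max(s.region.interval.end for s in run),
        ),
        event_type=et,
        members=tuple(run),
    )


# ---------------------------------------------------------------------------
# end-to-end orchestration

@dataclass(frozen=True)
class PipelineParams:
    filter_params: CnvnatorFilterParams = field(default_factory=CnvnatorFilterParams)
    min_overlap: float = 0.5
    min_support: int = 2
    repeat_max_frac: float = 0.5
    min_region_bp: int = 1
    or_correction: str = "haldane"
    selection: SelectionParams = field(default_factory=SelectionParams)
    burden_p_threshold: float = 1.0e-5
    #: selected regions of the same event type closer than this are reported
    #: as one locus; breakpoint jitter scatters a single CNV's boundaries
    #: over tens of bp, leaving sub-significant slivers between significant
    #: regions of the same underlying event
    locus_gap: int = 1000


@dataclass
class PipelineResult:
    sheet: SampleSheet
    consensus_primary: list[ConsensusCnv]
    regions_primary: list[AtomicRegion]
    matrix_primary: CopyStateMatrix
    primary_results: list[AssociationResult]
    batch1_results: list[AssociationResult]
    batch2_results: list[AssociationResult]
    consensus_secondary: list[ConsensusCnv]
    regions_secondary: list[AtomicRegion]
    matrix_secondary: CopyStateMatrix
    secondary_results: list[AssociationResult]
    selected: list[SelectedLocus]
    loci: list[LocusGroup]
    burden: BurdenSummary


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def analyze_cohorts(
    primary_calls: Sequence[CnvCall],
    secondary_calls: Sequence[CnvCall],
    sheet: SampleSheet,
    repeat_track: Sequence[GenomicInterval],
    params: PipelineParams = PipelineParams(),
) -> PipelineResult:
    """Run filter -> merge -> segment -> repeat-filter -> copy states ->
    association (overall and per batch) -> secondary branch -> selection.

    The secondary cohort is analysed with its single-caller calls treated
    as support-1 consensus (merging within the one caller only), matching a
    validation cohort genotyped with the depth-based caller alone.
    """
    with _stage("filter"):
        primary_f = filter_calls(primary_calls, params.filter_params)
        secondary_f = filter_calls(secondary_calls, params.filter_params)

    with _stage("merge"):
        consensus_p = merge_all_samples(
            primary_f, params.min_overlap, params.min_support
        )
        consensus_s = merge_all_samples(secondary_f, params.min_overlap, 1)

    with _stage("segment"):
        regions_p = build_atomic_regions(consensus_p)
        regions_s = build_atomic_regions(consensus_s)
        if params.min_region_bp > 1:
            regions_p = [
                r for r in regions_p if r.interval.length >= params.min_region_bp
            ]
            regions_s = [
                r for r in regions_s if r.interval.length >= params.min_region_bp
            ]

    with _stage("repeat-filter"):
        regions_p = filter_regions_by_repeats(
            regions_p, repeat_track, params.repeat_max_frac
        )
        regions_s = filter_regions_by_repeats(
            regions_s, repeat_track, params.repeat_max_frac
        )

    with _stage("copy-states"):
        primary_ids = sheet.sample_ids(cohort=Cohort.PRIMARY)
        secondary_ids = sheet.sample_ids(cohort=Cohort.SECONDARY)
        matrix_p = assign_copy_states(regions_p, consensus_p, primary_ids)
        matrix_s = assign_copy_states(regions_s, consensus_s, secondary_ids)

    with _stage("associate"):
        cases_p = sheet.sample_ids(Group.CASE, Cohort.PRIMARY)
        controls_p = sheet.sample_ids(Group.CONTROL, Cohort.PRIMARY)
        results_p = test_all_regions(
            matrix_p, sheet, cases_p, controls_p, params.or_correction
        )
        batches = sorted(
            set(
                sheet.frame.loc[
                    (sheet.frame["group"] == Group.CASE.value)
                    & (sheet.frame["cohort"] == Cohort.PRIMARY.value),
                    "batch",
                ]
            )
        )
        if len(batches) >= 2:
            b1_ids = sheet.sample_ids(Group.CASE, Cohort.PRIMARY, batches[0])
            b2_ids = sheet.sample_ids(Group.CASE, Cohort.PRIMARY, batches[1])
            results_b1 = test_all_regions(
                matrix_p, sheet, b1_ids, controls_p, params.or_correction,
                add_q_values=False,
            )
            results_b2 = test_all_regions(
                matrix_p, sheet, b2_ids, controls_p, params.or_correction,
                add_q_values=False,
            )
        else:
            # single-batch design: the batch gates collapse onto the one batch
            results_b1 = results_b2 = results_p

    with _stage("secondary-associate"):
        cases_s = sheet.sample_ids(Group.CASE, Cohort.SECONDARY)
        controls_s = sheet.sample_ids(Group.CONTROL, Cohort.SECONDARY)
        if cases_s and controls_s:
            results_s = test_all_regions(
                matrix_s, sheet, cases_s, controls_s, params.or_correction,
                add_q_values=False,
            )
        else:
            results_s = []

    with _stage("select"):
        selected = select_loci(
            results_p, results_b1, results_b2, results_s, params.selection
        )
        loci = group_selected_loci(selected, max_gap=params.locus_gap)

    with _stage("burden"):
        burden = global_burden_summary(results_p, params.burden_p_threshold)

    return PipelineResult(
        sheet=sheet,
        consensus_primary=consensus_p,
        regions_primary=regions_p,
        matrix_primary=matrix_p,
        primary_results=results_p,
        batch1_results=results_b1,
        batch2_results=results_b2,
        consensus_secondary=consensus_s,
        regions_secondary=regions_s,
        matrix_secondary=matrix_s,
        secondary_results=results_s,
        selected=selected,
        loci=loci,
        burden=burden,
    )


def simulate_and_analyze(config, params: PipelineParams = PipelineParams()):
    """Simulate a cohort under ``config`` and run the full analysis in memory.

    Returns ``(truth, result)``.  The primary cohort gets one callset per
    configured caller; the secondary cohort gets the depth-based caller
    only.  All randomness derives from ``config.seed``.
    """
    from .simulate import derive_seed, emit_caller_calls, simulate_repeat_track, simulate_truth

    truth = simulate_truth(config)
    repeats = simulate_repeat_track(config)
    primary_ids = truth.sheet.sample_ids(cohort=Cohort.PRIMARY)
    secondary_ids = truth.sheet.sample_ids(cohort=Cohort.SECONDARY)
    primary_calls: list[CnvCall] = []
    for k, model in enumerate(config.callers):
        primary_calls.extend(
            emit_caller_calls(
                truth, model, derive_seed(config.seed, 100 + k),
                sample_ids=primary_ids,
            )
        )
    cnv_models = [m for m in config.callers if m.caller_id == "cnvnator"]
    if not cnv_models:
        raise UsageError("config requires a 'cnvnator' caller model")
    secondary_calls = emit_caller_calls(
        truth, cnv_models[0], derive_seed(config.seed, 999),
        sample_ids=secondary_ids,
    )
    result = analyze_cohorts(
        primary_calls, secondary_calls, truth.sheet, repeats, params
    )
    return truth, result


def _write_selected_tsv(selected: Sequence[SelectedLocus], path: Path) -> None:
    cols = [
        "region_id", "chrom", "start", "end", "event_type",
        "primary_p", "primary_or",
        "batch1_p", "batch1_or", "batch2_p", "batch2_or",
        "secondary_region_id", "secondary_p", "secondary_or",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in selected:
            iv = s.region.interval
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        s.region.region_id, iv.chrom, iv.start, iv.end,
                        s.event_type.name,
                        repr(s.primary.p_value), repr(s.primary.odds_ratio),
                        repr(s.batch1.p_value), repr(s.batch1.odds_ratio),
                        repr(s.batch2.p_value), repr(s.batch2.odds_ratio),
                        s.secondary.region.region_id,
                        repr(s.secondary.p_value), repr(s.secondary.odds_ratio),
                    ]
                )
                + "\n"
            )


def _write_loci_tsv(loci: Sequence[LocusGroup], path: Path) -> None:
    cols = [
        "chrom", "start", "end", "event_type", "n_regions",
        "min_primary_p", "primary_or", "secondary_or",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for g in loci:
            rep = g.representative
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        g.interval.chrom, g.interval.start, g.interval.end,
                        g.event_type.name, len(g.members),
                        repr(g.min_primary_p),
                        repr(rep.primary.odds_ratio),
                        repr(rep.secondary.odds_ratio),
                    ]
                )
                + "\n"
            )


def load_fixture(input_dir: str | Path):
    """Read a fixture tree (see :func:`cnvburden.simulate.write_fixture`)."""
    input_dir = Path(input_dir)
    sheet = read_sample_sheet(input_dir / "sample_sheet.tsv")
    repeats = read_bed(input_dir / "repeats.bed")
    primary_calls: list[CnvCall] = []
    for path in sorted((input_dir / "primary").glob("calls_*.tsv")):
        primary_calls.extend(read_calls_tsv(path))
    secondary_calls: list[CnvCall] = []
    sec_dir = input_dir / "secondary"
    if sec_dir.is_dir():
        for path in sorted(sec_dir.glob("*.cnvnator.txt")):
            sample_id = path.name[: -len(".cnvnator.txt")]
            secondary_calls.extend(read_cnvnator(path, sample_id))
    return primary_calls, secondary_calls, sheet, repeats


def run_pipeline(
    input_dir: str | Path,
    outdir: str | Path,
    params: PipelineParams = PipelineParams(),
) -> PipelineResult:
    """File-based end-to-end run: read a fixture tree, analyse, write
    intermediate tables, the selection report and an audit log.

    Outputs are byte-identical across reruns on the same inputs (the audit
    log records parameters and gate counts, never wall-clock times).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    primary_calls, secondary_calls, sheet, repeats = load_fixture(input_dir)
    result = analyze_cohorts(primary_calls, secondary_calls, sheet, repeats, params)

    write_results_tsv(result.primary_results, outdir / "primary_results.tsv")
    write_results_tsv(result.batch1_results, outdir / "batch1_results.tsv")
    write_results_tsv(result.batch2_results, outdir / "batch2_results.tsv")
    write_results_tsv(result.secondary_results, outdir / "secondary_results.tsv")
    with open(outdir / "regions_primary.bed", "w") as fh:
        for r in result.regions_primary:
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.region_id}\n")
    result.matrix_primary.to_long_frame().to_csv(
        outdir / "copy_states_primary.tsv", sep="\t", index=False
    )
    _write_selected_tsv(result.selected, outdir / "selected_regions.tsv")
    _write_loci_tsv(result.loci, outdir / "selected_loci.tsv")

    log = {
        "params": dataclasses.asdict(params),
        "n_primary_calls_in": len(primary_calls),
        "n_secondary_calls_in": len(secondary_calls),
        "n_consensus_primary": len(result.consensus_primary),
        "n_regions_primary": len(result.regions_primary),
        "n_regions_secondary": len(result.regions_secondary),
        "n_primary_results": len(result.primary_results),
        "n_selected_regions": len(result.selected),
        "n_selected_loci": len(result.loci),
        "burden": {
            "n_significant_loss": len(result.burden.loss_ors),
            "n_significant_gain": len(result.burden.gain_ors),
            "median_loss_or": result.burden.median_loss_or,
            "median_gain_or": result.burden.median_gain_or,
            "ranksum_p": result.burden.ranksum_p,
        },
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, sort_keys=True, indent=1)
    return result
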