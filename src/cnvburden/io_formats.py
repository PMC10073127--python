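"""Readers and writers for all on-disk formats.

Formats handled here:

* **BED** (3+ columns, 0-based half-open) — repeat/blacklist tracks such as
  centromeres, telomeres and segmental duplications.
* **CNVnator native text** — whitespace-delimited rows
  ``type  chrom:start-end  length  normalized_RD  e-val1 e-val2 e-val3 e-val4  q0``
  with 1-based fully-closed coordinates; converted to the internal 0-based
  half-open convention on read (start is shifted by -1 exactly once, here).
* **Generic calls TSV** — a flat caller-agnostic dialect (one row per call,
  already 0-based half-open, empty string = missing) used as the
  interchange format for all callers.
* **Sample sheet TSV** — sample -> case/control group, cohort, batch.
* **Results TSV** — per-region association output with a stable column
  order.

All parse failures raise :class:`~cnvburden.errors.ParseError` (naming the
line) or :class:`~cnvburden.errors.SchemaError` (naming the columns); the
writers produce files their paired readers parse back to equal values.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import ParseError, SchemaError, ValidationError
from .intervals import GenomicInterval


class EventType(str, enum.Enum):
    """Direction of a copy-number call: DEL asserts < 2 copies, DUP > 2."""

    DEL = "DEL"
    DUP = "DUP"


class Group(str, enum.Enum):
    CASE = "CASE"
    CONTROL = "CONTROL"


class Cohort(str, enum.Enum):
    PRIMARY = "PRIMARY"
    SECONDARY = "SECONDARY"


#: Caller identifiers the pipeline knows about.  Only "cnvnator" carries
#: quality fields and has call-level filters; the rest are used with their
#: default output, passed through unfiltered.
KNOWN_CALLERS = ("cnvnator", "gatk_gcnv", "delly2", "cnmops", "lumpy")


@dataclass(frozen=True)
class CnvCall:
    """One caller's call for one sample.

    Quality fields (``norm_rd``, ``eval1``..``eval4``, ``q0``) are populated
    for CNVnator calls and ``None`` for callers that do not report them.
    ``norm_rd`` is read depth normalised to the genome average (diploid ~ 1.0);
    ``q0`` is the fraction of zero-mapping-quality reads in the call, in
    [0, 1], or the sentinel -1 meaning undefined.
    """

    sample_id: str
    caller_id: str
    interval: GenomicInterval
    event_type: EventType
    norm_rd: Optional[float] = None
    eval1: Optional[float] = None
    eval2: Optional[float] = None
    eval3: Optional[float] = None
    eval4: Optional[float] = None
    q0: Optional[float] = None

    def __post_init__(self) -> None:
        if self.q0 is not None and self.q0 != -1 and not (0.0 <= self.q0 <= 1.0):
            raise ValidationError(
                f"q0 must be -1 or in [0, 1], got {self.q0} "
                f"({self.sample_id} {self.interval})"
            )
        if self.norm_rd is not None and self.norm_rd < 0:
            raise ValidationError(
                f"norm_rd must be >= 0, got {self.norm_rd} "
                f"({self.sample_id} {self.interval})"
            )


@dataclass
class SampleSheet:
    """Cohort design table: one row per sample.

    ``batch`` is a free string stratifying cases within a cohort (for the
    emulated study design: "batch1"/"batch2" for primary cases, "hc" for
    primary controls, "secondary" for the validation cohort).
    """

    frame: pd.DataFrame = field(repr=False)

    COLUMNS = ("sample_id", "group", "cohort", "batch")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"sample sheet missing columns: {missing}")
        dupes = self.frame["sample_id"][self.frame["sample_id"].duplicated()]
        if len(dupes):
            raise ValidationError(
                f"duplicate sample_id in sample sheet: {sorted(set(dupes))}"
            )
        for col, allowed in (("group", Group), ("cohort", Cohort)):
            bad = set(self.frame[col]) - {m.value for m in allowed}
            if bad:
                raise ValidationError(f"unknown {col} token(s): {sorted(bad)}")
        # a sample may not appear in two cohorts (sample_id is globally unique,
        # so uniqueness above already guarantees this)

    def sample_ids(
        self,
        group: Optional[Group] = None,
        cohort: Optional[Cohort] = None,
        batch: Optional[str] = None,
    ) -> list[str]:
        """Sample ids matching every given stratum filter, in sheet order."""
        f = self.frame
        mask = pd.Series(True, index=f.index)
        if group is not None:
            mask &= f["group"] == group.value
        if cohort is not None:
            mask &= f["cohort"] == cohort.value
        if batch is not None:
            mask &= f["batch"] == batch
        return list(f.loc[mask, "sample_id"])

    def counts(self, cohort: Optional[Cohort] = None) -> dict[str, int]:
        """Case/control counts, optionally within one cohort."""
        return {
            "case": len(self.sample_ids(Group.CASE, cohort)),
            "control": len(self.sample_ids(Group.CONTROL, cohort)),
        }

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# BED

_BED_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3+-column BED file into intervals, order preserved.

    BED is already 0-based half-open so no coordinate shift is applied.
    ``track``/``browser``/comment/blank lines are skipped.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinate in {s!r}/{e!r}"
                ) from exc
            if not (0 <= start < end):
                raise ParseError(
                    f"{path}:{lineno}: invalid BED span {start}-{end} "
                    "(require 0 <= start < end)"
                )
            out.append(GenomicInterval(chrom, start, end))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# CNVnator native dialect

_CNVNATOR_TYPES = {"deletion": EventType.DEL, "duplication": EventType.DUP}


def _parse_cnvnator_coords(token: str, where: str) -> GenomicInterval:
    try:
        chrom, span = token.split(":")
        s, e = span.split("-")
        start1, end1 = int(s), int(e)
    except ValueError as exc:
        raise ParseError(
            f"{where}: coordinate token {token!r} does not match chrom:int-int"
        ) from exc
    if start1 < 1 or end1 < start1:
        raise ParseError(f"{where}: invalid 1-based closed span {token!r}")
    # 1-based fully-closed -> 0-based half-open: shift start only.
    return GenomicInterval(chrom, start1 - 1, end1)


def read_cnvnator(path: str | Path, sample_id: str) -> list[CnvCall]:
    """Parse CNVnator's native whitespace-delimited output for one sample.

    Expected columns: type, coordinates (1-based fully closed), length,
    normalized_RD, e-val1, e-val2, e-val3, e-val4, q0.  All quality fields
    are populated; ``caller_id`` is ``"cnvnator"``.  Filtering is a separate
    stage (:mod:`cnvburden.caller_filter`); this function only parses.
    """
    calls: list[CnvCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            where = f"{path}:{lineno}"
            if len(fields) < 9:
                raise ParseError(f"{where}: expected >= 9 columns, got {len(fields)}")
            type_token = fields[0].lower()
            if type_token not in _CNVNATOR_TYPES:
                raise ParseError(f"{where}: unknown CNV type token {fields[0]!r}")
            interval = _parse_cnvnator_coords(fields[1], where)
            try:
                norm_rd = float(fields[3])
                ev1, ev2, ev3, ev4 = (float(x) for x in fields[4:8])
                q0 = float(fields[8])
            except ValueError as exc:
                raise ParseError(f"{where}: non-numeric quality field") from exc
            calls.append(
                CnvCall(
                    sample_id=sample_id,
                    caller_id="cnvnator",
                    interval=interval,
                    event_type=_CNVNATOR_TYPES[type_token],
                    norm_rd=norm_rd,
                    eval1=ev1,
                    eval2=ev2,
                    eval3=ev3,
                    eval4=ev4,
                    q0=q0,
                )
            )
    return calls


def write_cnvnator(calls: Iterable[CnvCall], path: str | Path) -> None:
    """Write calls in the CNVnator native dialect (1-based closed coords)."""
    rev = {v: k for k, v in _CNVNATOR_TYPES.items()}
    with open(path, "w") as fh:
        for c in calls:
            iv = c.interval
            fh.write(
                "\t".join(
                    [
                        rev[c.event_type],
                        f"{iv.chrom}:{iv.start + 1}-{iv.end}",
                        str(iv.length),
                        repr(c.norm_rd),
                        repr(c.eval1),
                        repr(c.eval2),
                        repr(c.eval3),
                        repr(c.eval4),
                        repr(c.q0),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Generic calls TSV

CALLS_COLUMNS = (
    "sample_id",
    "caller_id",
    "chrom",
    "start",
    "end",
    "event_type",
    "norm_rd",
    "eval1",
    "eval2",
    "eval3",
    "eval4",
    "q0",
)


def _opt_float(token: str) -> Optional[float]:
    return None if token == "" else float(token)


def _fmt_opt(value: Optional[float]) -> str:
    # repr() round-trips IEEE doubles exactly through float()
    return "" if value is None else repr(value)


def read_calls_tsv(path: str | Path) -> list[CnvCall]:
    """Read the generic caller-agnostic calls TSV (0-based half-open)."""
    calls: list[CnvCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return calls
        missing = [c for c in CALLS_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: calls TSV missing columns: {missing}")
        for lineno, row in enumerate(reader, start=2):
            et = row["event_type"]
            if et not in (EventType.DEL.value, EventType.DUP.value):
                raise SchemaError(
                    f"{path}:{lineno}: unsupported event_type {et!r} "
                    "(only DEL/DUP)"
                )
            try:
                interval = GenomicInterval(
                    row["chrom"], int(row["start"]), int(row["end"])
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates: {exc}") from exc
            calls.append(
                CnvCall(
                    sample_id=row["sample_id"],
                    caller_id=row["caller_id"],
                    interval=interval,
                    event_type=EventType(et),
                    norm_rd=_opt_float(row["norm_rd"]),
                    eval1=_opt_float(row["eval1"]),
                    eval2=_opt_float(row["eval2"]),
                    eval3=_opt_float(row["eval3"]),
                    eval4=_opt_float(row["eval4"]),
                    q0=_opt_float(row["q0"]),
                )
            )
    return calls


def write_calls_tsv(calls: Iterable[CnvCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CALLS_COLUMNS)
        for c in calls:
            writer.writerow(
                [
                    c.sample_id,
                    c.caller_id,
                    c.interval.chrom,
                    c.interval.start,
                    c.interval.end,
                    c.event_type.value,
                    _fmt_opt(c.norm_rd),
                    _fmt_opt(c.eval1),
                    _fmt_opt(c.eval2),
                    _fmt_opt(c.eval3),
                    _fmt_opt(c.eval4),
                    _fmt_opt(c.q0),
                ]
            )


# ---------------------------------------------------------------------------
# Sample sheet

def read_sample_sheet(path: str | Path) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SampleSheet.COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: sample sheet missing columns: {missing}")
    return SampleSheet(frame=frame)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False, columns=list(SampleSheet.COLUMNS))


def make_sample_sheet(rows: Sequence[tuple[str, Group, Cohort, str]]) -> SampleSheet:
    """Build a sheet from (sample_id, group, cohort, batch) tuples."""
    frame = pd.DataFrame(
        [(s, g.value, c.value, b) for s, g, c, b in rows],
        columns=list(SampleSheet.COLUMNS),
    )
    return SampleSheet(frame=frame)


# ---------------------------------------------------------------------------
# Results table

RESULTS_COLUMNS = (
    "region_id",
    "chrom",
    "start",
    "end",
    "event_type",
    "a",
    "b",
    "c",
    "d",
    "p_value",
    "odds_ratio",
    "ci_low",
    "ci_high",
    "direction",
    "q_value",
)


def write_results_tsv(results: Iterable, path: str | Path) -> None:
    """Write association results with a stable column order.

    ``results`` is an iterable of :class:`cnvburden.association.AssociationResult`.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(RESULTS_COLUMNS)
        for r in results:
            iv = r.region.interval
            writer.writerow(
                [
                    r.region.region_id,
                    iv.chrom,
                    iv.start,
                    iv.end,
                    r.event_type.value,
                    r.table.a,
                    r.table.b,
                    r.table.c,
                    r.table.d,
                    repr(r.p_value),
                    repr(r.odds_ratio),
                    repr(r.ci_low),
                    repr(r.ci_high),
                    r.direction.value,
                    "" if r.q_value is None else repr(r.q_value),
                ]
            )


__all__ = [
    "EventType",
    "Group",
    "Cohort",
    "KNOWN_CALLERS",
    "CnvCall",
    "SampleSheet",
    "read_bed",
    "write_bed",
    "read_cnvnator",
    "write_cnvnator",
    "read_calls_tsv",
    "write_calls_tsv",
    "CALLS_COLUMNS",
    "read_sample_sheet",
    "write_sample_sheet",
    "make_sample_sheet",
    "write_results_tsv",
    "RESULTS_COLUMNS",
]
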