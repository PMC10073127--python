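"""Per-sample consensus merging, genome segmentation and copy states.

The pipeline stage between raw filtered calls and association testing:

1. :func:`merge_sample_calls` — within one sample and event type, calls
   from different callers whose reciprocal overlap exceeds a threshold
   (default: strictly > 0.5) are clustered transitively (connected
   components).  Each component becomes a consensus CNV whose interval is
   the union span of its members and whose support is the number of
   distinct contributing callers; components below the support floor
   (default 2 callers) are discarded.
2. :func:`build_atomic_regions` — all consensus breakpoints across all
   samples partition the genome into atomic regions: maximal intervals
   within which every sample's copy state is constant.
3. :func:`filter_regions_by_repeats` — regions covered >= 50% (default) by
   centromere/telomere/segmental-duplication track are removed.
4. :func:`assign_copy_states` — each (region, sample) cell becomes
   LOSS / GAIN / NEUTRAL, or CONFLICT when deletion and duplication
   consensus calls both cover the region for that sample.
"""

from __future__ import annotations

import enum
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import UsageError, ValidationError
from .intervals import GenomicInterval, IntervalUnion, reciprocal_overlap
from .io_formats import CnvCall, EventType


@dataclass(frozen=True)
class ConsensusCnv:
    """A per-sample cluster of concordant calls from >= 1 callers."""

    sample_id: str
    event_type: EventType
    interval: GenomicInterval  # union span of the members
    supporting_callers: frozenset[str]
    members: tuple[CnvCall, ...] = field(compare=False)

    @property
    def support(self) -> int:
        return len(self.supporting_callers)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("consensus CNV must have >= 1 member call")
        for m in self.members:
            if m.sample_id != self.sample_id or m.event_type != self.event_type:
                raise ValidationError(
                    "consensus members must share sample_id and event_type"
                )
            if not m.interval.overlaps(self.interval):
                raise ValidationError("consensus member outside union span")


@dataclass(frozen=True)
class AtomicRegion:
    """A maximal interval between consecutive consensus breakpoints."""

    region_id: str
    interval: GenomicInterval


class CopyState(enum.IntEnum):
    NEUTRAL = 0
    LOSS = 1
    GAIN = 2
    CONFLICT = 3


class CopyStateMatrix:
    """Atomic regions x samples grid of copy states.

    The substrate of association testing: ``states[i, j]`` holds the
    :class:`CopyState` of sample ``j`` at region ``i``.  The grid is
    complete; CONFLICT cells are excluded from contingency tables by the
    association stage.
    """

    def __init__(
        self,
        regions: Sequence[AtomicRegion],
        samples: Sequence[str],
        states: np.ndarray,
    ):
        if states.shape != (len(regions), len(samples)):
            raise ValidationError("state grid shape mismatch")
        self.regions = list(regions)
        self.samples = list(samples)
        self.states = states
        self._sample_index = {s: j for j, s in enumerate(self.samples)}
        self._region_index = {r.region_id: i for i, r in enumerate(self.regions)}

    def state(self, region_id: str, sample_id: str) -> CopyState:
        return CopyState(
            self.states[self._region_index[region_id], self._sample_index[sample_id]]
        )

    def sample_columns(self, sample_ids: Sequence[str]) -> np.ndarray:
        try:
            idx = [self._sample_index[s] for s in sample_ids]
        except KeyError as exc:
            raise UsageError(f"sample {exc.args[0]!r} not in matrix") from exc
        return self.states[:, idx]

    def to_long_frame(self):
        """Long-form (region_id, sample_id, state) table for serialisation."""
        import pandas as pd

        rows = np.nonzero(self.states)  # only non-NEUTRAL cells
        return pd.DataFrame(
            {
                "region_id": [self.regions[i].region_id for i in rows[0]],
                "sample_id": [self.samples[j] for j in rows[1]],
                "state": [CopyState(self.states[i, j]).name for i, j in zip(*rows)],
            }
        )


# ---------------------------------------------------------------------------
# merging

class _DisjointSet:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def merge_sample_calls(
    calls: Sequence[CnvCall],
    min_overlap: float = 0.5,
    min_support: int = 2,
) -> list[ConsensusCnv]:
    """Cluster one sample's calls into consensus CNVs.

    Within each event type, two calls are linked when their reciprocal
    overlap is strictly greater than ``min_overlap``; connected components
    become consensus CNVs (interval = union span, support = distinct
    callers).  Components supported by fewer than ``min_support`` callers
    are discarded.  The result is independent of input order.
    """
    if not 0 < min_overlap <= 1:
        raise UsageError(f"min_overlap must be in (0, 1], got {min_overlap}")
    calls = list(calls)
    if not calls:
        return []
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) > 1:
        raise UsageError(
            f"merge_sample_calls operates on one sample, got {sorted(sample_ids)}"
        )

    out: list[ConsensusCnv] = []
    for et in EventType:
        group = sorted(
            (c for c in calls if c.event_type is et),
            key=lambda c: (c.interval, c.caller_id),
        )
        if not group:
            continue
        dsu = _DisjointSet(len(group))
        # sorted by start: only forward neighbours can overlap
        for i, a in enumerate(group):
            for j in range(i + 1, len(group)):
                b = group[j]
                if (
                    b.interval.chrom != a.interval.chrom
                    or b.interval.start >= a.interval.end
                ):
                    break
                if reciprocal_overlap(a.interval, b.interval) > min_overlap:
                    dsu.union(i, j)
        components: dict[int, list[CnvCall]] = {}
        for i, c in enumerate(group):
            components.setdefault(dsu.find(i), []).append(c)
        for members in components.values():
            callers = frozenset(m.caller_id for m in members)
            if len(callers) < min_support:
                continue
            chrom = members[0].interval.chrom
            span = GenomicInterval(
                chrom,
                min(m.interval.start for m in members),
                max(m.interval.end for m in members),
            )
            out.append(
                ConsensusCnv(
                    sample_id=members[0].sample_id,
                    event_type=et,
                    interval=span,
                    supporting_callers=callers,
                    members=tuple(members),
                )
            )
    out.sort(key=lambda c: (c.interval, c.event_type.value))
    return out


def merge_all_samples(
    calls: Iterable[CnvCall],
    min_overlap: float = 0.5,
    min_support: int = 2,
) -> list[ConsensusCnv]:
    """Group a mixed-sample call list by sample and merge each sample."""
    by_sample: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    out: list[ConsensusCnv] = []
    for sid in sorted(by_sample):
        out.extend(merge_sample_calls(by_sample[sid], min_overlap, min_support))
    return out


# ---------------------------------------------------------------------------
# segmentation

def build_atomic_regions(consensus: Iterable[ConsensusCnv]) -> list[AtomicRegion]:
    """Split the consensus footprint at every consensus breakpoint.

    Per chromosome, all start/end positions are pooled and sorted; every
    interval between consecutive boundaries that is covered by at least one
    consensus call becomes an atomic region.  The regions are pairwise
    disjoint, sorted, and their union equals the union of consensus
    intervals exactly (footprint conservation).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c in consensus:
        by_chrom.setdefault(c.interval.chrom, []).append(
            (c.interval.start, c.interval.end)
        )
    regions: list[AtomicRegion] = []
    for chrom in sorted(by_chrom):
        spans = by_chrom[chrom]
        boundaries = sorted({p for s, e in spans for p in (s, e)})
        # sweep: coverage depth between consecutive boundaries
        deltas = dict.fromkeys(boundaries, 0)
        for s, e in spans:
            deltas[s] += 1
            deltas[e] -= 1
        depth = 0
        for lo, hi in zip(boundaries, boundaries[1:]):
            depth += deltas[lo]
            if depth > 0:
                regions.append(
                    AtomicRegion(f"{chrom}:{lo}-{hi}", GenomicInterval(chrom, lo, hi))
                )
    return regions


def filter_regions_by_repeats(
    regions: Sequence[AtomicRegion],
    repeat_track: Iterable[GenomicInterval],
    max_frac: float = 0.5,
) -> list[AtomicRegion]:
    """Drop regions covered >= ``max_frac`` by the (unioned) repeat track."""
    union = IntervalUnion(repeat_track)
    kept = []
    for r in regions:
        if union.covered_length(r.interval) / r.interval.length < max_frac:
            kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# copy states

def assign_copy_states(
    regions: Sequence[AtomicRegion],
    consensus: Iterable[ConsensusCnv] | Mapping[str, Sequence[ConsensusCnv]],
    samples: Sequence[str],
) -> CopyStateMatrix:
    """Assign each (region, sample) cell a copy state.

    ``regions`` must derive from the same consensus set (possibly minus
    repeat-filtered regions), so that every consensus interval covers each
    region entirely or not at all; a partial overlap raises an error.
    LOSS/GAIN mark a covering DEL/DUP consensus, CONFLICT marks both.
    """
    if isinstance(consensus, Mapping):
        flat: list[ConsensusCnv] = [c for v in consensus.values() for c in v]
    else:
        flat = list(consensus)

    sample_index = {s: j for j, s in enumerate(samples)}
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.interval.chrom, []).append(i)
    chrom_starts: dict[str, list[int]] = {}
    chrom_ends: dict[str, list[int]] = {}
    for chrom, idxs in by_chrom.items():
        idxs.sort(key=lambda i: regions[i].interval.start)
        chrom_starts[chrom] = [regions[i].interval.start for i in idxs]
        chrom_ends[chrom] = [regions[i].interval.end for i in idxs]

    loss = np.zeros((len(regions), len(samples)), dtype=bool)
    gain = np.zeros_like(loss)
    for c in flat:
        if c.sample_id not in sample_index:
            continue
        j = sample_index[c.sample_id]
        chrom = c.interval.chrom
        if chrom not in by_chrom:
            continue
        starts, ends = chrom_starts[chrom], chrom_ends[chrom]
        lo = bisect_left(starts, c.interval.start)
        hi = bisect_left(starts, c.interval.end)
        if lo > 0 and ends[lo - 1] > c.interval.start:
            raise ValidationError(
                f"region straddles consensus start at {c.interval}: regions "
                "were not derived from this consensus set"
            )
        if hi > lo and ends[hi - 1] > c.interval.end:
            raise ValidationError(
                f"region straddles consensus end at {c.interval}: regions "
                "were not derived from this consensus set"
            )
        target = loss if c.event_type is EventType.DEL else gain
        for k in range(lo, hi):
            target[by_chrom[chrom][k], j] = True

    states = np.zeros((len(regions), len(samples)), dtype=np.int8)
    states[loss] = CopyState.LOSS
    states[gain] = CopyState.GAIN
    states[loss & gain] = CopyState.CONFLICT
    return CopyStateMatrix(regions, samples, states)


# ---------------------------------------------------------------------------
# serialisation (CLI interchange)

CONSENSUS_COLUMNS = (
    "sample_id",
    "event_type",
    "chrom",
    "start",
    "end",
    "supporting_callers",
)


def write_consensus_tsv(consensus: Iterable[ConsensusCnv], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CONSENSUS_COLUMNS) + "\n")
        for c in consensus:
            iv = c.interval
            fh.write(
                "\t".join(
                    [
                        c.sample_id,
                        c.event_type.value,
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        ",".join(sorted(c.supporting_callers)),
                    ]
                )
                + "\n"
            )


def read_consensus_tsv(path) -> list[ConsensusCnv]:
    """Read consensus rows back for segmentation/state assignment.

    Member calls are not serialised; a placeholder member spanning the
    union interval is synthesised per supporting caller (segmentation and
    copy-state assignment only consult the union span and the caller set).
    """
    import csv as _csv

    from .errors import SchemaError

    out: list[ConsensusCnv] = []
    with open(path, newline="") as fh:
        reader = _csv.DictReader(fh, delimiter="\t")
        missing = [c for c in CONSENSUS_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise SchemaError(f"{path}: consensus TSV missing columns: {missing}")
        for row in reader:
            iv = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
            et = EventType(row["event_type"])
            callers = frozenset(row["supporting_callers"].split(","))
            members = tuple(
                CnvCall(
                    sample_id=row["sample_id"],
                    caller_id=cid,
                    interval=iv,
                    event_type=et,
                )
                for cid in sorted(callers)
            )
            out.append(
                ConsensusCnv(
                    sample_id=row["sample_id"],
                    event_type=et,
                    interval=iv,
                    supporting_callers=callers,
                    members=members,
                )
            )
    return out
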