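"""Synthetic cohorts and noisy multi-caller callsets.

The generator emulates the structure the analysis assumes, so that every
downstream stage can be exercised without any real data:

* a **primary cohort** of 310 cases (210 in batch 1, 100 in batch 2) and
  100 controls, plus an independent **secondary cohort** of 100 cases and
  100 controls analysed with the depth-based caller only;
* **planted loci** — case/control-differentiated CNVs carried as
  heterozygous one-copy losses (normalised read depth centred at 0.5) or
  one-copy gains (1.5), with per-group carrier probabilities.  The default
  plant is three risk deletions at ~50% carrier frequency in cases vs 15%
  in controls, the regime of a strong common risk locus;
* **background CNVs** — group-independent events per sample (Poisson
  count, log-normal lengths), giving a built-in null for type-I-error
  checks;
* **imperfect callers** — each true event is detected with a per-caller
  sensitivity, breakpoints get independent Gaussian jitter, false calls
  arrive as a Poisson stream, and the depth-based caller's quality fields
  (normalised read depth, e-values, q0) are drawn so its call-level
  filters remove a realistic share of false positives;
* a **repeat track** (telomere stubs at both chromosome ends, one central
  centromere block, random segmental-duplication blocks) covering a
  configured fraction of each chromosome and never overlapping planted
  loci.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ConfigError
from .intervals import GenomicInterval
from .io_formats import (
    CnvCall,
    Cohort,
    EventType,
    Group,
    SampleSheet,
    make_sample_sheet,
    write_bed,
    write_calls_tsv,
    write_cnvnator,
    write_sample_sheet,
)

DEFAULT_CHROM_LENGTHS = {"chr1": 5_000_000, "chr2": 5_000_000}

_MIN_EVENT_BP = 50
_PLACEMENT_TRIES = 1000


def derive_seed(base: int, stream: int) -> int:
    """A stable 31-bit stream seed derived from a base seed."""
    return (int(base) * 1_000_003 + stream) % (2**31)


@dataclass(frozen=True)
class PlantedLocus:
    """A case/control-differentiated CNV locus with carrier probabilities."""

    interval: GenomicInterval
    event_type: EventType
    case_freq: float
    control_freq: float

    def __post_init__(self) -> None:
        for f in (self.case_freq, self.control_freq):
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"carrier frequency {f} outside [0, 1]")


@dataclass(frozen=True)
class CallerModel:
    """Noise characteristics of one simulated caller.

    ``emits_quality`` marks the depth-based caller whose output carries
    normalised read depth, e-values and q0; other callers emit bare
    interval calls.  E-values for true calls are drawn uniformly below
    ``eval_scale``; false calls draw large e-values with probability 0.5,
    so the e-value filter removes about half of them.
    """

    caller_id: str
    sensitivity: float = 0.9
    fp_rate: float = 1.0
    jitter_sd: float = 20.0
    rd_loss_mean: float = 0.5
    rd_loss_sd: float = 0.05
    rd_gain_mean: float = 1.5
    rd_gain_sd: float = 0.10
    q0_alpha: float = 1.0
    q0_beta: float = 19.0
    eval_scale: float = 1.0e-4
    emits_quality: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ConfigError(f"sensitivity {self.sensitivity} outside [0, 1]")
        if self.fp_rate < 0 or self.jitter_sd < 0:
            raise ConfigError("fp_rate and jitter_sd must be >= 0")
        if min(self.rd_loss_sd, self.rd_gain_sd) < 0:
            raise ConfigError("read-depth sds must be >= 0")


def default_caller_models(
    sensitivity: float = 0.9, fp_rate: float = 1.0, jitter_sd: float = 20.0
) -> list[CallerModel]:
    """The five-caller ensemble used throughout: one depth-based caller
    with quality fields plus four generic callers."""
    kw = dict(sensitivity=sensitivity, fp_rate=fp_rate, jitter_sd=jitter_sd)
    return [
        CallerModel(caller_id="cnvnator", emits_quality=True, **kw),
        CallerModel(caller_id="gatk_gcnv", **kw),
        CallerModel(caller_id="delly2", **kw),
        CallerModel(caller_id="cnmops", **kw),
        CallerModel(caller_id="lumpy", **kw),
    ]


# fixed, well-separated locus slots (chrom, fractional position), avoiding
# the simulated telomere ends and the central centromere block
_LOCUS_SLOTS = [
    ("chr1", 0.12), ("chr2", 0.14), ("chr1", 0.20), ("chr2", 0.22),
    ("chr1", 0.28), ("chr2", 0.30), ("chr1", 0.36), ("chr2", 0.38),
    ("chr1", 0.60), ("chr2", 0.62), ("chr1", 0.68), ("chr2", 0.70),
    ("chr1", 0.76), ("chr2", 0.78), ("chr1", 0.84), ("chr2", 0.86),
]
_LOCUS_LENGTHS = (1331, 2000, 1500, 1800, 1200, 2400)


def _slot_locus(
    slot: int,
    event_type: EventType,
    case_freq: float,
    control_freq: float,
    chrom_lengths: dict[str, int],
) -> PlantedLocus:
    chrom, frac = _LOCUS_SLOTS[slot % len(_LOCUS_SLOTS)]
    length = _LOCUS_LENGTHS[slot % len(_LOCUS_LENGTHS)]
    start = int(frac * chrom_lengths[chrom])
    return PlantedLocus(
        GenomicInterval(chrom, start, start + length),
        event_type,
        case_freq,
        control_freq,
    )


def default_risk_deletions(
    n: int = 3,
    case_freq: float = 0.5,
    control_freq: float = 0.15,
    chrom_lengths: dict[str, int] = DEFAULT_CHROM_LENGTHS,
) -> list[PlantedLocus]:
    """Risk deletion loci: ~50% case carriers vs 15% control carriers,
    kilobase-scale, the regime of a common small genomic deletion."""
    return [
        _slot_locus(i, EventType.DEL, case_freq, control_freq, chrom_lengths)
        for i in range(n)
    ]


def default_protective_gains(
    n: int = 6,
    case_freq: float = 0.05,
    control_freq: float = 0.30,
    chrom_lengths: dict[str, int] = DEFAULT_CHROM_LENGTHS,
) -> list[PlantedLocus]:
    """Protective duplication loci (depleted in cases), placed on slots
    disjoint from the default risk deletions."""
    return [
        _slot_locus(6 + i, EventType.DUP, case_freq, control_freq, chrom_lengths)
        for i in range(n)
    ]


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    n_case_batch1: int = 210
    n_case_batch2: int = 100
    n_control_primary: int = 100
    n_case_secondary: int = 100
    n_control_secondary: int = 100
    planted: tuple[PlantedLocus, ...] = ()
    background_rate: float = 3.0
    background_len_logmean: float = float(np.log(2000.0))
    background_len_logsd: float = 0.6
    repeat_fraction: float = 0.05
    callers: tuple[CallerModel, ...] = ()

    def __post_init__(self) -> None:
        counts = (
            self.n_case_batch1,
            self.n_case_batch2,
            self.n_control_primary,
            self.n_case_secondary,
            self.n_control_secondary,
        )
        if any(c < 0 for c in counts):
            raise ConfigError("cohort counts must be >= 0")
        if self.background_rate < 0:
            raise ConfigError("background_rate must be >= 0")
        if not 0.0 <= self.repeat_fraction <= 0.5:
            raise ConfigError("repeat_fraction must be in [0, 0.5]")
        loci = list(self.planted)
        for locus in loci:
            L = self.chrom_lengths.get(locus.interval.chrom)
            if L is None or locus.interval.end > L:
                raise ConfigError(
                    f"planted locus {locus.interval} outside chromosome bounds"
                )
        for i, a in enumerate(loci):
            for b in loci[i + 1:]:
                if a.interval.overlaps(b.interval):
                    raise ConfigError(
                        f"planted loci overlap: {a.interval} and {b.interval}"
                    )


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The study-design configuration: 210+100 primary cases / 100 primary
    controls, 100/100 secondary, three planted risk deletions, five
    imperfect callers."""
    chrom_lengths = overrides.pop("chrom_lengths", dict(DEFAULT_CHROM_LENGTHS))
    if "planted" not in overrides:
        overrides["planted"] = tuple(
            default_risk_deletions(chrom_lengths=chrom_lengths)
        )
    if "callers" not in overrides:
        overrides["callers"] = tuple(default_caller_models())
    return SimulationConfig(seed=seed, chrom_lengths=chrom_lengths, **overrides)


@dataclass(frozen=True)
class TrueCnv:
    """One true CNV carried by one simulated sample."""

    sample_id: str
    interval: GenomicInterval
    event_type: EventType
    origin: str  # "planted" | "background"
    locus_index: Optional[int] = None


@dataclass
class SimulatedTruth:
    events: list[TrueCnv]
    sheet: SampleSheet
    config: SimulationConfig

    def events_by_sample(self) -> dict[str, list[TrueCnv]]:
        out: dict[str, list[TrueCnv]] = {s: [] for s in self.sheet.frame["sample_id"]}
        for e in self.events:
            out[e.sample_id].append(e)
        return out

    def carriers(self, locus_index: int) -> set[str]:
        return {
            e.sample_id for e in self.events if e.locus_index == locus_index
        }


def _build_sheet(config: SimulationConfig) -> SampleSheet:
    rows = []
    for i in range(config.n_case_batch1):
        rows.append((f"case_b1_{i:04d}", Group.CASE, Cohort.PRIMARY, "batch1"))
    for i in range(config.n_case_batch2):
        rows.append((f"case_b2_{i:04d}", Group.CASE, Cohort.PRIMARY, "batch2"))
    for i in range(config.n_control_primary):
        rows.append((f"hc_{i:04d}", Group.CONTROL, Cohort.PRIMARY, "hc"))
    for i in range(config.n_case_secondary):
        rows.append((f"sec_case_{i:04d}", Group.CASE, Cohort.SECONDARY, "secondary"))
    for i in range(config.n_control_secondary):
        rows.append((f"sec_hc_{i:04d}", Group.CONTROL, Cohort.SECONDARY, "secondary"))
    return make_sample_sheet(rows)


def _pick_chrom(rng: np.random.Generator, chrom_lengths: dict[str, int]) -> str:
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    return chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]


def _place_event(
    rng: np.random.Generator,
    config: SimulationConfig,
    length: int,
    avoid: Sequence[GenomicInterval],
) -> GenomicInterval:
    for _ in range(_PLACEMENT_TRIES):
        chrom = _pick_chrom(rng, config.chrom_lengths)
        L = config.chrom_lengths[chrom]
        if length >= L:
            continue
        start = int(rng.integers(0, L - length))
        iv = GenomicInterval(chrom, start, start + length)
        if not any(iv.overlaps(o) for o in avoid):
            return iv
    raise ConfigError(
        "could not place a background event without overlap after "
        f"{_PLACEMENT_TRIES} tries (genome too crowded)"
    )


def simulate_truth(config: SimulationConfig) -> SimulatedTruth:
    """Draw true per-sample CNV events and the cohort sample sheet.

    Each sample carries each planted locus independently with its group's
    carrier probability; background events are placed uniformly with
    log-normal lengths and resampled on overlap with any planted locus or
    with the same sample's existing events.  Deterministic given the seed.
    """
    sheet = _build_sheet(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    planted_ivs = [p.interval for p in config.planted]
    events: list[TrueCnv] = []
    for _, row in sheet.frame.iterrows():
        sid, group = row["sample_id"], row["group"]
        sample_ivs: list[GenomicInterval] = []
        for idx, locus in enumerate(config.planted):
            p = locus.case_freq if group == Group.CASE.value else locus.control_freq
            if rng.random() < p:
                events.append(
                    TrueCnv(sid, locus.interval, locus.event_type, "planted", idx)
                )
                sample_ivs.append(locus.interval)
        n_bg = int(rng.poisson(config.background_rate))
        for _ in range(n_bg):
            length = max(
                _MIN_EVENT_BP,
                int(
                    round(
                        rng.lognormal(
                            config.background_len_logmean,
                            config.background_len_logsd,
                        )
                    )
                ),
            )
            iv = _place_event(rng, config, length, planted_ivs + sample_ivs)
            et = EventType.DEL if rng.random() < 0.5 else EventType.DUP
            events.append(TrueCnv(sid, iv, et, "background"))
            sample_ivs.append(iv)
    return SimulatedTruth(events=events, sheet=sheet, config=config)


def simulate_repeat_track(config: SimulationConfig) -> list[GenomicInterval]:
    """Simulate centromere/telomere/segmental-duplication intervals.

    Per chromosome the track always contains a telomere block at each end
    and one central centromere block (1 bp stubs when repeat_fraction is
    0); the remaining budget is filled with randomly placed
    segmental-duplication blocks, the last one trimmed so total coverage
    equals ``repeat_fraction`` of the chromosome exactly.  No interval
    overlaps a planted locus.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    planted_ivs = [p.interval for p in config.planted]
    track: list[GenomicInterval] = []
    for chrom in sorted(config.chrom_lengths):
        L = config.chrom_lengths[chrom]
        target = int(round(config.repeat_fraction * L))
        tel = max(1, int(round(0.1 * target)))
        cen = max(1, int(round(0.3 * target)))
        cen_start = (L - cen) // 2
        forced = [
            GenomicInterval(chrom, 0, tel),
            GenomicInterval(chrom, L - tel, L),
            GenomicInterval(chrom, cen_start, cen_start + cen),
        ]
        for block in forced:
            if any(block.overlaps(p) for p in planted_ivs):
                raise ConfigError(
                    f"repeat_fraction {config.repeat_fraction} places mandatory "
                    f"repeat block {block} over a planted locus"
                )
        placed = list(forced)
        remaining = target - 2 * tel - cen
        while remaining > 0:
            blen = int(min(remaining, rng.integers(2000, 30001)))
            ok = False
            for _ in range(_PLACEMENT_TRIES):
                start = int(rng.integers(tel, L - tel - blen))
                block = GenomicInterval(chrom, start, start + blen)
                if not any(block.overlaps(x) for x in placed + planted_ivs):
                    placed.append(block)
                    remaining -= blen
                    ok = True
                    break
            if not ok:
                raise ConfigError(
                    "could not place segmental-duplication blocks at "
                    f"repeat_fraction {config.repeat_fraction}"
                )
        track.extend(placed)
    track.sort()
    return track


def emit_caller_calls(
    truth: SimulatedTruth,
    caller_model: CallerModel,
    seed: int,
    sample_ids: Optional[Sequence[str]] = None,
) -> list[CnvCall]:
    """One caller's noisy callset over the truth.

    Each true event is detected with probability ``sensitivity``; detected
    breakpoints get independent rounded Gaussian jitter (clamped to keep
    start < end and stay on the chromosome).  False positives arrive
    Poisson(``fp_rate``) per sample at uniform positions.  Quality fields
    are drawn only for quality-emitting callers.  Deterministic given the
    seed.
    """
    config = truth.config
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    by_sample = truth.events_by_sample()
    wanted = list(sample_ids) if sample_ids is not None else list(by_sample)
    calls: list[CnvCall] = []

    def jitter(iv: GenomicInterval) -> GenomicInterval:
        L = config.chrom_lengths[iv.chrom]
        if caller_model.jitter_sd > 0:
            s = iv.start + int(round(rng.normal(0.0, caller_model.jitter_sd)))
            e = iv.end + int(round(rng.normal(0.0, caller_model.jitter_sd)))
        else:
            s, e = iv.start, iv.end
        s = min(max(s, 0), L - 1)
        e = max(e, s + 1)
        e = min(e, L)
        s = min(s, e - 1)
        return GenomicInterval(iv.chrom, s, e)

    def quality(event_type: EventType, is_fp: bool) -> dict:
        if not caller_model.emits_quality:
            return {}
        if event_type is EventType.DEL:
            rd = max(0.0, rng.normal(caller_model.rd_loss_mean, caller_model.rd_loss_sd))
        else:
            rd = max(0.0, rng.normal(caller_model.rd_gain_mean, caller_model.rd_gain_sd))
        q0 = float(rng.beta(caller_model.q0_alpha, caller_model.q0_beta))
        if is_fp and rng.random() < 0.5:
            evs = rng.uniform(1e-2, 1.0, size=4)
        else:
            evs = rng.uniform(0.0, caller_model.eval_scale, size=4)
        return {
            "norm_rd": float(rd),
            "eval1": float(evs[0]),
            "eval2": float(evs[1]),
            "eval3": float(evs[2]),
            "eval4": float(evs[3]),
            "q0": q0,
        }

    for sid in wanted:
        for ev in by_sample[sid]:
            if rng.random() >= caller_model.sensitivity:
                continue
            calls.append(
                CnvCall(
                    sample_id=sid,
                    caller_id=caller_model.caller_id,
                    interval=jitter(ev.interval),
                    event_type=ev.event_type,
                    **quality(ev.event_type, is_fp=False),
                )
            )
        for _ in range(int(rng.poisson(caller_model.fp_rate))):
            length = max(
                _MIN_EVENT_BP,
                int(
                    round(
                        rng.lognormal(
                            config.background_len_logmean,
                            config.background_len_logsd,
                        )
                    )
                ),
            )
            iv = _place_event(rng, config, length, [])
            et = EventType.DEL if rng.random() < 0.5 else EventType.DUP
            calls.append(
                CnvCall(
                    sample_id=sid,
                    caller_id=caller_model.caller_id,
                    interval=iv,
                    event_type=et,
                    **quality(et, is_fp=True),
                )
            )
    return calls


def _config_to_jsonable(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)


def write_fixture(config: SimulationConfig, outdir: str | Path) -> dict:
    """Materialise a complete on-disk fixture for the pipeline.

    Layout::

        outdir/
          sample_sheet.tsv
          repeats.bed
          primary/calls_<caller>.tsv      one per caller, primary cohort
          secondary/<sample>.cnvnator.txt one per secondary-cohort sample
          manifest.json                   seed, config echo, truth table

    The secondary cohort gets depth-caller output only, mirroring a
    validation cohort genotyped with a single caller.  Returns the
    manifest dict.
    """
    outdir = Path(outdir)
    (outdir / "primary").mkdir(parents=True, exist_ok=True)
    (outdir / "secondary").mkdir(parents=True, exist_ok=True)

    truth = simulate_truth(config)
    repeats = simulate_repeat_track(config)
    sheet = truth.sheet
    write_sample_sheet(sheet, outdir / "sample_sheet.tsv")
    write_bed(repeats, outdir / "repeats.bed")

    primary_ids = sheet.sample_ids(cohort=Cohort.PRIMARY)
    secondary_ids = sheet.sample_ids(cohort=Cohort.SECONDARY)

    for k, model in enumerate(config.callers):
        calls = emit_caller_calls(
            truth, model, derive_seed(config.seed, 100 + k), sample_ids=primary_ids
        )
        write_calls_tsv(calls, outdir / "primary" / f"calls_{model.caller_id}.tsv")

    cnvnator_models = [m for m in config.callers if m.caller_id == "cnvnator"]
    if not cnvnator_models:
        raise ConfigError("fixture requires a 'cnvnator' caller model")
    sec_calls = emit_caller_calls(
        truth, cnvnator_models[0], derive_seed(config.seed, 999),
        sample_ids=secondary_ids,
    )
    by_sample: dict[str, list[CnvCall]] = {s: [] for s in secondary_ids}
    for c in sec_calls:
        by_sample[c.sample_id].append(c)
    for sid in secondary_ids:
        write_cnvnator(by_sample[sid], outdir / "secondary" / f"{sid}.cnvnator.txt")

    manifest = {
        "seed": config.seed,
        "config": _config_to_jsonable(config),
        "truth": [
            {
                "sample_id": e.sample_id,
                "chrom": e.interval.chrom,
                "start": e.interval.start,
                "end": e.interval.end,
                "event_type": e.event_type.value,
                "origin": e.origin,
                "locus_index": e.locus_index,
            }
            for e in truth.events
        ],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return manifest


def perfect_caller_models(n: int = 5) -> list[CallerModel]:
    """Noiseless caller ensemble: sensitivity 1, no jitter, no false calls.

    In this limit the downstream consensus set must equal truth exactly.
    """
    ids = ["cnvnator", "gatk_gcnv", "delly2", "cnmops", "lumpy"][:n]
    return [
        CallerModel(
            caller_id=cid,
            sensitivity=1.0,
            fp_rate=0.0,
            jitter_sd=0.0,
            rd_loss_sd=0.0,
            rd_gain_sd=0.0,
            emits_quality=(cid == "cnvnator"),
        )
        for cid in ids
    ]
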