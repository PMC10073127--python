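import json

import numpy as np
import pytest
from scipy.stats import binom, poisson

from cnvburden.errors import ConfigError
from cnvburden.intervals import GenomicInterval
from cnvburden.io_formats import Cohort, EventType, Group
from cnvburden.simulate import (
    CallerModel,
    PlantedLocus,
    SimulationConfig,
    default_caller_models,
    default_config,
    default_risk_deletions,
    derive_seed,
    emit_caller_calls,
    simulate_repeat_track,
    simulate_truth,
    write_fixture,
)


def small_config(**overrides):
    overrides.setdefault("n_case_batch1", 20)
    overrides.setdefault("n_case_batch2", 10)
    overrides.setdefault("n_control_primary", 10)
    overrides.setdefault("n_case_secondary", 10)
    overrides.setdefault("n_control_secondary", 10)
    overrides.setdefault("background_rate", 1.0)
    return default_config(**overrides)


class TestTruth:
    def test_degenerate_frequencies(self):
        loci = (
            PlantedLocus(GenomicInterval("chr1", 600_000, 601_331),
                         EventType.DEL, 1.0, 0.0),
        )
        truth = simulate_truth(small_config(seed=3, planted=loci))
        carriers = truth.carriers(0)
        cases = set(truth.sheet.sample_ids(Group.CASE))
        controls = set(truth.sheet.sample_ids(Group.CONTROL))
        assert carriers == cases
        assert carriers & controls == set()

    def test_same_seed_identical_truth(self):
        a = simulate_truth(small_config(seed=5))
        b = simulate_truth(small_config(seed=5))
        assert a.events == b.events
        assert a.sheet.frame.equals(b.sheet.frame)
        c = simulate_truth(small_config(seed=6))
        assert c.events != a.events

    def test_carrier_counts_within_binomial_bounds(self):
        # case_freq 0.5 over 310 primary cases: central 99.9% binomial band
        cfg = default_config(seed=9)
        truth = simulate_truth(cfg)
        primary_cases = set(truth.sheet.sample_ids(Group.CASE, Cohort.PRIMARY))
        lo, hi = binom.ppf([0.0005, 0.9995], 310, 0.5)
        for idx in range(len(cfg.planted)):
            n = len(truth.carriers(idx) & primary_cases)
            assert lo <= n <= hi

    def test_background_events_avoid_planted_loci_and_each_other(self):
        cfg = small_config(seed=13, background_rate=4.0)
        truth = simulate_truth(cfg)
        planted = [p.interval for p in cfg.planted]
        for sid, events in truth.events_by_sample().items():
            bg = [e.interval for e in events if e.origin == "background"]
            for b in bg:
                assert not any(b.overlaps(p) for p in planted)
            for i, x in enumerate(bg):
                assert not any(x.overlaps(y) for y in bg[i + 1:])

    def test_out_of_bounds_locus_rejected(self):
        bad = (
            PlantedLocus(GenomicInterval("chr1", 4_999_000, 5_001_000),
                         EventType.DEL, 0.5, 0.1),
        )
        with pytest.raises(ConfigError, match="bounds"):
            small_config(planted=bad)

    def test_overlapping_planted_loci_rejected(self):
        loci = (
            PlantedLocus(GenomicInterval("chr1", 600_000, 601_331),
                         EventType.DEL, 0.5, 0.1),
            PlantedLocus(GenomicInterval("chr1", 601_000, 602_000),
                         EventType.DUP, 0.5, 0.1),
        )
        with pytest.raises(ConfigError, match="overlap"):
            small_config(planted=loci)


class TestEmit:
    def test_noiseless_limit_reproduces_truth(self):
        cfg = small_config(seed=21)
        truth = simulate_truth(cfg)
        model = CallerModel("delly2", sensitivity=1.0, fp_rate=0.0, jitter_sd=0.0)
        calls = emit_caller_calls(truth, model, seed=1)
        expected = {(e.sample_id, e.interval, e.event_type) for e in truth.events}
        got = {(c.sample_id, c.interval, c.event_type) for c in calls}
        assert got == expected

    def test_zero_sensitivity_empty_callset(self):
        cfg = small_config(seed=21)
        truth = simulate_truth(cfg)
        model = CallerModel("delly2", sensitivity=0.0, fp_rate=0.0)
        assert emit_caller_calls(truth, model, seed=1) == []

    def test_false_positive_count_within_poisson_bounds(self):
        cfg = small_config(seed=22, n_case_batch1=100, n_case_batch2=0,
                           n_control_primary=0, n_case_secondary=0,
                           n_control_secondary=0, background_rate=0.0,
                           planted=())
        truth = simulate_truth(cfg)
        model = CallerModel("delly2", sensitivity=1.0, fp_rate=2.0)
        calls = emit_caller_calls(truth, model, seed=2)
        lo, hi = poisson.ppf([0.0005, 0.9995], 100 * 2.0)
        assert lo <= len(calls) <= hi

    def test_quality_fields_only_for_depth_caller(self):
        cfg = small_config(seed=23)
        truth = simulate_truth(cfg)
        plain = emit_caller_calls(
            truth, CallerModel("delly2", fp_rate=0.0), seed=3
        )
        rich = emit_caller_calls(
            truth, CallerModel("cnvnator", emits_quality=True, fp_rate=0.0), seed=3
        )
        assert all(c.norm_rd is None and c.q0 is None for c in plain)
        assert all(c.norm_rd is not None and c.q0 is not None for c in rich)
        # deletions centred at one-copy depth, duplications above diploid
        dels = [c.norm_rd for c in rich if c.event_type is EventType.DEL]
        dups = [c.norm_rd for c in rich if c.event_type is EventType.DUP]
        assert abs(np.mean(dels) - 0.5) < 0.1
        assert abs(np.mean(dups) - 1.5) < 0.1

    def test_emission_is_deterministic(self):
        cfg = small_config(seed=24)
        truth = simulate_truth(cfg)
        model = default_caller_models()[0]
        assert emit_caller_calls(truth, model, seed=4) == emit_caller_calls(
            truth, model, seed=4
        )


class TestRepeatTrack:
    def test_zero_fraction_minimal_stubs(self):
        cfg = small_config(seed=31, repeat_fraction=0.0)
        track = simulate_repeat_track(cfg)
        by_chrom = {}
        for ivl in track:
            by_chrom.setdefault(ivl.chrom, []).append(ivl)
        for chrom, L in cfg.chrom_lengths.items():
            stubs = sorted(by_chrom[chrom])
            assert len(stubs) == 3
            assert all(s.length == 1 for s in stubs)
            assert stubs[0].start == 0 and stubs[-1].end == L

    def test_coverage_accounting(self):
        cfg = small_config(seed=32, repeat_fraction=0.2,
                           chrom_lengths={"chr1": 1_000_000},
                           planted=(PlantedLocus(
                               GenomicInterval("chr1", 400_000, 401_000),
                               EventType.DEL, 0.5, 0.1),))
        track = simulate_repeat_track(cfg)
        total = sum(iv.length for iv in track)
        assert 180_000 <= total <= 220_000

    def test_track_never_touches_planted_loci(self):
        cfg = small_config(seed=33, repeat_fraction=0.2)
        track = simulate_repeat_track(cfg)
        for locus in cfg.planted:
            assert not any(iv.overlaps(locus.interval) for iv in track)

    def test_incompatible_planted_placement_rejected(self):
        # a locus at the chromosome centre collides with the centromere block
        mid = PlantedLocus(GenomicInterval("chr1", 2_499_000, 2_501_000),
                           EventType.DEL, 0.5, 0.1)
        cfg = small_config(seed=34, planted=(mid,), repeat_fraction=0.1)
        with pytest.raises(ConfigError, match="planted"):
            simulate_repeat_track(cfg)


class TestFrequencyRecovery:
    def test_law_of_large_numbers(self):
        cfg = small_config(
            seed=41, n_case_batch1=2000, n_case_batch2=0, n_control_primary=0,
            n_case_secondary=0, n_control_secondary=0, background_rate=0.0,
        )
        truth = simulate_truth(cfg)
        for idx, locus in enumerate(cfg.planted):
            freq = len(truth.carriers(idx)) / 2000
            assert abs(freq - locus.case_freq) <= 0.03


class TestFixture:
    def test_layout_and_determinism(self, tmp_path):
        cfg = small_config(seed=51)
        m1 = write_fixture(cfg, tmp_path / "a")
        m2 = write_fixture(cfg, tmp_path / "b")
        assert (tmp_path / "a" / "sample_sheet.tsv").exists()
        assert (tmp_path / "a" / "repeats.bed").exists()
        primary = sorted((tmp_path / "a" / "primary").glob("calls_*.tsv"))
        assert len(primary) == 5
        secondary = sorted((tmp_path / "a" / "secondary").glob("*.cnvnator.txt"))
        assert len(secondary) == 20  # 10 cases + 10 controls
        assert m1 == m2
        assert (tmp_path / "a" / "manifest.json").read_bytes() == (
            tmp_path / "b" / "manifest.json"
        ).read_bytes()

    def test_zero_samples_headers_only(self, tmp_path):
        cfg = small_config(
            seed=52, n_case_batch1=0, n_case_batch2=0, n_control_primary=0,
            n_case_secondary=0, n_control_secondary=0,
        )
        write_fixture(cfg, tmp_path)
        for f in (tmp_path / "primary").glob("calls_*.tsv"):
            assert len(f.read_text().splitlines()) == 1
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["truth"] == []


def test_derived_seeds_stay_31_bit():
    for base in (0, 1, 2**20, 2**31 - 1):
        for k in (0, 100, 999):
            assert 0 <= derive_seed(base, k) < 2**31
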