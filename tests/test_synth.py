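"""Synthetic cohort generator: kernel shape, schedule arithmetic,
determinism, class separability, and cohort I/O round trips."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edapain.labels import Label
from edapain.synth import (
    CohortFormatError,
    EdaRecording,
    SynthConfig,
    build_schedule,
    generate_cohort,
    generate_recording,
    read_cohort,
    read_config,
    scr_kernel,
    write_cohort,
)


class TestScrKernel:
    def test_causal_zero_before_onset(self):
        assert scr_kernel(0.0) == 0.0
        assert np.all(scr_kernel(np.array([-2.0, -0.1, 0.0])) == 0.0)

    def test_unit_peak_at_analytic_maximum(self):
        # t* from d/dt [exp(-t/td) - exp(-t/tr)] = 0
        tr, td = 0.75, 2.0
        t_peak = tr * td / (td - tr) * np.log(td / tr)
        assert scr_kernel(t_peak, tr, td) == pytest.approx(1.0, abs=1e-12)
        t = np.linspace(0, 20, 5000)
        vals = scr_kernel(t, tr, td)
        assert vals.max() == pytest.approx(1.0, abs=1e-6)

    def test_bounded_and_nonnegative(self):
        t = np.linspace(0.001, 30, 1000)
        vals = scr_kernel(t)
        assert np.all(vals > 0)
        assert np.all(vals <= 1.0)

    @pytest.mark.parametrize("tr,td", [(0.0, 2.0), (2.0, 2.0), (3.0, 2.0), (-1.0, 2.0)])
    def test_invalid_time_constants(self, tr, td):
        with pytest.raises(ValueError):
            scr_kernel(1.0, tr, td)


class TestSchedule:
    def test_default_schedule_counts(self, rng):
        events = build_schedule(SynthConfig(), rng)
        assert len(events) == 25  # 1 baseline + 24 trials
        assert events[0].label is Label.NO_PAIN
        labels = [e.label for e in events[1:]]
        assert labels.count(Label.LOW_PAIN) == 12
        assert labels.count(Label.HIGH_PAIN) == 12

    def test_baseline_only(self, rng):
        events = build_schedule(SynthConfig(n_low=0, n_high=0), rng)
        assert len(events) == 1
        assert events[0].duration_samples == 6000

    def test_events_sorted_and_disjoint(self, rng):
        events = build_schedule(SynthConfig(), rng)
        for prev, nxt in zip(events, events[1:]):
            assert prev.end_sample <= nxt.onset_sample

    def test_same_seed_same_order(self):
        cfg = SynthConfig()
        e1 = build_schedule(cfg, np.random.default_rng(7))
        e2 = build_schedule(cfg, np.random.default_rng(7))
        assert [e.label for e in e1] == [e.label for e in e2]

    def test_trial_durations_match_config(self, rng):
        cfg = SynthConfig()
        for ev in build_schedule(cfg, rng)[1:]:
            assert ev.duration_samples == int(cfg.trial_dur * cfg.fs)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_low": -1},
            {"fs": 0},
            {"trial_dur": -5},
            {"scr_amp_low_mean": 0.9},  # low >= high
            {"habituation": 1.5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SynthConfig(**kwargs)


class TestRecording:
    def test_length_matches_schedule_arithmetic(self, small_cohort, small_config):
        cfg = small_config
        expected = int(cfg.fs * (cfg.baseline_dur + 24 * (cfg.trial_dur + cfg.rest_dur)))
        for rec in small_cohort:
            assert rec.n_samples == expected

    def test_all_samples_positive(self, small_cohort):
        for rec in small_cohort:
            assert np.all(rec.samples > 0)

    def test_noiseless_trialless_recording_is_tonic_plus_drift(self):
        cfg = SynthConfig(n_subjects=1, n_low=0, n_high=0, noise_sd=0.0, seed=5)
        rec = generate_recording(cfg, "S1", np.random.default_rng(5))
        t = np.arange(rec.n_samples) / cfg.fs
        # exactly affine: residual of a linear fit is zero
        coeffs = np.polyfit(t, rec.samples, 1)
        assert np.allclose(np.polyval(coeffs, t), rec.samples, atol=1e-9)

    def test_determinism_same_seed(self):
        cfg = SynthConfig(n_subjects=2, seed=42)
        c1, c2 = generate_cohort(cfg), generate_cohort(cfg)
        for r1, r2 in zip(c1, c2):
            assert np.array_equal(r1.samples, r2.samples)
            assert r1.events == r2.events

    def test_noise_free_high_trials_deflect_more_than_low(self):
        """With noise off and no habituation, every High-trial max deflection
        strictly exceeds every Low-trial max deflection of the same subject."""
        cfg = SynthConfig(n_subjects=3, noise_sd=0.0, habituation=1.0, drift_slope_sd=0.0, seed=9)
        for rec in generate_cohort(cfg):
            base = np.median(rec.samples[: int(cfg.baseline_dur * cfg.fs)])
            defl = {Label.LOW_PAIN: [], Label.HIGH_PAIN: []}
            for ev in rec.trial_events():
                defl[ev.label].append(rec.samples[ev.onset_sample : ev.end_sample].max() - base)
            assert min(defl[Label.HIGH_PAIN]) > max(defl[Label.LOW_PAIN])

    def test_mean_peak_deflection_ratio_tracks_amplitude_ratio(self):
        """Monte-Carlo over many subjects: mean High/Low peak deflection
        ratio approaches scr_amp_high_mean / scr_amp_low_mean."""
        cfg = SynthConfig(
            n_subjects=150, noise_sd=0.0, habituation=1.0, drift_slope_sd=0.0,
            tonic_level_sd=0.0, seed=11,
        )
        highs, lows = [], []
        for rec in generate_cohort(cfg):
            base = rec.samples[0]
            for ev in rec.trial_events():
                peak = rec.samples[ev.onset_sample : ev.end_sample].max() - base
                (highs if ev.label is Label.HIGH_PAIN else lows).append(peak)
        ratio = np.mean(highs) / np.mean(lows)
        assert ratio == pytest.approx(cfg.scr_amp_high_mean / cfg.scr_amp_low_mean, rel=0.05)

    def test_cohort_size_and_distinct_ids(self, small_cohort, small_config):
        assert len(small_cohort) == small_config.n_subjects
        ids = [r.subject_id for r in small_cohort]
        assert len(set(ids)) == len(ids)


@settings(max_examples=20, deadline=None)
@given(n_low=st.integers(0, 4), n_high=st.integers(0, 4), baseline=st.integers(10, 40))
def test_schedule_sample_arithmetic_property(n_low, n_high, baseline):
    """Total samples = fs·(baseline + n·trial + n·rest) for any config."""
    if n_low + n_high == 0:
        cfg = SynthConfig(n_subjects=1, n_low=0, n_high=0, baseline_dur=baseline, seed=1)
    else:
        cfg = SynthConfig(n_subjects=1, n_low=n_low, n_high=n_high, baseline_dur=baseline, seed=1)
    rec = generate_recording(cfg, "S1", np.random.default_rng(0))
    n = cfg.n_low + cfg.n_high
    assert rec.n_samples == int(cfg.fs * (baseline + n * (cfg.trial_dur + cfg.rest_dur)))


class TestCohortIO:
    def test_round_trip_exact(self, tmp_path, small_cohort, small_config):
        write_cohort(small_cohort, tmp_path, config=small_config)
        back = read_cohort(tmp_path)
        assert len(back) == len(small_cohort)
        by_id = {r.subject_id: r for r in back}
        for rec in small_cohort:
            other = by_id[rec.subject_id]
            assert np.array_equal(rec.samples, other.samples)
            assert rec.events == other.events
        assert read_config(tmp_path) == small_config

    def test_layout_two_subjects(self, tmp_path):
        cohort = generate_cohort(SynthConfig(n_subjects=2, n_low=1, n_high=1, seed=3))
        write_cohort(cohort, tmp_path)
        csvs = sorted(p.name for p in tmp_path.glob("*.csv"))
        assert csvs == ["S001.csv", "S002.csv", "annotations.csv"]

    def test_empty_directory_is_format_error(self, tmp_path):
        with pytest.raises(CohortFormatError):
            read_cohort(tmp_path)

    def test_malformed_annotation_row_names_file_and_row(self, tmp_path):
        cohort = generate_cohort(SynthConfig(n_subjects=1, n_low=1, n_high=1, seed=3))
        write_cohort(cohort, tmp_path)
        ann = tmp_path / "annotations.csv"
        lines = ann.read_text().splitlines()
        lines[1] = lines[1].replace("NoPain", "Agony")
        ann.write_text("\n".join(lines) + "\n")
        with pytest.raises(CohortFormatError, match=r"annotations\.csv.*row 1"):
            read_cohort(tmp_path)


def test_recording_rejects_nothing_but_keeps_float64(small_cohort):
    rec = small_cohort[0]
    assert rec.samples.dtype == np.float64
    assert isinstance(rec, EdaRecording)


def test_distinct_seeds_give_distinct_cohorts():
    a = generate_cohort(SynthConfig(n_subjects=1, seed=0))[0]
    b = generate_cohort(dataclasses.replace(SynthConfig(n_subjects=1, seed=0), seed=1))[0]
    assert not np.array_equal(a.samples, b.samples)
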