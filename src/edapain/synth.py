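"""Synthetic EDA cohort generator.

Emulates the structure of a TENS pain-stimulation study: 65 subjects, one
60 s *No Pain* baseline each, then 12 *Low Pain* and 12 *High Pain* 10 s
stimulation trials in a counterbalanced (seeded-shuffled) order, each
followed by a rest period.  The signal model is standard EDA
phenomenology:

    conductance(t) = tonic + drift·t
                   + Σ_k amp_k · h(t − onset_k − latency)   (phasic SCRs)
                   + gaussian noise,     clipped to stay positive

where ``h`` is a bi-exponential Bateman-type skin-conductance-response
kernel normalised to unit peak, ``amp_k`` grows with stimulus intensity
(High > Low) and decays multiplicatively with trial index (habituation).
Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from edapain.labels import Label

#: physiological latency between stimulus onset and SCR onset, seconds
SCR_LATENCY_S = 1.0


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-level generation parameters.

    Durations are in seconds, conductance quantities in microsiemens (µS).
    ``scr_amp_high_mean > scr_amp_low_mean`` is the class-separability
    knob: it controls how far apart the High- and Low-Pain phasic
    amplitudes are relative to ``scr_amp_sd`` and ``noise_sd``.
    """

    n_subjects: int = 65
    fs: float = 100.0
    baseline_dur: float = 60.0
    n_low: int = 12
    n_high: int = 12
    trial_dur: float = 10.0
    rest_dur: float = 20.0
    tonic_level_mean: float = 6.0
    tonic_level_sd: float = 1.5
    drift_slope_sd: float = 0.002
    scr_amp_low_mean: float = 0.3
    scr_amp_high_mean: float = 0.8
    scr_amp_sd: float = 0.1
    tau_rise: float = 0.75
    tau_decay: float = 2.0
    habituation: float = 0.97
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_low < 0 or self.n_high < 0:
            raise ValueError("trial counts must be non-negative")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        for name in ("baseline_dur", "trial_dur", "rest_dur"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.scr_amp_high_mean <= self.scr_amp_low_mean:
            raise ValueError("scr_amp_high_mean must exceed scr_amp_low_mean")
        if not 0.0 <= self.habituation <= 1.0:
            raise ValueError("habituation must lie in [0, 1]")

    @property
    def n_trials(self) -> int:
        return self.n_low + self.n_high

    @property
    def total_samples(self) -> int:
        """fs × (baseline + n_trials·trial + n_trials·rest); every trial is
        followed by one rest block."""
        total_dur = self.baseline_dur + self.n_trials * (self.trial_dur + self.rest_dur)
        return int(round(self.fs * total_dur))


@dataclass(frozen=True)
class StimulusEvent:
    """One annotated condition interval, half-open in samples."""

    onset_sample: int
    duration_samples: int
    label: Label

    @property
    def end_sample(self) -> int:
        return self.onset_sample + self.duration_samples


@dataclass
class EdaRecording:
    """One subject's annotated conductance stream."""

    subject_id: str
    fs: float
    samples: np.ndarray  # 1-D float array, µS, strictly positive
    events: list[StimulusEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    def trial_events(self) -> list[StimulusEvent]:
        return [e for e in self.events if e.label is not Label.NO_PAIN]


def scr_kernel(t: np.ndarray | float, tau_rise: float = 0.75, tau_decay: float = 2.0) -> np.ndarray:
    """Unit-peak bi-exponential skin-conductance-response kernel.

    ``h(t) = (exp(-t/tau_decay) - exp(-t/tau_rise)) / h_peak`` for t > 0,
    zero for t ≤ 0 (causality).  The peak occurs at
    ``t* = tau_rise·tau_decay/(tau_decay - tau_rise) · ln(tau_decay/tau_rise)``.
    """
    if tau_rise <= 0 or tau_decay <= 0:
        raise ValueError("time constants must be positive")
    if tau_decay <= tau_rise:
        raise ValueError("tau_decay must exceed tau_rise")
    t = np.asarray(t, dtype=np.float64)
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    raw = np.where(t > 0, np.exp(-np.clip(t, 0, None) / tau_decay) - np.exp(-np.clip(t, 0, None) / tau_rise), 0.0)
    return raw / peak


def build_schedule(config: SynthConfig, rng: np.random.Generator) -> list[StimulusEvent]:
    """Stimulation schedule: one leading baseline block, then the
    counterbalanced (shuffled) Low/High trials, each followed by a rest.

    Rests are not annotated; they are implicitly No Pain.
    """
    fs = config.fs
    baseline_len = int(round(config.baseline_dur * fs))
    trial_len = int(round(config.trial_dur * fs))
    rest_len = int(round(config.rest_dur * fs))

    labels = [Label.LOW_PAIN] * config.n_low + [Label.HIGH_PAIN] * config.n_high
    order = rng.permutation(len(labels))
    shuffled = [labels[i] for i in order]

    events = [StimulusEvent(0, baseline_len, Label.NO_PAIN)]
    cursor = baseline_len
    for lab in shuffled:
        events.append(StimulusEvent(cursor, trial_len, lab))
        cursor += trial_len + rest_len
    return events


def generate_recording(config: SynthConfig, subject_id: str, rng: np.random.Generator) -> EdaRecording:
    """Simulate one subject: schedule + tonic/drift + habituating SCRs + noise."""
    events = build_schedule(config, rng)
    n = config.total_samples
    t = np.arange(n) / config.fs

    tonic = rng.normal(config.tonic_level_mean, config.tonic_level_sd)
    tonic = max(tonic, 0.5)  # keep the signal physiological and positive
    drift = rng.normal(0.0, config.drift_slope_sd)
    x = tonic + drift * t

    amp_mean = {Label.LOW_PAIN: config.scr_amp_low_mean, Label.HIGH_PAIN: config.scr_amp_high_mean}
    latency = int(round(SCR_LATENCY_S * config.fs))
    # one kernel template, truncated where it has decayed to ~nothing
    kernel_len = int(round(8 * config.tau_decay * config.fs))
    kernel = scr_kernel(np.arange(1, kernel_len + 1) / config.fs, config.tau_rise, config.tau_decay)

    for k, ev in enumerate(e for e in events if e.label is not Label.NO_PAIN):
        amp = rng.normal(amp_mean[ev.label], config.scr_amp_sd)
        amp = max(amp, 0.0) * config.habituation**k
        start = ev.onset_sample + latency
        stop = min(start + kernel_len, n)
        if start < n:
            x[start:stop] += amp * kernel[: stop - start]

    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=n)
    x = np.maximum(x, 1e-3)
    return EdaRecording(subject_id=subject_id, fs=config.fs, samples=x, events=events)


def generate_cohort(config: SynthConfig) -> list[EdaRecording]:
    """Generate ``n_subjects`` independent recordings.

    Each subject gets an independent child seed spawned from
    ``config.seed`` so the cohort is reproducible as a whole and
    per-subject streams do not overlap.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    cohort = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        cohort.append(generate_recording(config, subject_id=f"S{i + 1:03d}", rng=rng))
    return cohort


# ---------------------------------------------------------------------------
# cohort I/O: per-subject sample CSVs + one annotation CSV + a YAML config
# ---------------------------------------------------------------------------

ANNOTATION_FILE = "annotations.csv"
CONFIG_FILE = "cohort_config.yaml"


def write_cohort(cohort: list[EdaRecording], directory: str | Path, config: SynthConfig | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        pd.DataFrame(
            {"sample_index": np.arange(rec.n_samples), "conductance_uS": rec.samples}
        ).to_csv(directory / f"{rec.subject_id}.csv", index=False, float_format="%.17g")
        for ev in rec.events:
            rows.append((rec.subject_id, ev.onset_sample, ev.duration_samples, str(ev.label), rec.fs))
    pd.DataFrame(rows, columns=["subject_id", "onset_sample", "duration_samples", "label", "fs"]).to_csv(
        directory / ANNOTATION_FILE, index=False
    )
    if config is not None:
        (directory / CONFIG_FILE).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=False))


class CohortFormatError(ValueError):
    """Raised when a cohort directory is missing files or malformed."""


def _iter_annotations(path: Path) -> Iterator[tuple[str, StimulusEvent, float]]:
    try:
        table = pd.read_csv(path)
    except FileNotFoundError:
        raise CohortFormatError(f"missing annotation file {path}") from None
    required = {"subject_id", "onset_sample", "duration_samples", "label", "fs"}
    if not required.issubset(table.columns):
        raise CohortFormatError(f"{path}: missing columns {sorted(required - set(table.columns))}")
    for i, row in enumerate(table.itertuples(index=False)):
        try:
            ev = StimulusEvent(int(row.onset_sample), int(row.duration_samples), Label.from_string(row.label))
        except (TypeError, ValueError) as exc:
            raise CohortFormatError(f"{path}, data row {i + 1}: {exc}") from None
        yield str(row.subject_id), ev, float(row.fs)


def read_cohort(directory: str | Path) -> list[EdaRecording]:
    """Inverse of :func:`write_cohort`; full-precision round trip."""
    directory = Path(directory)
    by_subject: dict[str, list[StimulusEvent]] = {}
    fs_by_subject: dict[str, float] = {}
    for sid, ev, fs in _iter_annotations(directory / ANNOTATION_FILE):
        by_subject.setdefault(sid, []).append(ev)
        fs_by_subject[sid] = fs
    cohort = []
    for sid in by_subject:
        sample_file = directory / f"{sid}.csv"
        try:
            table = pd.read_csv(sample_file, float_precision="round_trip")
        except FileNotFoundError:
            raise CohortFormatError(f"missing sample file {sample_file}") from None
        if "conductance_uS" not in table.columns:
            raise CohortFormatError(f"{sample_file}: missing conductance_uS column")
        events = sorted(by_subject[sid], key=lambda e: e.onset_sample)
        cohort.append(
            EdaRecording(subject_id=sid, fs=fs_by_subject[sid], samples=table["conductance_uS"].to_numpy(), events=events)
        )
    return cohort


def read_config(directory: str | Path) -> SynthConfig:
    raw = yaml.safe_load(Path(directory, CONFIG_FILE).read_text())
    return SynthConfig(**raw)
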