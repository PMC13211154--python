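"""Filtering and windowing.

Recordings are low-pass filtered (4th-order Butterworth, 3 Hz cut-off,
causal forward pass) and cut into labelled 10 s windows with a selective
class-balancing scheme: the single No-Pain baseline segment is windowed
with 50 % overlap (eleven windows per 60 s baseline), while Low/High-Pain
trials stay as single non-overlapping windows.  For the default cohort
this yields 11 + 12 + 12 = 35 windows per subject and 715/780/780 = 2275
windows overall.

Filtering is causal everywhere (``scipy.signal.lfilter``, forward pass
only) so that the offline training distribution matches what the
streaming estimator can compute in real time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from edapain.labels import Label
from edapain.synth import EdaRecording

logger = logging.getLogger(__name__)

#: default window length in samples (10 s at 100 Hz)
WIN_LEN = 1000


def butter_lowpass(samples: np.ndarray, fs: float, cutoff: float = 3.0, order: int = 4) -> np.ndarray:
    """Causal 4th-order Butterworth low-pass filter with unit DC gain."""
    samples = np.asarray(samples, dtype=np.float64)
    if samples.size == 0:
        raise ValueError("cannot filter an empty signal")
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below the Nyquist frequency {fs / 2} Hz")
    b, a = signal.butter(order, cutoff, btype="low", fs=fs)
    return signal.lfilter(b, a, samples)


@dataclass
class Window:
    """One labelled fixed-length segment of a recording (half-open
    ``[start_sample, start_sample + len)``, 0-based)."""

    subject_id: str
    label: Label
    start_sample: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)


@dataclass
class WindowSet:
    windows: list[Window] = field(default_factory=list)

    @property
    def counts(self) -> dict[Label, int]:
        c = {lab: 0 for lab in Label}
        for w in self.windows:
            c[w.label] += 1
        return c

    def __len__(self) -> int:
        return len(self.windows)

    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.windows:
            seen.setdefault(w.subject_id)
        return list(seen)

    def matrix(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Stack into (X, y, subjects) arrays for model training."""
        X = np.stack([w.samples for w in self.windows]).astype(np.float64)
        y = np.array([int(w.label) for w in self.windows], dtype=np.int64)
        subjects = np.array([w.subject_id for w in self.windows])
        return X, y, subjects


def segment_overlapping(segment: np.ndarray, win_len: int = WIN_LEN, overlap_fraction: float = 0.5) -> list[tuple[int, np.ndarray]]:
    """Cut ``segment`` into overlapping windows of ``win_len`` samples.

    Windows start at multiples of ``step = win_len·(1 − overlap)``;
    trailing samples that do not fill a full window are dropped.  Returns
    ``(start_offset, samples)`` pairs; a segment shorter than ``win_len``
    yields an empty list.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    segment = np.asarray(segment)
    step = int(round(win_len * (1.0 - overlap_fraction)))
    if segment.shape[0] < win_len:
        return []
    n = (segment.shape[0] - win_len) // step + 1
    return [(i * step, segment[i * step : i * step + win_len]) for i in range(n)]


def segment_trials(recording: EdaRecording, samples: np.ndarray | None = None, win_len: int = WIN_LEN) -> list[Window]:
    """One non-overlapping window per Low/High-Pain event, aligned to the
    event onset.  Events shorter than ``win_len`` are skipped with a
    warning."""
    src = recording.samples if samples is None else np.asarray(samples)
    out = []
    for ev in recording.trial_events():
        if ev.duration_samples < win_len:
            logger.warning(
                "subject %s: event at sample %d lasts %d < %d samples; skipped",
                recording.subject_id, ev.onset_sample, ev.duration_samples, win_len,
            )
            continue
        out.append(Window(recording.subject_id, ev.label, ev.onset_sample, src[ev.onset_sample : ev.onset_sample + win_len]))
    return out


def segment_recording(recording: EdaRecording, samples: np.ndarray | None = None, win_len: int = WIN_LEN, overlap_fraction: float = 0.5) -> list[Window]:
    """All windows of one recording: overlapping No-Pain baseline windows
    followed by the non-overlapping trial windows."""
    src = recording.samples if samples is None else np.asarray(samples)
    windows = []
    for ev in recording.events:
        if ev.label is Label.NO_PAIN:
            seg = src[ev.onset_sample : ev.end_sample]
            for off, w in segment_overlapping(seg, win_len=win_len, overlap_fraction=overlap_fraction):
                windows.append(Window(recording.subject_id, Label.NO_PAIN, ev.onset_sample + off, w))
    windows.extend(segment_trials(recording, samples=src, win_len=win_len))
    return windows


def build_dataset(cohort: list[EdaRecording], filter_first: bool = True, win_len: int = WIN_LEN, cutoff: float = 3.0, order: int = 4) -> WindowSet:
    """Filter each full recording (optionally) and segment it."""
    ws = WindowSet()
    for rec in cohort:
        src = butter_lowpass(rec.samples, rec.fs, cutoff=cutoff, order=order) if filter_first else rec.samples
        ws.windows.extend(segment_recording(rec, samples=src, win_len=win_len))
    return ws


# ---------------------------------------------------------------------------
# window persistence: one manifest CSV + a wide samples CSV
# ---------------------------------------------------------------------------

def write_windows(ws: WindowSet, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = pd.DataFrame(
        [(w.subject_id, str(w.label), w.start_sample) for w in ws.windows],
        columns=["subject_id", "label", "start_sample"],
    )
    manifest.to_csv(directory / "manifest.csv", index=False)
    np.savetxt(directory / "windows.csv", np.stack([w.samples for w in ws.windows]) if ws.windows else np.empty((0, 0)), delimiter=",", fmt="%.17g")


def read_windows(directory: str | Path) -> WindowSet:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    data = np.loadtxt(directory / "windows.csv", delimiter=",", ndmin=2)
    ws = WindowSet()
    for row, samples in zip(manifest.itertuples(index=False), data):
        ws.windows.append(Window(str(row.subject_id), Label.from_string(row.label), int(row.start_sample), samples))
    return ws
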