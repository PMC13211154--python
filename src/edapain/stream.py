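"""Sliding-window real-time pain estimation.

The estimator keeps a bounded FIFO of the most recent 1000 samples.
When the buffer first fills, and every 100 samples thereafter, the
buffered window is Butterworth-filtered (causal, per window, no state
carried between windows), passed through the trained classifier, and a
``(class, confidence)`` event is emitted, where the confidence is the
maximum softmax probability.  Replay of a recorded stream is bit-for-bit
equivalent to batch inference on the same window boundaries, which is
the module's central correctness oracle.
"""

from __future__ import annotations

import time
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from edapain.fcn import FcnModel, predict_with_confidence
from edapain.labels import Label
from edapain.metrics import MetricsReport, compute_metrics
from edapain.preprocess import WIN_LEN, butter_lowpass
from edapain.synth import EdaRecording

#: new prediction every this many samples once the window is full (1 s at 100 Hz)
STRIDE = 100


@dataclass
class StreamState:
    """Algorithm state: bounded sample buffer + stride counter."""

    win_len: int = WIN_LEN
    stride: int = STRIDE
    fs: float = 100.0
    samples: deque = field(default_factory=deque)
    window_ready: bool = False
    counter: int = 0
    n_seen: int = 0  # total samples pushed, = 1-based index of the last sample

    def __post_init__(self) -> None:
        self.samples = deque(self.samples, maxlen=self.win_len)


@dataclass(frozen=True)
class PredictionEvent:
    sample_index: int          # 1-based index of the triggering sample
    predicted: Label
    confidence: float
    latency_ms: float = float("nan")

    @property
    def window_start(self) -> int:
        """0-based start of the underlying window [start, sample_index)."""
        return self.sample_index - WIN_LEN


def _predict_window(state: StreamState, model: FcnModel) -> PredictionEvent:
    t0 = time.perf_counter()
    w = butter_lowpass(np.array(state.samples), fs=state.fs)
    cls, conf = predict_with_confidence(model.forward(w[None, :], train=False)[0])
    latency = (time.perf_counter() - t0) * 1e3
    return PredictionEvent(sample_index=state.n_seen, predicted=Label(int(cls)), confidence=float(conf), latency_ms=latency)


def push_sample(state: StreamState, x: float, model: FcnModel) -> PredictionEvent | None:
    """Feed one conductance sample; emit a prediction when due.

    The first event fires on the ``win_len``-th sample; afterwards one
    event fires every ``stride`` samples.  Non-finite samples are
    rejected without touching the state.
    """
    if not np.isfinite(x):
        raise FloatingPointError(f"non-finite sample {x!r} rejected")
    if not state.window_ready:
        state.samples.append(float(x))
        state.n_seen += 1
        if len(state.samples) == state.win_len:
            state.window_ready = True
            event = _predict_window(state, model)
            state.counter = 0
            return event
        return None
    state.samples.append(float(x))  # deque maxlen evicts the oldest sample
    state.n_seen += 1
    state.counter += 1
    if state.counter == state.stride:
        event = _predict_window(state, model)
        state.counter = 0
        return event
    return None


def replay(recording: EdaRecording, model: FcnModel, win_len: int = WIN_LEN, stride: int = STRIDE, expected_fs: float = 100.0) -> list[PredictionEvent]:
    """Feed a recorded stream sample-by-sample; returns all emitted events."""
    if recording.fs != expected_fs:
        raise ValueError(f"recording sampled at {recording.fs} Hz but the model expects {expected_fs} Hz")
    if win_len != model.config.input_len:
        raise ValueError(f"model expects {model.config.input_len}-sample windows, stream uses {win_len}")
    state = StreamState(win_len=win_len, stride=stride, fs=recording.fs)
    events = []
    for x in recording.samples:
        event = push_sample(state, float(x), model)
        if event is not None:
            events.append(event)
    return events


def _label_array(recording: EdaRecording) -> np.ndarray:
    """Per-sample condition labels; samples not covered by any annotated
    event (rests, tail) are No Pain."""
    labels = np.zeros(recording.n_samples, dtype=np.int64)
    for ev in sorted(recording.events, key=lambda e: e.onset_sample):
        labels[ev.onset_sample : min(ev.end_sample, recording.n_samples)] = int(ev.label)
    return labels


def align_truth(events: list[PredictionEvent], recording: EdaRecording, win_len: int = WIN_LEN) -> np.ndarray:
    """Ground-truth label per event: the condition covering the majority
    of the event's window; exact ties go to the later-starting condition
    (the one covering the end of the window)."""
    labels = _label_array(recording)
    truth = np.empty(len(events), dtype=np.int64)
    for i, ev in enumerate(events):
        start = max(ev.sample_index - win_len, 0)
        seg = labels[start : ev.sample_index]
        counts = np.bincount(seg, minlength=3)
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        if len(tied) == 1:
            truth[i] = tied[0]
        else:
            # later-starting condition = the one found nearest the window end
            for s in seg[::-1]:
                if s in tied:
                    truth[i] = s
                    break
    return truth


def score_stream(events: list[PredictionEvent], truth: np.ndarray) -> tuple[MetricsReport, dict]:
    """Metric suite over the event stream plus a descriptive latency
    summary (milliseconds; informational only, never asserted)."""
    if len(events) != len(truth):
        raise ValueError(f"{len(events)} events but {len(truth)} truth labels")
    y_pred = np.array([int(e.predicted) for e in events], dtype=np.int64)
    report = compute_metrics(np.asarray(truth), y_pred, provenance={"n_events": len(events)})
    lat = np.array([e.latency_ms for e in events], dtype=np.float64)
    lat = lat[np.isfinite(lat)]
    latency = {
        "mean_ms": float(lat.mean()) if lat.size else float("nan"),
        "median_ms": float(np.median(lat)) if lat.size else float("nan"),
        "max_ms": float(lat.max()) if lat.size else float("nan"),
    }
    return report, latency
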