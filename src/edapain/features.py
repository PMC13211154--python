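"""Handcrafted features for the classical baselines.

Each 10 s window yields 36 features: six time-domain statistics (mean,
standard deviation, skewness, kurtosis, minimum, maximum) on the raw
window, plus the same six statistics on the detail coefficients of a
five-level Daubechies-4 discrete wavelet transform, ordered
``[time | D1 | D2 | D3 | D4 | D5]``.  A PCA fitted on training-fold rows
only reduces the 36 features to 12 components.

Conventions (pinned for reproducibility): standard deviation uses the
sample (n−1) divisor; kurtosis is excess (normal → 0); skewness and
kurtosis of a zero-variance input are defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pywt
from scipy import stats
from sklearn.decomposition import PCA

N_TIME_FEATURES = 6
DWT_LEVELS = 5
N_FEATURES = N_TIME_FEATURES * (1 + DWT_LEVELS)  # 36
N_COMPONENTS = 12
WAVELET = "db4"
DWT_MODE = "symmetric"


def time_stats(values: np.ndarray) -> np.ndarray:
    """(mean, std, skewness, kurtosis, min, max) of a 1-D array."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 values for the statistics")
    sd = values.std(ddof=1)
    # variance at round-off level => moments 3/4 are numerically undefined
    degenerate_tol = 1e-12 * max(1.0, float(np.abs(values).max()))
    if sd <= degenerate_tol:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(values))
        kurt = float(stats.kurtosis(values))  # Fisher: excess kurtosis
    return np.array([values.mean(), sd, skew, kurt, values.min(), values.max()])


def dwt_stats(window: np.ndarray, wavelet: str = WAVELET, levels: int = DWT_LEVELS, mode: str = DWT_MODE) -> np.ndarray:
    """Six statistics on each of the level-1 … level-5 detail coefficient
    bands of the db4 DWT, concatenated in level order (30 values)."""
    window = np.asarray(window, dtype=np.float64)
    max_level = pywt.dwt_max_level(window.shape[0], pywt.Wavelet(wavelet).dec_len)
    if max_level < levels:
        raise ValueError(
            f"window of {window.shape[0]} samples supports at most {max_level} "
            f"decomposition levels with {wavelet}; {levels} requested"
        )
    coeffs = pywt.wavedec(window, wavelet, mode=mode, level=levels)
    details = coeffs[1:][::-1]  # wavedec returns [A5, D5, ..., D1]; reorder to D1..D5
    return np.concatenate([time_stats(d) for d in details])


def extract(window: np.ndarray) -> np.ndarray:
    """The full 36-feature vector of one window."""
    return np.concatenate([time_stats(window), dwt_stats(window)])


def _stats_rows(data: np.ndarray) -> np.ndarray:
    """Row-wise (mean, std, skew, kurt, min, max) on a 2-D array; identical
    conventions to :func:`time_stats`, vectorised over rows."""
    mean = data.mean(axis=1)
    sd = data.std(axis=1, ddof=1)
    centered = data - mean[:, None]
    m2 = (centered**2).mean(axis=1)
    m3 = (centered**3).mean(axis=1)
    m4 = (centered**4).mean(axis=1)
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(data).max(axis=1))
    safe_m2 = np.where(degenerate, 1.0, m2)
    skew = np.where(degenerate, 0.0, m3 / safe_m2**1.5)
    kurt = np.where(degenerate, 0.0, m4 / safe_m2**2 - 3.0)
    return np.column_stack([mean, sd, skew, kurt, data.min(axis=1), data.max(axis=1)])


def extract_matrix(windows: list, wavelet: str = WAVELET, levels: int = DWT_LEVELS, mode: str = DWT_MODE) -> np.ndarray:
    """Feature matrix (n_windows × 36) from Window objects or arrays.

    Row-wise vectorised (one multi-signal DWT, closed-form moments);
    agrees with per-window :func:`extract` to floating round-off.
    """
    data = np.stack([np.asarray(getattr(w, "samples", w), dtype=np.float64) for w in windows])
    blocks = [_stats_rows(data)]
    coeffs = pywt.wavedec(data, wavelet, mode=mode, level=levels, axis=-1)
    for detail in coeffs[1:][::-1]:  # D1 .. D5
        blocks.append(_stats_rows(detail))
    return np.hstack(blocks)


@dataclass
class PcaModel:
    """Fitted 36 → 12 principal-component projection.

    ``scale`` holds the per-feature standard deviations when the model
    was fitted with standardisation, else ones; the transform divides by
    it after centering.
    """

    components: np.ndarray          # (36, k) loadings, orthonormal columns
    mean: np.ndarray                # per-feature centering offsets
    scale: np.ndarray               # per-feature divisors (ones if unstandardised)
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def save(self, path: str | Path) -> None:
        np.savez(path, components=self.components, mean=self.mean, scale=self.scale,
                 explained_variance_ratio=self.explained_variance_ratio)

    @classmethod
    def load(cls, path: str | Path) -> "PcaModel":
        d = np.load(path)
        return cls(d["components"], d["mean"], d["scale"], d["explained_variance_ratio"])


def fit_pca(feature_matrix: np.ndarray, k: int = N_COMPONENTS, standardize: bool = True) -> PcaModel:
    """Fit the PCA reduction on TRAINING rows only (the caller guards the
    fold boundary); raises if the matrix rank cannot support k components.

    With ``standardize`` (the default) each feature is z-scored before the
    decomposition, so no wavelet band dominates the components by raw
    variance and downstream kernels operate at unit scale.
    """
    feature_matrix = np.asarray(feature_matrix, dtype=np.float64)
    if feature_matrix.shape[0] < k:
        raise ValueError(f"need at least {k} rows to fit {k} components, got {feature_matrix.shape[0]}")
    if standardize:
        scale = feature_matrix.std(axis=0, ddof=1)
        scale = np.where(scale > 0, scale, 1.0)
    else:
        scale = np.ones(feature_matrix.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(feature_matrix / scale)
    rank = int(np.sum(pca.explained_variance_ > 1e-12))
    if rank < k:
        raise ValueError(f"feature matrix rank {rank} < requested {k} components")
    return PcaModel(pca.components_.T.copy(), pca.mean_.copy() * scale, scale,
                    pca.explained_variance_ratio_.copy())


def apply_pca(model: PcaModel, features: np.ndarray) -> np.ndarray:
    """Center, rescale, then project; accepts a single vector or a matrix."""
    features = np.asarray(features, dtype=np.float64)
    return ((features - model.mean) / model.scale) @ model.components
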