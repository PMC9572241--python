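"""Handcrafted per-window features and train-set Z-score normalization.

Each 5-second, 4-channel window is summarized by 48 scalar functionals
per channel — 16 statistical, 16 temporal and 16 high-level spectral —
giving the fixed 192-dimensional handcrafted representation.  The
registry deliberately contains only whole-signal summaries: no raw FFT
bins, eCDF values or histogram counts, and no wavelet or audio-style
(MFCC/LPCC) coefficients.  High-level summaries *of* the FFT (centroid,
spread, entropy, roll-off, dominant frequency, band powers, ...) are
kept, because they capture the cadence structure that separates the
locomotion classes.

All functionals operate on batches: an [n_windows x n_samples] array in,
an [n_windows] vector out.  Degenerate inputs (constant or all-zero
windows) are mapped to finite conventional values, never NaN/inf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .harmonize import WINDOW_SAMPLES, N_CHANNELS, TARGET_RATE, WindowSet
from .synthgen import ConfigurationError

REGISTRY_SIZE = 48
N_FEATURES = REGISTRY_SIZE * N_CHANNELS  # 192
CHANNEL_NAMES = ("x", "y", "z", "mag")

_EPS = 1e-24


# ---------------------------------------------------------------------------
# Statistical functionals (whole-signal distribution summaries)

def _safe_div(num, den):
    den = np.asarray(den, dtype=float)
    out = np.zeros(np.broadcast_shapes(np.shape(num), den.shape))
    np.divide(num, den, out=out, where=np.abs(den) > _EPS)
    return out


def _skewness(X, fs):
    m = X.mean(axis=1, keepdims=True)
    s = X.std(axis=1)
    m3 = ((X - m) ** 3).mean(axis=1)
    return _safe_div(m3, s ** 3)


def _kurtosis(X, fs):
    m = X.mean(axis=1, keepdims=True)
    s = X.std(axis=1)
    m4 = ((X - m) ** 4).mean(axis=1)
    return np.where(s > _EPS, _safe_div(m4, s ** 4) - 3.0, 0.0)


_STATISTICAL = [
    ("mean", lambda X, fs: X.mean(axis=1)),
    ("std", lambda X, fs: X.std(axis=1)),
    ("variance", lambda X, fs: X.var(axis=1)),
    ("median", lambda X, fs: np.median(X, axis=1)),
    ("min", lambda X, fs: X.min(axis=1)),
    ("max", lambda X, fs: X.max(axis=1)),
    ("range", lambda X, fs: X.max(axis=1) - X.min(axis=1)),
    ("iqr", lambda X, fs: np.percentile(X, 75, axis=1) - np.percentile(X, 25, axis=1)),
    ("rms", lambda X, fs: np.sqrt((X ** 2).mean(axis=1))),
    ("skewness", _skewness),
    ("kurtosis", _kurtosis),
    ("mean_abs_dev", lambda X, fs: np.abs(X - X.mean(axis=1, keepdims=True)).mean(axis=1)),
    ("median_abs_dev", lambda X, fs: np.median(
        np.abs(X - np.median(X, axis=1, keepdims=True)), axis=1)),
    ("percentile_05", lambda X, fs: np.percentile(X, 5, axis=1)),
    ("percentile_95", lambda X, fs: np.percentile(X, 95, axis=1)),
    ("crest_factor", lambda X, fs: _safe_div(
        np.abs(X).max(axis=1), np.sqrt((X ** 2).mean(axis=1)))),
]


# ---------------------------------------------------------------------------
# Temporal functionals (sample-order-sensitive summaries)

def _crossing_rate(X, level):
    s = np.sign(X - level)
    return (s[:, 1:] * s[:, :-1] < 0).mean(axis=1)


def _autocorr_lag1(X, fs):
    Xc = X - X.mean(axis=1, keepdims=True)
    num = (Xc[:, :-1] * Xc[:, 1:]).sum(axis=1)
    den = (Xc ** 2).sum(axis=1)
    return _safe_div(num, den)


def _slope(X, fs):
    n = X.shape[1]
    t = np.arange(n) / fs
    tc = t - t.mean()
    return (X - X.mean(axis=1, keepdims=True)) @ tc / (tc @ tc)


def _peak_count(X, fs):
    interior = X[:, 1:-1]
    return ((interior > X[:, :-2]) & (interior > X[:, 2:])).sum(axis=1).astype(float)


def _hjorth_mobility(X, fs):
    return np.sqrt(_safe_div(np.diff(X, axis=1).var(axis=1), X.var(axis=1)))


def _hjorth_complexity(X, fs):
    d1 = np.diff(X, axis=1)
    return _safe_div(_hjorth_mobility(d1, fs), _hjorth_mobility(X, fs))


def _turning_points(X, fs):
    d = np.sign(np.diff(X, axis=1))
    return (d[:, 1:] * d[:, :-1] < 0).sum(axis=1).astype(float)


def _time_centroid(X, fs):
    t = np.arange(X.shape[1]) / fs
    w = np.abs(X)
    return _safe_div((w * t).sum(axis=1), w.sum(axis=1))


_TEMPORAL = [
    ("zero_crossing_rate", lambda X, fs: _crossing_rate(X, 0.0)),
    ("mean_crossing_rate", lambda X, fs: _crossing_rate(X, X.mean(axis=1, keepdims=True))),
    ("mean_abs_diff", lambda X, fs: np.abs(np.diff(X, axis=1)).mean(axis=1)),
    ("median_abs_diff", lambda X, fs: np.median(np.abs(np.diff(X, axis=1)), axis=1)),
    ("mean_diff", lambda X, fs: np.diff(X, axis=1).mean(axis=1)),
    ("sum_abs_diff", lambda X, fs: np.abs(np.diff(X, axis=1)).sum(axis=1)),
    ("abs_energy", lambda X, fs: (X ** 2).sum(axis=1)),
    ("area_under_curve", lambda X, fs: np.trapezoid(np.abs(X), dx=1.0 / fs, axis=1)),
    ("slope", _slope),
    ("autocorr_lag1", _autocorr_lag1),
    ("peak_count", _peak_count),
    ("hjorth_mobility", _hjorth_mobility),
    ("hjorth_complexity", _hjorth_complexity),
    ("rms_successive_diff", lambda X, fs: np.sqrt((np.diff(X, axis=1) ** 2).mean(axis=1))),
    ("turning_points", _turning_points),
    ("time_centroid", _time_centroid),
]


# ---------------------------------------------------------------------------
# High-level spectral functionals (FFT summaries; the DC bin is excluded
# so the gravity offset does not masquerade as signal content)

def _power_spectrum(X, fs):
    P = np.abs(np.fft.rfft(X, axis=1)) ** 2
    freqs = np.fft.rfftfreq(X.shape[1], d=1.0 / fs)
    return freqs[1:], P[:, 1:]


def _spectral_moments(freqs, P):
    total = P.sum(axis=1)
    p = _safe_div(P, total[:, None])
    centroid = (p * freqs).sum(axis=1)
    spread = np.sqrt((p * (freqs - centroid[:, None]) ** 2).sum(axis=1))
    return total, p, centroid, spread


def _spec(fn):
    def wrapped(X, fs):
        freqs, P = _power_spectrum(X, fs)
        return fn(freqs, P)
    return wrapped


def _spectral_centroid(freqs, P):
    return _spectral_moments(freqs, P)[2]


def _spectral_spread(freqs, P):
    return _spectral_moments(freqs, P)[3]


def _spectral_skewness(freqs, P):
    _, p, centroid, spread = _spectral_moments(freqs, P)
    m3 = (p * (freqs - centroid[:, None]) ** 3).sum(axis=1)
    return _safe_div(m3, spread ** 3)


def _spectral_kurtosis(freqs, P):
    _, p, centroid, spread = _spectral_moments(freqs, P)
    m4 = (p * (freqs - centroid[:, None]) ** 4).sum(axis=1)
    return _safe_div(m4, spread ** 4)


def _spectral_entropy(freqs, P):
    # Normalized Shannon entropy of the power distribution; 0 for silent
    # or single-line spectra.
    total = P.sum(axis=1)
    p = _safe_div(P, total[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > _EPS, p * np.log(p), 0.0)
    return -plogp.sum(axis=1) / np.log(P.shape[1])


def _rolloff(threshold):
    def fn(freqs, P):
        total = P.sum(axis=1)
        cum = np.cumsum(P, axis=1)
        idx = np.argmax(cum >= threshold * total[:, None], axis=1)
        return np.where(total > _EPS, freqs[idx], 0.0)
    return fn


def _dominant_frequency(freqs, P):
    peak = P.max(axis=1)
    return np.where(peak > _EPS, freqs[np.argmax(P, axis=1)], 0.0)


def _max_power(freqs, P):
    return P.max(axis=1) / P.shape[1]


def _spectral_slope(freqs, P):
    fc = freqs - freqs.mean()
    return (P - P.mean(axis=1, keepdims=True)) @ fc / (fc @ fc)


def _band_power(lo, hi):
    def fn(freqs, P):
        band = (freqs >= lo) & (freqs < hi)
        return _safe_div(P[:, band].sum(axis=1), P.sum(axis=1))
    return fn


def _spectral_flatness(freqs, P):
    total = P.sum(axis=1)
    geo = np.exp(np.log(P + _EPS).mean(axis=1))
    arith = P.mean(axis=1)
    return np.where(total > _EPS, _safe_div(geo, arith), 0.0)


def _spectral_decrease(freqs, P):
    k = np.arange(1, P.shape[1])
    num = ((P[:, 1:] - P[:, :1]) / k).sum(axis=1)
    return _safe_div(num, P[:, 1:].sum(axis=1))


_SPECTRAL = [
    ("spectral_centroid", _spec(_spectral_centroid)),
    ("spectral_spread", _spec(_spectral_spread)),
    ("spectral_skewness", _spec(_spectral_skewness)),
    ("spectral_kurtosis", _spec(_spectral_kurtosis)),
    ("spectral_entropy", _spec(_spectral_entropy)),
    ("spectral_rolloff_85", _spec(_rolloff(0.85))),
    ("spectral_rollon_05", _spec(_rolloff(0.05))),
    ("median_frequency", _spec(_rolloff(0.50))),
    ("dominant_frequency", _spec(_dominant_frequency)),
    ("max_power", _spec(_max_power)),
    ("spectral_slope", _spec(_spectral_slope)),
    ("band_power_0.5_3", _spec(_band_power(0.5, 3.0))),
    ("band_power_3_10", _spec(_band_power(3.0, 10.0))),
    ("band_power_10_25", _spec(_band_power(10.0, 25.001))),
    ("spectral_flatness", _spec(_spectral_flatness)),
    ("spectral_decrease", _spec(_spectral_decrease)),
]

_FAMILIES = {
    "statistical": _STATISTICAL,
    "temporal": _TEMPORAL,
    "spectral": _SPECTRAL,
}


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered collection of exactly 48 per-channel scalar functionals."""

    entries: tuple  # of (name, family, callable(batch, fs) -> vector)

    def __post_init__(self):
        if len(self.entries) != REGISTRY_SIZE:
            raise ConfigurationError(
                f"registry must contain exactly {REGISTRY_SIZE} features, "
                f"got {len(self.entries)}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.entries)


def build_registry(config: dict | None = None) -> FeatureRegistry:
    """Build the default 48-entry registry.

    ``config`` may restrict ``families``; any restriction that breaks the
    48-feature contract is a configuration error, because the downstream
    representation width is pinned to 192.
    """
    families = (config or {}).get("families", tuple(_FAMILIES))
    entries = []
    for fam in families:
        if fam not in _FAMILIES:
            raise ConfigurationError(f"unknown feature family {fam!r}")
        entries.extend((name, fam, fn) for name, fn in _FAMILIES[fam])
    return FeatureRegistry(tuple(entries))


@dataclass
class RepresentationMatrix:
    """Per-window representation vectors (handcrafted or learned)."""

    values: np.ndarray
    dim_names: tuple[str, ...]
    source: str  # "handcrafted" | "embedding"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.dim_names) != self.values.shape[1]:
            raise ValueError("dim_names must match n_dims")
        if self.source == "handcrafted" and self.values.shape[1] != N_FEATURES:
            raise ValueError(
                f"handcrafted representations must have {N_FEATURES} dims")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite representation values")

    def __len__(self) -> int:
        return len(self.values)


def extract_features(windowset: WindowSet,
                     registry: FeatureRegistry | None = None) -> RepresentationMatrix:
    """Extract the 192 handcrafted features per window.

    Output is channel-major: all 48 features of channel x, then y, z and
    magnitude.  Extraction is a pure function of the window values.
    """
    registry = registry or build_registry()
    X = windowset.values
    if X.ndim != 3 or X.shape[1:] != (WINDOW_SAMPLES, N_CHANNELS):
        raise ValueError(f"expected windows of shape [n x {WINDOW_SAMPLES} x {N_CHANNELS}]")
    cols, names = [], []
    for c, ch_name in enumerate(CHANNEL_NAMES):
        batch = np.ascontiguousarray(X[:, :, c])
        for name, _, fn in registry.entries:
            cols.append(fn(batch, TARGET_RATE))
            names.append(f"{ch_name}__{name}")
    return RepresentationMatrix(np.column_stack(cols), tuple(names), "handcrafted")


# ---------------------------------------------------------------------------
# Train-set Z-score normalization

@dataclass(frozen=True)
class Scaler:
    """Column-wise Z-score parameters fitted on training rows only."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        if self.mean.shape != self.sd.shape or np.any(self.sd < 0):
            raise ValueError("invalid scaler parameters")


def fit_scaler(train: RepresentationMatrix) -> Scaler:
    return Scaler(train.values.mean(axis=0), train.values.std(axis=0))


def apply_scaler(scaler: Scaler, rep: RepresentationMatrix) -> RepresentationMatrix:
    """Z-score with train statistics; constant training columns map to 0."""
    if rep.values.shape[1] != scaler.mean.shape[0]:
        raise ValueError("scaler/representation dimension mismatch")
    scaled = _safe_div(rep.values - scaler.mean, scaler.sd)
    return RepresentationMatrix(scaled, rep.dim_names, rep.source)


def inverse_scale(scaler: Scaler, rep: RepresentationMatrix) -> RepresentationMatrix:
    values = rep.values * scaler.sd + scaler.mean
    return RepresentationMatrix(values, rep.dim_names, rep.source)


# ---------------------------------------------------------------------------
# I/O

def write_representation(rep: RepresentationMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("# source: " + rep.source + "\n")
        fh.write("\t".join(rep.dim_names) + "\n")
        for row in rep.values:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def read_representation(path) -> RepresentationMatrix:
    with open(path) as fh:
        source = fh.readline().split(":", 1)[1].strip()
        names = tuple(fh.readline().rstrip("\n").split("\t"))
        values = np.loadtxt(fh, ndmin=2)
    return RepresentationMatrix(values, names, source)


def write_scaler(scaler: Scaler, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(f"{v:.17g}" for v in scaler.mean) + "\n")
        fh.write("\t".join(f"{v:.17g}" for v in scaler.sd) + "\n")


def read_scaler(path) -> Scaler:
    rows = np.loadtxt(path, ndmin=2)
    return Scaler(rows[0], rows[1])
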