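"""Multi-domain EEG feature engineering.

Per channel the feature set is: 41 base features (30 statistical + 11
spectral) computed on the broadband signal and again on each of six
frequency bands (delta 0-4, theta 4-8, alpha 8-12, beta_1 12-20, beta_2
20-32, gamma 32-64 Hz), plus a 183-entry cross-band block built from
absolute band powers, relative band powers and their ratios — 41 x 7 + 183
= 470 features per channel, 6,580 over the 14-channel montage.

The registry (:func:`default_registry`) is the single source of truth for
feature identities and ordering; the count contracts are asserted when it is
built.  Column names follow ``<channel>__<signal>__<feature_id>`` where
``signal`` is ``broadband``, a band name, or ``crossband``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from neuroads.types import ParameterError, StimulusEpoch

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "FeatureRegistry",
    "default_registry",
    "decompose_bands",
    "band_powers",
    "compute_base_features",
    "compute_ratio_features",
    "compute_epoch_features",
    "build_feature_matrix",
]

MIN_SIGNAL_LEN = 64


@dataclass(frozen=True)
class BandDefinition:
    """One frequency band: name and edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 <= self.low < self.high:
            raise ParameterError(f"band {self.name!r}: need 0 <= low < high")


#: Default band set, in fixed order.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta_1", 12.0, 20.0),
    BandDefinition("beta_2", 20.0, 32.0),
    BandDefinition("gamma", 32.0, 64.0),
)

STATISTICAL_FEATURES: tuple[str, ...] = (
    "mean", "std", "variance", "skewness", "kurtosis", "rms", "peak_to_peak",
    "min", "max", "mean_abs", "zero_cross_rate",
    "p05", "p25", "median", "p75", "p95", "iqr", "idr", "mad", "aad",
    "hjorth_mobility", "hjorth_complexity", "line_length", "energy",
    "teager_energy", "diff1_std", "diff2_std", "hist_entropy",
    "crest_factor", "impulse_factor",
)

SPECTRAL_FEATURES: tuple[str, ...] = (
    "total_power", "mean_freq", "median_freq", "peak_freq", "spectral_entropy",
    "spectral_edge_90", "spectral_edge_95", "spectral_std",
    "spectral_skewness", "spectral_kurtosis", "spectral_flatness",
)

BASE_FEATURES: tuple[str, ...] = STATISTICAL_FEATURES + SPECTRAL_FEATURES


def _ratio_feature_names(bands: Sequence[BandDefinition]) -> tuple[str, ...]:
    """The 183-entry cross-band block, in fixed order.

    6 absolute powers + 6 relative powers + 30 ordered absolute-power ratios
    + 30 ordered relative-power ratios + 15 unordered broadband-normalized
    pair ratios + 96 composite engagement-style ratios ({beta_1, beta_2,
    beta, gamma} over {alpha, theta, delta, alpha_theta, alpha_delta,
    theta_delta} x {abs, rel} x {raw, log}).
    """
    names = [b.name for b in bands]
    out: list[str] = []
    out += [f"abs_power_{b}" for b in names]
    out += [f"rel_power_{b}" for b in names]
    out += [f"abs_ratio_{i}_over_{j}" for i in names for j in names if i != j]
    out += [f"rel_ratio_{i}_over_{j}" for i in names for j in names if i != j]
    out += [f"norm_ratio_{names[i]}_{names[j]}"
            for i in range(len(names)) for j in range(i + 1, len(names))]
    for num in ("beta_1", "beta_2", "beta", "gamma"):
        for den in ("alpha", "theta", "delta", "alpha_theta", "alpha_delta", "theta_delta"):
            for kind in ("abs", "rel"):
                for form in ("raw", "log"):
                    suffix = "" if form == "raw" else "_log"
                    out.append(f"cmp_{num}_over_{den}_{kind}{suffix}")
    return tuple(out)


RATIO_FEATURES: tuple[str, ...] = _ratio_feature_names(DEFAULT_BANDS)

SIGNAL_TAGS: tuple[str, ...] = ("broadband",) + tuple(b.name for b in DEFAULT_BANDS)


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered feature identities and the per-channel column layout."""

    bands: tuple[BandDefinition, ...]
    base_features: tuple[str, ...]
    ratio_features: tuple[str, ...]
    version: str = "1"

    def __post_init__(self) -> None:
        # count contracts, asserted at build time
        if len(self.base_features) != 41:
            raise ParameterError(f"base block must have 41 features, got {len(self.base_features)}")
        if len(set(self.base_features)) != len(self.base_features):
            raise ParameterError("base feature names must be unique")
        if len(set(self.ratio_features)) != len(self.ratio_features):
            raise ParameterError("ratio feature names must be unique")
        expected = 41 * (1 + len(self.bands)) + len(self.ratio_features)
        if expected != self.per_channel_count:
            raise AssertionError("inconsistent registry")

    @property
    def per_channel_count(self) -> int:
        return len(self.base_features) * (1 + len(self.bands)) + len(self.ratio_features)

    def per_channel_names(self) -> list[tuple[str, str]]:
        """(signal_tag, feature_id) pairs in column order for one channel."""
        out = [("broadband", f) for f in self.base_features]
        for b in self.bands:
            out += [(b.name, f) for f in self.base_features]
        out += [("crossband", f) for f in self.ratio_features]
        return out

    def columns(self, channel_labels: Sequence[str]) -> list[str]:
        per = self.per_channel_names()
        return [f"{ch}__{sig}__{feat}" for ch in channel_labels for sig, feat in per]

    @staticmethod
    def parse_column(name: str) -> tuple[str, str, str]:
        parts = name.split("__")
        if len(parts) != 3:
            raise ParameterError(f"feature column {name!r} does not parse as channel__signal__feature")
        return parts[0], parts[1], parts[2]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dict(
                version=self.version,
                bands=[dict(name=b.name, low=b.low, high=b.high) for b in self.bands],
                base_features=list(self.base_features),
                ratio_features=list(self.ratio_features),
            ), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FeatureRegistry":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            bands=tuple(BandDefinition(**b) for b in d["bands"]),
            base_features=tuple(d["base_features"]),
            ratio_features=tuple(d["ratio_features"]),
            version=d.get("version", "1"),
        )


def default_registry() -> FeatureRegistry:
    """The shipped registry: 41 base features, 470 per channel."""
    reg = FeatureRegistry(DEFAULT_BANDS, BASE_FEATURES, RATIO_FEATURES)
    assert reg.per_channel_count == 470
    return reg


# -- band decomposition ----------------------------------------------------


def decompose_bands(data: np.ndarray, fs: float,
                    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
                    order: int = 4) -> dict[str, np.ndarray]:
    """Split a (channels x samples) signal into zero-phase band-limited parts.

    Band edges at or above Nyquist are clipped (with a warning); a band that
    becomes empty after clipping is an error.  Bands are returned in the
    given order, each the same shape as the input.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    nyq = fs / 2.0
    out: dict[str, np.ndarray] = {}
    for b in bands:
        low, high = b.low, b.high
        if low >= 0.99 * nyq:
            raise ParameterError(f"band {b.name!r} lies entirely above Nyquist ({nyq} Hz)")
        if high >= nyq:
            clipped = 0.99 * nyq
            warnings.warn(f"band {b.name!r} high edge {high} Hz clipped to {clipped:.2f} Hz")
            high = clipped
        if low <= 0:
            sos = sps.butter(order, high, btype="lowpass", fs=fs, output="sos")
        elif high >= 0.99 * nyq:
            sos = sps.butter(order, low, btype="highpass", fs=fs, output="sos")
        else:
            sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
        out[b.name] = sps.sosfiltfilt(sos, data, axis=-1)
    return out


def band_powers(band_signals: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-channel absolute power (variance) of each band-limited signal."""
    return {name: x.var(axis=-1) for name, x in band_signals.items()}


# -- base features ---------------------------------------------------------


def compute_base_features(data: np.ndarray, fs: float) -> np.ndarray:
    """The 41 base features for each row of a (channels x samples) array.

    Statistical block: location/scale/shape moments, amplitude summaries,
    dispersion family (percentiles, IQR, MAD family), Hjorth mobility and
    complexity, waveform-complexity and energy measures, histogram entropy
    and crest/impulse factors.  Spectral block (Welch PSD, 2 s Hann windows,
    50% overlap): total power, spectral moments, median/peak frequency,
    spectral entropy, edge frequencies and flatness.  Degenerate (zero or
    constant) signals map to 0 for features whose definition would divide by
    zero.  Returns a (channels, 41) array ordered as ``BASE_FEATURES``.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    n = x.shape[-1]
    if n < MIN_SIGNAL_LEN:
        raise ParameterError(f"signal has {n} samples; minimum is {MIN_SIGNAL_LEN}")
    mean = x.mean(axis=-1)
    std = x.std(axis=-1)
    var = std ** 2
    nz = std > 0
    with np.errstate(all="ignore"):
        skew = np.where(nz, stats.skew(x, axis=-1, bias=True), 0.0)
        kurt = np.where(nz, stats.kurtosis(x, axis=-1, bias=True), 0.0)
    rms = np.sqrt((x ** 2).mean(axis=-1))
    ptp = x.max(axis=-1) - x.min(axis=-1)
    mean_abs = np.abs(x).mean(axis=-1)
    zc = (np.diff(np.signbit(x), axis=-1) != 0).sum(axis=-1) / (n - 1)
    pcts = np.percentile(x, [5, 25, 50, 75, 95], axis=-1)
    p05, p25, med, p75, p95 = pcts
    iqr = p75 - p25
    idr = p95 - p05
    mad = np.median(np.abs(x - med[:, None]), axis=-1)
    aad = np.abs(x - mean[:, None]).mean(axis=-1)

    d1 = np.diff(x, axis=-1)
    d2 = np.diff(x, n=2, axis=-1)
    v1 = d1.var(axis=-1)
    v2 = d2.var(axis=-1)
    with np.errstate(all="ignore"):
        mobility = np.where(var > 0, np.sqrt(np.where(var > 0, v1 / np.where(var > 0, var, 1), 0.0)), 0.0)
        mob_d = np.where(v1 > 0, np.sqrt(np.where(v1 > 0, v2 / np.where(v1 > 0, v1, 1), 0.0)), 0.0)
        complexity = np.where(mobility > 0, mob_d / np.where(mobility > 0, mobility, 1), 0.0)
    line_length = np.abs(d1).mean(axis=-1)
    energy = (x ** 2).sum(axis=-1)
    teager = (x[:, 1:-1] ** 2 - x[:, :-2] * x[:, 2:]).mean(axis=-1)
    diff1_std = d1.std(axis=-1)
    diff2_std = d2.std(axis=-1)

    hist_entropy = np.zeros(x.shape[0])
    for ch in range(x.shape[0]):
        if ptp[ch] > 0:
            counts, _ = np.histogram(x[ch], bins=16)
            p = counts[counts > 0] / n
            hist_entropy[ch] = -(p * np.log(p)).sum()
    max_abs = np.abs(x).max(axis=-1)
    crest = np.where(rms > 0, max_abs / np.where(rms > 0, rms, 1), 0.0)
    impulse = np.where(mean_abs > 0, max_abs / np.where(mean_abs > 0, mean_abs, 1), 0.0)

    statistical = np.stack([
        mean, std, var, skew, kurt, rms, ptp, x.min(axis=-1), x.max(axis=-1),
        mean_abs, zc, p05, p25, med, p75, p95, iqr, idr, mad, aad,
        mobility, complexity, line_length, energy, teager, diff1_std, diff2_std,
        hist_entropy, crest, impulse,
    ], axis=-1)

    spectral = _spectral_features(x, fs)
    return np.concatenate([statistical, spectral], axis=-1)


def _spectral_features(x: np.ndarray, fs: float) -> np.ndarray:
    nperseg = min(x.shape[-1], int(2 * fs))
    freqs, psd = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2, axis=-1)
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    total = psd.sum(axis=-1) * df
    out = np.zeros((x.shape[0], len(SPECTRAL_FEATURES)))
    for ch in range(x.shape[0]):
        p = psd[ch]
        tp = total[ch]
        if tp <= 0 or not np.isfinite(tp):
            continue
        q = p / p.sum()
        mean_f = float((freqs * q).sum())
        cum = np.cumsum(q)
        median_f = float(freqs[np.searchsorted(cum, 0.5)])
        peak_f = float(freqs[int(np.argmax(p))])
        qpos = q[q > 0]
        sent = float(-(qpos * np.log(qpos)).sum() / np.log(len(q))) if len(q) > 1 else 0.0
        edge90 = float(freqs[np.searchsorted(cum, 0.90)])
        edge95 = float(freqs[np.searchsorted(cum, 0.95)])
        sstd = float(np.sqrt(((freqs - mean_f) ** 2 * q).sum()))
        if sstd > 0:
            sskew = float((((freqs - mean_f) / sstd) ** 3 * q).sum())
            skurt = float((((freqs - mean_f) / sstd) ** 4 * q).sum())
        else:
            sskew = skurt = 0.0
        ppos = p[p > 0]
        flat = float(np.exp(np.mean(np.log(ppos))) / ppos.mean()) if ppos.size else 0.0
        out[ch] = (tp, mean_f, median_f, peak_f, sent, edge90, edge95,
                   sstd, sskew, skurt, flat)
    return out


# -- cross-band ratio block ------------------------------------------------


def compute_ratio_features(band_signals: dict[str, np.ndarray],
                           bands: Sequence[BandDefinition] = DEFAULT_BANDS,
                           ) -> np.ndarray:
    """The 183 cross-band power-ratio features per channel.

    Absolute power is the variance of the band-limited signal; relative power
    divides by the sum over bands.  A zero total or zero denominator power is
    an error (surfaced, not silently NaN).
    """
    names = [b.name for b in bands]
    missing = [b for b in names if b not in band_signals]
    if missing:
        raise ParameterError(f"missing band signals: {missing}")
    p = np.stack([band_signals[b].var(axis=-1) for b in names], axis=-1)  # (C, 6)
    total = p.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ParameterError("zero total band power; cannot form ratio features")
    if np.any(p <= 0):
        bad = names[int(np.argwhere(p <= 0)[0][1])]
        raise ParameterError(f"zero power in band {bad!r}; cannot form ratio features")
    rel = p / total
    cols: list[np.ndarray] = []
    cols += [p[:, i] for i in range(len(names))]
    cols += [rel[:, i] for i in range(len(names))]
    cols += [p[:, i] / p[:, j] for i in range(len(names)) for j in range(len(names)) if i != j]
    cols += [rel[:, i] / rel[:, j] for i in range(len(names)) for j in range(len(names)) if i != j]
    cols += [(p[:, i] / total[:, 0]) / (p[:, j] / total[:, 0])
             for i in range(len(names)) for j in range(i + 1, len(names))]
    ix = {b: names.index(b) for b in names}
    agg_abs = {
        "beta_1": p[:, ix["beta_1"]], "beta_2": p[:, ix["beta_2"]],
        "beta": p[:, ix["beta_1"]] + p[:, ix["beta_2"]], "gamma": p[:, ix["gamma"]],
        "alpha": p[:, ix["alpha"]], "theta": p[:, ix["theta"]], "delta": p[:, ix["delta"]],
        "alpha_theta": p[:, ix["alpha"]] + p[:, ix["theta"]],
        "alpha_delta": p[:, ix["alpha"]] + p[:, ix["delta"]],
        "theta_delta": p[:, ix["theta"]] + p[:, ix["delta"]],
    }
    agg_rel = {k: v / total[:, 0] for k, v in agg_abs.items()}
    for num in ("beta_1", "beta_2", "beta", "gamma"):
        for den in ("alpha", "theta", "delta", "alpha_theta", "alpha_delta", "theta_delta"):
            for kind in ("abs", "rel"):
                src = agg_abs if kind == "abs" else agg_rel
                ratio = src[num] / src[den]
                cols.append(ratio)
                cols.append(np.log(ratio))
    out = np.stack(cols, axis=-1)
    assert out.shape[-1] == len(RATIO_FEATURES)
    return out


# -- epoch / matrix assembly -----------------------------------------------


def compute_epoch_features(epoch: StimulusEpoch,
                           registry: Optional[FeatureRegistry] = None) -> np.ndarray:
    """All per-channel features for one epoch, flattened in column order."""
    registry = registry or default_registry()
    fs = epoch.sampling_rate
    bands = decompose_bands(epoch.data, fs, registry.bands)
    blocks = [compute_base_features(epoch.data, fs)]
    blocks += [compute_base_features(bands[b.name], fs) for b in registry.bands]
    blocks.append(compute_ratio_features(bands, registry.bands))
    return np.concatenate(blocks, axis=-1).reshape(-1)


def build_feature_matrix(epochs: Sequence[StimulusEpoch],
                         registry: Optional[FeatureRegistry] = None) -> pd.DataFrame:
    """Feature matrix over epochs: one row per (subject, ad), 6,580 columns.

    Column order is deterministic: channels in montage order, then broadband
    followed by the six bands, features in registry order, then the
    cross-band block.  Registry metadata is attached in ``DataFrame.attrs``.
    """
    registry = registry or default_registry()
    if not epochs:
        raise ParameterError("no epochs given")
    labels = epochs[0].channel_labels
    for ep in epochs:
        if ep.channel_labels != labels:
            missing = set(labels) ^ set(ep.channel_labels)
            raise ParameterError(f"inconsistent channel sets across epochs: {sorted(missing)}")
    columns = registry.columns(labels)
    rows = np.stack([compute_epoch_features(ep, registry) for ep in epochs])
    index = pd.MultiIndex.from_tuples(
        [(ep.subject_id, ep.ad_id) for ep in epochs], names=["subject_id", "ad_id"])
    df = pd.DataFrame(rows, index=index, columns=columns)
    if df.isna().any().any():
        bad = df.columns[df.isna().any()][:5].tolist()
        raise ParameterError(f"NaN feature values in columns {bad}")
    df.attrs["registry_version"] = registry.version
    df.attrs["bands"] = [(b.name, b.low, b.high) for b in registry.bands]
    return df
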