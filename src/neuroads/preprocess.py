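"""Signal cleaning: band-pass, notch, ocular ICA, burst repair, normalization.

The chain runs in a fixed order — zero-phase Butterworth band-pass, 50 Hz
notch, Infomax ICA with automated ocular-component rejection on the
continuous recording, then per-epoch burst repair and normalization — and
records every applied step with its parameters in a provenance list.

Ocular components are flagged automatically: any independent component whose
absolute Pearson correlation with a frontal low-frequency proxy (the mean of
AF3/AF4 band-passed to 0.5-4 Hz) exceeds a threshold is zeroed before
back-projection.  High-amplitude movement bursts are repaired by a robust-z
interpolation scheme: samples whose channel-wise robust z-score (median/MAD)
exceeds a threshold are replaced by linear interpolation from flanking clean
samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from neuroads.types import (
    CleanEpoch,
    ParameterError,
    Recording,
    StimulusEpoch,
)

__all__ = [
    "PreprocessConfig",
    "bandpass_filter",
    "notch_filter",
    "remove_ocular_ica",
    "repair_bursts",
    "normalize",
    "preprocess_recording",
    "clean_epochs",
]


@dataclass
class PreprocessConfig:
    """Parameters of the cleaning chain (defaults follow the analysis contract)."""

    bandpass_low: float = 0.5
    bandpass_high: float = 70.0
    butter_order: int = 3
    notch_freq: float = 50.0
    notch_q: float = 10.0
    ica_enabled: bool = True
    ocular_detection_threshold: float = 0.7
    ica_seed: int = 0
    ica_max_iter: int = 1000
    burst_zscore_threshold: float = 5.0
    normalize: bool = True
    normalize_mode: str = "per_channel"  # or "global"

    def validate(self) -> None:
        if not 0 < self.bandpass_low < self.bandpass_high:
            raise ParameterError("need 0 < bandpass_low < bandpass_high")
        if self.butter_order < 1:
            raise ParameterError("butter_order must be >= 1")
        if not self.bandpass_low < self.notch_freq < self.bandpass_high:
            raise ParameterError("notch_freq must lie inside the pass band")
        if self.normalize_mode not in ("per_channel", "global"):
            raise ParameterError(f"unknown normalize_mode {self.normalize_mode!r}")


def _clip_high_edge(high: float, fs: float) -> float:
    nyq = fs / 2.0
    if high >= nyq:
        clipped = 0.99 * nyq
        warnings.warn(
            f"band-pass high edge {high} Hz is at or above Nyquist ({nyq} Hz); "
            f"clipping to {clipped:.2f} Hz"
        )
        return clipped
    return high


def bandpass_filter(data: np.ndarray, fs: float, low: float = 0.5,
                    high: float = 70.0, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward ``sosfiltfilt``).

    The effective magnitude response is the squared Butterworth response and
    the phase is exactly zero.  A high edge at or above Nyquist is clipped to
    0.99 x Nyquist with a warning.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if not 0 < low < high:
        raise ParameterError("need 0 < low < high")
    high = _clip_high_edge(high, fs)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    min_len = 3 * (2 * sos.shape[0] + 1)
    if data.shape[-1] <= min_len:
        raise ParameterError(
            f"signal has {data.shape[-1]} samples but the order-{order} zero-phase "
            f"filter needs more than {min_len}"
        )
    return signal.sosfiltfilt(sos, data, axis=-1)


def notch_filter(data: np.ndarray, fs: float, freq: float = 50.0,
                 q: float = 10.0) -> np.ndarray:
    """Zero-phase IIR notch removing narrow-band power-line interference."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if freq >= fs / 2.0:
        raise ParameterError(f"notch frequency {freq} Hz must be below Nyquist ({fs / 2} Hz)")
    b, a = signal.iirnotch(freq, q, fs=fs)
    return signal.filtfilt(b, a, data, axis=-1)


def remove_ocular_ica(recording: Recording, threshold: float = 0.7,
                      seed: int = 0, max_iter: int = 1000,
                      proxy_channels: Sequence[str] = ("AF3", "AF4"),
                      ) -> tuple[Recording, tuple[int, ...]]:
    """Remove ocular artifact components with extended-Infomax ICA.

    The decomposition is computed on the continuous recording.  Components
    whose absolute correlation with the frontal low-frequency proxy exceeds
    ``threshold`` are zeroed before back-projection.  If the decomposition
    fails, the recording is passed through unchanged with a warning.
    """
    import mne

    data = recording.data
    if data.shape[0] < 2:
        raise ParameterError("ICA needs at least 2 channels")
    info = mne.create_info(list(recording.channel_labels), recording.sampling_rate, "eeg")
    raw = mne.io.RawArray(data * 1e-6, info, verbose="error")
    ica = mne.preprocessing.ICA(
        n_components=None, method="infomax", fit_params=dict(extended=True),
        random_state=seed, max_iter=max_iter, verbose="error",
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica.fit(raw, verbose="error")
        sources = ica.get_sources(raw).get_data()
    except Exception as exc:  # pragma: no cover - defensive
        warnings.warn(f"ICA failed ({exc}); returning recording unchanged")
        return recording, ()

    proxy_idx = [recording.channel_labels.index(c) for c in proxy_channels
                 if c in recording.channel_labels]
    if not proxy_idx:
        raise ParameterError("none of the proxy channels are in the montage")
    proxy = bandpass_filter(data[proxy_idx].mean(axis=0), recording.sampling_rate,
                            0.5, 4.0, order=3)[0]
    pc = proxy - proxy.mean()
    pn = np.linalg.norm(pc)
    flagged = []
    for k in range(sources.shape[0]):
        s = sources[k] - sources[k].mean()
        denom = np.linalg.norm(s) * pn
        r = float(s @ pc / denom) if denom > 0 else 0.0
        if abs(r) > threshold:
            flagged.append(k)

    cleaned_raw = ica.apply(raw.copy(), exclude=flagged, verbose="error")
    cleaned = replace(
        recording,
        data=cleaned_raw.get_data() * 1e6,
        clean_data=None,
        blink_source=None,
    )
    return cleaned, tuple(flagged)


def repair_bursts(data: np.ndarray, zscore_threshold: float = 5.0,
                  ) -> tuple[np.ndarray, float]:
    """Interpolate over high-amplitude burst samples.

    Samples whose channel-wise robust z-score (|x - median| / (1.4826 MAD))
    exceeds the threshold are replaced by linear interpolation from the
    flanking clean samples.  Returns the repaired data and the fraction of
    samples modified; more than 50% flagged is treated as a data-quality
    error.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if not zscore_threshold > 0:
        raise ParameterError("zscore_threshold must be positive")
    if np.isinf(zscore_threshold):
        return data.copy(), 0.0
    med = np.median(data, axis=-1, keepdims=True)
    mad = np.median(np.abs(data - med), axis=-1, keepdims=True)
    scale = 1.4826 * mad
    scale[scale == 0] = np.inf
    z = np.abs(data - med) / scale
    bad = z > zscore_threshold
    frac = float(bad.mean())
    if frac > 0.5:
        raise ParameterError(f"{frac:.0%} of samples exceed the burst threshold; data unusable")
    out = data.copy()
    n = data.shape[-1]
    idx = np.arange(n)
    for ch in range(data.shape[0]):
        b = bad[ch]
        if not b.any():
            continue
        good = ~b
        if good.sum() < 2:
            raise ParameterError(f"channel {ch}: too few clean samples to interpolate")
        out[ch, b] = np.interp(idx[b], idx[good], data[ch, good])
    return out, frac


def normalize(data: np.ndarray, mode: str = "per_channel") -> np.ndarray:
    """Center to zero mean and scale to unit SD (population convention).

    ``per_channel`` standardizes each row independently; ``global`` uses the
    grand mean and SD of the whole array.  A constant channel is an error.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if mode == "global":
        sd = data.std()
        if sd == 0:
            raise ParameterError("cannot normalize: zero variance overall")
        return (data - data.mean()) / sd
    if mode != "per_channel":
        raise ParameterError(f"unknown normalize mode {mode!r}")
    sd = data.std(axis=-1, keepdims=True)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ParameterError(f"cannot normalize: constant channel(s) at index {flat.tolist()}")
    return (data - data.mean(axis=-1, keepdims=True)) / sd


def preprocess_recording(recording: Recording, config: Optional[PreprocessConfig] = None,
                         ) -> tuple[Recording, list[dict], tuple[int, ...]]:
    """Run band-pass -> notch -> ICA on a continuous recording.

    Returns the cleaned recording, the provenance list of applied steps and
    the indices of the ICA components that were zeroed.
    """
    config = config or PreprocessConfig()
    config.validate()
    fs = recording.sampling_rate
    provenance: list[dict] = []
    data = bandpass_filter(recording.data, fs, config.bandpass_low,
                           config.bandpass_high, config.butter_order)
    provenance.append(dict(step="bandpass", low=config.bandpass_low,
                           high=config.bandpass_high, order=config.butter_order))
    data = notch_filter(data, fs, config.notch_freq, config.notch_q)
    provenance.append(dict(step="notch", freq=config.notch_freq, q=config.notch_q))
    rec = replace(recording, data=data, clean_data=None, blink_source=None)
    removed: tuple[int, ...] = ()
    if config.ica_enabled:
        rec, removed = remove_ocular_ica(
            rec, threshold=config.ocular_detection_threshold,
            seed=config.ica_seed, max_iter=config.ica_max_iter)
        provenance.append(dict(step="ica", method="extended-infomax",
                               threshold=config.ocular_detection_threshold,
                               removed=list(removed)))
    return rec, provenance, removed


def clean_epochs(recording: Recording, ads, ratings: Optional[pd.DataFrame] = None,
                 config: Optional[PreprocessConfig] = None) -> list[CleanEpoch]:
    """Full cleaning chain: continuous steps, epoching, burst repair, normalize."""
    from neuroads.synthgen import extract_epochs

    config = config or PreprocessConfig()
    rec, provenance, removed = preprocess_recording(recording, config)
    epochs = extract_epochs(rec, ads, ratings)
    out = []
    for ep in epochs:
        data = ep.data
        prov = list(provenance)
        frac = 0.0
        data, frac = repair_bursts(data, config.burst_zscore_threshold)
        prov.append(dict(step="burst_repair", zscore_threshold=config.burst_zscore_threshold,
                         repaired_fraction=frac))
        if config.normalize:
            data = normalize(data, config.normalize_mode)
            prov.append(dict(step="normalize", mode=config.normalize_mode))
        out.append(CleanEpoch(
            subject_id=ep.subject_id, ad_id=ep.ad_id, topic=ep.topic, style=ep.style,
            data=data, sampling_rate=ep.sampling_rate, channel_labels=ep.channel_labels,
            rating=ep.rating, provenance=prov, removed_components=removed,
            repaired_fraction=frac,
        ))
    return out
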