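"""Synthetic EEG ad-viewing sessions.

Generates datasets with the statistical structure the downstream analysis
assumes: 14-channel band-structured oscillatory EEG on the Emotiv EPOC X
montage, one continuous recording per subject containing all ads in random
order separated by fixation gaps, a marker track with a 1 at each stimulus
onset and offset, right-skewed self-report ratings (1-10), a planted positive
relationship between the frontal beta/alpha engagement index and the rating,
alpha-power suppression for shock-style ads of graphic topics, and ocular /
power-line artifacts.

The oscillator model is band-limited Gaussian noise: per epoch, channel and
band, white noise is band-pass filtered (zero phase) and rescaled to an exact
target variance, then the bands are summed.  Target variances come from a
baseline per-band profile modulated by (i) log-normal epoch-to-epoch gain
jitter, (ii) an engagement latent that raises beta and lowers alpha power in
designated frontal channels, and (iii) a fractional alpha reduction for
graphic-topic shock epochs.  The rating is a monotone function of the same
engagement latent plus noise, discretized through a right-skewed link; the
latent-to-rating coupling is calibrated numerically so that the population
Pearson correlation between the planted frontal beta/alpha ratio and the
rating equals ``effect_rho``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, signal
from scipy.special import ndtr

from neuroads.types import (
    EPOC_X_CHANNELS,
    GRAPHIC_TOPICS,
    AdSpec,
    ParameterError,
    Recording,
    StimulusEpoch,
    StructuralError,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "DEFAULT_ADS",
    "generate_dataset",
    "extract_epochs",
    "planted_summary",
]

#: Synthesis bands (Hz).  Beta is generated as one 12-32 Hz band; the feature
#: stage splits it into beta_1/beta_2.  The gamma upper edge is clipped to
#: just below Nyquist at generation time.
SYNTH_BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 0.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("beta", 12.0, 32.0),
    ("gamma", 32.0, 64.0),
)

#: Default stimulus set: 4 topics x {shock, comic}; durations average 49 s
#: with ~9 s spread across ads.
DEFAULT_ADS: tuple[AdSpec, ...] = (
    AdSpec("seatbelt_shock", "seatbelt", "shock", 58.0),
    AdSpec("seatbelt_comic", "seatbelt", "comic", 46.0),
    AdSpec("helmet_shock", "helmet", "shock", 63.0),
    AdSpec("helmet_comic", "helmet", "comic", 40.0),
    AdSpec("water_shock", "water", "shock", 36.0),
    AdSpec("water_comic", "water", "comic", 52.0),
    AdSpec("electricity_shock", "electricity", "shock", 43.0),
    AdSpec("electricity_comic", "electricity", "comic", 54.0),
)

#: Channels carrying the planted engagement effect (frontal/fronto-temporal set).
DEFAULT_EFFECT_CHANNELS: tuple[str, ...] = (
    "AF3", "F3", "F4", "AF4", "F7", "F8", "FC5", "FC6", "T8",
)

#: Baseline per-band signal variance (microvolt^2), roughly 1/f-shaped.
DEFAULT_BAND_POWER: dict[str, float] = {
    "delta": 40.0,
    "theta": 20.0,
    "alpha": 15.0,
    "beta": 10.0,
    "gamma": 3.0,
}


@dataclass
class SimulationConfig:
    """Parameters of one simulated study.

    Attributes
    ----------
    n_subjects : int
        Number of simulated participants (default 20).
    ads : sequence of AdSpec
        Stimulus set; each subject sees every ad once, in random order.
    sampling_rate : float
        Device output rate in Hz (default 128, a native EPOC X rate).
    channel_labels : tuple of str
        Montage; must contain exactly 14 names.
    band_power_profile : dict
        Baseline variance (uV^2) for each synthesis band.
    effect_rho : float
        Target population Pearson correlation between the planted frontal
        beta/alpha power ratio and the self-report rating, in [0, 1).
    engagement_log_slope : float
        Log-EI range per unit of the engagement latent: the planted
        log(beta/alpha) gain equals ``engagement_log_slope * latent``.
    alpha_suppression : float
        Fractional alpha-variance reduction for shock-style epochs of graphic
        topics, in [0, 1).
    rating_skew : float
        Exponent of the power link mapping the latent quantile to the 1-10
        scale; values < 1 push mass toward high ratings.  The default 0.45
        yields roughly 75-80% of ratings above the scale midpoint.
    gain_jitter_sigma : float
        SD of the log-normal epoch/channel/band gain jitter.
    blink_rate_per_min : float
        Mean ocular-artifact event rate.
    line_noise_amplitude : float
        Amplitude (uV) of the 50 Hz power-line component; 0 disables it.
    fixation_gap_s : float
        Fixation-cross interval preceding every ad.
    effect_channels : tuple of str
        Channels carrying the planted engagement effect.
    seed : int
        Seed of the single random generator driving the whole dataset.
    keep_clean : bool
        If True each Recording also stores its artifact-free copy and the
        blink source time course (ground truth for artifact-removal tests).
    """

    n_subjects: int = 20
    ads: tuple[AdSpec, ...] = DEFAULT_ADS
    sampling_rate: float = 128.0
    channel_labels: tuple[str, ...] = EPOC_X_CHANNELS
    band_power_profile: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BAND_POWER))
    effect_rho: float = 0.5
    engagement_log_slope: float = 0.5
    alpha_suppression: float = 0.3
    rating_skew: float = 0.45
    gain_jitter_sigma: float = 0.2
    blink_rate_per_min: float = 15.0
    line_noise_amplitude: float = 5.0
    line_noise_freq: float = 50.0
    fixation_gap_s: float = 5.0
    effect_channels: tuple[str, ...] = DEFAULT_EFFECT_CHANNELS
    graphic_topics: tuple[str, ...] = GRAPHIC_TOPICS
    seed: int = 0
    keep_clean: bool = False

    def __post_init__(self) -> None:
        self.ads = tuple(a if isinstance(a, AdSpec) else AdSpec(**a) for a in self.ads)
        self.channel_labels = tuple(self.channel_labels)
        self.effect_channels = tuple(self.effect_channels)
        self.graphic_topics = tuple(self.graphic_topics)

    def validate(self) -> None:
        if len(self.channel_labels) != 14:
            raise ParameterError(f"montage must have exactly 14 channels, got {len(self.channel_labels)}")
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if not self.ads:
            raise ParameterError("ad table is empty")
        if not 0 <= self.effect_rho < 1:
            raise ParameterError(f"effect_rho must be in [0, 1), got {self.effect_rho}")
        if not 0 <= self.alpha_suppression < 1:
            raise ParameterError(f"alpha_suppression must be in [0, 1), got {self.alpha_suppression}")
        if not self.sampling_rate > 0:
            raise ParameterError("sampling_rate must be positive")
        for name, _, _ in SYNTH_BANDS:
            if self.band_power_profile.get(name, 0.0) < 0:
                raise ParameterError(f"band_power_profile[{name!r}] must be >= 0")
        missing = set(n for n, _, _ in SYNTH_BANDS) - set(self.band_power_profile)
        if missing:
            raise ParameterError(f"band_power_profile missing bands: {sorted(missing)}")
        unknown = set(self.effect_channels) - set(self.channel_labels)
        if unknown:
            raise ParameterError(f"effect_channels not in montage: {sorted(unknown)}")
        for ad in self.ads:
            if ad.duration_s * self.sampling_rate < self.sampling_rate:
                raise ParameterError(f"ad {ad.ad_id!r} shorter than 1 s")
        if not self.rating_skew > 0:
            raise ParameterError("rating_skew must be positive")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ads"] = [dataclasses.asdict(a) for a in self.ads]
        for key in ("channel_labels", "effect_channels", "graphic_topics"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimulatedDataset:
    """A generated study: recordings, ratings and planting ground truth."""

    recordings: list[Recording]
    ratings: pd.DataFrame  # subject_id, ad_id, topic, style, rating
    planted_ei: pd.DataFrame  # per-epoch planted beta/alpha ratio per effect channel
    component_variances: pd.DataFrame  # subject_id, ad_id, channel, band, variance
    config: SimulationConfig

    def epochs(self) -> list[StimulusEpoch]:
        """Slice every recording on its marker track and attach ratings."""
        out: list[StimulusEpoch] = []
        for rec in self.recordings:
            out.extend(extract_epochs(rec, self.config.ads, self.ratings))
        return out


# -- internal helpers ------------------------------------------------------


def _band_sos(fs: float) -> dict[str, np.ndarray]:
    """Zero-phase synthesis filters; edges clipped below Nyquist."""
    nyq = fs / 2.0
    out = {}
    for name, low, high in SYNTH_BANDS:
        high = min(high, 0.99 * nyq)
        if low <= 0:
            out[name] = signal.butter(4, high, btype="lowpass", fs=fs, output="sos")
        elif high >= 0.99 * nyq:
            out[name] = signal.butter(4, low, btype="highpass", fs=fs, output="sos")
        else:
            out[name] = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return out


def _band_noise(rng: np.random.Generator, sos: np.ndarray, n_channels: int, n: int,
                variances: np.ndarray) -> np.ndarray:
    """Band-limited Gaussian noise with exact per-channel variance."""
    x = signal.sosfiltfilt(sos, rng.standard_normal((n_channels, n)), axis=-1)
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1)
    sd[sd == 0] = 1.0
    return x * (np.sqrt(variances) / sd)[:, None]


def _rating_from_latent(g: np.ndarray, kappa: float) -> np.ndarray:
    """Map a standard-normal latent to a right-skewed integer 1-10 rating."""
    u = ndtr(np.asarray(g, dtype=float))
    r = 1 + np.floor(10.0 * u ** kappa)
    return np.minimum(r, 10.0).astype(int)


_CALIBRATION_CACHE: dict[tuple, float] = {}
_CALIBRATION_SEED = 987654321  # internal, independent of dataset seeds
_CALIBRATION_N = 200_000


def _calibrate_coupling(effect_rho: float, log_slope: float, jitter_sigma: float,
                        alpha_suppression: float, p_graphic_shock: float,
                        kappa: float) -> float:
    """Latent-to-rating coupling that realizes the requested EI-rating correlation.

    Works on the closed-form planting model (no signal synthesis): the planted
    per-channel EI is log-normal in the engagement latent plus gain jitter and
    the graphic-shock alpha factor; the rating is the skew-discretized mixture
    of the same latent with independent noise.  The mixing weight is found by
    root-finding on a large fixed Monte-Carlo sample, so identical parameters
    always give the same coupling.
    """
    if effect_rho == 0:
        return 0.0
    key = (round(effect_rho, 10), round(log_slope, 10), round(jitter_sigma, 10),
           round(alpha_suppression, 10), round(p_graphic_shock, 10), round(kappa, 10))
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    rng = np.random.default_rng(_CALIBRATION_SEED)
    e = rng.standard_normal(_CALIBRATION_N)
    eta = rng.standard_normal(_CALIBRATION_N)
    jb = rng.normal(0.0, jitter_sigma, _CALIBRATION_N)
    ja = rng.normal(0.0, jitter_sigma, _CALIBRATION_N)
    gs = rng.random(_CALIBRATION_N) < p_graphic_shock
    alpha_factor = np.where(gs, 1.0 - alpha_suppression, 1.0)
    ei = np.exp(log_slope * e + jb - ja) / alpha_factor

    def planted_corr(lam: float) -> float:
        g = lam * e + np.sqrt(1.0 - lam * lam) * eta
        rating = _rating_from_latent(g, kappa)
        return float(np.corrcoef(ei, rating)[0, 1])

    hi = 0.9995
    if planted_corr(hi) < effect_rho:
        raise ParameterError(
            f"effect_rho={effect_rho} is not attainable with "
            f"engagement_log_slope={log_slope} and the current noise settings"
        )
    lam = optimize.brentq(lambda l: planted_corr(l) - effect_rho, 0.0, hi, xtol=1e-4)
    _CALIBRATION_CACHE[key] = float(lam)
    return float(lam)


def _epoch_plan(rng: np.random.Generator, config: SimulationConfig, ad: AdSpec,
                lam: float, profile: np.ndarray, effect_idx: np.ndarray,
                i_alpha: int, i_beta: int) -> tuple[int, np.ndarray]:
    """Draw one epoch's rating and per-channel/band target variances."""
    n_ch = len(config.channel_labels)
    e = rng.standard_normal()
    eta = rng.standard_normal()
    g = lam * e + np.sqrt(1.0 - lam * lam) * eta
    rating = int(_rating_from_latent(np.array([g]), config.rating_skew)[0])
    var = profile[None, :] * np.exp(
        rng.normal(0.0, config.gain_jitter_sigma, (n_ch, len(profile))))
    half = 0.5 * config.engagement_log_slope * e
    var[effect_idx, i_beta] *= np.exp(half)
    var[effect_idx, i_alpha] *= np.exp(-half)
    if ad.style == "shock" and ad.topic in config.graphic_topics:
        var[:, i_alpha] *= 1.0 - config.alpha_suppression
    return rating, var


def planted_summary(config: SimulationConfig) -> pd.DataFrame:
    """Planted per-epoch ratings and effect-channel beta/alpha ratios.

    Draws the same epoch-level planting model as :func:`generate_dataset`
    (latents, gain jitter, style effects, rating link) without synthesizing
    any signal — useful for fast Monte-Carlo checks of the planting
    mechanism.  Columns: subject_id, ad_id, rating, then one planted EI
    column per effect channel.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    band_names = [b[0] for b in SYNTH_BANDS]
    profile = np.array([config.band_power_profile[b] for b in band_names])
    i_alpha = band_names.index("alpha")
    i_beta = band_names.index("beta")
    effect_idx = np.array([config.channel_labels.index(c) for c in config.effect_channels])
    p_gs = sum(1 for a in config.ads
               if a.style == "shock" and a.topic in config.graphic_topics) / len(config.ads)
    lam = _calibrate_coupling(config.effect_rho, config.engagement_log_slope,
                              config.gain_jitter_sigma, config.alpha_suppression,
                              p_gs, config.rating_skew)
    rows = []
    for si in range(config.n_subjects):
        subject_id = f"S{si + 1:02d}"
        order = rng.permutation(len(config.ads))
        for oi in order:
            ad = config.ads[oi]
            rating, var = _epoch_plan(rng, config, ad, lam, profile,
                                      effect_idx, i_alpha, i_beta)
            rows.append(dict(subject_id=subject_id, ad_id=ad.ad_id, rating=rating,
                             **{c: var[ci, i_beta] / var[ci, i_alpha]
                                for c, ci in zip(config.effect_channels, effect_idx)}))
    return pd.DataFrame(rows)


# -- public operations -----------------------------------------------------


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate one full study under ``config``.

    Returns one :class:`Recording` per subject (all ads in randomized order,
    each preceded by a fixation gap, marker 1s bracketing every ad), the
    per-(subject, ad) rating table, the planted per-channel beta/alpha ratios
    (ground truth for marker-recovery checks) and the realized per-epoch band
    component variances (ground truth for power checks).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n_ch = len(config.channel_labels)
    ads = config.ads
    band_names = [b[0] for b in SYNTH_BANDS]
    profile = np.array([config.band_power_profile[b] for b in band_names])
    i_alpha = band_names.index("alpha")
    i_beta = band_names.index("beta")
    sos = _band_sos(fs)
    effect_idx = np.array([config.channel_labels.index(c) for c in config.effect_channels])
    p_gs = sum(1 for a in ads if a.style == "shock" and a.topic in config.graphic_topics) / len(ads)
    lam = _calibrate_coupling(config.effect_rho, config.engagement_log_slope,
                              config.gain_jitter_sigma, config.alpha_suppression,
                              p_gs, config.rating_skew)

    gap_n = int(round(config.fixation_gap_s * fs))
    tail_n = int(round(2.0 * fs))
    total_var = float(profile.sum())

    recordings: list[Recording] = []
    rating_rows = []
    ei_rows = []
    var_rows = []

    for si in range(config.n_subjects):
        subject_id = f"S{si + 1:02d}"
        order = rng.permutation(len(ads))
        shown = tuple(ads[i].ad_id for i in order)
        segments: list[np.ndarray] = []
        marker_idx: list[int] = []
        pos = 0
        for oi in order:
            ad = ads[oi]
            n_ad = int(round(ad.duration_s * fs))
            # fixation gap: baseline background, no planted effects
            segments.append(sum(
                _band_noise(rng, sos[b], n_ch, gap_n, np.full(n_ch, profile[bi]))
                for bi, b in enumerate(band_names)
            ))
            pos += gap_n
            rating, var = _epoch_plan(rng, config, ad, lam, profile,
                                      effect_idx, i_alpha, i_beta)
            segments.append(sum(
                _band_noise(rng, sos[b], n_ch, n_ad, var[:, bi])
                for bi, b in enumerate(band_names)
            ))
            marker_idx.extend([pos, pos + n_ad])
            pos += n_ad
            rating_rows.append((subject_id, ad.ad_id, ad.topic, ad.style, rating))
            ei_rows.append(
                dict(subject_id=subject_id, ad_id=ad.ad_id,
                     **{c: var[ci, i_beta] / var[ci, i_alpha]
                        for c, ci in zip(config.effect_channels, effect_idx)})
            )
            for ci, ch in enumerate(config.channel_labels):
                for bi, b in enumerate(band_names):
                    var_rows.append((subject_id, ad.ad_id, ch, b, var[ci, bi]))
        segments.append(sum(
            _band_noise(rng, sos[b], n_ch, tail_n, np.full(n_ch, profile[bi]))
            for bi, b in enumerate(band_names)
        ))
        data = np.concatenate(segments, axis=-1)
        n_total = data.shape[1]
        clean = data.copy() if config.keep_clean else None

        # ocular artifacts: a single frontal-dominant blink source
        blink_source = np.zeros(n_total)
        if config.blink_rate_per_min > 0:
            n_events = rng.poisson(config.blink_rate_per_min * n_total / fs / 60.0)
            starts = rng.integers(0, max(1, n_total - int(0.5 * fs)), n_events)
            for t0 in np.sort(starts):
                width = int(rng.uniform(0.3, 0.5) * fs)
                t = np.arange(width)
                blink_source[t0:t0 + width] += 0.5 * (1 - np.cos(2 * np.pi * t / width))
            weights = np.array([_BLINK_WEIGHTS.get(c, 0.05) for c in config.channel_labels])
            data = data + 10.0 * np.sqrt(total_var) * weights[:, None] * blink_source[None, :]

        # power-line interference: common-phase sinusoid
        if config.line_noise_amplitude > 0:
            t = np.arange(n_total) / fs
            phase = rng.uniform(0, 2 * np.pi)
            amp = config.line_noise_amplitude * rng.uniform(0.8, 1.2, n_ch)
            data = data + amp[:, None] * np.sin(2 * np.pi * config.line_noise_freq * t + phase)[None, :]

        marker = np.zeros(n_total, dtype=int)
        marker[np.array(marker_idx)] = 1
        recordings.append(Recording(
            subject_id=subject_id, sampling_rate=fs, data=data, marker=marker,
            channel_labels=config.channel_labels, stimulus_order=shown,
            clean_data=clean,
            blink_source=blink_source if config.keep_clean else None,
        ))

    ratings = pd.DataFrame(rating_rows, columns=["subject_id", "ad_id", "topic", "style", "rating"])
    planted_ei = pd.DataFrame(ei_rows)
    component_variances = pd.DataFrame(
        var_rows, columns=["subject_id", "ad_id", "channel", "band", "variance"])
    return SimulatedDataset(recordings, ratings, planted_ei, component_variances, config)


_BLINK_WEIGHTS = {
    "AF3": 1.0, "AF4": 1.0, "F3": 0.6, "F4": 0.6,
    "F7": 0.35, "F8": 0.35, "FC5": 0.2, "FC6": 0.2,
}


def extract_epochs(recording: Recording, ads: Sequence[AdSpec],
                   ratings: Optional[pd.DataFrame] = None) -> list[StimulusEpoch]:
    """Slice a recording into per-ad epochs using its marker track.

    Marker 1s must pair up as (onset, offset); the i-th pair is matched to the
    i-th entry of ``recording.stimulus_order``.  Ratings are attached from the
    tidy rating table when given.
    """
    ads_by_id = {a.ad_id: a for a in ads}
    idx = np.flatnonzero(np.asarray(recording.marker) == 1)
    if idx.size == 0:
        raise StructuralError("marker track contains no stimulus markers")
    if idx.size % 2 != 0:
        raise StructuralError(f"odd marker count ({idx.size}); onsets and offsets must pair up")
    onsets, offsets = idx[0::2], idx[1::2]
    if np.any(offsets <= onsets) or np.any(onsets[1:] < offsets[:-1]):
        raise StructuralError("marker pairs overlap or are out of order")
    if len(onsets) != len(ads):
        raise StructuralError(f"{len(onsets)} marker pairs but {len(ads)} ads in the table")
    if recording.stimulus_order is None:
        raise StructuralError("recording has no stimulus_order; cannot match epochs to ads")
    if len(recording.stimulus_order) != len(onsets):
        raise StructuralError("stimulus_order length does not match marker pair count")

    lookup = {}
    if ratings is not None:
        sub = ratings[ratings["subject_id"] == recording.subject_id]
        lookup = dict(zip(sub["ad_id"], sub["rating"]))

    out = []
    for (on, off), ad_id in zip(zip(onsets, offsets), recording.stimulus_order):
        if ad_id not in ads_by_id:
            raise StructuralError(f"presented ad {ad_id!r} not in the ad table")
        ad = ads_by_id[ad_id]
        out.append(StimulusEpoch(
            subject_id=recording.subject_id, ad_id=ad.ad_id, topic=ad.topic,
            style=ad.style, data=recording.data[:, on:off],
            sampling_rate=recording.sampling_rate,
            channel_labels=recording.channel_labels,
            rating=int(lookup[ad_id]) if ad_id in lookup else None,
        ))
    return out
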