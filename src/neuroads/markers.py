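"""Engagement-index and alpha-discomfort marker analyses.

Two engagement indices are computed per channel from band powers: EI1 =
P(beta)/P(alpha) and EI2 = P(beta)/(P(alpha)+P(theta)), with beta taken as
the 12-32 Hz power (beta_1 + beta_2) by default.  Per-channel indices are
correlated with self-report ratings across epochs and the per-channel
p-values are corrected with the Benjamini-Hochberg step-up procedure.

The alpha-discomfort analysis contrasts mean alpha power between shock- and
comic-style epochs of the same topic: lower alpha during shock-style ads of
graphic topics indicates viewer discomfort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from neuroads.features import DEFAULT_BANDS, decompose_bands
from neuroads.types import ParameterError, StimulusEpoch

__all__ = [
    "band_power_table",
    "engagement_index",
    "engagement_table",
    "correlate_with_ratings",
    "alpha_contrast",
    "AlphaContrast",
]


def band_power_table(epochs: Sequence[StimulusEpoch],
                     bands=DEFAULT_BANDS) -> pd.DataFrame:
    """Tidy per-epoch, per-channel band powers (variance of band signals).

    Columns: subject_id, ad_id, topic, style, rating, channel, then one
    column per band.
    """
    rows = []
    for ep in epochs:
        sig = decompose_bands(ep.data, ep.sampling_rate, bands)
        powers = {b.name: sig[b.name].var(axis=-1) for b in bands}
        for ci, ch in enumerate(ep.channel_labels):
            row = dict(subject_id=ep.subject_id, ad_id=ep.ad_id, topic=ep.topic,
                       style=ep.style, rating=ep.rating, channel=ch)
            row.update({b.name: powers[b.name][ci] for b in bands})
            rows.append(row)
    return pd.DataFrame(rows)


def engagement_index(band_power: pd.DataFrame, beta: str = "sum") -> pd.DataFrame:
    """EI1 = P_beta/P_alpha and EI2 = P_beta/(P_alpha+P_theta) per row.

    ``band_power`` needs columns alpha, theta and (depending on ``beta``)
    beta_1/beta_2.  ``beta`` selects what counts as beta power: ``"sum"``
    (beta_1 + beta_2, the 12-32 Hz default), ``"beta_1"`` or ``"beta_2"``.
    """
    if beta == "sum":
        p_beta = band_power["beta_1"] + band_power["beta_2"]
    elif beta in ("beta_1", "beta_2"):
        p_beta = band_power[beta]
    else:
        raise ParameterError(f"beta must be 'sum', 'beta_1' or 'beta_2', got {beta!r}")
    p_alpha = band_power["alpha"]
    p_theta = band_power["theta"]
    if (p_alpha <= 0).any():
        raise ParameterError("zero alpha power; engagement index undefined")
    if ((p_alpha + p_theta) <= 0).any():
        raise ParameterError("zero alpha+theta power; engagement index undefined")
    out = band_power.copy()
    out["EI1"] = p_beta / p_alpha
    out["EI2"] = p_beta / (p_alpha + p_theta)
    return out


def engagement_table(epochs: Sequence[StimulusEpoch], beta: str = "sum",
                     bands=DEFAULT_BANDS) -> pd.DataFrame:
    """Convenience: band powers then engagement indices for a list of epochs."""
    return engagement_index(band_power_table(epochs, bands), beta=beta)


def correlate_with_ratings(index_values: pd.DataFrame, q: float = 0.05,
                           index: str = "EI1", method: str = "pearson",
                           ) -> pd.DataFrame:
    """Correlate a per-channel engagement index with ratings across epochs.

    ``index_values`` is a tidy table with columns channel, rating and the
    chosen index (as produced by :func:`engagement_table`).  Returns one row
    per channel with the correlation r, raw p and the Benjamini-Hochberg
    significance flag at level ``q`` (corrected across channels).
    """
    if method not in ("pearson", "spearman"):
        raise ParameterError(f"unknown correlation method {method!r}")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for ch, grp in index_values.groupby("channel", sort=False):
        vals = grp[index].to_numpy(dtype=float)
        ratings = grp["rating"].to_numpy(dtype=float)
        if len(vals) < 3:
            raise ParameterError(f"channel {ch}: need >= 3 paired observations")
        if np.ptp(ratings) == 0:
            raise ParameterError("zero rating variance; correlation undefined")
        r, p = corr(vals, ratings)
        rows.append(dict(channel=ch, r=float(r), p=float(p)))
    out = pd.DataFrame(rows)
    out["significant"] = multipletests(out["p"].to_numpy(), alpha=q, method="fdr_bh")[0]
    out.attrs["q"] = q
    out.attrs["index"] = index
    out.attrs["method"] = method
    return out


@dataclass
class AlphaContrast:
    """Per-topic shock-vs-comic mean alpha power and breakdowns."""

    per_topic: pd.DataFrame  # topic, alpha_shock, alpha_comic, difference
    breakdown: pd.DataFrame  # subject_id, channel, topic, style, alpha
    overall_shock: float
    overall_comic: float


def alpha_contrast(band_power: pd.DataFrame) -> AlphaContrast:
    """Shock-vs-comic alpha contrast per topic.

    ``band_power`` is the tidy table from :func:`band_power_table`.  Alpha
    power is averaged over channels (and subjects) per style within each
    topic; ``difference`` is comic minus shock, so a positive value means
    alpha suppression during shock-style ads.  Topics missing one of the two
    styles are skipped with a warning.
    """
    if "alpha" not in band_power.columns:
        raise ParameterError("band_power table has no 'alpha' column")
    rows = []
    for topic, grp in band_power.groupby("topic", sort=False):
        styles = set(grp["style"])
        if not {"shock", "comic"} <= styles:
            warnings.warn(f"topic {topic!r} lacks one of shock/comic; skipped")
            continue
        m = grp.groupby("style")["alpha"].mean()
        rows.append(dict(topic=topic, alpha_shock=float(m["shock"]),
                         alpha_comic=float(m["comic"]),
                         difference=float(m["comic"] - m["shock"])))
    if not rows:
        raise ParameterError("no topic has both styles; cannot form contrast")
    per_topic = pd.DataFrame(rows)
    breakdown = (band_power
                 .groupby(["subject_id", "channel", "topic", "style"], sort=False)["alpha"]
                 .mean().reset_index())
    overall = band_power.groupby("style")["alpha"].mean()
    return AlphaContrast(per_topic, breakdown,
                         overall_shock=float(overall.get("shock", np.nan)),
                         overall_comic=float(overall.get("comic", np.nan)))


def plot_channel_correlations(result: pd.DataFrame, path) -> None:
    """Bar plot of per-channel engagement-rating correlations (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    colors = ["tab:green" if s else "tab:gray" for s in result["significant"]]
    ax.bar(result["channel"], result["r"], color=colors)
    ax.set_ylabel(f"r ({result.attrs.get('index', 'EI')} vs rating)")
    ax.axhline(0, color="k", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
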