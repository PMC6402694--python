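"""Delay-window averaging, session centering and channel screening."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import RateTimeSeries, rate_column_names, rate_matrix, validate_trials


def select_delay_window(
    series: RateTimeSeries, window: tuple[float, float] = (-200.0, 0.0)
) -> pd.DataFrame:
    """Average rates over a go-cue-relative window into a TrialTable.

    The window is half-open, (lo, hi] ms relative to the go cue; the default
    (-200, 0] is the 200 ms immediately preceding the go cue.
    """
    lo, hi = window
    if not hi > lo:
        raise ValueError("window must have positive length")
    k, n, _ = series.rates.shape
    out = np.empty((k, n))
    for i in range(k):
        rel = series.time_ms - series.go_cue_ms[i]
        mask = (rel > lo) & (rel <= hi)
        if not mask.any():
            tid = series.meta["trial_id"].iloc[i]
            raise ValueError(f"window outside recorded series for trial_id {tid}")
        out[i] = series.rates[i, :, mask].mean(axis=0)
    table = series.meta.copy()
    table[rate_column_names(n)] = out
    return validate_trials(table)


def subtract_session_baseline(table: pd.DataFrame) -> pd.DataFrame:
    """Center each channel at zero mean within each recording session.

    Removes day-to-day baseline drifts before sessions are pooled; idempotent,
    and leaves within-session trial-to-trial differences untouched.
    """
    out = table.copy()
    cols = [c for c in table.columns if c.startswith("rate_")]
    out[cols] = table.groupby("session_id")[cols].transform(lambda x: x - x.mean())
    return out


@dataclasses.dataclass
class ChannelScreenResult:
    """Per-channel task-relevance screen (Bonferroni-corrected)."""

    pvalues: np.ndarray  # overall regression p per channel
    kept: np.ndarray  # bool, p < alpha / n_channels
    alpha: float

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def mask(self) -> np.ndarray:
        return self.kept.copy()


def screen_channels(table: pd.DataFrame, alpha: float = 0.05) -> ChannelScreenResult:
    """Screen channels by linear regression of rate on target (x, y).

    Per channel, the overall p-value is the F test of the two-predictor
    linear model against the intercept-only model; a channel is kept iff
    p < alpha / n_channels (Bonferroni over channels).  Constant channels get
    p = 1 and are dropped.  Channels are flagged, not deleted; downstream
    stages accept an optional mask.
    """
    xy = table[["target_x", "target_y"]].to_numpy(dtype=float)
    if len(np.unique(xy, axis=0)) < 3:
        raise ValueError("need at least 3 distinct target positions")
    R = rate_matrix(table)
    k, n = R.shape
    X = np.column_stack([np.ones(k), xy])
    coef, _, _, _ = np.linalg.lstsq(X, R, rcond=None)
    resid = R - X @ coef
    rss1 = (resid**2).sum(axis=0)
    rss0 = ((R - R.mean(axis=0)) ** 2).sum(axis=0)
    df_num, df_den = 2, k - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    pvals = stats.f.sf(F, df_num, df_den)
    constant = rss0 <= 1e-12 * max(1.0, np.abs(R).max()) ** 2
    pvals = np.where(constant | ~np.isfinite(pvals), 1.0, pvals)
    kept = pvals < alpha / n
    return ChannelScreenResult(pvalues=pvals, kept=kept, alpha=alpha)
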