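"""Low-dimensional structure of delay activity.

The pipeline here mirrors targeted dimensionality reduction with
orthogonalized regression:

1. Average trials within each reach condition and run PCA on the
   condition-averaged matrix (mean-centered across conditions), keeping the
   smallest number of components whose cumulative explained variance reaches
   a threshold (default 95%).
2. Regress the single-trial PC scores onto the target x and y coordinates to
   obtain the "spatial plane" axes (x_neural, y_neural), and regress the
   *full-dimensional* rates onto per-trial maximum speed to obtain the speed
   axis: the PCs were derived from condition averages, so within-condition
   speed variability is averaged out of them.
3. Orthogonalize sequentially (x, then y, then speed) by projecting the data
   into the null space of the previously fitted coefficient vectors before
   each subsequent fit, yielding three pairwise-orthogonal channel-space
   axes.

Projections of single trials onto these axes give per-trial neural states
(x_neural, y_neural, speed_neural) on the cm / cm/s scale of the regressed
variables.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .core_io import RateTimeSeries, rate_matrix, target_distances

#: Relative singular-value cutoff used by every least-squares fit here.
RCOND = 1e-10


class DegenerateInputError(ValueError):
    """Input has no usable variance for the requested fit."""


def condition_average(table: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Condition-mean matrix (n_channels x n_conditions) and its index.

    Conditions are pooled across sessions; tables from different tasks may be
    concatenated beforehand, in which case (task, condition_id) identifies a
    condition.
    """
    rates = rate_matrix(table)
    keys = table[["task", "condition_id", "target_x", "target_y"]]
    groups = table.groupby(["task", "condition_id"], sort=True).indices
    index_rows = []
    cols = []
    for (task, cid), idx in groups.items():
        cols.append(rates[idx].mean(axis=0))
        index_rows.append(
            {
                "task": task,
                "condition_id": cid,
                "target_x": keys["target_x"].iloc[idx[0]],
                "target_y": keys["target_y"].iloc[idx[0]],
                "n_trials": len(idx),
            }
        )
    cond_matrix = np.column_stack(cols)
    return cond_matrix, pd.DataFrame(index_rows)


@dataclasses.dataclass
class PCAResult:
    """PCA of the condition-averaged matrix."""

    components: np.ndarray  # (n_components, n_channels), the A transform rows
    explained_variance_ratio: np.ndarray
    center: np.ndarray  # per-channel mean over conditions
    d: int  # retained count at the variance threshold

    @property
    def A(self) -> np.ndarray:
        """Retained transform, d x n_channels."""
        return self.components[: self.d]


def fit_pca(cond_matrix: np.ndarray, variance_threshold: float = 0.95) -> PCAResult:
    """PCA on condition averages, centered across conditions.

    d is the smallest component count whose cumulative explained variance
    reaches the threshold.
    """
    cond_matrix = np.asarray(cond_matrix, dtype=float)
    n, c = cond_matrix.shape
    if c < 2:
        raise ValueError("need at least 2 conditions")
    center = cond_matrix.mean(axis=1)
    centered = cond_matrix - center[:, None]
    if not np.any(np.abs(centered) > 0):
        raise DegenerateInputError("zero variance across conditions")
    pca = PCA(svd_solver="full")
    pca.fit(centered.T)  # observations = conditions
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    # tolerate floating round-off when the threshold is 1.0
    d = int(np.searchsorted(cum, variance_threshold - 1e-9) + 1)
    d = min(d, len(evr))
    return PCAResult(
        components=pca.components_, explained_variance_ratio=evr, center=center, d=d
    )


@dataclasses.dataclass
class SubspaceModel:
    """Fitted initial-condition subspace.

    axis_x / axis_y / axis_speed are channel-space coefficient vectors;
    projecting a centered rate vector on them yields x_neural, y_neural and
    speed_neural (cm / cm/s scale).  They are pairwise orthogonal by
    construction.
    """

    center: np.ndarray  # per-channel centering vector (condition-average mean)
    components: np.ndarray  # full PCA transform
    explained_variance_ratio: np.ndarray
    d: int
    beta_x: np.ndarray  # regression coefficients over the d PC scores
    beta_y: np.ndarray
    axis_x: np.ndarray  # channel space
    axis_y: np.ndarray
    axis_speed: np.ndarray
    cond_matrix: np.ndarray
    cond_index: pd.DataFrame

    @property
    def A(self) -> np.ndarray:
        return self.components[: self.d]

    @property
    def n_channels(self) -> int:
        return self.center.size

    def plane_basis(self) -> np.ndarray:
        """Orthonormal basis (n_channels x 2) of the spatial plane."""
        bx = self.axis_x / np.linalg.norm(self.axis_x)
        by = self.axis_y / np.linalg.norm(self.axis_y)
        return np.column_stack([bx, by])

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "center": self.center.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "d": self.d,
            "beta_x": self.beta_x.tolist(),
            "beta_y": self.beta_y.tolist(),
            "axis_x": self.axis_x.tolist(),
            "axis_y": self.axis_y.tolist(),
            "axis_speed": self.axis_speed.tolist(),
            "cond_matrix": self.cond_matrix.tolist(),
            "cond_index": self.cond_index.to_dict(orient="list"),
        }
        path = Path(path)
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SubspaceModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            center=np.array(payload["center"]),
            components=np.array(payload["components"]),
            explained_variance_ratio=np.array(payload["explained_variance_ratio"]),
            d=int(payload["d"]),
            beta_x=np.array(payload["beta_x"]),
            beta_y=np.array(payload["beta_y"]),
            axis_x=np.array(payload["axis_x"]),
            axis_y=np.array(payload["axis_y"]),
            axis_speed=np.array(payload["axis_speed"]),
            cond_matrix=np.array(payload["cond_matrix"]),
            cond_index=pd.DataFrame(payload["cond_index"]),
        )


def _lstsq_axis(X: np.ndarray, y: np.ndarray, what: str) -> np.ndarray:
    """Min-norm least-squares slope of y on (centered) X.

    Centering both sides absorbs the intercept; the pseudoinverse cutoff
    keeps the fit stable under rank deficiency, and the minimum-norm solution
    lies in the row space of X (hence orthogonal to previously nulled axes).
    """
    yc = y - y.mean()
    if np.allclose(yc, 0.0):
        raise DegenerateInputError(f"zero variance in regressand for {what}")
    Xc = X - X.mean(axis=0)
    return np.linalg.pinv(Xc, rcond=RCOND) @ yc


def _null_project(X: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Project rows of X into the null space of a coefficient vector."""
    u = axis / np.linalg.norm(axis)
    return X - np.outer(X @ u, u)


def fit_axes(table: pd.DataFrame, pca: PCAResult) -> SubspaceModel:
    """Fit the spatial plane and speed axis with sequential orthogonalization.

    beta_x is fit by least squares of target_x on the single-trial PC scores;
    the scores are then projected into the null space of beta_x before
    fitting beta_y.  The speed axis is fit from the full-dimensional rates
    (projected into the null space of the composed x/y channel axes), so all
    three channel-space axes come out pairwise orthogonal.
    """
    rates = rate_matrix(table)
    centered = rates - pca.center
    A = pca.A
    scores = centered @ A.T  # trials x d

    beta_x = _lstsq_axis(scores, table["target_x"].to_numpy(float), "x axis")
    scores_y = _null_project(scores, beta_x)
    beta_y = _lstsq_axis(scores_y, table["target_y"].to_numpy(float), "y axis")

    axis_x = A.T @ beta_x
    axis_y = A.T @ beta_y

    resid = _null_project(_null_project(centered, axis_x), axis_y)
    axis_speed = _lstsq_axis(resid, table["max_speed"].to_numpy(float), "speed axis")

    cond_matrix, cond_index = condition_average(table)
    return SubspaceModel(
        center=pca.center,
        components=pca.components,
        explained_variance_ratio=pca.explained_variance_ratio,
        d=pca.d,
        beta_x=beta_x,
        beta_y=beta_y,
        axis_x=axis_x,
        axis_y=axis_y,
        axis_speed=axis_speed,
        cond_matrix=cond_matrix,
        cond_index=cond_index,
    )


def fit_subspace(
    table: pd.DataFrame,
    variance_threshold: float = 0.95,
    channel_mask: Optional[np.ndarray] = None,
) -> SubspaceModel:
    """Condition-average, PCA and axis fitting in one call.

    A channel mask (e.g. from the task-relevance screen) zeroes the excluded
    channels throughout, keeping channel indexing stable.
    """
    if channel_mask is not None:
        from .core_io import set_rate_matrix

        rates = rate_matrix(table)
        table = set_rate_matrix(table, np.where(channel_mask[None, :], rates, 0.0))
    cond_matrix, _ = condition_average(table)
    pca = fit_pca(cond_matrix, variance_threshold)
    return fit_axes(table, pca)


def project_states(table: pd.DataFrame, model: SubspaceModel) -> pd.DataFrame:
    """Per-trial neural states: inner products of centered rates with the axes.

    Single trials are centered with the condition-average centering vector,
    so a rate vector equal to that vector projects to the origin.
    """
    rates = rate_matrix(table)
    if rates.shape[1] != model.n_channels:
        raise ValueError(
            f"channel mismatch: table has {rates.shape[1]}, model {model.n_channels}"
        )
    centered = rates - model.center
    states = table[
        [
            "trial_id",
            "session_id",
            "task",
            "condition_id",
            "target_x",
            "target_y",
            "max_speed",
            "max_speed_x",
            "max_speed_y",
        ]
    ].copy()
    states["x_neural"] = centered @ model.axis_x
    states["y_neural"] = centered @ model.axis_y
    states["speed_neural"] = centered @ model.axis_speed
    return states


def explained_variance_in_plane(
    model: SubspaceModel,
    cond_matrix: np.ndarray,
    cond_index: pd.DataFrame,
    task: Optional[str] = None,
) -> float:
    """Fraction of condition-averaged variance captured by the spatial plane.

    Variance of the task's centered condition means projected onto the
    orthonormalized {x, y} axes, divided by their total variance.
    """
    cond_matrix = np.asarray(cond_matrix, dtype=float)
    if task is not None:
        mask = (cond_index["task"] == task).to_numpy()
        if not mask.any():
            raise ValueError(f"no conditions for task {task!r}")
        cond_matrix = cond_matrix[:, mask]
    centered = cond_matrix - cond_matrix.mean(axis=1, keepdims=True)
    total = (centered**2).sum()
    if total == 0:
        raise DegenerateInputError("zero variance across conditions")
    proj = model.plane_basis().T @ centered
    return float((proj**2).sum() / total)


def within_distance_speed_test(
    states: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Regress speed_neural on max speed separately at each target distance.

    Controls for the speed-distance correlation: a significant slope within a
    distance shows the axis carries speed information beyond distance.
    Distances with (near-)constant speed are excluded.  The returned frame
    has one row per distance with slope, p-value, n and a significance flag.
    """
    d = np.round(np.hypot(states["target_x"], states["target_y"]), 6)
    rows = []
    for dist in np.unique(d):
        sub = states[d == dist]
        speeds = sub["max_speed"].to_numpy(float)
        if len(sub) < 3 or np.std(speeds) == 0:
            continue
        res = stats.linregress(speeds, sub["speed_neural"].to_numpy(float))
        rows.append(
            {
                "distance": float(dist),
                "slope": res.slope,
                "pvalue": res.pvalue,
                "n": len(sub),
                "significant": res.pvalue < alpha,
            }
        )
    if not rows:
        raise DegenerateInputError("no distance had enough speed variation")
    return pd.DataFrame(rows)


def residual_distance_correlation(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[float, float]:
    """Distance information remaining after speed is regressed out.

    Each channel is residualized on max speed, a distance-regression axis is
    fit to the residuals, and the correlation between the residual projection
    and target distance is reported.  Both steps are cross-fitted on
    even/odd trial halves (fit on one half, evaluate on the other) so that
    under the null -- distance entering only through speed -- the
    correlation is centered at zero rather than inflated by in-sample
    overfitting.
    """
    rates = rate_matrix(table)
    speed = table["max_speed"].to_numpy(float)
    dist = target_distances(table)
    if np.std(dist) == 0:
        raise DegenerateInputError("only one target distance present")
    k = len(table)
    idx = np.arange(k)
    halves = (idx % 2 == 0, idx % 2 == 1)
    proj_all, dist_all = [], []
    for fit_half, eval_half in (halves, halves[::-1]):
        Xf = np.column_stack([np.ones(fit_half.sum()), speed[fit_half]])
        coef, _, _, _ = np.linalg.lstsq(Xf, rates[fit_half], rcond=RCOND)
        resid_fit = rates[fit_half] - Xf @ coef
        if (resid_fit**2).sum() <= 1e-12 * max(1.0, (rates**2).sum()):
            raise DegenerateInputError("zero residual variance after speed removal")
        axis = _lstsq_axis(resid_fit, dist[fit_half], "distance axis")
        Xe = np.column_stack([np.ones(eval_half.sum()), speed[eval_half]])
        resid_eval = rates[eval_half] - Xe @ coef
        proj_all.append(resid_eval @ axis)
        dist_all.append(dist[eval_half])
    r, p = stats.pearsonr(np.concatenate(proj_all), np.concatenate(dist_all))
    return float(r), float(p)


@dataclasses.dataclass
class ConvergenceProfile:
    """Mean in-plane distance to the converged delay state over time."""

    time_ms: np.ndarray
    mean_distance: np.ndarray
    crossing_ms: float  # first time mean distance < threshold * initial value
    threshold: float


def state_convergence_profile(
    series: RateTimeSeries,
    model: SubspaceModel,
    threshold: float = 0.1,
    window: tuple[float, float] = (-200.0, 0.0),
) -> ConvergenceProfile:
    """Time course of convergence toward the delay state in the spatial plane.

    Per trial, the converged state is the delay-window average of the
    in-plane projection; the profile is the across-trial mean Euclidean
    distance between the instantaneous and converged state.  The crossing
    time (linearly interpolated between samples) is the first time the mean
    distance drops below threshold x its initial value.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    k, n, T = series.rates.shape
    axes = np.column_stack([model.axis_x, model.axis_y])  # n x 2
    centered = series.rates - model.center[None, :, None]
    states = np.einsum("knt,nj->kjt", centered, axes)  # k x 2 x T
    conv = np.empty((k, 2))
    lo, hi = window
    for i in range(k):
        rel = series.time_ms - series.go_cue_ms[i]
        mask = (rel > lo) & (rel <= hi)
        if not mask.any():
            raise ValueError("delay window outside recorded series")
        conv[i] = states[i, :, mask].mean(axis=0)
    dist = np.linalg.norm(states - conv[:, :, None], axis=1)  # k x T
    mean_dist = dist.mean(axis=0)
    scale = max(1.0, float(np.linalg.norm(conv, axis=1).mean()))
    if mean_dist[0] <= 1e-9 * scale:
        # already at the converged state
        return ConvergenceProfile(
            time_ms=series.time_ms.copy(),
            mean_distance=mean_dist,
            crossing_ms=float(series.time_ms[0]),
            threshold=threshold,
        )
    level = threshold * mean_dist[0]
    below = np.nonzero(mean_dist <= level)[0]
    if below.size == 0:
        crossing = float("nan")
    else:
        j = int(below[0])
        if j == 0:
            crossing = float(series.time_ms[0])
        else:
            t0, t1 = series.time_ms[j - 1], series.time_ms[j]
            d0, d1 = mean_dist[j - 1], mean_dist[j]
            crossing = float(t0 + (d0 - level) / (d0 - d1) * (t1 - t0))
    return ConvergenceProfile(
        time_ms=series.time_ms.copy(),
        mean_distance=mean_dist,
        crossing_ms=crossing,
        threshold=threshold,
    )
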