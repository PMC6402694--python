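"""Trial-to-trial variability of the in-plane neural state.

A trial's *deviation* is its displacement from the condition-average state
in the spatial plane.  Deviations are decomposed along the radial direction
(origin to condition mean: the "on-axis" component, a proxy for distance
variability) and perpendicular to it ("off-axis", direction variability).
The same decomposition applies to kinematic deviations of the spatial
position of maximum speed.  Per-condition equal-frequency ellipses are
covariance-aligned, with one global scale calibrated so the stated fraction
of trials falls inside on average.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .subspace import DegenerateInputError

#: Conditions whose mean lies closer to the origin than this are excluded
#: (their radial direction is undefined).
MIN_MEAN_NORM = 1e-9


def _decompose(
    points: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Decompose per-point deviations from group means on/off the radial axis.

    Returns (on, off, valid_mask, excluded_groups).  The off-axis direction is
    the radial unit vector rotated by 90 degrees, u_perp = (-u_y, u_x), so a
    deviation counterclockwise of the radial direction is positive off-axis.
    """
    on = np.full(len(points), np.nan)
    off = np.full(len(points), np.nan)
    valid = np.zeros(len(points), dtype=bool)
    excluded = []
    for g in pd.unique(groups):
        idx = np.nonzero(groups == g)[0]
        mean = points[idx].mean(axis=0)
        norm = np.linalg.norm(mean)
        if norm < MIN_MEAN_NORM:
            excluded.append(g)
            continue
        u = mean / norm
        u_perp = np.array([-u[1], u[0]])
        dev = points[idx] - mean
        on[idx] = dev @ u
        off[idx] = dev @ u_perp
        valid[idx] = True
    return on, off, valid, excluded


def decompose_deviations(states: pd.DataFrame) -> pd.DataFrame:
    """On-/off-axis deviation of every trial's in-plane neural state.

    The radial axis of each condition points from the origin toward the
    condition-mean *neural state* (not the instructed target).  Conditions
    whose mean state sits at the origin are excluded and listed in the
    result's ``attrs["excluded_conditions"]``.  on^2 + off^2 equals the
    squared in-plane deviation (Pythagorean identity).
    """
    points = states[["x_neural", "y_neural"]].to_numpy(float)
    groups = (
        states["task"].astype(str) + "/" + states["condition_id"].astype(str)
    ).to_numpy()
    on, off, valid, excluded = _decompose(points, groups)
    out = states.loc[
        valid, ["trial_id", "task", "condition_id", "target_x", "target_y"]
    ].copy()
    out["on_axis"] = on[valid]
    out["off_axis"] = off[valid]
    out.attrs["excluded_conditions"] = excluded
    return out


def kinematic_deviations(table: pd.DataFrame) -> pd.DataFrame:
    """Same decomposition applied to the spatial position of maximum speed.

    The radial axis per condition is the direction of the condition-mean
    max-speed position, mirroring the neural convention.
    """
    points = table[["max_speed_x", "max_speed_y"]].to_numpy(float)
    groups = (
        table["task"].astype(str) + "/" + table["condition_id"].astype(str)
    ).to_numpy()
    on, off, valid, excluded = _decompose(points, groups)
    out = table.loc[
        valid, ["trial_id", "task", "condition_id", "target_x", "target_y"]
    ].copy()
    out["on_axis"] = on[valid]
    out["off_axis"] = off[valid]
    out.attrs["excluded_conditions"] = excluded
    return out


def correlate_neural_kinematic(
    neural: pd.DataFrame, kinematic: pd.DataFrame
) -> dict[str, tuple[float, float]]:
    """Trial-by-trial correlation of neural vs kinematic deviations.

    Returns {"on": (r, p), "off": (r, p)} across trials present in both
    decompositions (matched on task / condition / trial id).
    """
    keys = ["task", "condition_id", "trial_id"]
    merged = neural.merge(kinematic, on=keys, suffixes=("_neural", "_kin"))
    if len(merged) < 3:
        raise DegenerateInputError("too few matched trials for correlation")
    out = {}
    for comp in ("on", "off"):
        r, p = stats.pearsonr(
            merged[f"{comp}_axis_neural"], merged[f"{comp}_axis_kin"]
        )
        out[comp] = (float(r), float(p))
    return out


@dataclasses.dataclass
class EllipseSummary:
    """Per-condition equal-frequency ellipse in the spatial plane."""

    task: str
    condition_id: int
    center: np.ndarray  # mean state
    major_axis: np.ndarray  # unit vector
    minor_axis: np.ndarray
    major_length: float  # semi-axis after coverage scaling
    minor_length: float
    orientation_rad: float  # acute angle between major axis and radial dir
    degenerate: bool


def _inside_fraction(
    devs: list[np.ndarray], sds: list[np.ndarray], scale: float
) -> float:
    """Across-condition mean fraction of trials inside their scaled ellipse."""
    fracs = []
    for dev, sd in zip(devs, sds):
        with np.errstate(divide="ignore", invalid="ignore"):
            m = (dev / (scale * sd)) ** 2
        # a collapsed axis contributes 0 for points on it, inf otherwise
        m = np.where(sd > 0.0, m, np.where(np.abs(dev) <= 1e-9, 0.0, np.inf))
        inside = m.sum(axis=1) <= 1.0
        fracs.append(inside.mean())
    return float(np.mean(fracs))


def equal_frequency_ellipses(
    states: pd.DataFrame, coverage: float = 0.95
) -> tuple[list[EllipseSummary], float]:
    """Covariance-aligned ellipses with a globally calibrated coverage scale.

    Per condition, the ellipse axes are the principal components of the
    in-plane states and the semi-axis lengths are the per-axis standard
    deviations times a single global scale s, found by bisection so that the
    across-condition average fraction of trials inside their ellipse equals
    the requested coverage.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    points = states[["x_neural", "y_neural"]].to_numpy(float)
    summaries = []
    devs, sds = [], []
    for (task, cid), idx in states.groupby(["task", "condition_id"]).indices.items():
        if len(idx) < 3:
            raise ValueError(f"condition {task}/{cid} has fewer than 3 trials")
        pts = points[idx]
        center = pts.mean(axis=0)
        cov = np.cov(pts.T)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
        sd = np.sqrt(evals)
        degenerate = sd[1] <= 1e-12 * max(sd[0], 1.0)
        dev = pts - center
        local = dev @ evecs  # coordinates along (major, minor)
        devs.append(local)
        sds.append(sd)
        norm = np.linalg.norm(center)
        if norm < MIN_MEAN_NORM:
            orientation = float("nan")
        else:
            cosang = abs(evecs[:, 0] @ (center / norm))
            orientation = float(np.arccos(np.clip(cosang, 0.0, 1.0)))
        summaries.append(
            EllipseSummary(
                task=task,
                condition_id=int(cid),
                center=center,
                major_axis=evecs[:, 0],
                minor_axis=evecs[:, 1],
                major_length=sd[0],
                minor_length=sd[1],
                orientation_rad=orientation,
                degenerate=bool(degenerate),
            )
        )
    # bisection on the global scale; inside-fraction is nondecreasing in s
    lo, hi = 1e-6, 10.0
    while _inside_fraction(devs, sds, hi) < coverage:
        hi *= 2.0
        if hi > 1e6:
            break
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _inside_fraction(devs, sds, mid) >= coverage:
            hi = mid
        else:
            lo = mid
    scale = hi
    for summ in summaries:
        summ.major_length *= scale
        summ.minor_length *= scale
    return summaries, float(scale)


def relative_deviation_profile(devs: pd.DataFrame) -> pd.DataFrame:
    """Mean |on|/d and |off|/d per target distance, with SEM and a trend test.

    The profile frame has one row per distance; ``attrs["spearman"]`` holds
    {"on": (rho, p), "off": (rho, p)} rank correlations of the per-distance
    means against distance (negative rho = relative deviation shrinks with
    distance).
    """
    d = np.round(np.hypot(devs["target_x"], devs["target_y"]), 6)
    if len(np.unique(d)) < 2:
        raise ValueError("need at least 2 distinct target distances")
    rows = []
    for dist in np.unique(d):
        sub = devs[d == dist]
        rel_on = np.abs(sub["on_axis"]) / dist
        rel_off = np.abs(sub["off_axis"]) / dist
        rows.append(
            {
                "distance": float(dist),
                "rel_on_mean": rel_on.mean(),
                "rel_on_sem": rel_on.std(ddof=1) / np.sqrt(len(sub)),
                "rel_off_mean": rel_off.mean(),
                "rel_off_sem": rel_off.std(ddof=1) / np.sqrt(len(sub)),
                "n": len(sub),
            }
        )
    profile = pd.DataFrame(rows).sort_values("distance", ignore_index=True)
    trend = {}
    for comp in ("on", "off"):
        means = profile[f"rel_{comp}_mean"]
        if means.nunique() <= 1:  # constant profile: trend undefined
            trend[comp] = (float("nan"), float("nan"))
            continue
        rho, p = stats.spearmanr(profile["distance"], means)
        trend[comp] = (float(rho), float(p))
    profile.attrs["spearman"] = trend
    return profile


def welch_ttest(a, b) -> tuple[float, float]:
    """Two-sided Student t test assuming unequal variances (Welch).

    Degrees of freedom via Welch-Satterthwaite.  Raises on the undefined
    case of two zero-variance samples with equal means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            raise DegenerateInputError("both samples constant with equal means")
        return float(np.inf * np.sign(a.mean() - b.mean())), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
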