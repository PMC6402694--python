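"""Synthetic delay-period population activity.

The generator emulates the statistical structure the downstream analyses
assume about premotor (PMd) multiunit delay activity in an instructed-delay
center-out task:

* four target layouts (an 8 cm ring; horizontal and vertical lines of targets
  1..12 cm either side of the center; three concentric rings at 4/8/12 cm);
* linear population encoding of the *planned endpoint* (x, y in cm) and of
  maximum reach speed (cm/s) with additive Gaussian channel noise on binned
  rates;
* positively correlated speed and distance (speed = a + b*d + noise) with
  within-distance speed variability;
* anisotropic endpoint planning noise: radial ("on-axis", distance) standard
  deviation exceeds tangential ("off-axis", direction), both growing like
  sqrt(distance) so the deviation *relative* to distance shrinks with
  distance;
* a shared component between neural and kinematic trial-to-trial deviations
  (the spatial position of maximum speed), controlled by a coupling kappa;
* post-target-onset dynamics: the population state ramps exponentially from
  baseline to its converged delay state after a latency t0.

Defaults are chosen for testability of the analysis chain, not biological
fidelity (no public dataset accompanies the analyses this package
reimplements).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import (
    METADATA_COLUMNS,
    RateTimeSeries,
    SUBJECTS,
    TASKS,
    rate_column_names,
    validate_trials,
)

#: Uniform delay ranges (ms) per subject, matching the task design.
DELAY_RANGE = {"J": (300.0, 700.0), "R": (400.0, 900.0)}


@dataclasses.dataclass
class TargetLayout:
    """Named set of reach targets with contiguous condition ids."""

    name: str
    subject: str
    targets: pd.DataFrame  # columns: condition_id, x, y
    ring_radii: tuple[float, ...] = ()

    @property
    def n_conditions(self) -> int:
        return len(self.targets)

    def positions(self) -> np.ndarray:
        return self.targets[["x", "y"]].to_numpy(dtype=float)


def make_target_layout(name: str, subject: str = "J") -> TargetLayout:
    """Deterministic target layout for one task configuration.

    ``ring``: radius 8 cm, 24 targets (J) or 36 (R), evenly spaced starting
    at angle 0.  ``horizontal``/``vertical``: 12 targets per side of the
    center spaced 1 cm apart along y=0 / x=0.  ``rings3``: three concentric
    rings of 16 targets at radii 4, 8 and 12 cm.
    """
    if name not in TASKS:
        raise ValueError(f"unknown layout {name!r}")
    if subject not in SUBJECTS:
        raise ValueError(f"unknown subject {subject!r}")
    if name == "ring":
        n = 24 if subject == "J" else 36
        ang = 2.0 * np.pi * np.arange(n) / n
        xy = 8.0 * np.column_stack([np.cos(ang), np.sin(ang)])
        radii = (8.0,)
    elif name == "rings3":
        rows = []
        for r in (4.0, 8.0, 12.0):
            ang = 2.0 * np.pi * np.arange(16) / 16
            rows.append(r * np.column_stack([np.cos(ang), np.sin(ang)]))
        xy = np.vstack(rows)
        radii = (4.0, 8.0, 12.0)
    else:
        offsets = np.concatenate([np.arange(-12.0, 0.0), np.arange(1.0, 13.0)])
        if name == "horizontal":
            xy = np.column_stack([offsets, np.zeros_like(offsets)])
        else:
            xy = np.column_stack([np.zeros_like(offsets), offsets])
        radii = ()
    targets = pd.DataFrame(
        {"condition_id": np.arange(len(xy)), "x": xy[:, 0], "y": xy[:, 1]}
    )
    return TargetLayout(name=name, subject=subject, targets=targets, ring_radii=radii)


@dataclasses.dataclass
class GeneratorParams:
    """Tunable parameters of the synthetic recording.

    Encoding gains are drawn once from a seeded standard normal scaled to
    give O(10 spikes/s) modulation over the workspace; the channel baseline
    keeps rate clipping at zero rare (<1% of entries) so linear-recovery
    tests remain valid.
    """

    n_channels: int = 96
    baseline: float = 40.0  # spikes/s
    sigma_ch: float = 2.0  # spikes/s, additive rate noise per channel
    speed_intercept: float = 10.0  # a, cm/s
    speed_slope: float = 2.0  # b, (cm/s)/cm; > 0 couples speed to distance
    sigma_speed: float = 2.0  # cm/s, within-distance speed sd
    c_on: float = 0.4  # cm * cm^-1/2: on-axis sd = c_on * sqrt(d)
    c_off: float = 0.2  # cm * cm^-1/2: off-axis sd = c_off * sqrt(d)
    deviation_model: str = "sqrt_distance"  # or "constant": sd = c (cm)
    kappa: float = 0.8  # neural-kinematic deviation coupling
    sigma_kin: float = 0.1  # cm, independent kinematic noise
    rho: float = 0.5  # max-speed position scale (~mid-reach)
    t0: float = 50.0  # ms, response latency after target onset
    tau: float = 80.0  # ms, convergence time constant
    w_scale_xy: float = 0.8  # spikes/s per cm
    w_scale_speed: float = 0.15  # spikes/s per (cm/s)
    w_seed: int = 12345
    w_orthogonal: bool = False  # orthogonalize encoding columns (QR)
    W: Optional[np.ndarray] = None  # n_channels x 3; drawn if None

    def __post_init__(self) -> None:
        if self.deviation_model not in ("sqrt_distance", "constant"):
            raise ValueError(f"unknown deviation model {self.deviation_model!r}")
        for name in ("sigma_ch", "sigma_speed", "c_on", "c_off", "sigma_kin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def encoding_matrix(self) -> np.ndarray:
        """Channel gains for (x, y, speed); drawn once per w_seed."""
        if self.W is not None:
            W = np.asarray(self.W, dtype=float)
            if W.shape != (self.n_channels, 3):
                raise ValueError("W must be n_channels x 3")
            return W
        rng = np.random.default_rng(self.w_seed)
        W = rng.standard_normal((self.n_channels, 3))
        W *= np.array([self.w_scale_xy, self.w_scale_xy, self.w_scale_speed])
        if self.w_orthogonal:
            # exactly orthogonal encoding directions with the same gains;
            # makes the sequential axis orthogonalization lossless, which is
            # the premise of noiseless-identifiability checks
            norms = np.linalg.norm(W, axis=0)
            Q, _ = np.linalg.qr(W)
            W = Q * norms
        return W

    def deviation_sd(self, distance: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(on-axis sd, off-axis sd) at the given target distances."""
        d = np.asarray(distance, dtype=float)
        if self.deviation_model == "sqrt_distance":
            root = np.sqrt(d)
            return self.c_on * root, self.c_off * root
        return np.full_like(d, self.c_on), np.full_like(d, self.c_off)


def _condition_draws(
    layout: TargetLayout, params: GeneratorParams, n_per_condition: int, rng
):
    """Per-trial planned endpoints, speeds and kinematic max-speed positions."""
    pos = np.repeat(layout.positions(), n_per_condition, axis=0)
    cond = np.repeat(layout.targets["condition_id"].to_numpy(), n_per_condition)
    d = np.hypot(pos[:, 0], pos[:, 1])
    u = pos / d[:, None]  # radial unit vector (no target sits at the origin)
    u_perp = np.column_stack([-u[:, 1], u[:, 0]])
    sd_on, sd_off = params.deviation_sd(d)
    delta_on = rng.normal(0.0, 1.0, size=len(d)) * sd_on
    delta_off = rng.normal(0.0, 1.0, size=len(d)) * sd_off
    dev = delta_on[:, None] * u + delta_off[:, None] * u_perp
    endpoint = pos + dev
    speed = (
        params.speed_intercept
        + params.speed_slope * d
        + rng.normal(0.0, params.sigma_speed, size=len(d))
    )
    kin = params.rho * (pos + params.kappa * dev) + rng.normal(
        0.0, params.sigma_kin, size=(len(d), 2)
    )
    return cond, pos, endpoint, speed, kin


def simulate_trials(
    layout: TargetLayout,
    params: GeneratorParams,
    n_per_condition: int = 10,
    seed: int = 0,
    session_id: str = "s0",
) -> pd.DataFrame:
    """Simulate a TrialTable: rates = W @ [endpoint, speed] + baseline + noise.

    Per trial of condition c with target p_c (distance d, radial unit u):
    delta_on ~ N(0, sd_on(d)^2) and delta_off ~ N(0, sd_off(d)^2) displace the
    planned endpoint along u and its perpendicular; maximum speed is
    a + b*d + eps; the spatial position of maximum speed is
    rho*(p_c + kappa*deviation) + eps_kin.  Rates are clipped at zero.
    Same seed, same table (bit-reproducible).
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    rng = np.random.default_rng(seed)
    cond, pos, endpoint, speed, kin = _condition_draws(
        layout, params, n_per_condition, rng
    )
    k = len(cond)
    W = params.encoding_matrix()
    latent = np.column_stack([endpoint, speed])  # k x 3
    rates = latent @ W.T + params.baseline
    rates += rng.normal(0.0, params.sigma_ch, size=rates.shape)
    np.clip(rates, 0.0, None, out=rates)
    lo, hi = DELAY_RANGE[layout.subject]
    table = pd.DataFrame(
        {
            "trial_id": np.arange(k),
            "session_id": session_id,
            "task": layout.name,
            "condition_id": cond,
            "target_x": pos[:, 0],
            "target_y": pos[:, 1],
            "delay": rng.uniform(lo, hi, size=k),
            "max_speed": speed,
            "max_speed_x": kin[:, 0],
            "max_speed_y": kin[:, 1],
        }
    )
    table[rate_column_names(params.n_channels)] = rates
    return validate_trials(table)


def simulate_timecourse(
    layout: TargetLayout,
    params: GeneratorParams,
    n_per_condition: int = 1,
    timesteps: int = 80,
    dt: float = 10.0,
    seed: int = 0,
    session_id: str = "s0",
) -> RateTimeSeries:
    """Simulate rate time series from target onset through the delay.

    The latent gain ramps as g(t) = 0 for t < t0 and 1 - exp(-(t-t0)/tau)
    after, so rates move from baseline toward the converged delay state:
    r(t) = W @ (g(t) * [endpoint, speed]) + baseline + noise.  The go cue is
    placed at the final sample, so the delay window (-200, 0] ms precedes it.
    """
    if timesteps * dt < params.t0:
        raise ValueError("series must extend past the latency t0")
    rng = np.random.default_rng(seed)
    cond, pos, endpoint, speed, kin = _condition_draws(
        layout, params, n_per_condition, rng
    )
    k = len(cond)
    W = params.encoding_matrix()
    latent = np.column_stack([endpoint, speed])  # k x 3
    time_ms = np.arange(timesteps) * dt
    g = np.where(
        time_ms < params.t0, 0.0, 1.0 - np.exp(-(time_ms - params.t0) / params.tau)
    )
    drive = latent @ W.T  # k x n
    rates = g[None, None, :] * drive[:, :, None] + params.baseline
    if params.sigma_ch > 0:
        rates = rates + rng.normal(0.0, params.sigma_ch, size=rates.shape)
    np.clip(rates, 0.0, None, out=rates)
    lo, hi = DELAY_RANGE[layout.subject]
    meta = pd.DataFrame(
        {
            "trial_id": np.arange(k),
            "session_id": session_id,
            "task": layout.name,
            "condition_id": cond,
            "target_x": pos[:, 0],
            "target_y": pos[:, 1],
            "delay": rng.uniform(lo, hi, size=k),
            "max_speed": speed,
            "max_speed_x": kin[:, 0],
            "max_speed_y": kin[:, 1],
        }
    )
    go_cue = np.full(k, time_ms[-1])
    return RateTimeSeries(rates=rates, time_ms=time_ms, go_cue_ms=go_cue, meta=meta)
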