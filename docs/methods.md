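# Methods

## The synthetic recording

No public dataset accompanies the analyses this package reimplements, so a
generator stands in for the array recordings. It emulates exactly the
statistical structure the downstream stages assume; everything it does is
visible in `delaystate.synthetic`.

Per trial of condition *c* with target `p_c` (distance `d = |p_c|`, radial
unit `u`):

* planned endpoint `e = p_c + δ_on·u + δ_off·u⊥`, with
  `δ_on ~ N(0, c_on²·d)` and `δ_off ~ N(0, c_off²·d)`. The √d scaling makes
  the absolute deviation grow with distance while the *relative* deviation
  `sd/d = c/√d` shrinks, and `c_on > c_off` makes distance variability exceed
  direction variability — both are structural assumptions of the
  variability analyses. A `constant` mode (`sd = c`, independent of d)
  exists for decoding-geometry constructions (below).
* maximum reach speed `s = a + b·d + ε`, `ε ~ N(0, σ_s²)`: speed and
  distance are strongly correlated across distances but speed still varies
  within a distance — the premise of the within-distance speed test.
* channel rates `r = W·[e_x, e_y, s]ᵀ + baseline + η`, `η ~ N(0, σ_ch² I)`,
  clipped at 0. Noise is Gaussian on binned rates, not Poisson on spike
  counts, because the analyses operate on 200-ms multiunit rate averages.
* spatial position of maximum speed `k = ρ·(p_c + κ·(δ_on·u + δ_off·u⊥)) + ε_k`:
  the kinematic deviation shares the neural deviation through κ, giving the
  neural–kinematic correlation something true to detect; ρ = 0.5 places the
  max-speed point mid-reach (only the correlation structure matters
  downstream).

The time-course generator ramps the latent drive with gain
`g(t) = 1 − exp(−(t−t0)/τ)` after a latency `t0`, so the population state
moves from baseline to its converged delay state; the 10%-criterion
convergence time has the closed form `t0 + τ·ln 10`, used as an oracle.

### Parameters

| parameter | default | units | why |
|---|---|---|---|
| `n_channels` | 96 | — | one Utah array of multiunit channels |
| `baseline` | 40 | spikes/s | typical multiunit rate; keeps zero-clipping <0.01% so linear-recovery tests stay valid |
| `sigma_ch` | 2 | spikes/s | per-channel rate noise at 200-ms binning |
| `w_scale_xy` / `w_scale_speed` | 0.8 / 0.15 | spikes/s per cm, per cm/s | drawn once from a seeded normal; O(10 spikes/s) modulation over the workspace |
| `speed_intercept` / `speed_slope` | 10 / 2 | cm/s, (cm/s)/cm | speeds 12–34 cm/s over 1–12 cm reaches |
| `sigma_speed` | 2 | cm/s | within-distance speed variability |
| `c_on` / `c_off` | 0.4 / 0.2 | cm·cm^-1/2 | 2:1 distance:direction anisotropy |
| `kappa` | 0.8 | — | neural–kinematic deviation coupling |
| `sigma_kin` | 0.1 | cm | independent kinematic measurement noise |
| `t0` / `tau` | 50 / 80 | ms | post-target-onset latency and convergence constant |

Defaults were chosen once for testability of the analysis chain, not
biological fidelity; the magnitudes of PMd channel noise are not publicly
characterized at this granularity.

The target layouts are fixed: an 8-cm ring (24 targets for subject J, 36 for
R), horizontal and vertical lines (12 targets per side, 1 cm apart), and
three concentric rings (radii 4, 8, 12 cm; 16 targets each). Delay lengths
are uniform (300–700 ms for J, 400–900 ms for R).

### What the generator does not emulate

Poisson spiking, unit instability across sessions, reaction times, failed or
zero-delay catch trials, eye/arm posture covariates, nonlinear or
heterogeneous tuning, and temporal dynamics richer than a single exponential
ramp. Passing tests therefore certify the *analysis chain* — that each stage
recovers the structure it targets when that structure is present, and stays
calibrated when it is absent — not that real PMd data would yield the same
numbers.

## Preprocessing conventions

* Delay window: half-open `(−200, 0]` ms relative to the go cue, which
  avoids double-counting a sample exactly at the cue.
* Baseline subtraction centers each channel within each *session* (day);
  task is deliberately not part of the grouping because tasks are pooled
  after centering.
* The channel screen regresses each channel on target (x, y) and evaluates
  the overall two-predictor F test against the intercept-only model
  (Bonferroni-corrected at α/96). Constant channels get p = 1. Screened-out
  channels are flagged, not deleted; the subspace fit takes an optional
  mask. The default analysis uses all channels, since it is not established
  that screening preceded the published PCA.

## Subspace numerics

* PCA runs on the condition-averaged matrix, mean-centered across
  conditions; `d` is the smallest count whose cumulative explained variance
  reaches the threshold (a 1e−9 slack absorbs floating round-off when the
  threshold is 1.0).
* All least squares use a pseudoinverse with relative singular-value cutoff
  1e−10, so rank-deficient designs degrade gracefully; the minimum-norm
  solution keeps each new axis in the row space of the null-projected data
  and hence orthogonal to its predecessors to machine precision.
* Single trials are centered with the condition-average centering vector
  before projection, which makes the centering vector itself project to the
  origin.
* Orthogonalization order is fixed to x → y → speed. Sequential
  orthogonalization is lossless only when the underlying channel-space
  encodings are themselves orthogonal; with a randomly drawn 96-channel
  encoding the x/y encodings overlap by ~1/√96, leaving a structured
  residual of relative size ~1e−5 in the y fit. The generator's
  `w_orthogonal` option (QR of the drawn gains, column norms preserved)
  provides the exactly-orthogonal regime in which noiseless identifiability
  holds to machine precision; on noisy defaults the distinction is far below
  the noise floor.
* "Per distance" grouping rounds distances to 1e−6 cm first.
* Both single-trial speed analyses are *cross-fitted*: the within-distance
  speed test is run on trials not used to fit the axes, and the residual
  distance correlation fits its speed-residualization and distance axis on
  even trials and evaluates on odd trials (and vice versa). In-sample
  variants are anti-conservative at desk scale — a least-squares axis fit on
  n trials of p channels couples the projection to the trial noise at
  magnitude ~√(p/n), which would inflate null significance rates.

## Variability conventions

* The radial ("on") axis of a condition points from the origin to the
  condition-mean *neural state*, not to the instructed target (the two are
  close whenever the plane is well fit); conditions whose mean state sits at
  the origin are excluded and reported. The off-axis direction is the radial
  unit rotated 90° (`u⊥ = (−u_y, u_x)`); its sign affects no reported
  statistic.
* Equal-frequency ellipses are per-condition PCA ellipses with one *global*
  scale found by bisection so the across-condition mean inside-fraction
  equals the requested coverage (matching "95% on average", not
  per-condition quantiles).
* The on-vs-off comparison is a two-sided Welch t test (unequal variances,
  Welch–Satterthwaite degrees of freedom) on per-trial absolute deviations.

## Decoding choices

* Classifier: `SVC(kernel="rbf", C=1, gamma="scale")`, one-vs-one, under
  seeded stratified k-fold (default 10). The published hyperparameter search
  on a held-out set is replaced by an optional grid-search flag; class
  imbalance across folds would corrupt per-ring metrics, hence
  stratification. Features default to raw channel rates (PC scores are an
  option).
* Distance classification on line layouts trains and tests within one
  direction (task × side of center) at a time and aggregates errors.
* Arc-length error is the minimal circular angle difference times the *true*
  target's ring radius; the restricted arc mean keeps only errors within the
  error range of the smallest ring (≤ π·r_min). The variance-ratio F test is
  two-sided with the larger variance in the numerator.
* The arc-length distance-independence construction uses the generator's
  `constant` deviation mode with positional sd 3.0 cm. That value sits in
  the regime the construction is meant to exhibit: large enough that
  misclassifications occur at every radius and the ring-specific target-grid
  quantization (inter-target spacing 1.6/3.1/4.7 cm) does not dominate the
  arc-error variance, yet small enough that wrapping around the 4-cm ring
  does not truncate the distribution. Outside that window the F test
  correctly detects the grid, which is a property of the construction, not
  of the statistic.
* The spatial-plane ablation compares mean distance-classification error
  with full rates versus plane-only features. When speed is uncoupled from
  distance (b = 0) the comparison is assessed with a paired per-trial
  confidence interval from a single experiment; a small systematic benefit
  of the 2-D features (fewer irrelevant dimensions for the RBF kernel)
  exists but is well inside that interval.

## Problem sizes

The shipped drivers and checks use 50 trials/condition for the main study
(6,000 trials over four tasks), 100/condition for variability recovery,
500/condition for coverage calibration, 10/condition for the decoding-
geometry replicates, and 200 replicates for the null-calibration rates —
sizes chosen as a desk-scale study that keeps every statistic comfortably
powered.

## Known limitations

* The generator's linear-Gaussian encoding means the residual distance
  correlation after speed removal is near zero by construction (distance
  enters the rates only through the endpoint and speed codes); a positive
  correlation appears only when channels encode distance directly, as the
  corresponding test constructs.
* The speed-axis-to-distance-axis PC-projection ratio reported descriptively
  in the source analyses depends on unpublished generator-level quantities
  and is not asserted anywhere.
* Equal-frequency ellipse axis ratios are biased upward at small
  per-condition trial counts (sample-eigenvalue spreading); calibrations use
  ≥100 trials/condition.
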