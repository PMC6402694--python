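import numpy as np
import pandas as pd
import pytest

from delaystate import preprocess, subspace, synthetic
from delaystate.core_io import rate_matrix
from delaystate.subspace import (
    DegenerateInputError,
    condition_average,
    explained_variance_in_plane,
    fit_pca,
    fit_subspace,
    project_states,
    residual_distance_correlation,
    state_convergence_profile,
    within_distance_speed_test,
)
from delaystate.synthetic import GeneratorParams, make_target_layout, simulate_trials

NOISELESS = dict(sigma_ch=0.0, sigma_speed=0.0, c_on=0.0, c_off=0.0, sigma_kin=0.0)


def pca_oracle(cond_matrix):
    """Brute-force covariance eigendecomposition (channels x conditions)."""
    X = cond_matrix - cond_matrix.mean(axis=1, keepdims=True)
    cov = X @ X.T / (X.shape[1] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    return evecs[:, order].T, evals / evals.sum()


class TestConditionAverage:
    def test_matches_loop_oracle(self, small_table):
        mat, idx = condition_average(small_table)
        R = rate_matrix(small_table)
        for j, row in idx.iterrows():
            mask = (small_table["condition_id"] == row.condition_id).to_numpy()
            np.testing.assert_allclose(mat[:, j], R[mask].mean(axis=0), atol=1e-12)

    def test_single_and_pair_trials(self, ring_layout, default_params):
        t = simulate_trials(ring_layout, default_params, 2, seed=1)
        mat, idx = condition_average(t)
        R = rate_matrix(t)
        a, b = R[0], R[1]  # first condition's two trials
        j = idx.index[idx.condition_id == t.condition_id.iloc[0]][0]
        np.testing.assert_allclose(mat[:, j], (a + b) / 2, atol=1e-12)


class TestPCA:
    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n, c = rng.integers(3, 11, size=2)
            M = rng.normal(size=(n, c))
            res = fit_pca(M, 0.95)
            axes, evr = pca_oracle(M)
            m = min(len(res.explained_variance_ratio), c - 1)
            np.testing.assert_allclose(res.explained_variance_ratio[:m], evr[:m], atol=1e-10)
            for i in range(m):
                dot = abs(res.components[i] @ axes[i])
                assert dot > 1.0 - 1e-8

    def test_rank2_plane_needs_two_components(self):
        rng = np.random.default_rng(1)
        basis = rng.normal(size=(5, 2))
        M = basis @ rng.normal(size=(2, 8)) + rng.normal(size=(5, 1))
        res = fit_pca(M, 0.95)
        assert res.d == 2
        assert res.explained_variance_ratio[:2].sum() > 1.0 - 1e-10

    def test_variance_fractions_sorted(self, small_table):
        mat, _ = condition_average(small_table)
        res = fit_pca(mat)
        evr = res.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-9
        # d is the smallest count reaching the threshold
        cum = np.cumsum(evr)
        assert cum[res.d - 1] >= 0.95 - 1e-9
        assert res.d == 1 or cum[res.d - 2] < 0.95

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_pca(np.ones((4, 6)))


class TestAxes:
    def test_axes_pairwise_orthogonal(self, line_tables):
        m = fit_subspace(line_tables)
        for a, b in [
            (m.axis_x, m.axis_y),
            (m.axis_x, m.axis_speed),
            (m.axis_y, m.axis_speed),
        ]:
            rel = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert rel < 1e-8

    def test_row_permutation_invariance(self, small_table):
        m1 = fit_subspace(small_table)
        shuffled = small_table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        m2 = fit_subspace(shuffled)
        np.testing.assert_allclose(m1.axis_x, m2.axis_x, atol=1e-8)
        np.testing.assert_allclose(m1.axis_speed, m2.axis_speed, atol=1e-8)

    def test_degenerate_regressand_raises(self, default_params):
        h = make_target_layout("horizontal", "J")
        t = simulate_trials(h, default_params, 5, seed=0)
        with pytest.raises(DegenerateInputError, match="y axis"):
            fit_subspace(t)  # all targets share y = 0

    def test_noiseless_projection_recovers_targets(self, rings3_layout):
        p = GeneratorParams(w_orthogonal=True, **NOISELESS)
        t = simulate_trials(rings3_layout, p, 2, seed=3)
        m = fit_subspace(t, variance_threshold=1.0)
        s = project_states(t, m)
        xy = s[["x_neural", "y_neural"]].to_numpy()
        tgt = t[["target_x", "target_y"]].to_numpy()
        assert ((xy - tgt) ** 2).sum() / (tgt**2).sum() < 1e-16


class TestProjection:
    def test_center_maps_to_origin(self, small_table):
        m = fit_subspace(small_table)
        t = small_table.iloc[[0]].copy()
        t[[f"rate_{i:03d}" for i in range(96)]] = m.center
        s = project_states(t, m)
        assert np.allclose(
            s[["x_neural", "y_neural", "speed_neural"]].to_numpy(), 0.0, atol=1e-9
        )

    def test_projection_is_linear(self, small_table):
        m = fit_subspace(small_table)
        cols = [f"rate_{i:03d}" for i in range(96)]
        a = small_table.iloc[[0]].copy()
        b = small_table.iloc[[1]].copy()
        ab = a.copy()
        ab[cols] = a[cols].to_numpy() + b[cols].to_numpy() - m.center
        va = project_states(a, m)[["x_neural", "y_neural", "speed_neural"]].to_numpy()
        vb = project_states(b, m)[["x_neural", "y_neural", "speed_neural"]].to_numpy()
        vab = project_states(ab, m)[["x_neural", "y_neural", "speed_neural"]].to_numpy()
        np.testing.assert_allclose(vab, va + vb, atol=1e-8)

    def test_channel_mismatch_raises(self, small_table):
        m = fit_subspace(small_table)
        t = small_table.drop(columns=["rate_095"])
        with pytest.raises(ValueError, match="channel mismatch"):
            project_states(t, m)


class TestPlaneVariance:
    def test_limits_and_oracle(self, small_table):
        m = fit_subspace(small_table)
        mat, idx = condition_average(small_table)
        ev = explained_variance_in_plane(m, mat, idx, "ring")
        # brute-force oracle
        centered = mat - mat.mean(axis=1, keepdims=True)
        B = m.plane_basis()
        oracle = ((B.T @ centered) ** 2).sum() / (centered**2).sum()
        assert np.isclose(ev, oracle, atol=1e-12)
        assert 0.0 <= ev <= 1.0

    def test_full_and_zero_capture(self):
        rng = np.random.default_rng(2)
        Q = np.linalg.qr(rng.normal(size=(6, 6)))[0]
        mat = Q[:, :2] @ rng.normal(size=(2, 9))
        mat -= mat.mean(axis=1, keepdims=True)
        idx = pd.DataFrame(
            {"task": "ring", "condition_id": range(9), "target_x": 0.0, "target_y": 0.0}
        )

        def model_with_plane(ax, ay):
            return subspace.SubspaceModel(
                center=np.zeros(6),
                components=np.eye(6),
                explained_variance_ratio=np.ones(6) / 6,
                d=2,
                beta_x=np.zeros(2),
                beta_y=np.zeros(2),
                axis_x=ax,
                axis_y=ay,
                axis_speed=Q[:, 4],
                cond_matrix=mat,
                cond_index=idx,
            )

        spanning = model_with_plane(Q[:, 0], Q[:, 1])
        assert np.isclose(
            explained_variance_in_plane(spanning, mat, idx, "ring"), 1.0, atol=1e-10
        )
        orthogonal = model_with_plane(Q[:, 2], Q[:, 3])
        assert explained_variance_in_plane(orthogonal, mat, idx, "ring") < 1e-10


class TestSpeedTest:
    def test_perfect_fit_gives_unit_slope(self):
        rng = np.random.default_rng(0)
        n = 40
        states = pd.DataFrame(
            {
                "target_x": np.repeat([3.0, 6.0], n // 2),
                "target_y": 0.0,
                "max_speed": rng.uniform(10, 30, n),
            }
        )
        states["speed_neural"] = states["max_speed"]
        res = within_distance_speed_test(states)
        assert np.allclose(res["slope"], 1.0, atol=1e-12)
        assert (res["pvalue"] < 1e-10).all()

    def test_constant_speed_distance_excluded(self):
        states = pd.DataFrame(
            {
                "target_x": np.repeat([3.0, 6.0], 10),
                "target_y": 0.0,
                "max_speed": np.concatenate([np.full(10, 20.0), np.linspace(10, 30, 10)]),
                "speed_neural": np.zeros(20),
            }
        )
        res = within_distance_speed_test(states)
        assert list(res["distance"]) == [6.0]

    def test_speed_significant_at_nearly_all_distances(self, line_tables, default_params):
        h = make_target_layout("horizontal", "J")
        v = make_target_layout("vertical", "J")
        test = pd.concat(
            [
                simulate_trials(h, default_params, 20, seed=70),
                simulate_trials(v, default_params, 20, seed=71),
            ],
            ignore_index=True,
        )
        model = fit_subspace(line_tables)
        states = project_states(test, model)
        res = within_distance_speed_test(states)
        assert len(res) == 12
        assert res["significant"].sum() >= 11


class TestResidualDistance:
    def test_null_when_distance_enters_only_via_speed(self):
        v = make_target_layout("vertical", "J")
        p0 = GeneratorParams()
        W = p0.encoding_matrix().copy()
        W[:, :2] = 0.0  # no endpoint encoding: distance info only via speed
        t = simulate_trials(v, GeneratorParams(W=W), 40, seed=3)
        r, p = residual_distance_correlation(t)
        assert abs(r) < 0.1

    def test_positive_with_explicit_distance_channel(self, default_params):
        v = make_target_layout("vertical", "J")
        t = simulate_trials(v, default_params, 40, seed=4).copy()
        d = np.hypot(t.target_x, t.target_y)
        rng = np.random.default_rng(0)
        for ch in range(4):  # a few channels encode distance directly
            t[f"rate_{ch:03d}"] = 3.0 * d + rng.normal(0, 2.0, len(t))
        r, p = residual_distance_correlation(t)
        assert r > 0.2 and p < 0.05

    def test_single_distance_rejected(self, small_table):
        with pytest.raises(DegenerateInputError):
            residual_distance_correlation(small_table)

    def test_zero_residual_variance_rejected(self):
        v = make_target_layout("vertical", "J")
        p = GeneratorParams(**NOISELESS)
        t = simulate_trials(v, p, 4, seed=0)
        W = p.encoding_matrix()
        speeds = t["max_speed"].to_numpy()
        # every channel an exact affine function of speed
        t[[f"rate_{i:03d}" for i in range(96)]] = np.outer(speeds, W[:, 2]) + 1.0
        with pytest.raises(DegenerateInputError):
            residual_distance_correlation(t)


class TestConvergence:
    def _noiseless_series(self, t0=50.0, tau=80.0, timesteps=801, dt=1.0):
        lay = make_target_layout("rings3", "J")
        p = GeneratorParams(t0=t0, tau=tau, **NOISELESS)
        ts = synthetic.simulate_timecourse(lay, p, 1, timesteps=timesteps, dt=dt, seed=0)
        table = preprocess.select_delay_window(ts)
        model = fit_subspace(table, variance_threshold=1.0)
        return ts, model

    def test_crossing_matches_closed_form(self):
        ts, model = self._noiseless_series()
        prof = state_convergence_profile(ts, model, threshold=0.1)
        assert abs(prof.crossing_ms - (50.0 + 80.0 * np.log(10.0))) < 2.0

    def test_doubling_tau_doubles_crossing_delay(self):
        ts1, m1 = self._noiseless_series(tau=80.0, timesteps=1601)
        ts2, m2 = self._noiseless_series(tau=160.0, timesteps=1601)
        c1 = state_convergence_profile(ts1, m1, 0.1).crossing_ms - 50.0
        c2 = state_convergence_profile(ts2, m2, 0.1).crossing_ms - 50.0
        assert abs(c2 / c1 - 2.0) < 0.02

    def test_constant_trajectory_crosses_immediately(self, small_table):
        model = fit_subspace(small_table)
        R = rate_matrix(small_table)[:4]
        rates = np.repeat(R[:, :, None], 30, axis=2)
        ts = synthetic.RateTimeSeries(
            rates=rates,
            time_ms=np.arange(30) * 10.0,
            go_cue_ms=np.full(4, 290.0),
            meta=small_table.iloc[:4, :10].reset_index(drop=True),
        )
        prof = state_convergence_profile(ts, model, 0.5)
        assert np.allclose(prof.mean_distance, 0.0, atol=1e-9)
        assert prof.crossing_ms == 0.0

    def test_threshold_bounds_checked(self, small_table):
        model = fit_subspace(small_table)
        ts, _ = self._noiseless_series(timesteps=401)
        with pytest.raises(ValueError):
            state_convergence_profile(ts, model, threshold=1.5)


def test_model_json_roundtrip(small_table, tmp_path):
    m = fit_subspace(small_table)
    path = m.to_json(tmp_path / "model.json")
    back = subspace.SubspaceModel.from_json(path)
    np.testing.assert_allclose(back.axis_x, m.axis_x)
    np.testing.assert_allclose(back.components, m.components)
    assert back.d == m.d
    s1 = project_states(small_table, m)
    s2 = project_states(small_table, back)
    np.testing.assert_allclose(
        s1[["x_neural", "y_neural", "speed_neural"]],
        s2[["x_neural", "y_neural", "speed_neural"]],
        atol=1e-9,
    )
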