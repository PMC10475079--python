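import numpy as np
import pytest
import scipy.stats

from lrcausal.datatypes import ExpressionMatrix, InterpolationParams, LRPair, OrderedSeries
from lrcausal.granger import (
    call_active_lr_paracrine,
    classify_elr,
    granger_test,
    interaction_score_autocrine,
    interpolation_sensitivity,
)
from lrcausal.regulon import TTFClusters
from lrcausal.synthetic import simulate_var_pair


def granger_ols_oracle(x, y, lag):
    """From-scratch nested-OLS Granger F test (normal equations, explicit loops)."""
    n = len(y)
    rows_y, rows_r, rows_u = [], [], []
    for t in range(lag, n):
        rows_y.append(y[t])
        past_y = [y[t - j] for j in range(1, lag + 1)]
        past_x = [x[t - j] for j in range(1, lag + 1)]
        rows_r.append([1.0] + past_y)
        rows_u.append([1.0] + past_y + past_x)
    yt = np.array(rows_y)
    Xr, Xu = np.array(rows_r), np.array(rows_u)
    br = np.linalg.solve(Xr.T @ Xr, Xr.T @ yt)
    bu = np.linalg.solve(Xu.T @ Xu, Xu.T @ yt)
    rss_r = float(((yt - Xr @ br) ** 2).sum())
    rss_u = float(((yt - Xu @ bu) ** 2).sum())
    dfd = (n - lag) - (2 * lag + 1)
    F = ((rss_r - rss_u) / lag) / (rss_u / dfd)
    return F, float(scipy.stats.f.sf(F, lag, dfd))


class TestGrangerTest:
    def test_hand_sized_series_matches_oracle(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0, 5.5, 8.0])
        y = np.array([0.5, 1.0, 2.5, 2.0, 4.5, 4.0, 6.0, 5.0])
        F, p, deg = granger_test(x, y, lag=1)
        Fo, po = granger_ols_oracle(x, y, 1)
        assert not deg
        assert F == pytest.approx(Fo, abs=1e-10)
        assert p == pytest.approx(po, abs=1e-10)

    @pytest.mark.parametrize("lag", [1, 2, 3])
    def test_random_series_match_statsmodels(self, lag):
        from statsmodels.tsa.stattools import grangercausalitytests

        rng = np.random.default_rng(42)
        x, y = rng.normal(size=40), rng.normal(size=40)
        F, p, _ = granger_test(x, y, lag)
        res = grangercausalitytests(np.column_stack([y, x]), maxlag=[lag], verbose=False)
        F_sm, p_sm = res[lag][0]["ssr_ftest"][:2]
        assert F == pytest.approx(F_sm, abs=1e-8)
        assert p == pytest.approx(p_sm, abs=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=60), rng.normal(size=60)
        F0, _, _ = granger_test(x, y, 2)
        F1, _, _ = granger_test(3.2 * x - 7.0, -0.5 * y + 2.0, 2)
        assert F1 == pytest.approx(F0, abs=1e-9)

    def test_degenerate_inputs_return_p1_not_raise(self):
        const = np.ones(30)
        wig = np.random.default_rng(0).normal(size=30)
        for a, b in [(const, wig), (wig, const), (const, const)]:
            F, p, deg = granger_test(a, b, 1)
            assert deg and p == 1.0
        # too short for the regression
        F, p, deg = granger_test(wig[:4], wig[:4], 1)
        assert deg and p == 1.0

    def test_planted_causality_detected(self):
        hits = 0
        for seed in range(30):
            x, y = simulate_var_pair(200, coupling=0.8, direction="x->y", seed=seed)
            _, p, _ = granger_test(x.values, y.values, 1)
            hits += p < 0.01
        assert hits >= 28

    def test_reversed_time_stays_valid(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=50), rng.normal(size=50)
        _, p_rev, deg = granger_test(x[::-1], y[::-1], 1)
        assert not deg and 0 < p_rev <= 1


class TestInteractionScore:
    def test_geometric_mean_round_numbers(self):
        mat = ExpressionMatrix(
            np.array([[4.0, 0.0, 1.0], [9.0, 5.0, 1.0]]), ["L", "R"], ["c1", "c2", "c3"]
        )
        s = interaction_score_autocrine(mat, ["c1", "c2", "c3"], LRPair("L", "R"))
        np.testing.assert_allclose(s.values, [6.0, 0.0, 1.0])

    def test_matches_sqrt_product_oracle(self):
        rng = np.random.default_rng(0)
        vals = np.abs(rng.normal(1, 0.5, (2, 50)))
        mat = ExpressionMatrix(vals, ["L", "R"], [f"c{i}" for i in range(50)])
        s = interaction_score_autocrine(mat, mat.cell_ids, LRPair("L", "R"))
        np.testing.assert_array_equal(s.values, np.sqrt(vals[0] * vals[1]))

    def test_missing_gene_named_in_error(self, toy_matrix):
        with pytest.raises(KeyError, match="ABSENT"):
            interaction_score_autocrine(toy_matrix, toy_matrix.cell_ids, LRPair("g1", "ABSENT"))


def _mk_clusters(activities):
    pos = np.arange(len(next(iter(activities.values()))), dtype=float)
    return TTFClusters(
        assignments={f"TF{c}": c for c in activities},
        k=len(activities),
        activity={c: OrderedSeries(pos, v) for c, v in activities.items()},
    )


def _mat_for_pair(lig, rec):
    vals = np.vstack([lig - lig.min(), rec - rec.min()])
    cells = [f"c{i:03d}" for i in range(vals.shape[1])]
    return ExpressionMatrix(vals, ["L", "R"], cells), cells


class TestClassifyELR:
    def _planted(self, direction, seed, n=200):
        """Activity and IS latents coupled per the requested direction.

        Mutual (feedback) coupling uses 0.4 per link so the joint VAR stays
        stationary; one-way coupling can afford 0.8.
        """
        rng = np.random.default_rng(seed)
        c = 0.4 if direction == "feedback" else 0.8
        act = np.zeros(n)
        s = np.zeros(n)
        ea, es = rng.normal(0, 1, n), rng.normal(0, 0.3, n)
        for t in range(1, n):
            a_drive = c * s[t - 1] if direction in ("forward", "feedback") else 0.0
            s_drive = c * act[t - 1] if direction in ("backward", "feedback") else 0.0
            act[t] = 0.5 * act[t - 1] + a_drive + ea[t]
            s[t] = 0.5 * s[t - 1] + s_drive + es[t]
        return act, s

    @pytest.mark.parametrize("direction", ["backward", "feedback"])
    def test_planted_direction_recovered(self, direction):
        hits = 0
        reps = 25
        for seed in range(reps):
            act, s = self._planted(direction, seed)
            mat, cells = _mat_for_pair(s, s)
            calls = classify_elr([LRPair("L", "R")], _mk_clusters({1: act}), mat, cells)
            hits += calls[0].klass == direction
        assert hits >= 0.8 * reps

    def test_alpha_endpoints(self):
        act, s = self._planted("feedback", 0)
        mat, cells = _mat_for_pair(s, s)
        clusters = _mk_clusters({1: act})
        (none_call,) = classify_elr([LRPair("L", "R")], clusters, mat, cells, alpha=0.0)
        assert none_call.klass == "none"
        (fb_call,) = classify_elr([LRPair("L", "R")], clusters, mat, cells, alpha=1.0)
        assert fb_call.klass == "feedback"

    def test_null_pairs_rarely_called(self):
        rng = np.random.default_rng(7)
        n = 200
        acts = {c: rng.normal(size=n) for c in range(1, 7)}
        clusters = _mk_clusters(acts)
        n_elr = 0
        n_some_class = 0
        reps = 200
        for _ in range(reps):
            s = rng.normal(size=n)
            mat, cells = _mat_for_pair(s, s)
            (call,) = classify_elr([LRPair("L", "R")], clusters, mat, cells)
            n_elr += call.is_elr
            n_some_class += call.klass != "none"
        # min-p over 6 clusters inflates each direction to ~6%; the
        # two-direction ("both") eLR rule keeps the null rate far below 1%
        assert n_elr / reps <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / reps)
        assert n_some_class / reps <= 12 * 0.01 * 1.5

    def test_elr_rule_either_is_superset_of_both(self):
        act, s = self._planted("backward", 3)
        mat, cells = _mat_for_pair(s, s)
        clusters = _mk_clusters({1: act})
        (both,) = classify_elr([LRPair("L", "R")], clusters, mat, cells, elr_rule="both")
        (either,) = classify_elr([LRPair("L", "R")], clusters, mat, cells, elr_rule="either")
        assert either.is_elr or not both.is_elr


class TestCallActiveLRParacrine:
    def _grid(self, n=200):
        return np.linspace(0, 1, n)

    def test_shifted_tf_is_active(self):
        rng = np.random.default_rng(0)
        base = np.cumsum(rng.normal(size=201))
        is_vals = base[1:]
        tf_vals = base[:-1]  # TF leads IS by one grid step
        grid = self._grid()
        is_series = {LRPair("L", "R"): OrderedSeries(grid, is_vals)}
        cells = [f"c{i:03d}" for i in range(60)]
        # receiver matrix whose interpolated TF series reproduces the lead
        tf_cells = np.interp(np.linspace(0, 1, 60), grid, tf_vals)
        mat = ExpressionMatrix(tf_cells[None, :] - tf_cells.min(), ["TF"], cells)
        calls = call_active_lr_paracrine(
            is_series, ["TF"], mat, cells, np.linspace(0, 1, 60),
            params=InterpolationParams(winsz=0.02, num_pts=200),
        )
        assert calls[0].scc_ens == pytest.approx(1.0, abs=0.05)
        assert calls[0].active

    def test_no_tf_passes_gives_missing_scc(self):
        grid = self._grid(40)
        is_series = {LRPair("L", "R"): OrderedSeries(grid, np.ones(40))}  # degenerate
        cells = [f"c{i}" for i in range(30)]
        mat = ExpressionMatrix(
            np.abs(np.random.default_rng(0).normal(1, 0.2, (1, 30))), ["TF"], cells
        )
        calls = call_active_lr_paracrine(
            is_series, ["TF"], mat, cells, np.linspace(0, 1, 30),
            params=InterpolationParams(num_pts=40),
        )
        assert calls[0].scc_ens is None and not calls[0].active

    def test_no_masters_raises(self):
        with pytest.raises(ValueError, match="master"):
            call_active_lr_paracrine({}, [], None, [], np.array([]))


class TestInterpolationSensitivity:
    def test_rates_are_valid_and_reported_per_winsz(self):
        t = interpolation_sensitivity("independent", [0.05, 0.2], reps=20, rng=0)
        assert list(t["winsz"]) == [0.05, 0.2]
        assert ((t["rejection_rate"] >= 0) & (t["rejection_rate"] <= 1)).all()

    def test_coupled_model_detected_at_default_winsz(self):
        t = interpolation_sensitivity("coupled", [0.1], reps=40, n=200, rng=0)
        assert t["rejection_rate"].iloc[0] >= 0.5

    def test_single_rep_gives_indicator(self):
        t = interpolation_sensitivity("independent", [0.1], reps=1, rng=0)
        assert t["rejection_rate"].iloc[0] in (0.0, 1.0)
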