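import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from waverisk import survival as sv
from tests.conftest import make_surv


class TestUnivariateCox:
    def test_constant_gene_skipped(self, rng):
        z, t, e = make_surv(rng, 30, 1.0)
        expr = pd.DataFrame({"flat": np.full(30, 2.0), "real": z}).T
        res = sv.univariate_cox(expr, t, e)
        assert np.isnan(res.set_index("gene_id").loc["flat", "coef"])
        assert not res.set_index("gene_id").loc["flat", "selected"]
        assert np.isfinite(res.set_index("gene_id").loc["real", "coef"])

    def test_matches_efron_partial_likelihood_oracle(self, rng):
        # 20 random 8-patient datasets with ties; the oracle maximizes the
        # explicit Efron partial likelihood by 1-D numerical optimization.
        # Draws with a monotone partial likelihood (no finite MLE) are
        # rejected: neither route has a defined answer there.
        checked = 0
        while checked < 20:
            t = rng.integers(1, 5, size=8).astype(float)   # heavy ties
            e = rng.integers(0, 2, size=8)
            if e.sum() < 2:
                e[:2] = 1
            z = rng.normal(size=8)
            res = sv.univariate_cox(pd.DataFrame(z[None, :], index=["g"]), t, e)
            beta_hat = res.loc[0, "coef"]
            if not np.isfinite(beta_hat) or abs(beta_hat) > 5:
                continue
            checked += 1
            zc = z - z.mean()
            opt = minimize_scalar(lambda b: -sv.efron_partial_loglik(b, zc, t, e),
                                  bounds=(-8, 8), method="bounded",
                                  options={"xatol": 1e-10})
            assert beta_hat == pytest.approx(opt.x, abs=1e-6)

    def test_agrees_with_lifelines(self, rng):
        from lifelines import CoxPHFitter
        z, t, e = make_surv(rng, 100, 0.8)
        res = sv.univariate_cox(pd.DataFrame(z[None, :], index=["g"]), t, e)
        cph = CoxPHFitter().fit(pd.DataFrame({"z": z, "os_days": t, "event": e}),
                                "os_days", "event")
        assert res.loc[0, "coef"] == pytest.approx(cph.params_["z"], abs=1e-4)
        assert res.loc[0, "p_value"] == pytest.approx(cph.summary["p"]["z"], rel=1e-3)

    def test_parameter_recovery(self):
        # true log-hazard 1 per unit covariate at n=500
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            z, t, e = make_surv(rng, 500, 1.0)
            res = sv.univariate_cox(pd.DataFrame(z[None, :], index=["g"]), t, e)
            hits += abs(res.loc[0, "coef"] - 1.0) <= 0.3
        assert hits >= 9

    def test_too_few_events(self, rng):
        with pytest.raises(ValueError, match="events"):
            sv.univariate_cox(pd.DataFrame(np.ones((1, 5))), np.arange(1, 6.0),
                              np.array([1, 0, 0, 0, 0]))


class TestMultivariateCox:
    def test_two_strong_genes_recovered(self):
        rng = np.random.default_rng(11)
        n = 500
        z1, z2 = rng.normal(size=n), rng.normal(size=n)
        T = rng.exponential(np.exp(-(1.0 * z1 - 0.8 * z2)))
        C = rng.uniform(0, 3, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        expr = pd.DataFrame({"up": z1, "down": z2}).T
        model = sv.multivariate_cox(expr, t, e)
        assert set(model.gene_ids) == {"up", "down"}
        betas = dict(zip(model.gene_ids, model.betas))
        assert betas["up"] > 0 and betas["down"] < 0
        assert model.fit_mode == "standard"

    def test_single_gene_reduces_to_univariate(self, rng):
        z, t, e = make_surv(rng, 120, 0.7)
        expr = pd.DataFrame(z[None, :], index=["g"])
        uni = sv.univariate_cox(expr, t, e)
        multi = sv.multivariate_cox(expr, t, e)
        assert multi.betas[0] == pytest.approx(uni.loc[0, "coef"], abs=1e-4)

    def test_collinear_duplicate_takes_penalized_path(self, rng):
        z, t, e = make_surv(rng, 80, 1.0)
        expr = pd.DataFrame(np.vstack([z, z]), index=["a", "b"])
        model = sv.multivariate_cox(expr, t, e)
        assert model.fit_mode == "penalized"
        assert len(model.gene_ids) == 2

    def test_empty_input_errors(self, rng):
        with pytest.raises(ValueError):
            sv.multivariate_cox(pd.DataFrame(np.empty((0, 10))), np.arange(10.0),
                                np.ones(10, int))


class TestRiskScore:
    def test_linear_combination(self):
        m = sv.RiskModel(["a", "b", "c"], np.array([1.0, -1.0, 0.5]))
        expr = pd.DataFrame({"s1": [2.0, 3.0, 4.0]}, index=["a", "b", "c"])
        assert sv.risk_score(m, expr)[0] == pytest.approx(1.0)

    def test_zero_betas(self, rng):
        m = sv.RiskModel(["a", "b"], np.zeros(2))
        expr = pd.DataFrame(rng.normal(size=(2, 5)), index=["a", "b"])
        np.testing.assert_array_equal(sv.risk_score(m, expr), np.zeros(5))

    def test_single_gene(self):
        m = sv.RiskModel(["g"], np.array([2.0]))
        expr = pd.DataFrame({"s": [3.0]}, index=["g"])
        assert sv.risk_score(m, expr)[0] == 6.0

    def test_missing_gene_errors(self):
        m = sv.RiskModel(["a", "zzz"], np.ones(2))
        expr = pd.DataFrame({"s": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="zzz"):
            sv.risk_score(m, expr)

    def test_monotone_in_positive_beta_gene(self, rng):
        m = sv.RiskModel(["a", "b"], np.array([0.7, -0.2]))
        expr = pd.DataFrame(rng.normal(size=(2, 4)), index=["a", "b"])
        base = sv.risk_score(m, expr)
        bumped = expr.copy()
        bumped.loc["a"] += 1.0
        assert (sv.risk_score(m, bumped) > base).all()


def youden_scan_oracle(scores, labels):
    best = (-np.inf, None)
    for t in sorted(set(scores)):
        pred = scores > t
        sens = pred[labels == 1].mean()
        spec = (~pred[labels == 0]).mean()
        j = sens + spec - 1
        if j > best[0]:
            best = (j, t)
    return best


class TestCutoffAndStratify:
    def test_perfect_separation_classifies_all(self):
        scores = np.array([1.0, 2.0, 8.0, 9.0])
        labels = np.array([0, 0, 1, 1])
        cut = sv.choose_cutoff_roc(scores, labels)
        groups = sv.stratify(scores, cut)
        np.testing.assert_array_equal(groups, labels)

    def test_simple_case(self):
        cut = sv.choose_cutoff_roc(np.array([1.0, 2, 3, 4]), np.array([0, 0, 1, 1]))
        assert cut == pytest.approx(2.0)

    def test_matches_exhaustive_scan(self, rng):
        scores = rng.normal(size=20)
        labels = (scores + rng.normal(0, 1.2, 20) > 0).astype(int)
        if labels.min() == labels.max():
            labels[:2] = [0, 1]
        cut = sv.choose_cutoff_roc(scores, labels)
        j_best, t_best = youden_scan_oracle(scores, labels)
        pred = scores > cut
        j_got = pred[labels == 1].mean() + (~pred[labels == 0]).mean() - 1
        assert j_got == pytest.approx(j_best)

    def test_constant_scores_error(self):
        with pytest.raises(ValueError, match="constant"):
            sv.choose_cutoff_roc(np.ones(6), np.array([0, 1] * 3))

    def test_equal_to_cutoff_is_low_risk(self):
        groups = sv.stratify(np.array([1.0, 2.0, 3.0]), 2.0)
        np.testing.assert_array_equal(groups, [0, 0, 1])

    def test_conservation(self, rng):
        scores = rng.normal(size=25)
        groups = sv.stratify(scores, 0.3)
        assert ((groups == 0) | (groups == 1)).all()
        assert len(groups) == 25


def logrank_oracle(times, events, groups):
    """Hand tabulation of observed-minus-expected over distinct event times."""
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestKMLogrank:
    def test_identical_event_times_statistic_zero(self):
        times = np.array([2.0, 2, 4, 4, 6, 6, 8, 8])
        events = np.ones(8, int)
        groups = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        res = sv.km_logrank(groups, times, events)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_median_from_km_steps(self):
        res = sv.km_logrank(np.array([0, 0, 0, 1, 1, 1]),
                            np.array([2.0, 4, 6, 20, 30, 40]), np.ones(6, int))
        assert res.medians[0] == pytest.approx(4.0)
        assert res.medians[1] == pytest.approx(30.0)

    def test_matches_hand_tabulation_oracle(self, rng):
        times = np.array([1.0, 2, 3, 3, 4, 5, 6, 7, 8, 9])
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 1])
        groups = np.array([0, 1, 0, 1, 0, 0, 1, 1, 0, 1])
        res = sv.km_logrank(groups, times, events)
        assert res.statistic == pytest.approx(logrank_oracle(times, events, groups), rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            sv.km_logrank(np.zeros(5, int), np.arange(1, 6.0), np.ones(5, int))


class TestTuneTopN:
    @pytest.fixture
    def cohort(self):
        rng = np.random.default_rng(5)
        n, p = 160, 120
        expr = pd.DataFrame(np.exp(rng.normal(2, 0.5, size=(p, n))),
                            index=[f"g{i:03d}" for i in range(p)])
        z = np.log(expr.iloc[:10]).apply(lambda r: (r - r.mean()) / r.std(), axis=1)
        lp = z.sum(axis=0).to_numpy()
        T = rng.exponential(1000 * np.exp(-lp))
        C = rng.uniform(0, 4000, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        labels = (lp > np.median(lp)).astype(int)
        score_table = pd.DataFrame({"gene_id": expr.index,
                                    "score": -np.arange(p, dtype=float),
                                    "rank": np.arange(1, p + 1)})
        return expr, score_table, t, e, labels

    def test_single_grid_value(self, cohort):
        expr, tbl, t, e, labels = cohort
        assert sv.tune_top_n(expr, tbl, t, e, labels, grid=[30], random_state=0) == 30

    def test_deterministic(self, cohort):
        expr, tbl, t, e, labels = cohort
        a = sv.tune_top_n(expr, tbl, t, e, labels, grid=[20, 60], random_state=1)
        b = sv.tune_top_n(expr, tbl, t, e, labels, grid=[20, 60], random_state=1)
        assert a == b
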