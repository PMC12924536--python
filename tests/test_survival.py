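"""Tests for the Cox screening machinery: the Newton solver against
lifelines, concordance against brute force, bootstrap p behaviour,
LASSO-Cox selection and the stratified proteome screen."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from strataprot._coxfit import concordance_index, cox_newton, wald_p
from strataprot.data_io import ValidationError
from strataprot.preprocess import log2_transform
from strataprot.survival import (SurvivalTask, bootstrap_pvalue, fit_cox,
                                 km_by_median_abundance, km_logrank,
                                 lasso_cox_select, screen_proteome)
from strataprot.synthetic_data import (PlantedHazardEffect, SimulationConfig,
                                       SurvivalConfig, generate_cohort)


def _sim_surv(rng, n=80, beta=0.0, censor=0.4, ties=False, p_extra=0):
    """Exponential PH data with one binary covariate of log HR beta."""
    grp = rng.integers(0, 2, n).astype(float)
    rate = 0.001 * np.exp(beta * grp)
    t = rng.exponential(1 / rate)
    c = rng.exponential(1 / (0.001 * censor / (1 - censor)), n) if censor else np.inf
    time = np.minimum(t, c)
    event = (t <= np.broadcast_to(c, (n,))).astype(int)
    if ties:
        time = np.ceil(time / 200) * 200  # coarse grid forces tied event days
    extras = rng.standard_normal((n, p_extra)) if p_extra else None
    return time, event, grp, extras


class TestCoxNewton:
    @pytest.mark.parametrize("ties", [False, True])
    def test_matches_lifelines(self, ties):
        rng = np.random.default_rng(1)
        for trial in range(5):
            time, event, grp, extras = _sim_surv(rng, n=70, beta=0.7, ties=ties,
                                                 p_extra=2)
            X = np.column_stack([grp, extras])
            res = cox_newton(X, time, event)
            df = pd.DataFrame({"t": time, "e": event, "g": grp,
                               "x1": extras[:, 0], "x2": extras[:, 1]})
            # lifelines halts at a gradient norm ~1e-6; our Newton solver runs
            # to ~1e-14, so agreement is limited by the oracle's tolerance
            cph = CoxPHFitter().fit(df, "t", "e")
            np.testing.assert_allclose(res.beta, cph.params_.to_numpy(), atol=1e-4)
            np.testing.assert_allclose(res.se, cph.standard_errors_.to_numpy(),
                                       atol=1e-4)
            assert wald_p(res, 0) == pytest.approx(cph.summary.loc["g", "p"],
                                                   abs=1e-4)

    def test_separation_is_non_estimable(self):
        # the binary covariate perfectly orders the survival times
        time = np.arange(1.0, 11.0)
        event = np.ones(10, int)
        grp = np.r_[np.ones(5), np.zeros(5)]  # all short times in one group
        assert cox_newton(grp, time, event) is None

    def test_no_events_is_non_estimable(self):
        rng = np.random.default_rng(2)
        time, _, grp, _ = _sim_surv(rng, n=20)
        assert cox_newton(grp, time, np.zeros(20, int)) is None


class TestConcordance:
    def test_matches_brute_force_on_small_fixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(5, 11))
            time = rng.exponential(100, n)
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                continue
            risk = rng.normal(size=n)
            num = den = 0.0
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    # i experiences the event first
                    if event[i] == 1 and (time[i] < time[j]
                                          or (time[i] == time[j] and event[j] == 0)):
                        den += 1
                        num += (risk[i] > risk[j]) + 0.5 * (risk[i] == risk[j])
            assert concordance_index(time, risk, event) == pytest.approx(num / den)

    def test_perfect_ordering_no_censoring(self):
        time = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        risk = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert concordance_index(time, risk, np.ones(5, int)) == 1.0

    def test_agrees_with_lifelines(self):
        from lifelines.utils import concordance_index as ll_ci
        rng = np.random.default_rng(4)
        time, event, grp, extras = _sim_surv(rng, n=60, beta=0.5, p_extra=1)
        risk = grp + 0.3 * extras[:, 0]
        # lifelines scores "predicted survival time" (higher = longer)
        assert concordance_index(time, risk, event) == \
            pytest.approx(ll_ci(time, -risk, event))


class TestFitCox:
    def test_recovers_planted_hazard_ratio(self):
        rng = np.random.default_rng(5)
        hrs = []
        for _ in range(20):
            time, event, grp, _ = _sim_surv(rng, n=200, beta=np.log(2.0),
                                            censor=0.5)
            fit = fit_cox(time, event, grp)
            hrs.append(fit.hr)
        assert 1.7 <= np.mean(hrs) <= 2.3

    def test_relabelling_high_low_inverts_hazard_ratio(self):
        rng = np.random.default_rng(6)
        time, event, grp, _ = _sim_surv(rng, n=120, beta=0.8)
        a = fit_cox(time, event, grp)
        b = fit_cox(time, event, 1 - grp)
        assert b.beta == pytest.approx(-a.beta, abs=1e-8)
        assert b.ci_low == pytest.approx(1 / a.ci_high, rel=1e-6)
        assert b.ci_high == pytest.approx(1 / a.ci_low, rel=1e-6)
        assert b.wald_p == pytest.approx(a.wald_p, abs=1e-10)

    def test_null_coverage_of_confidence_interval(self):
        rng = np.random.default_rng(7)
        covered = 0
        trials = 60
        for _ in range(trials):
            time, event, grp, _ = _sim_surv(rng, n=150, beta=0.0, censor=0.3)
            fit = fit_cox(time, event, grp)
            covered += fit.ci_low <= 1.0 <= fit.ci_high
        # ~95% nominal; binomial 3-sigma band around 0.95 at 60 trials
        assert covered / trials >= 0.95 - 3 * np.sqrt(0.95 * 0.05 / trials)

    def test_constant_covariate_dropped(self):
        rng = np.random.default_rng(8)
        time, event, grp, _ = _sim_surv(rng, n=60, beta=0.5)
        fit = fit_cox(time, event, grp,
                      pd.DataFrame({"const": np.ones(60), "age": rng.normal(60, 8, 60)}))
        assert fit.covariates == ("age",)


class TestBootstrap:
    def test_null_bootstrap_p_mean_matches_theory(self):
        # under the null the resampled Wald z is ~ N(0, sqrt(2)) (the
        # bootstrap doubles the coefficient's sampling variance), so the
        # exact mean of the bootstrap-averaged p is
        # E[2*Phi(-|z*|)] = 1 - (2/pi)*arctan(sqrt(2)) = 0.3918
        rng = np.random.default_rng(9)
        boots = []
        for seed in range(10):
            time, event, grp, _ = _sim_surv(rng, n=100, beta=0.0, censor=0.3)
            bp, n_conv, reliable = bootstrap_pvalue(time, event, grp, B=200,
                                                    seed=seed)
            assert reliable
            boots.append(bp)
        theory = 1 - (2 / np.pi) * np.arctan(np.sqrt(2))
        assert abs(np.mean(boots) - theory) < 0.09  # ~2.5 sigma at 10 datasets

    def test_strong_effect_gives_small_bootstrap_p(self):
        rng = np.random.default_rng(10)
        time, event, grp, _ = _sim_surv(rng, n=150, beta=1.8, censor=0.2)
        bp, _, _ = bootstrap_pvalue(time, event, grp, B=100, seed=0)
        assert bp < 0.05

    def test_single_resample_equals_single_refit(self):
        rng = np.random.default_rng(11)
        time, event, grp, _ = _sim_surv(rng, n=80, beta=0.5)
        bp, n_conv, _ = bootstrap_pvalue(time, event, grp, B=1, seed=42)
        idx = np.random.default_rng(42).integers(0, 80, size=80)
        refit = fit_cox(time[idx], event[idx], grp[idx])
        assert n_conv == 1
        assert bp == pytest.approx(refit.wald_p)


class TestLassoCoxSelect:
    def _design(self, rng, n=80, p=10, beta=1.2):
        X = pd.DataFrame(rng.standard_normal((n, p)),
                         columns=[f"P{i}" for i in range(p)])
        eta = beta * X["P0"].to_numpy()
        t = rng.exponential(1 / (0.001 * np.exp(eta)))
        c = rng.exponential(1000, n)
        return X, np.minimum(t, c), (t <= c).astype(int)

    def test_recovers_planted_protein(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(20 + seed)
            X, time, event = self._design(rng)
            selected = lasso_cox_select(X, time, event, seed=seed)
            hits += "P0" in selected
        assert hits >= 8

    def test_null_selection_small_and_subset(self):
        sizes = []
        for seed in range(6):
            rng = np.random.default_rng(50 + seed)
            X, time, event = self._design(rng, beta=0.0)
            X["dup"] = X["P0"]
            selected = lasso_cox_select(X, time, event, seed=seed)
            assert set(selected) <= set(X.columns)
            sizes.append(len(selected))
        assert np.median(sizes) <= 1

    def test_needs_two_events(self):
        rng = np.random.default_rng(12)
        X, time, _ = self._design(rng, n=20)
        with pytest.raises(ValidationError):
            lasso_cox_select(X, time, np.r_[1, np.zeros(19)].astype(int))


def _stratum_cohort(seed, planted=(), n_cell=100, n_proteins=40, censor=0.3):
    """Single-stratum cohort (HGSC late) for screen tests."""
    sc = SurvivalConfig(planted=list(planted), censoring_rate=censor)
    cfg = SimulationConfig(n_per_cell={("HGSC", "late"): n_cell},
                           n_proteins=n_proteins, detection_quantile=0.0,
                           survival=sc, seed=seed)
    matrix, meta, truth = generate_cohort(cfg)
    return log2_transform(matrix), meta, truth


class TestScreenProteome:
    def test_planted_protein_called_increased_risk(self):
        log2m, meta, _ = _stratum_cohort(31, planted=[PlantedHazardEffect(2, 1.6)],
                                         n_cell=150)
        tbl = screen_proteome(log2m, meta, SurvivalTask("os", "HGSC", "late"),
                              B=200, seed=0)
        row = tbl[tbl["protein_id"] == "P00003"]
        assert len(row) == 1
        assert row["call"].iloc[0] == "increased_risk"
        assert row["hr"].iloc[0] > 1

    def test_null_cohort_produces_no_calls(self):
        log2m, meta, _ = _stratum_cohort(32)
        tbl = screen_proteome(log2m, meta, SurvivalTask("os", "HGSC", "late"),
                              B=100, seed=1, bootstrap_all_threshold=0)
        assert (tbl["call"] == "ns").all()

    def test_zero_event_task_yields_empty_table(self):
        log2m, meta, _ = _stratum_cohort(33, n_cell=20, censor=0.0)
        df = meta.df.copy()
        df["os_event"] = 0
        df["dss_event"] = 0
        meta2 = type(meta)(df)
        tbl = screen_proteome(log2m, meta2, SurvivalTask("os", "HGSC", "late"))
        assert tbl.empty

    def test_constant_protein_skipped(self):
        log2m, meta, _ = _stratum_cohort(34, n_cell=30, n_proteins=10)
        vals = log2m.values.copy()
        vals.iloc[0, :] = 20.0
        m2 = type(log2m)(vals, scale="log2")
        tbl = screen_proteome(m2, meta, SurvivalTask("os", "HGSC", "late"),
                              B=50, seed=2, bootstrap_all_threshold=0)
        assert "P00001" not in set(tbl["protein_id"])


class TestKaplanMeier:
    def test_identical_groups_logrank_p_near_one(self):
        time = np.array([5.0, 8, 12, 20, 25, 30] * 2)
        event = np.array([1, 1, 0, 1, 0, 1] * 2)
        groups = np.r_[["a"] * 6, ["b"] * 6]
        summary = km_logrank(time, event, groups)
        assert summary.logrank_p > 0.99

    def test_km_equals_empirical_survival_without_censoring(self):
        time = np.array([2.0, 4, 6, 8, 10, 3, 5, 7, 9, 11])
        event = np.ones(10, int)
        groups = np.r_[["a"] * 5, ["b"] * 5]
        summary = km_logrank(time, event, groups)
        curve = summary.curves["a"]
        surv = dict(zip(curve["time"], curve["survival"]))
        for t, s in [(2.0, 0.8), (4.0, 0.6), (6.0, 0.4), (8.0, 0.2), (10.0, 0.0)]:
            assert surv[t] == pytest.approx(s)

    def test_two_group_logrank_matches_hand_computation(self):
        # O-E / V chi-square on a 6-subject fixture, computed by hand via the
        # standard hypergeometric variance formula
        time = np.array([1.0, 2, 3, 4, 5, 6])
        event = np.ones(6, int)
        groups = np.array(["a", "b", "a", "b", "a", "b"])
        o_minus_e, var = 0.0, 0.0
        at_risk = {"a": 3, "b": 3}
        for i, t in enumerate(time):
            n = at_risk["a"] + at_risk["b"]
            e_a = at_risk["a"] / n
            o_minus_e += (groups[i] == "a") - e_a
            if n > 1:
                var += e_a * (1 - e_a)  # d=1, hypergeometric variance
            at_risk[groups[i]] -= 1
        from scipy.stats import chi2
        expected_p = float(chi2.sf(o_minus_e ** 2 / var, 1))
        summary = km_logrank(time, event, groups)
        assert summary.logrank_p == pytest.approx(expected_p, abs=1e-10)

    def test_median_dichotomized_helper(self):
        log2m, meta, _ = _stratum_cohort(35, n_cell=40, n_proteins=5)
        summary = km_by_median_abundance(log2m, meta,
                                         SurvivalTask("os", "HGSC", "late"),
                                         "P00001")
        assert set(summary.curves) == {"high", "low"}
        for curve in summary.curves.values():
            assert (np.diff(curve["survival"]) <= 1e-12).all()
            assert curve["survival"].iloc[0] <= 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            km_logrank(np.arange(1.0, 5), np.ones(4, int), np.array(["a"] * 4))
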