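"""Estimators against independent oracles, algebraic identities, invariances."""

import itertools

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import integrate, optimize, stats
from scipy.special import expit

import trialsim as ts
from trialsim._cox import CoxData, FrailtyData, fit_frailty_cox, newton_cox
from trialsim._glmm import fit_logistic_random_intercept


def two_sample_mean_difference(frame):
    return frame.y[frame.arm == 1].mean() - frame.y[frame.arm == 0].mean()


# ---------------------------------------------------------------------------
# continuous outcomes


class TestContinuous:
    def make_frame(self, n=300, seed=0, beta_treat=0.0, fixture=None):
        fixture = fixture or ts.load_fixture("mist2")
        model = fixture.covariate_model()
        rng = np.random.default_rng(seed)
        X, stratum = ts.sample_covariates(model, n, rng)
        arm = ts.allocate_simple(n, seed + 1)
        eff = fixture.effect_spec().with_(beta_treat=beta_treat)
        y = ts.gen_continuous(ts.linear_predictor(eff, X, arm), eff.sigma, rng)
        return ts.TrialFrame(X=X, arm=arm, family="continuous", y=y,
                             stratum=stratum, names=model.names)

    def test_constant_covariates_reduce_to_mean_difference(self):
        rng = np.random.default_rng(4)
        frame = ts.TrialFrame(
            X=np.ones((100, 2), dtype=int),
            arm=ts.allocate_simple(100, 9),
            family="continuous",
            y=rng.normal(size=100),
        )
        res = ts.fit_method(frame, "covariate_adjusted")
        assert res.estimate == pytest.approx(two_sample_mean_difference(frame))

    def test_fixed_effects_equals_all_interactions_adjustment(self):
        """Stratum indicators reproduce exactly the fit that adjusts for all
        covariates and all their interactions (same estimate and SE)."""
        frame = self.make_frame(seed=10)
        res = ts.fit_method(frame, "stratified_fixed")
        cols = [frame.arm.astype(float)]
        for k in range(1, frame.X.shape[1] + 1):
            for combo in itertools.combinations(range(frame.X.shape[1]), k):
                cols.append(np.prod(frame.X[:, combo], axis=1).astype(float))
        ols = sm.OLS(frame.y, sm.add_constant(np.column_stack(cols))).fit()
        assert res.estimate == pytest.approx(ols.params[1], abs=1e-8)
        assert res.se == pytest.approx(ols.bse[1], abs=1e-8)

    def test_reference_stratum_choice_is_irrelevant(self):
        frame = self.make_frame(seed=11)
        res = ts.fit_method(frame, "stratified_fixed")
        # relabel stratum codes so a different stratum becomes the reference
        relabeled = ts.TrialFrame(
            X=frame.X, arm=frame.arm, family="continuous", y=frame.y,
            stratum=(frame.stratum.max() - frame.stratum), names=frame.names,
        )
        res2 = ts.fit_method(relabeled, "stratified_fixed")
        assert res2.estimate == pytest.approx(res.estimate, abs=1e-9)
        assert res2.se == pytest.approx(res.se, abs=1e-9)

    def test_single_stratum_equals_unadjusted_fit(self):
        rng = np.random.default_rng(6)
        frame = ts.TrialFrame(
            X=np.zeros((80, 1), dtype=int), arm=ts.allocate_simple(80, 3),
            family="continuous", y=rng.normal(size=80),
        )
        res = ts.fit_method(frame, "stratified_fixed")
        assert res.estimate == pytest.approx(two_sample_mean_difference(frame))

    def test_random_effects_with_exchangeable_strata(self):
        """When strata carry no signal the random-intercept fit collapses to
        (nearly) the unadjusted mean difference with a tiny variance."""
        rng = np.random.default_rng(12)
        X, stratum = ts.sample_covariates(
            ts.build_covariate_model([0.5, 0.5]), 400, rng
        )
        arm = ts.allocate_simple(400, 13)
        y = rng.normal(size=400)  # outcomes independent of the strata
        frame = ts.TrialFrame(X=X, arm=arm, family="continuous", y=y,
                              stratum=stratum)
        res = ts.fit_method(frame, "stratified_random")
        assert res.converged
        assert res.tau2 < 0.05
        assert abs(res.estimate - two_sample_mean_difference(frame)) < 3 * res.se

    def test_consistency_under_generating_model(self):
        frame = self.make_frame(n=20_000, seed=14, beta_treat=5.0)
        res = ts.fit_method(frame, "covariate_adjusted")
        assert abs(res.estimate - 5.0) < 3 * res.se


# ---------------------------------------------------------------------------
# binary outcomes


def irls_logistic_oracle(y, design, n_iter=200):
    """Direct Newton iteration on the logistic log-likelihood."""
    beta = np.zeros(design.shape[1])
    for _ in range(n_iter):
        p = expit(design @ beta)
        W = p * (1 - p)
        H = design.T @ (design * W[:, None])
        g = design.T @ (y - p)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(step).max() < 1e-12:
            break
    cov = np.linalg.inv(H)
    return beta, np.sqrt(np.diag(cov))


class TestBinary:
    def test_logistic_against_irls_oracle_on_2x2x2_table(self):
        # fully specified 2x2x2 table: (covariate, arm) cell counts of y=1/0
        counts = {  # (x, t): (events, non-events)
            (0, 0): (8, 22), (0, 1): (14, 16), (1, 0): (15, 15), (1, 1): (22, 8),
        }
        rows = []
        for (x, t), (e, ne) in counts.items():
            rows += [(x, t, 1)] * e + [(x, t, 0)] * ne
        arr = np.array(rows)
        frame = ts.TrialFrame(X=arr[:, [0]], arm=arr[:, 1], family="binary",
                              y=arr[:, 2])
        res = ts.fit_method(frame, "covariate_adjusted")
        design = np.column_stack(
            [np.ones(len(arr)), arr[:, 1], arr[:, 0]]
        ).astype(float)
        beta, se = irls_logistic_oracle(arr[:, 2].astype(float), design)
        assert res.estimate == pytest.approx(beta[1], abs=1e-8)
        assert res.se == pytest.approx(se[1], abs=1e-6)

    def test_random_intercept_against_quadrature_oracle(self):
        """Marginal-likelihood maximiser cross-checked against brute-force
        numerical integration over the random effect."""
        rng = np.random.default_rng(17)
        n_per = 200
        stratum = np.repeat([0, 1], n_per)
        arm = np.tile([0, 1], n_per)
        eta = -0.3 + 0.8 * arm + np.where(stratum == 0, -0.9, 0.9)
        y = (rng.uniform(size=2 * n_per) < expit(eta)).astype(float)

        def marginal_nll(theta):
            alpha, beta, log_sd = theta
            sd = np.exp(log_sd)
            total = 0.0
            for j in (0, 1):
                m = stratum == j
                yj, tj = y[m], arm[m]

                def cond_ll(v):
                    p = expit(alpha + beta * tj + sd * v)
                    return np.sum(yj * np.log(p) + (1 - yj) * np.log1p(-p))

                offset = cond_ll(0.0)  # keeps the integrand in float range

                def f(v):
                    return np.exp(cond_ll(v) - offset) * stats.norm.pdf(v)

                val, _ = integrate.quad(f, -8, 8, limit=200)
                total -= offset + np.log(val)
            return total

        oracle = optimize.minimize(
            marginal_nll, x0=[0.0, 0.5, np.log(0.8)], method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
        )
        fit = fit_logistic_random_intercept(y, arm, stratum, 2)
        assert fit.converged
        assert fit.beta == pytest.approx(oracle.x[1], abs=1e-3)

        # lies between the fixed-effects and unadjusted estimates
        frame = ts.TrialFrame(
            X=stratum[:, None].astype(int), arm=arm, family="binary", y=y
        )
        fixed = ts.fit_method(frame, "stratified_fixed").estimate
        unadj = irls_logistic_oracle(
            y, np.column_stack([np.ones_like(y), arm]).astype(float)
        )[0][1]
        lo, hi = sorted([fixed, unadj])
        assert lo - 1e-6 <= fit.beta <= hi + 1e-6

    def test_random_intercept_matches_frozen_glmer_reference(self, augib,
                                                             augib_calibrated):
        """Frozen reference from lme4::glmer(..., nAGQ=15) on the identical
        regenerated dataset."""
        model = augib.covariate_model()
        rng = np.random.default_rng(6)
        X, _ = ts.sample_covariates(model, 300, rng)
        arm = ts.allocate_simple(300, 13)
        eff = ts.calibrate_intercept(
            augib.effect_spec(beta_treat=-0.6), model, 0.236, seed=5
        )
        y = ts.gen_binary(ts.linear_predictor(eff, X, arm), rng)
        frame = ts.TrialFrame(X=X, arm=arm, family="binary", y=y)
        idx = frame.stratum_index()
        g = fit_logistic_random_intercept(y, arm, idx, idx.max() + 1)
        assert g.alpha == pytest.approx(-0.6412132, abs=2e-4)
        assert g.beta == pytest.approx(-0.6617557, abs=2e-4)
        assert g.se_beta == pytest.approx(0.3421550, rel=1e-3)
        assert g.tau2 == pytest.approx(2.353304, rel=1e-3)

    def test_separation_is_flagged_not_raised(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        arm = y.copy()
        frame = ts.TrialFrame(X=np.zeros((8, 1), dtype=int), arm=arm,
                              family="binary", y=y)
        res = ts.fit_method(frame, "covariate_adjusted")
        assert not res.converged
        with pytest.raises(ValueError):
            ts.wald_reject(res)


class TestMantelHaenszel:
    @staticmethod
    def build_frame(tables):
        rows = []
        for s, (a, b, c, d) in enumerate(tables):
            rows += [(s, 1, 1)] * a + [(s, 1, 0)] * b
            rows += [(s, 0, 1)] * c + [(s, 0, 0)] * d
        arr = np.array(rows)
        return ts.TrialFrame(X=np.zeros((len(arr), 0), dtype=int),
                             arm=arr[:, 1], family="binary", y=arr[:, 2],
                             stratum=arr[:, 0])

    def test_single_stratum_equals_crude_odds_ratio(self):
        res = ts.fit_method(self.build_frame([(10, 5, 6, 9)]), "mantel_haenszel")
        assert np.exp(res.estimate) == pytest.approx(3.0)

    def test_homogeneous_strata_pool_to_common_odds_ratio(self):
        res = ts.fit_method(
            self.build_frame([(10, 5, 6, 9), (10, 5, 6, 9)]), "mantel_haenszel"
        )
        assert np.exp(res.estimate) == pytest.approx(3.0)

    def test_pooled_or_and_rbg_se_against_formula_oracle(self):
        """Cell-by-cell evaluation of the Mantel-Haenszel estimator and the
        Robins-Breslow-Greenland variance."""
        tables = [(12, 8, 7, 13), (5, 15, 3, 17), (20, 10, 14, 16)]
        res = ts.fit_method(self.build_frame(tables), "mantel_haenszel")
        R = S = 0.0
        num1 = num2 = num3 = 0.0
        for a, b, c, d in tables:
            n = a + b + c + d
            P, Q = (a + d) / n, (b + c) / n
            R_k, S_k = a * d / n, b * c / n
            R, S = R + R_k, S + S_k
            num1 += P * R_k
            num2 += P * S_k + Q * R_k
            num3 += Q * S_k
        or_mh = R / S
        var = num1 / (2 * R**2) + num2 / (2 * R * S) + num3 / (2 * S**2)
        assert res.estimate == pytest.approx(np.log(or_mh), abs=1e-10)
        assert res.se == pytest.approx(np.sqrt(var), abs=1e-10)

    def test_empty_margin_strata_carry_no_information(self):
        with_empty = self.build_frame([(10, 5, 6, 9), (0, 0, 4, 6)])
        plain = self.build_frame([(10, 5, 6, 9)])
        a = ts.fit_method(with_empty, "mantel_haenszel")
        b = ts.fit_method(plain, "mantel_haenszel")
        assert a.estimate == pytest.approx(b.estimate)

    def test_all_informative_cells_empty_fails(self):
        res = ts.fit_method(self.build_frame([(5, 0, 3, 0)]), "mantel_haenszel")
        assert not res.converged


# ---------------------------------------------------------------------------
# survival outcomes


class TestCox:
    def test_covariate_adjusted_matches_lifelines(self, pbc_frame):
        from lifelines import CoxPHFitter

        res = ts.fit_method(pbc_frame, "covariate_adjusted")
        df = pbc_frame.to_dataframe()
        cph = CoxPHFitter().fit(
            df.drop(columns="stratum"), "time", "event",
            formula="arm + " + " + ".join(pbc_frame.names),
        )
        assert res.estimate == pytest.approx(cph.params_["arm"], abs=1e-6)
        assert res.se == pytest.approx(cph.standard_errors_["arm"], abs=1e-6)

    def test_stratified_cox_matches_lifelines(self, pbc_frame):
        from lifelines import CoxPHFitter

        res = ts.fit_method(pbc_frame, "stratified_cox")
        df = pbc_frame.to_dataframe()
        cph = CoxPHFitter().fit(df, "time", "event", formula="arm",
                                strata=["stratum"])
        # tolerance set by lifelines' own stopping rule, not by the engine
        assert res.estimate == pytest.approx(cph.params_["arm"], abs=1e-4)
        assert res.se == pytest.approx(cph.standard_errors_["arm"], rel=1e-3)

    def test_single_stratum_equals_plain_cox(self):
        rng = np.random.default_rng(23)
        n = 120
        arm = ts.allocate_simple(n, 2)
        eff = ts.EffectSpec(family="survival", beta_treat=-0.4,
                            baseline_rate=1.0, censor_time=1.0)
        time, event = ts.gen_survival(eff.beta_treat * arm, eff, rng)
        frame = ts.TrialFrame(X=np.zeros((n, 0), dtype=int), arm=arm,
                              family="survival", time=time, event=event)
        strat = ts.fit_method(frame, "stratified_cox")
        plain = newton_cox(CoxData(time, event, arm.astype(float)[:, None]))
        assert strat.estimate == pytest.approx(plain.beta[0], abs=1e-6)

    def test_eventless_stratum_contributes_nothing(self):
        rng = np.random.default_rng(29)
        n = 60
        arm = ts.allocate_simple(n, 5)
        time = rng.exponential(size=n)
        event = np.ones(n, dtype=int)
        frame1 = ts.TrialFrame(X=np.zeros((n, 0), dtype=int), arm=arm,
                               family="survival", time=time, event=event)
        # append a censored-only stratum
        frame2 = ts.TrialFrame(
            X=np.zeros((n + 20, 0), dtype=int),
            arm=np.r_[arm, ts.allocate_simple(20, 6)],
            family="survival",
            time=np.r_[time, np.full(20, 2.0)],
            event=np.r_[event, np.zeros(20, dtype=int)],
            stratum=np.r_[np.zeros(n, dtype=int), np.ones(20, dtype=int)],
        )
        a = ts.fit_method(frame1, "stratified_cox")
        b = ts.fit_method(frame2, "stratified_cox")
        assert b.estimate == pytest.approx(a.estimate, abs=1e-10)

    def test_stratified_partial_likelihood_grid_search_oracle(self):
        """Six patients, two strata, no ties: the fitted log-HR maximises the
        written-out stratified partial likelihood."""
        time = np.array([1.0, 2.0, 3.0, 1.5, 2.5, 3.5])
        event = np.array([1, 1, 0, 1, 1, 1])
        arm = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        strata = np.array([0, 0, 0, 1, 1, 1])

        def log_pl(b):
            total = 0.0
            for s in (0, 1):
                m = strata == s
                t, e, x = time[m], event[m], arm[m]
                for i in np.flatnonzero(e):
                    risk = t >= t[i]
                    total += b * x[i] - np.log(np.sum(np.exp(b * x[risk])))
            return total

        grid = np.arange(-3, 3, 1e-3)
        oracle = grid[np.argmax([log_pl(b) for b in grid])]
        frame = ts.TrialFrame(X=np.zeros((6, 0), dtype=int), arm=arm.astype(int),
                              family="survival", time=time, event=event,
                              stratum=strata)
        res = ts.fit_method(frame, "stratified_cox")
        assert res.estimate == pytest.approx(oracle, abs=1e-3)

    def test_no_events_fails_cleanly(self):
        frame = ts.TrialFrame(
            X=np.zeros((20, 0), dtype=int), arm=ts.allocate_simple(20, 1),
            family="survival", time=np.ones(20), event=np.zeros(20, dtype=int),
        )
        assert not ts.fit_method(frame, "stratified_cox").converged


class TestFrailtyCox:
    def regen_reference_data(self):
        pbc = ts.load_fixture("pbc")
        model = pbc.covariate_model()
        eff = ts.calibrate_intercept(
            pbc.effect_spec(beta_treat=-0.5), model, 0.404, seed=9
        )
        rng = np.random.default_rng(4)
        X, stratum = ts.sample_covariates(model, 200, rng)
        arm = ts.allocate_simple(200, 11)
        time, event = ts.gen_survival(ts.linear_predictor(eff, X, arm), eff, rng)
        frame = ts.TrialFrame(X=X, arm=arm, family="survival", time=time,
                              event=event, stratum=stratum)
        return frame

    def test_penalised_fit_matches_coxph_at_fixed_variance(self):
        """Frozen reference: R survival::coxph with frailty.gaussian(theta=0.5),
        Efron ties, on the identical regenerated dataset."""
        frame = self.regen_reference_data()
        idx = frame.stratum_index()
        J = idx.max() + 1
        data = FrailtyData(frame.time, frame.event, frame.arm, idx, J)
        prec = np.r_[0.0, np.full(J, 1 / 0.5)]
        fit = newton_cox(data, penalty_prec=prec)
        assert fit.beta[0] == pytest.approx(-0.5098527, abs=1e-4)
        assert np.sqrt(fit.cov[0, 0]) == pytest.approx(0.2571683, rel=0.01)

    def test_full_fit_close_to_coxph_profile_solution(self):
        """The profiled-variance fit agrees with coxph's frailty.gaussian
        solution on the treatment effect (variance criteria differ slightly)."""
        frame = self.regen_reference_data()
        res = ts.fit_method(frame, "stratified_random")
        assert res.converged
        assert res.estimate == pytest.approx(-0.5230178, abs=0.02)
        assert res.se == pytest.approx(0.2578627, rel=0.02)
        assert res.tau2 > 0.3

    def test_exchangeable_strata_hit_the_boundary(self):
        rng = np.random.default_rng(41)
        n = 300
        arm = ts.allocate_simple(n, 7)
        eff = ts.EffectSpec(family="survival", beta_treat=-0.5,
                            baseline_rate=1.0, censor_time=1.5)
        time, event = ts.gen_survival(eff.beta_treat * arm, eff, rng)
        stratum = rng.integers(0, 4, size=n)  # pure noise strata
        fit = fit_frailty_cox(time, event, arm, stratum, 4)
        plain = newton_cox(CoxData(time, event, arm.astype(float)[:, None]))
        assert fit.converged
        assert fit.tau2 == pytest.approx(0.0, abs=0.05)
        if fit.tau2 == 0.0:
            assert fit.beta[0] == pytest.approx(plain.beta[0], abs=1e-6)

    def test_dense_and_sparse_kernels_agree(self):
        frame = self.regen_reference_data()
        idx = frame.stratum_index()
        J = idx.max() + 1
        U = np.zeros((frame.n, J))
        U[np.arange(frame.n), idx] = 1.0
        Z = np.column_stack([frame.arm.astype(float), U])
        beta = np.linspace(-0.5, 0.5, 1 + J)
        dense = CoxData(frame.time, frame.event, Z)
        sparse = FrailtyData(frame.time, frame.event, frame.arm, idx, J)
        l1, g1, h1 = dense.loglik_grad_hess(beta)
        l2, g2, h2 = sparse.loglik_grad_hess(beta)
        assert l1 == pytest.approx(l2, abs=1e-10)
        assert np.allclose(g1, g2, atol=1e-10)
        assert np.allclose(h1, h2, atol=1e-9)


# ---------------------------------------------------------------------------
# cross-method properties and the rejection rule


def test_binary_methods_agree_at_scale(augib, augib_calibrated):
    """On a large generated binary trial under the null, all four estimators
    give log odds ratios within three joint standard errors."""
    model = augib.covariate_model()
    rng = np.random.default_rng(55)
    X, stratum = ts.sample_covariates(model, 2000, rng)
    arm = ts.allocate_simple(2000, 56)
    y = ts.gen_binary(ts.linear_predictor(augib_calibrated, X, arm), rng)
    frame = ts.TrialFrame(X=X, arm=arm, family="binary", y=y, stratum=stratum,
                          names=model.names)
    fits = {
        m: ts.fit_method(frame, m)
        for m in ("covariate_adjusted", "stratified_fixed", "stratified_random",
                  "mantel_haenszel")
    }
    assert all(f.converged for f in fits.values())
    for a, b in itertools.combinations(fits.values(), 2):
        assert abs(a.estimate - b.estimate) < 3 * np.hypot(a.se, b.se)


class TestWaldReject:
    def make(self, est, se, df=None):
        return ts.TrialFitResult(method="covariate_adjusted", family="binary",
                                 estimate=est, se=se, p_value=0.5,
                                 converged=True, df=df)

    def test_null_estimate_never_rejects(self):
        assert not ts.wald_reject(self.make(0.0, 1.0))

    def test_normal_reference_threshold(self):
        assert not ts.wald_reject(self.make(1.95, 1.0))
        assert ts.wald_reject(self.make(1.97, 1.0))

    def test_t_reference_is_wider(self):
        assert ts.wald_reject(self.make(2.05, 1.0))
        assert not ts.wald_reject(self.make(2.05, 1.0, df=10))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ts.AnalysisSpec(method="mantel_haenszel", family="survival")
        with pytest.raises(ValueError):
            ts.AnalysisSpec(method="stratified_cox", family="binary")


def test_model_results_interface(pbc_frame):
    model = ts.TrialModel(pbc_frame, method="stratified_cox")
    res = model.fit()
    text = res.summary()
    assert "log hazard ratio" in text and "hazard ratio" in text
    lo, hi = res.conf_int()
    assert lo < res.estimate < hi
    df = pbc_frame.to_dataframe()
    model2 = ts.TrialModel.from_dataframe(
        df, method="stratified_cox", family="survival",
        covariate_cols=list(pbc_frame.names),
    )
    res2 = model2.fit()
    assert res2.estimate == pytest.approx(res.estimate)
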