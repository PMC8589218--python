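"""Location-scale model fitting: designs, updates, recovery, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gaitspan as g
from gaitspan.gamlss import (
    ModelStructure,
    assemble_design,
    fit_location_scale,
    log_likelihood,
    penalized_wls,
)
from gaitspan.smooth_basis import SmoothTermSpec


def toy_frame(y, cycle=None, **extra):
    n = len(y)
    base = {
        "power": np.asarray(y, float),
        "cycle": np.tile(np.arange(101), n // 101 + 1)[:n] if cycle is None else cycle,
        "sex": np.tile(["F", "M"], n // 2 + 1)[:n],
        "age": np.linspace(20, 80, n),
        "speed": np.linspace(1.0, 1.5, n),
        "height": np.full(n, 1.7),
        "strlen": np.full(n, 1.4),
        "study": np.tile(["s1", "s2"], n // 2 + 1)[:n],
        "subject": np.repeat([f"p{i}" for i in range(max(n // 101, 1) + 1)], 101)[:n],
    }
    base.update(extra)
    return pd.DataFrame(base)


class TestAssembleDesign:
    def test_dimension_bookkeeping(self, hip_cohort):
        data, _ = hip_cohort
        st = ModelStructure(mean_terms=[SmoothTermSpec(("cycle",), (10,))])
        mean, sig = assemble_design(data, st)
        n_re = data["study"].nunique() + data["subject"].nunique()
        assert mean.X.shape[1] == 1 + 1 + n_re + 9  # intercept, sex, REs, k-1
        assert sig.X.shape[1] == 1 + (st.sigma_k - 1)

    def test_empty_mean_terms(self, hip_cohort):
        data, _ = hip_cohort
        mean, _ = assemble_design(data, ModelStructure(mean_terms=[]))
        n_re = data["study"].nunique() + data["subject"].nunique()
        assert mean.X.shape[1] == 2 + n_re

    def test_block_map_reconstructs_design(self, hip_cohort):
        data, _ = hip_cohort
        st = ModelStructure(mean_terms=[
            SmoothTermSpec(("cycle",), (8,)), SmoothTermSpec(("age",), (5,)),
        ])
        mean, _ = assemble_design(data, st)
        rebuilt = np.zeros_like(mean.X)
        for label, sl in mean.blocks.items():
            rebuilt[:, sl] = mean.X[:, sl]
        assert np.array_equal(rebuilt, mean.X)
        # block slices tile the columns without gaps or overlap
        cols = sorted((sl.start, sl.stop) for sl in mean.blocks.values())
        assert cols[0][0] == 0 and cols[-1][1] == mean.X.shape[1]
        assert all(a[1] == b[0] for a, b in zip(cols, cols[1:]))

    def test_missing_covariate_and_duplicates_rejected(self, hip_cohort):
        data, _ = hip_cohort
        st = ModelStructure(mean_terms=[SmoothTermSpec(("cadence",), (5,))])
        with pytest.raises(KeyError):
            assemble_design(data, st)
        with pytest.raises(ValueError):
            ModelStructure(mean_terms=[
                SmoothTermSpec(("age",), (5,)), SmoothTermSpec(("age",), (7,)),
            ])


class TestPenalizedWLS:
    def test_matches_dense_normal_equations(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 12))
        z = rng.standard_normal(200)
        w = rng.uniform(0.5, 2.0, 200)
        S = np.eye(5)
        penalties = [(slice(3, 8), S, "blk")]
        lam = np.array([2.7])
        beta, A = penalized_wls(X, z, w, penalties, lam)
        P = np.zeros((12, 12))
        P[3:8, 3:8] = 2.7 * S
        oracle = np.linalg.solve(X.T @ np.diag(w) @ X + P, X.T @ np.diag(w) @ z)
        assert np.abs(beta - oracle).max() < 1e-8

    def test_converged_mean_update_satisfies_score_equation(self, hip_cohort):
        """With lambdas fixed, the fitted mean solves the penalized normal
        equations for the Gaussian working model exactly."""
        data, _ = hip_cohort
        st = ModelStructure(mean_terms=[SmoothTermSpec(("cycle",), (10,))])
        lam_mu = np.array([5.0, 5.0, 1.0])
        m = fit_location_scale(data, st, lambdas_mu=lam_mu, lambdas_sigma=[10.0])
        X = m.mean_design.X
        y = data["power"].values
        _, sigma = m.fitted()
        w = 1.0 / sigma**2
        grad = X.T @ (w * (y - X @ m.beta_mu))
        for lam, (sl, S, _n) in zip(lam_mu, m.mean_design.penalties):
            grad[sl] -= lam * (S @ m.beta_mu[sl])
        scale = np.abs(X.T @ (w * y)).max()
        assert np.abs(grad).max() < 1e-6 * scale


class TestFitting:
    def test_constant_mean_recovery(self):
        rng = np.random.default_rng(1)
        n = 2020
        x = rng.uniform(0, 1, n)
        y = 2.0 + 0.3 * rng.standard_normal(n)
        df = toy_frame(y, age=x * 60 + 20)
        st = ModelStructure(mean_terms=[SmoothTermSpec(("age",), (8,))])
        m = fit_location_scale(df, st)
        pred = m.predict(df.iloc[:50], population_re=True)
        mc_se = 0.3 / np.sqrt(n)
        # fitted level within 2 MC standard errors of truth, after the
        # average sex effect (coded 0/1, truth 0) is accounted for
        level = m.beta_mu[0] + 0.5 * m.beta_mu[1]
        assert abs(level - 2.0) < 4 * mc_se
        # the estimated smooth is flat
        eff = g.partial_effect(m, "age", np.linspace(25, 75, 30))
        assert np.abs(eff.effect).max() < 0.1

    def test_perfect_fit_limit(self):
        cyc = np.tile(np.arange(101), 4)
        y = np.sin(2 * np.pi * cyc / 100)
        df = toy_frame(y, cycle=cyc)
        st = ModelStructure(mean_terms=[SmoothTermSpec(("cycle",), (30,))])
        # random-effect ridges stay at a moderate lambda (unpenalized
        # indicators are collinear with the intercept); the spline is free
        m = fit_location_scale(df, st, lambdas_mu=[1.0, 1.0, 1e-8],
                               lambdas_sigma=[1.0])
        mu, sigma = m.fitted()
        assert np.abs(mu - y).max() < 1e-3
        assert sigma.max() < 1e-3  # scale collapses toward its floor

    def test_sigma_cycle_recovery(self):
        """Heteroscedastic truth sigma(cycle)=exp(0.5 sin(2 pi c/100) - 1):
        fitted log sigma correlates > 0.9 with truth at 200 subjects."""
        rng = np.random.default_rng(3)
        n_subj = 200
        cyc = np.tile(np.arange(101), n_subj)
        sig_true = np.exp(0.5 * np.sin(2 * np.pi * cyc / 100) - 1.0)
        y = sig_true * rng.standard_normal(cyc.size)
        df = toy_frame(y, cycle=cyc,
                       subject=np.repeat([f"p{i}" for i in range(n_subj)], 101))
        st = ModelStructure(mean_terms=[SmoothTermSpec(("cycle",), (8,))], sigma_k=10)
        m = fit_location_scale(df, st)
        _, sigma_hat = m.fitted()
        r = np.corrcoef(np.log(sigma_hat[:101]), np.log(sig_true[:101]))[0, 1]
        assert r > 0.9

    def test_penalized_loglik_nondecreasing_after_freeze(self, hip_cohort):
        data, _ = hip_cohort
        st = ModelStructure(mean_terms=[SmoothTermSpec(("cycle",), (12,))])
        m = fit_location_scale(data, st, lambdas_mu=[1.0, 1.0, 1.0],
                               lambdas_sigma=[1.0])
        trace = np.asarray(m.pll_trace)
        # objective fixed from the first iteration when lambdas are given
        assert np.all(np.diff(trace[1:]) > -1e-6)

    def test_gaussian_limit_of_scaled_t(self, hip_cohort):
        data, _ = hip_cohort
        terms = [SmoothTermSpec(("cycle",), (10,))]
        lam = dict(lambdas_mu=[10.0, 10.0, 10.0], lambdas_sigma=[10.0])
        m_n = fit_location_scale(data, ModelStructure(mean_terms=terms), **lam)
        m_t = fit_location_scale(
            data,
            ModelStructure(mean_terms=terms, family="scaled_t",
                           family_kwargs={"df": 1e6}),
            **lam,
        )
        assert np.abs(m_n.beta_mu - m_t.beta_mu).max() < 1e-3

    def test_degenerate_inputs_rejected(self):
        df = toy_frame(np.zeros(202))
        with pytest.raises(ValueError):
            fit_location_scale(df, ModelStructure(mean_terms=[]))
        df2 = toy_frame(np.random.default_rng(0).standard_normal(202))
        df2.loc[3, "power"] = np.nan
        with pytest.raises(ValueError):
            fit_location_scale(df2, ModelStructure(mean_terms=[]))


class TestLogLikelihood:
    def test_matches_scipy_normal(self, hip_cohort, hip_model):
        data, _ = hip_cohort
        ll = log_likelihood(hip_model, data)
        pred = hip_model.predict(data, population_re=False)
        oracle = stats.norm.logpdf(
            data["power"].values, loc=pred["mu"], scale=pred["sigma"]
        ).sum()
        assert np.isclose(ll, oracle, rtol=1e-10)

    def test_single_standard_normal_observation(self):
        fam = g.get_family("normal")
        assert np.isclose(fam.log_density(0.0, 0.0, 1.0), -0.9189385, atol=1e-7)


class TestPrediction:
    def test_training_rows_reproduce_fitted_values(self, hip_cohort, hip_model):
        data, _ = hip_cohort
        mu_fit, sigma_fit = hip_model.fitted()
        pred = hip_model.predict(data, population_re=False)
        assert np.abs(pred["mu"].values - mu_fit).max() < 1e-10
        assert np.abs(pred["sigma"].values - sigma_fit).max() < 1e-10

    def test_se_nonnegative_and_extrapolation_flagged(self, hip_cohort, hip_model):
        data, _ = hip_cohort
        nd = data.iloc[:5].copy()
        nd["age"] = 200.0
        with pytest.warns(UserWarning, match="extrapolat"):
            pred = hip_model.predict(nd)
        assert (pred["se_mu"] >= 0).all()
        assert pred["extrapolated"].all()

    def test_se_larger_in_sparse_age_regions(self):
        """A cohort with an age gap: prediction se at the gap exceeds the se
        where training ages are dense."""
        rng = np.random.default_rng(8)
        n_subj = 40
        ages = np.concatenate([rng.uniform(20, 35, n_subj // 2),
                               rng.uniform(70, 85, n_subj // 2)])
        cyc = np.tile(np.arange(101), n_subj)
        age_col = np.repeat(ages, 101)
        y = 0.01 * age_col + 0.2 * rng.standard_normal(cyc.size)
        df = toy_frame(y, cycle=cyc, age=age_col,
                       subject=np.repeat([f"p{i}" for i in range(n_subj)], 101))
        st = ModelStructure(mean_terms=[SmoothTermSpec(("age",), (6,))])
        m = fit_location_scale(df, st)
        nd = df.iloc[:1].copy()
        def se_at(a):
            row = nd.copy()
            row["age"] = a
            return m.predict(row, population_re=True)["se_mu"].iloc[0]
        assert se_at(52.0) > se_at(27.0)

    def test_serialization_round_trip(self, hip_cohort, hip_model):
        data, _ = hip_cohort
        clone = g.FittedLSSModel.from_json(hip_model.to_json())
        p1 = hip_model.predict(data.iloc[:50], population_re=False)
        p2 = clone.predict(data.iloc[:50], population_re=False)
        assert np.abs(p1["mu"].values - p2["mu"].values).max() < 1e-12
        assert np.abs(p1["se_mu"].values - p2["se_mu"].values).max() < 1e-12
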