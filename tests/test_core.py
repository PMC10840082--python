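"""Model core: design matrix, joint density, posterior summaries,
convergence diagnostics, the conventional comparator, and the
conjugate-oracle check of the Gibbs sampler."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rsmeta as rs
from rsmeta.core import (
    ParameterState,
    _bgr,
    build_design_matrix,
    dersimonian_laird,
    fit_conventional_pairwise,
    gelman_rubin,
    log_joint,
    summarize_posterior,
)
from rsmeta.types import (
    ArmRecord,
    ModelConfig,
    PosteriorDraws,
    PriorSpec,
    StudyDataset,
    ValidationError,
)

from conftest import mcse_mean


class TestDesignMatrix:
    def test_control_arm_row_is_intercept_only(self, toy_ds):
        D = build_design_matrix(toy_ds)
        assert D.shape == (4, 4)
        np.testing.assert_array_equal(D[0], [1, 0, 0, 0])

    def test_rows_follow_arm_order(self, toy_ds):
        D = build_design_matrix(toy_ds)
        perm = [2, 0, 3, 1]
        shuffled = StudyDataset(
            [toy_ds.arms[i] for i in perm], toy_ds.component_names
        )
        np.testing.assert_array_equal(build_design_matrix(shuffled), D[perm])


def _toy_state(ds, rng):
    m, S = ds.m, ds.n_studies
    return ParameterState(
        beta0=8.0 + rng.normal(0, 0.3),
        beta=rng.normal(0, 0.3, m),
        tau0=0.4,
        tau=np.full(m, 0.2),
        study_intercepts=8.0 + rng.normal(0, 0.4, S),
        study_coefs=rng.normal(0, 0.3, (S, m)),
    )


def _oracle_log_joint(ds, state, priors):
    """Independent density-sum oracle for the base model (all dispersions
    observed, no clusters)."""
    total = 0.0
    sidx = {s: i for i, s in enumerate(ds.study_ids)}
    for a in ds.arms:
        i = sidx[a.study_id]
        mu = state.study_intercepts[i] + float(
            np.dot(state.study_coefs[i], a.components)
        )
        total += stats.norm.logpdf(a.y, mu, a.resolved_se)
    for i in range(ds.n_studies):
        total += stats.norm.logpdf(state.study_intercepts[i], state.beta0, state.tau0)
        for k in range(ds.m):
            total += stats.norm.logpdf(
                state.study_coefs[i, k], state.beta[k], state.tau[k]
            )
    total += stats.norm.logpdf(
        state.beta0, priors.beta0_mean, math.sqrt(priors.beta0_var)
    )
    for k in range(ds.m):
        total += stats.norm.logpdf(state.beta[k], 0.0, math.sqrt(priors.betak_var))
    total += -(ds.m + 1) * math.log(priors.tau_upper)
    return total


class TestLogJoint:
    def test_matches_density_sum_oracle(self, toy_ds):
        rng = np.random.default_rng(3)
        priors = PriorSpec()
        for _ in range(5):
            state = _toy_state(toy_ds, rng)
            assert log_joint(toy_ds, state, priors) == pytest.approx(
                _oracle_log_joint(toy_ds, state, priors), abs=1e-10
            )

    def test_outside_uniform_support_is_minus_inf(self, toy_ds):
        priors = PriorSpec()
        state = _toy_state(toy_ds, np.random.default_rng(0))
        state.tau0 = priors.tau_upper + 0.1
        assert log_joint(toy_ds, state, priors) == -np.inf

    def test_invariant_to_arm_permutation_within_study(self, toy_ds):
        state = _toy_state(toy_ds, np.random.default_rng(1))
        priors = PriorSpec()
        swapped = StudyDataset(
            [toy_ds.arms[1], toy_ds.arms[0], toy_ds.arms[3], toy_ds.arms[2]],
            toy_ds.component_names,
        )
        assert log_joint(toy_ds, state, priors) == pytest.approx(
            log_joint(swapped, state, priors), abs=1e-12
        )

    def test_dimension_mismatch_rejected(self, toy_ds):
        state = _toy_state(toy_ds, np.random.default_rng(2))
        state.beta = state.beta[:-1]
        with pytest.raises(ValidationError):
            log_joint(toy_ds, state, PriorSpec())


def _draws_from_array(x: np.ndarray) -> PosteriorDraws:
    """Wrap a (chains, draws) array as the beta0 draws of a minimal fit."""
    C, T = x.shape
    pop = {
        "beta0": x,
        "beta": np.zeros((C, T, 1)),
        "tau0": np.full((C, T), 0.1),
        "tau": np.full((C, T, 1), 0.1),
    }
    meta = {"variant": "base", "component_names": ["A"], "study_ids": ["s1"]}
    cfg = ModelConfig(chains=C, burnin=0, iterations=T, seed=0)
    return PosteriorDraws(pop, {}, {}, meta, cfg, PriorSpec())


class TestSummaries:
    def test_constant_draws(self):
        d = _draws_from_array(np.full((2, 50), 3.25))
        row = summarize_posterior(d).loc["beta0"]
        assert (row["median"], row["lo2.5"], row["hi97.5"]) == (3.25, 3.25, 3.25)

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(5)
        d = _draws_from_array(rng.standard_normal((2, 50_000)))
        row = summarize_posterior(d).loc["beta0"]
        assert row["median"] == pytest.approx(0.0, abs=0.02)
        assert row["lo2.5"] == pytest.approx(-1.96, abs=0.04)
        assert row["hi97.5"] == pytest.approx(1.96, abs=0.04)

    def test_quantile_ordering(self, base_draws_small):
        summ = summarize_posterior(base_draws_small)
        assert (summ["lo2.5"] <= summ["median"]).all()
        assert (summ["median"] <= summ["hi97.5"]).all()


class TestGelmanRubin:
    def test_identical_distribution_gives_psrf_near_one(self):
        rng = np.random.default_rng(11)
        psrf, upper = _bgr(rng.standard_normal((2, 4000)))
        assert psrf == pytest.approx(1.0, abs=0.02)
        assert upper < 1.1

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((2, 1000))
        x[1] += 5.0
        psrf, upper = _bgr(x)
        assert psrf > 1.5
        assert upper > psrf

    def test_single_chain_rejected(self):
        d = _draws_from_array(np.random.default_rng(0).standard_normal((2, 100)))
        d.population = {k: v[:1] for k, v in d.population.items()}
        d.n_chains = 1
        with pytest.raises(ValidationError):
            gelman_rubin(d)

    def test_reporting_fractions(self, base_draws_small):
        res = gelman_rubin(base_draws_small)
        assert 0.0 <= res.frac_below_1_1 <= res.frac_below_1_2 <= 1.0
        assert "% of parameters monitored" in res.summary()

    def test_matches_coda_oracle(self, tmp_path):
        """Point PSRF and upper bound agree with R coda's gelman.diag."""
        rng = np.random.default_rng(42)
        x = np.cumsum(rng.standard_normal((2, 500)), axis=1) * 0.05
        x += rng.standard_normal((2, 500))
        csv = tmp_path / "chains.csv"
        np.savetxt(csv, x.T, delimiter=",")
        script = textwrap.dedent(f"""
            suppressMessages(library(coda))
            x <- as.matrix(read.csv("{csv}", header=FALSE))
            ml <- mcmc.list(mcmc(x[,1]), mcmc(x[,2]))
            g <- gelman.diag(ml, autoburnin=FALSE, multivariate=FALSE)
            cat(sprintf("%.10f %.10f", g$psrf[1,1], g$psrf[1,2]))
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_psrf, r_upper = map(float, out.stdout.split())
        psrf, upper = _bgr(x)
        assert psrf == pytest.approx(r_psrf, abs=1e-6)
        assert upper == pytest.approx(r_upper, abs=1e-6)


def _pairwise_ds(mds, vars_, component_present=None):
    """Two-arm studies with prescribed mean differences and MD variances."""
    arms = []
    present = component_present or [1] * len(mds)
    for i, (md, v) in enumerate(zip(mds, vars_)):
        se = math.sqrt(v / 2.0)
        arms.append(ArmRecord(f"s{i}", "a1", 50, 8.0, (0,), se=se))
        arms.append(ArmRecord(f"s{i}", "a2", 50, 8.0 + md, (present[i],), se=se))
    return StudyDataset(arms, ["A"])


class TestConventionalPairwise:
    def test_identical_mds_pool_exactly(self):
        ds = _pairwise_ds([-0.4, -0.4], [0.02, 0.02])
        res = fit_conventional_pairwise(ds, "A")
        assert res.estimate == pytest.approx(-0.4, abs=1e-12)
        assert res.tau2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_dl(self):
        md = np.array([-0.5, -0.3, -0.1])
        v = np.array([0.04, 0.09, 0.02])
        # hand DerSimonian-Laird
        w = 1 / v
        fixed = np.sum(w * md) / np.sum(w)
        q = np.sum(w * (md - fixed) ** 2)
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - 2) / c)
        wstar = 1 / (v + tau2)
        pooled = np.sum(wstar * md) / np.sum(wstar)
        ds = _pairwise_ds(list(md), list(v))
        res = fit_conventional_pairwise(ds, "A")
        assert res.estimate == pytest.approx(pooled, abs=1e-8)
        assert res.tau2 == pytest.approx(tau2, abs=1e-8)
        est, se, t2, i2, qstat = dersimonian_laird(md, v)
        assert est == pytest.approx(pooled, abs=1e-12)
        assert qstat == pytest.approx(q, abs=1e-10)

    def test_only_component_bearing_studies_pooled(self):
        ds = _pairwise_ds([-0.5, -0.5, 0.4], [0.02, 0.02, 0.02], [1, 1, 0])
        res = fit_conventional_pairwise(ds, "A")
        assert res.estimate == pytest.approx(-0.5, abs=1e-12)
        assert res.n_studies == 2

    def test_too_few_studies_rejected(self):
        ds = _pairwise_ds([-0.5, 0.4], [0.02, 0.02], [1, 0])
        with pytest.raises(ValidationError, match="fewer than 2"):
            fit_conventional_pairwise(ds, "A")

    def test_multiarm_input_rejected(self, toy_ds):
        three = toy_ds.arms + [
            ArmRecord("s1", "a3", 40, 7.8, (1, 0, 0), se=0.2)
        ]
        ds = StudyDataset(three, toy_ds.component_names)
        with pytest.raises(ValidationError, match="select_extreme_arms"):
            fit_conventional_pairwise(ds, "A")


class TestFitGuards:
    def test_zero_prevalence_component_refused(self):
        arms = [
            ArmRecord("s1", "a1", 50, 8.0, (0, 0), se=0.2),
            ArmRecord("s1", "a2", 50, 7.6, (1, 0), se=0.2),
            ArmRecord("s2", "a1", 50, 8.2, (0, 0), se=0.2),
            ArmRecord("s2", "a2", 50, 7.7, (1, 0), se=0.2),
        ]
        ds = StudyDataset(arms, ["A", "B"])
        with pytest.raises(ValidationError, match="B"):
            rs.fit_base_model(ds, ModelConfig(burnin=10, iterations=10))

    def test_seeded_determinism(self, sim_small):
        _, ds, _ = sim_small
        cfg = ModelConfig(chains=2, burnin=50, iterations=100, seed=9)
        d1 = rs.fit_base_model(ds, cfg)
        d2 = rs.fit_base_model(ds, cfg)
        for key in d1.population:
            np.testing.assert_array_equal(d1.population[key], d2.population[key])
        for key in d1.imputed:
            np.testing.assert_array_equal(d1.imputed[key], d2.imputed[key])


class TestConjugateOracle:
    def test_posterior_matches_closed_form_when_heterogeneity_vanishes(self):
        """With tau ~ 0 and known arm variances the model collapses to a
        Bayesian linear regression with known noise; the sampler's posterior
        means must match the conjugate normal posterior."""
        cfg = rs.SimConfig(
            n_studies=20, m=3, beta=(-0.4, -0.2, 0.1), tau=0.0, tau0=0.0,
            component_prevalence=(0.5, 0.4, 0.3),
            miss_sd_rate=0.0, miss_icc_rate=0.0, cluster_fraction=0.0,
            seed=77,
        )
        ds, _ = rs.simulate_dataset(cfg)
        priors = PriorSpec(tau_upper=0.01)
        draws = rs.fit_base_model(
            ds, ModelConfig(chains=2, burnin=1000, iterations=4000, seed=5),
            priors, store_study=False,
        )
        D = build_design_matrix(ds)
        w = 1.0 / np.array([a.resolved_se for a in ds.arms]) ** 2
        prior_prec = np.diag(
            1.0 / np.r_[priors.beta0_var, np.full(ds.m, priors.betak_var)]
        )
        prior_mean = np.r_[priors.beta0_mean, np.zeros(ds.m)]
        post_prec = D.T @ (D * w[:, None]) + prior_prec
        post_mean = np.linalg.solve(
            post_prec, D.T @ (w * ds.y) + prior_prec @ prior_mean
        )
        sampled = np.column_stack(
            [draws.stacked("beta0"), draws.stacked("beta")]
        ).mean(axis=0)
        per_chain = np.concatenate(
            [draws.population["beta0"][:, :, None], draws.population["beta"]],
            axis=2,
        )
        for k in range(ds.m + 1):
            mcse = mcse_mean(per_chain[:, :, k])
            assert abs(sampled[k] - post_mean[k]) < 3 * mcse + 1e-3, (
                f"coefficient {k}: {sampled[k]:.5f} vs oracle {post_mean[k]:.5f}"
            )
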