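"""Interaction models, covariate-modification models and contrasts, and the
difference-based (contrast-level) model."""

import numpy as np
import pandas as pd
import pytest

import rsmeta as rs
from rsmeta.extensions import (
    InteractionConfig,
    ModifierConfig,
    _difference_data,
    code_modifier,
    fit_difference_model,
    fit_interaction_model,
    fit_modifier_model,
    modification_contrasts,
)
from rsmeta.types import (
    ArmRecord,
    ModelConfig,
    PosteriorDraws,
    PriorSpec,
    StudyDataset,
    ValidationError,
)

QUICK = ModelConfig(chains=2, burnin=100, iterations=200, seed=3)


@pytest.fixture(scope="module")
def ds_m9():
    cfg = rs.SimConfig(
        n_studies=40, m=9, seed=33, miss_sd_rate=0.0, miss_icc_rate=0.0,
        cluster_fraction=0.0,
    )
    ds, _ = rs.simulate_dataset(cfg)
    return ds


class TestInteraction:
    def test_nine_components_add_eight_product_parameters(self, ds_m9):
        draws = fit_interaction_model(ds_m9, InteractionConfig("comp1"), QUICK)
        assert draws.population["gamma"].shape[2] == 8
        gamma_names = [n for n in draws.parameter_names() if n.startswith("gamma")]
        assert len(gamma_names) == 8
        assert all("comp1" not in n for n in gamma_names)

    def test_unknown_focal_rejected(self, ds_m9):
        with pytest.raises(ValidationError, match="nope"):
            fit_interaction_model(ds_m9, InteractionConfig("nope"), QUICK)

    def test_focal_without_cooccurrence_rejected(self):
        arms = []
        for i in range(4):
            arms.append(ArmRecord(f"s{i}", "a1", 50, 8.0, (0, 0), se=0.2))
            # component A always appears alone
            arms.append(ArmRecord(f"s{i}", "a2", 50, 7.6, (1, 0) if i < 2 else (0, 1), se=0.2))
        ds = StudyDataset(arms, ["A", "B"])
        with pytest.raises(ValidationError, match="co-occur"):
            fit_interaction_model(ds, InteractionConfig("A"), QUICK)

    def test_recovers_a_true_product_effect(self):
        cfg = rs.SimConfig(
            n_studies=150, m=3, beta=(-0.4, -0.2, 0.0), tau=0.1,
            component_prevalence=(0.6, 0.5, 0.3),
            gamma={("comp1", "comp2"): -0.5},
            miss_sd_rate=0.0, miss_icc_rate=0.0, cluster_fraction=0.0,
            seed=55,
        )
        ds, _ = rs.simulate_dataset(cfg)
        draws = fit_interaction_model(
            ds, InteractionConfig("comp1"),
            ModelConfig(chains=2, burnin=1000, iterations=2500, seed=8),
        )
        summ = rs.summarize_posterior(draws)
        row = summ.loc["gamma[comp2]"]
        assert row["lo2.5"] <= -0.5 <= row["hi97.5"]
        assert row["median"] == pytest.approx(-0.5, abs=0.25)
        null = summ.loc["gamma[comp3]"]
        assert null["lo2.5"] <= 0.0 <= null["hi97.5"]


class TestModifier:
    def test_nine_components_add_ten_parameters(self, ds_m9):
        draws = fit_modifier_model(ds_m9, ModifierConfig(mode="binary"), QUICK)
        assert draws.population["phi"].ndim == 2
        assert draws.population["psi"].shape[2] == 9
        extra = [
            n for n in draws.parameter_names()
            if n == "phi" or n.startswith("psi")
        ]
        assert len(extra) == 10

    def test_binary_coding_at_cutpoint(self):
        arms = [
            ArmRecord("s1", "a1", 50, 8.0, (1,), se=0.2, baseline_cov=8.2),
            ArmRecord("s2", "a1", 50, 8.0, (1,), se=0.2, baseline_cov=7.6),
        ]
        ds = StudyDataset(arms, ["A"])
        z = code_modifier(ds, ModifierConfig(mode="binary", cutpoint=8.0))
        assert list(z) == [1.0, 0.0]

    def test_continuous_coding_is_mean_centered(self):
        arms = [
            ArmRecord("s1", "a1", 50, 8.0, (1,), se=0.2, baseline_cov=8.5),
            ArmRecord("s2", "a1", 50, 8.0, (1,), se=0.2, baseline_cov=7.5),
        ]
        ds = StudyDataset(arms, ["A"])
        z = code_modifier(ds, ModifierConfig(mode="continuous"))
        assert list(z) == [0.5, -0.5]

    def test_constant_covariate_rejected(self):
        arms = [
            ArmRecord(f"s{i}", "a1", 50, 8.0, (1,), se=0.2, baseline_cov=8.0)
            for i in range(3)
        ]
        ds = StudyDataset(arms, ["A"])
        with pytest.raises(ValidationError, match="constant"):
            code_modifier(ds, ModifierConfig(mode="continuous"))

    def test_missing_covariate_rejected(self, toy_ds):
        with pytest.raises(ValidationError, match="covariate missing"):
            code_modifier(toy_ds, ModifierConfig(mode="binary"))

    def test_recovers_a_true_covariate_effect(self):
        cfg = rs.SimConfig(
            n_studies=150, m=3, beta=(-0.4, -0.2, 0.0), tau=0.1,
            component_prevalence=(0.6, 0.5, 0.3), phi=1.0,
            miss_sd_rate=0.0, miss_icc_rate=0.0, cluster_fraction=0.0,
            seed=56,
        )
        ds, _ = rs.simulate_dataset(cfg)
        draws = fit_modifier_model(
            ds, ModifierConfig(mode="continuous"),
            ModelConfig(chains=2, burnin=1000, iterations=2500, seed=9),
        )
        summ = rs.summarize_posterior(draws)
        assert summ.loc["phi", "median"] == pytest.approx(1.0, abs=0.2)
        psi_rows = summ.loc[[f"psi[comp{k}]" for k in (1, 2, 3)]]
        covers = (psi_rows["lo2.5"] <= 0) & (0 <= psi_rows["hi97.5"])
        assert covers.all()


def _toy_modifier_draws(beta0, beta, phi, psi):
    """(draws, m) arrays wrapped as a 1-chain modifier fit."""
    beta0 = np.asarray(beta0, dtype=float)
    T = beta0.size
    m = np.asarray(beta).shape[1]
    pop = {
        "beta0": beta0[None, :],
        "beta": np.asarray(beta, dtype=float)[None],
        "tau0": np.full((1, T), 0.1),
        "tau": np.full((1, T, m), 0.1),
        "phi": np.asarray(phi, dtype=float)[None, :],
        "psi": np.asarray(psi, dtype=float)[None],
    }
    meta = {
        "variant": "modifier",
        "component_names": [f"c{k}" for k in range(m)],
        "study_ids": ["s1"],
        "modifier_mode": "binary",
    }
    cfg = ModelConfig(chains=2, burnin=0, iterations=T, seed=0)
    return PosteriorDraws(pop, {}, {}, meta, cfg, PriorSpec())


class TestModificationContrasts:
    def test_matches_per_draw_hand_arithmetic(self):
        beta0 = [8.0, 8.2, 7.9]
        beta = [[-0.3, 0.1], [-0.2, 0.0], [-0.4, 0.2]]
        phi = [0.5, 0.6, 0.4]
        psi = [[-0.1, 0.05], [-0.2, 0.0], [0.0, 0.1]]
        table = modification_contrasts(_toy_modifier_draws(beta0, beta, phi, psi))
        b0, b, p, ps = map(np.asarray, (beta0, beta, phi, psi))
        for k, comp in enumerate(["c0", "c1"]):
            cells = {
                "uncontrolled_plus_strategy": b0 + b[:, k] + p + ps[:, k],
                "uncontrolled_difference": b[:, k] + ps[:, k],
                "controlled_plus_strategy": b0 + b[:, k],
                "controlled_difference": b[:, k],
                "difference_of_differences": -ps[:, k],
            }
            for label, vals in cells.items():
                lo, med, hi = np.quantile(vals, [0.025, 0.5, 0.975])
                assert table.loc[comp, f"{label}_median"] == pytest.approx(med)
                assert table.loc[comp, f"{label}_lo"] == pytest.approx(lo)
                assert table.loc[comp, f"{label}_hi"] == pytest.approx(hi)

    def test_zero_psi_gives_zero_difference_of_differences(self):
        rng = np.random.default_rng(0)
        table = modification_contrasts(
            _toy_modifier_draws(
                8 + rng.normal(0, 0.1, 50),
                rng.normal(0, 0.2, (50, 2)),
                rng.normal(0, 0.1, 50),
                np.zeros((50, 2)),
            )
        )
        assert (table["difference_of_differences_median"] == 0).all()
        assert (table["difference_of_differences_lo"] == 0).all()

    def test_requires_modifier_fit(self, base_draws_small):
        with pytest.raises(ValidationError, match="phi"):
            modification_contrasts(base_draws_small)


def _diff_ds():
    arms = [
        ArmRecord("s1", "a1", 50, 8.1, (0, 1), se=0.2),   # reference (1 comp... )
        ArmRecord("s1", "a2", 50, 7.6, (1, 1), se=0.3),   # B present in both arms
        ArmRecord("s2", "a1", 50, 8.3, (0, 0), se=0.25),
        ArmRecord("s2", "a2", 50, 7.8, (1, 0), se=0.15),
        ArmRecord("s3", "a1", 50, 8.2, (0, 0), se=0.2),
        ArmRecord("s3", "a2", 50, 7.9, (0, 1), se=0.2),
    ]
    return StudyDataset(arms, ["A", "B"])


class TestDifferenceModel:
    def test_shared_component_cancels_within_study(self):
        M, h = _difference_data(_diff_ds())
        # study s1: B present in both arms -> its contrast column is zero
        assert M[0][1, 1] == 0.0
        assert h[0][1] == 0.0

    def test_two_arm_contrast_variance_is_sum(self):
        ds = _diff_ds()
        M, h = _difference_data(ds)
        # study s2: dX = (1, 0), Sigma = se1^2 + se2^2
        v = 0.25**2 + 0.15**2
        assert M[1][0, 0] == pytest.approx(1.0 / v, rel=1e-12)

    def test_shared_reference_covariance_in_multiarm_study(self):
        arms = [
            ArmRecord("s1", "a1", 50, 8.2, (0, 0), se=0.2),
            ArmRecord("s1", "a2", 50, 7.8, (1, 0), se=0.3),
            ArmRecord("s1", "a3", 50, 7.7, (0, 1), se=0.25),
            ArmRecord("s2", "a1", 50, 8.0, (0, 0), se=0.2),
            ArmRecord("s2", "a2", 50, 7.6, (1, 1), se=0.2),
        ]
        ds = StudyDataset(arms, ["A", "B"])
        M, h = _difference_data(ds)
        dX = np.array([[1.0, 0.0], [0.0, 1.0]])
        cov = np.array(
            [[0.2**2 + 0.3**2, 0.2**2], [0.2**2, 0.2**2 + 0.25**2]]
        )
        expected = dX.T @ np.linalg.inv(cov) @ dX
        np.testing.assert_allclose(M[0], expected, rtol=1e-12)

    def test_invariant_to_constant_shift_of_study_outcomes(self):
        # outcome values and shifts chosen exactly representable in binary so
        # the within-study differences are bitwise unchanged by the shift
        def mk(shift):
            arms = [
                ArmRecord("s1", "a1", 50, 8.0 + shift, (0, 1), se=0.2),
                ArmRecord("s1", "a2", 50, 7.5 + shift, (1, 1), se=0.3),
                ArmRecord("s2", "a1", 50, 8.25 - shift, (0, 0), se=0.25),
                ArmRecord("s2", "a2", 50, 7.75 - shift, (1, 0), se=0.15),
                ArmRecord("s3", "a1", 50, 8.5, (0, 0), se=0.2),
                ArmRecord("s3", "a2", 50, 8.0, (0, 1), se=0.2),
            ]
            return StudyDataset(arms, ["A", "B"])

        cfg = ModelConfig(chains=2, burnin=100, iterations=300, seed=4)
        d1 = fit_difference_model(mk(0.0), cfg)
        d2 = fit_difference_model(mk(1.5), cfg)
        np.testing.assert_array_equal(d1.population["beta"], d2.population["beta"])

    def test_missing_dispersion_rejected(self):
        arms = [
            ArmRecord("s1", "a1", 50, 8.1, (0,), se=0.2),
            ArmRecord("s1", "a2", 50, 7.6, (1,), se=None),
        ]
        ds = StudyDataset(arms, ["A"])
        with pytest.raises(ValidationError, match="dispersion"):
            fit_difference_model(ds, QUICK)

    def test_single_arm_study_rejected(self):
        arms = [ArmRecord("s1", "a1", 50, 8.1, (1,), se=0.2)]
        ds = StudyDataset(arms, ["A"])
        with pytest.raises(ValidationError, match="single arm"):
            fit_difference_model(ds, QUICK)
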