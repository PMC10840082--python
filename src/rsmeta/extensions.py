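"""Model extensions: nonadditivity, covariate effect modification, and the
contrast-level (difference-based) model.

*Interaction models* add pairwise product terms between one focal component
``r`` and every remaining component, one model per focal component; the
product coefficients ``gamma_l`` are population-level with N(0, gamma_var)
priors, so a fit with ``m`` retained components adds ``m - 1`` parameters.

*Modifier models* add a study-level covariate ``Z`` (binary at a cutpoint,
or mean-centered continuous) and its products with every component:
``phi·Z + sum_k psi_k·Z·X_k``, adding ``m + 1`` parameters.

*The difference model* analyses within-study contrasts against a reference
arm instead of arm means; study intercepts cancel, as do coefficients of
components present in both arms of a contrast. Contrasts sharing the
reference arm are correlated (covariance ``theta_ref^2``), which the
likelihood accounts for exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import _fit_arm_model, _sample_trunc_tau
from .types import (
    ModelConfig,
    PosteriorDraws,
    PriorSpec,
    StudyDataset,
    ValidationError,
)

__all__ = [
    "InteractionConfig",
    "ModifierConfig",
    "fit_interaction_model",
    "fit_modifier_model",
    "modification_contrasts",
    "fit_difference_model",
]


# ---------------------------------------------------------------------------
# interaction (nonadditivity) models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionConfig:
    """One focal component ``r`` crossed with all remaining components."""

    focal: str

    def partners(self, component_names: list[str]) -> list[str]:
        if self.focal not in component_names:
            raise ValidationError(f"focal component {self.focal!r} not in dataset")
        return [c for c in component_names if c != self.focal]


def fit_interaction_model(
    ds: StudyDataset,
    cfg: InteractionConfig,
    config: ModelConfig,
    priors: PriorSpec | None = None,
    store_study: bool = True,
) -> PosteriorDraws:
    """Fit the additive model extended with product terms
    ``gamma_l · X_r · X_l`` for every partner ``l`` of the focal component.

    The ``gamma_l`` are population-level coefficients with independent
    N(0, gamma_var) priors; with ``m`` components this adds ``m - 1``
    parameters. Raises if the focal component never co-occurs with any
    partner (all product columns would be zero)."""
    priors = priors or PriorSpec()
    partners = cfg.partners(ds.component_names)
    r = ds.component_names.index(cfg.focal)
    X = ds.X
    cols = [X[:, r] * X[:, ds.component_names.index(l)] for l in partners]
    F = np.column_stack(cols)
    if not np.any(F.sum(axis=0) > 0):
        raise ValidationError(
            f"focal component {cfg.focal!r} never co-occurs with any partner; "
            "all product columns are zero"
        )
    q = F.shape[1]
    return _fit_arm_model(
        ds,
        config,
        priors,
        F=F,
        fixed_prior_var=np.full(q, priors.gamma_var),
        fixed_split=[("gamma", q)],
        variant="interaction",
        meta_extra={"focal": cfg.focal, "gamma_partners": partners},
        store_study=store_study,
    )


# ---------------------------------------------------------------------------
# covariate effect-modification models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModifierConfig:
    """Study-level covariate coding for effect-modification models.

    ``mode="binary"`` dichotomises the study-mean baseline covariate at
    ``cutpoint`` (values at or above the cutpoint are coded 1, e.g.
    "uncontrolled" baseline HbA1c at the conventional 8.0% threshold).
    ``mode="continuous"`` uses the covariate mean-centered across studies.
    """

    covariate: str = "baseline_cov"
    mode: str = "binary"
    cutpoint: float = 8.0
    centering: bool = True

    def __post_init__(self):
        if self.mode not in ("binary", "continuous"):
            raise ValidationError("mode must be 'binary' or 'continuous'")


def _study_covariate(ds: StudyDataset, cfg: ModifierConfig) -> np.ndarray:
    vals = np.full(ds.n_studies, np.nan)
    for i, sid in enumerate(ds.study_ids):
        obs = [
            a.baseline_cov for a in ds.arms_of(sid) if a.baseline_cov is not None
        ]
        if not obs:
            raise ValidationError(
                f"study {sid!r}: baseline covariate missing; modifier models "
                "require the covariate for every study"
            )
        vals[i] = float(np.mean(obs))
    return vals


def code_modifier(ds: StudyDataset, cfg: ModifierConfig) -> np.ndarray:
    """Per-arm coded covariate Z (constant within study)."""
    study_vals = _study_covariate(ds, cfg)
    if cfg.mode == "binary":
        z_study = (study_vals >= cfg.cutpoint).astype(float)
    else:
        center = study_vals.mean() if cfg.centering else 0.0
        z_study = study_vals - center
    if np.allclose(z_study, z_study[0]):
        raise ValidationError(
            "coded covariate is constant across studies; phi is unidentifiable"
        )
    return z_study[ds.study_index]


def fit_modifier_model(
    ds: StudyDataset,
    cfg: ModifierConfig,
    config: ModelConfig,
    priors: PriorSpec | None = None,
    store_study: bool = True,
) -> PosteriorDraws:
    """Fit the additive model extended with covariate-modification terms
    ``phi·Z + sum_k psi_k·Z·X_k``.

    ``phi`` and the ``psi_k`` are population-level coefficients with
    independent N(0, phi_psi_var) priors; with ``m`` components this adds
    ``m + 1`` parameters."""
    priors = priors or PriorSpec()
    z = code_modifier(ds, cfg)
    F = np.column_stack([z, z[:, None] * ds.X])
    q = F.shape[1]
    return _fit_arm_model(
        ds,
        config,
        priors,
        F=F,
        fixed_prior_var=np.full(q, priors.phi_psi_var),
        fixed_split=[("phi", 1), ("psi", ds.m)],
        variant="modifier",
        meta_extra={
            "modifier_mode": cfg.mode,
            "modifier_cutpoint": cfg.cutpoint,
            "modifier_covariate": cfg.covariate,
        },
        store_study=store_study,
    )


def _summ(draws_1d: np.ndarray) -> tuple[float, float, float]:
    lo, med, hi = np.quantile(draws_1d, [0.025, 0.5, 0.975])
    return float(med), float(lo), float(hi)


def modification_contrasts(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-component contrast table from a binary-modifier fit.

    For each component ``k`` the per-draw linear combinations are summarised
    as median and 95% CrI:

    - uncontrolled baseline + strategy: ``beta_0 + beta_k + phi + psi_k``
    - difference, uncontrolled baseline: ``beta_k + psi_k``
    - controlled baseline + strategy: ``beta_0 + beta_k``
    - difference, controlled baseline: ``beta_k``
    - difference between differences: ``-psi_k``

    All quantities are computed per draw and then summarised (medians of
    sums, never sums of medians).
    """
    if "phi" not in draws or "psi" not in draws:
        raise ValidationError("draws lack phi/psi; fit a modifier model first")
    beta0 = draws.stacked("beta0")
    beta = draws.stacked("beta")
    phi = draws.stacked("phi")
    psi = draws.stacked("psi")
    rows = []
    blocks = {
        "uncontrolled_plus_strategy": lambda k: beta0 + beta[:, k] + phi + psi[:, k],
        "uncontrolled_difference": lambda k: beta[:, k] + psi[:, k],
        "controlled_plus_strategy": lambda k: beta0 + beta[:, k],
        "controlled_difference": lambda k: beta[:, k],
        "difference_of_differences": lambda k: -psi[:, k],
    }
    for k, name in enumerate(draws.component_names):
        row = {"component": name}
        for label, fn in blocks.items():
            med, lo, hi = _summ(fn(k))
            row[f"{label}_median"] = med
            row[f"{label}_lo"] = lo
            row[f"{label}_hi"] = hi
        rows.append(row)
    return pd.DataFrame(rows).set_index("component")


# ---------------------------------------------------------------------------
# difference-based (contrast-level) model
# ---------------------------------------------------------------------------

def _difference_data(ds: StudyDataset):
    """Per-study contrasts vs the reference arm (fewest components, ties
    broken by lowest arm label), with the exact contrast covariance."""
    M_list, h_list = [], []
    dX_all = []
    for sid in ds.study_ids:
        arms = ds.arms_of(sid)
        if len(arms) < 2:
            raise ValidationError(f"study {sid!r} has a single arm")
        ref = min(arms, key=lambda a: (a.n_components_active, a.arm_id))
        others = [a for a in arms if a is not ref]
        ses = {}
        for a in arms:
            se = a.resolved_se
            if se is None:
                raise ValidationError(
                    f"arm ({a.study_id}, {a.arm_id}): the difference model "
                    "requires an observed or derivable dispersion"
                )
            if a.needs_cluster_adjustment:
                if a.icc_missing:
                    raise ValidationError(
                        f"arm ({a.study_id}, {a.arm_id}): the difference model "
                        "requires an observed ICC for unadjusted cluster arms"
                    )
                se *= math.sqrt(1.0 + (a.avg_cluster_size - 1.0) * a.icc)
            ses[a.arm_id] = se
        d = np.array([a.y - ref.y for a in others])
        dX = np.array(
            [np.asarray(a.components) - np.asarray(ref.components) for a in others],
            dtype=float,
        )
        c = len(others)
        cov = np.full((c, c), ses[ref.arm_id] ** 2)
        cov[np.diag_indices(c)] += np.array([ses[a.arm_id] for a in others]) ** 2
        prec = np.linalg.inv(cov)
        M_list.append(dX.T @ prec @ dX)
        h_list.append(dX.T @ prec @ d)
        dX_all.append(dX)
    dX_stack = np.vstack(dX_all)
    dead = np.nonzero(np.all(dX_stack == 0, axis=0))[0]
    if dead.size:
        names = [ds.component_names[k] for k in dead]
        raise ValidationError(
            f"components {names} never differ between arms within any study; "
            "their coefficients cancel everywhere and are unidentifiable in "
            "the difference model"
        )
    return np.stack(M_list), np.stack(h_list)


def fit_difference_model(
    ds: StudyDataset,
    config: ModelConfig,
    priors: PriorSpec | None = None,
    store_study: bool = True,
) -> PosteriorDraws:
    """Fit the contrast-level model of within-study outcome differences.

    Models ``Y_ij - Y_i,ref`` with mean ``sum_k b_ki (X_ijk - X_i,ref,k)``;
    the study intercept drops out, and components present in both arms of a
    contrast contribute nothing ("cancel"). Contrast variances are
    ``theta_ij^2 + theta_ref^2`` with covariance ``theta_ref^2`` between
    contrasts sharing the reference arm. Study-level ``b_ki`` remain
    exchangeable around ``beta_k`` with SD ``tau_k`` as in the arm-based
    model. All arm dispersions must be observed or derivable.
    """
    priors = priors or PriorSpec()
    M, h0 = _difference_data(ds)
    S, m = h0.shape[0], ds.m
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    kept = config.n_kept
    eye = np.eye(m)
    prior_var = np.full(m, priors.betak_var)

    pop_out, tau_out, b_out = [], [], []
    for seq in seeds:
        rng = np.random.default_rng(seq)
        beta = 0.5 * rng.standard_normal(m)
        hi = min(1.0, priors.tau_upper)
        tau = rng.uniform(0.05 * hi, hi, size=m)
        b = beta + tau * rng.standard_normal((S, m))
        o_pop = np.empty((kept, m))
        o_tau = np.empty((kept, m))
        o_b = np.empty((kept, S, m)) if store_study else None
        total = config.burnin + config.iterations
        for it in range(total):
            prior_prec = 1.0 / tau**2
            P = M + prior_prec * eye
            h = h0 + prior_prec * beta
            L = np.linalg.cholesky(P)
            z = rng.standard_normal((S, m, 1))
            b = np.linalg.solve(P, h[:, :, None] + L @ z)[:, :, 0]
            prec_pop = S / tau**2 + 1.0 / prior_var
            mean_pop = (b.sum(axis=0) / tau**2) / prec_pop
            beta = mean_pop + rng.standard_normal(m) / np.sqrt(prec_pop)
            S_k = np.sum((b - beta) ** 2, axis=0)
            tau = _sample_trunc_tau(rng, S_k, S, priors.tau_upper)
            k = it - config.burnin
            if k >= 0 and k % config.thin == 0:
                k //= config.thin
                if k < kept:
                    o_pop[k] = beta
                    o_tau[k] = tau
                    if store_study:
                        o_b[k] = b
        pop_out.append(o_pop)
        tau_out.append(o_tau)
        if store_study:
            b_out.append(o_b)

    population = {"beta": np.stack(pop_out), "tau": np.stack(tau_out)}
    study = {"b": np.stack(b_out)} if store_study else {}
    meta = {
        "variant": "difference",
        "component_names": list(ds.component_names),
        "study_ids": list(ds.study_ids),
    }
    return PosteriorDraws(population, study, {}, meta, config, priors)
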