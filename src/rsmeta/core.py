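"""Arm-based hierarchical response-surface meta-regression.

The model treats the posttreatment mean ``Y_ij`` of arm ``j`` in study ``i``
as normal around an arm-specific true mean with known (or imputed) sampling
variance::

    Y_ij ~ N(mu_ij, theta_ij^2)
    mu_ij = b_0i + sum_k b_ki X_ijk        (additive in the m components)
    b_ki ~ N(beta_k, tau_k^2),   b_0i ~ N(beta_0, tau_0^2)

Population coefficients carry normal priors (variance parameterisation) and
all between-study SDs carry uniform priors on ``[0, tau_upper]``. Missing
sampling SDs are given a log-normal prior whose hyperparameters default to
empirical estimates from the arms with observed dispersion, and missing ICCs
of unadjusted cluster arms a uniform prior on ``[0, icc_upper]``; both are
sampled alongside the model parameters so their uncertainty propagates.

Sampling is blocked Gibbs: study-level coefficient vectors and population
means have conditionally normal updates (drawn exactly, vectorised across
studies), the between-study SDs have exact truncated inverse-gamma
conditionals under the uniform prior, imputed log-dispersions use a
log-scale random-walk Metropolis step, and imputed ICCs an independence
proposal from their uniform prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .types import (
    ArmRecord,
    ModelConfig,
    PosteriorDraws,
    PriorSpec,
    StudyDataset,
    ValidationError,
)

__all__ = [
    "ParameterState",
    "build_design_matrix",
    "log_joint",
    "fit_base_model",
    "summarize_posterior",
    "gelman_rubin",
    "GelmanRubinResult",
    "fit_conventional_pairwise",
    "PairwiseResult",
    "dersimonian_laird",
]

_Z975 = 1.959963984540054


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

@dataclass
class _FitData:
    """Arm-level arrays with dispersion/ICC resolution applied."""

    y: np.ndarray               # (n_arms,)
    X: np.ndarray               # (n_arms, m)
    D: np.ndarray               # (n_arms, m+1) intercept + components
    study_index: np.ndarray     # (n_arms,)
    n_studies: int
    s_obs: np.ndarray           # observed base SE (nan where missing); observed-ICC
                                # design effects already folded in
    deff_base: np.ndarray       # fixed design-effect multiplier on the variance
    csize: np.ndarray           # average cluster size (1 where irrelevant)
    needs_theta: np.ndarray     # arm indices with missing dispersion
    needs_icc: np.ndarray       # arm indices with missing ICC (unadjusted cluster)
    theta_logmean: float
    theta_logsd: float
    component_names: list
    study_ids: list
    pad_arm: np.ndarray         # (S, A) arm index per study slot
    pad_mask: np.ndarray        # (S, A) 1.0 where slot holds a real arm

    @property
    def n_arms(self) -> int:
        return self.y.size

    @property
    def m(self) -> int:
        return self.X.shape[1]


def build_design_matrix(ds: StudyDataset) -> np.ndarray:
    """Arm-level design matrix: a leading all-ones intercept column followed
    by the m component indicator columns, in arm order."""
    X = ds.X
    return np.column_stack([np.ones(len(X)), X])


def _prepare(ds: StudyDataset, priors: PriorSpec) -> _FitData:
    X = ds.X
    prev = X.sum(axis=0)
    dead = np.nonzero(prev == 0)[0]
    if dead.size:
        names = [ds.component_names[k] for k in dead]
        raise ValidationError(
            f"components never present in any arm: {names}; their coefficients "
            "are unidentifiable — drop or pool them before fitting"
        )
    n = ds.n_arms
    s_obs = np.full(n, np.nan)
    deff_base = np.ones(n)
    csize = np.ones(n)
    needs_theta, needs_icc = [], []
    for j, a in enumerate(ds.arms):
        se = a.resolved_se
        if se is not None and se <= 0:
            raise ValidationError(
                f"arm ({a.study_id}, {a.arm_id}): non-positive dispersion"
            )
        if a.needs_cluster_adjustment:
            if a.avg_cluster_size is None:
                raise ValidationError(
                    f"arm ({a.study_id}, {a.arm_id}): cluster arm without "
                    "avg_cluster_size"
                )
            csize[j] = a.avg_cluster_size
            if a.icc_missing:
                needs_icc.append(j)
                if se is None:
                    needs_theta.append(j)
                else:
                    s_obs[j] = se
            else:
                deff = 1.0 + (a.avg_cluster_size - 1.0) * a.icc
                if se is None:
                    needs_theta.append(j)
                    deff_base[j] = deff
                else:
                    s_obs[j] = se * math.sqrt(deff)
        else:
            if se is None:
                needs_theta.append(j)
            else:
                s_obs[j] = se
    # empirical log-normal hyperparameters for missing dispersions
    obs = s_obs[~np.isnan(s_obs)]
    if priors.dispersion_logmean is not None:
        lm = priors.dispersion_logmean
        ls = priors.dispersion_logsd if priors.dispersion_logsd else 1.0
    else:
        if needs_theta and obs.size < 2:
            raise ValidationError(
                "cannot estimate a dispersion prior: fewer than 2 arms with "
                "observed dispersion; supply dispersion_logmean/logsd"
            )
        if obs.size:
            logs = np.log(obs)
            lm = float(logs.mean())
            ls = float(max(logs.std(ddof=1) if obs.size > 1 else 0.5, 0.1))
        else:  # fully missing handled above; keep a fallback
            lm, ls = math.log(0.2), 1.0
    study_index = ds.study_index
    S = ds.n_studies
    counts = np.bincount(study_index, minlength=S)
    A = int(counts.max())
    pad_arm = np.zeros((S, A), dtype=int)
    pad_mask = np.zeros((S, A))
    slot = np.zeros(S, dtype=int)
    for j, s in enumerate(study_index):
        pad_arm[s, slot[s]] = j
        pad_mask[s, slot[s]] = 1.0
        slot[s] += 1
    return _FitData(
        y=ds.y,
        X=X,
        D=build_design_matrix(ds),
        study_index=study_index,
        n_studies=S,
        s_obs=s_obs,
        deff_base=deff_base,
        csize=csize,
        needs_theta=np.array(needs_theta, dtype=int),
        needs_icc=np.array(needs_icc, dtype=int),
        theta_logmean=lm,
        theta_logsd=ls,
        component_names=list(ds.component_names),
        study_ids=list(ds.study_ids),
        pad_arm=pad_arm,
        pad_mask=pad_mask,
    )


# ---------------------------------------------------------------------------
# log joint density
# ---------------------------------------------------------------------------

@dataclass
class ParameterState:
    """One full set of model parameters (base model plus optional extension
    coefficients). ``imputed_theta`` holds sampling SDs for arms with missing
    dispersion, in the order of their arm indices; its prior is evaluated on
    the log scale (the sampler's parameterisation)."""

    beta0: float
    beta: np.ndarray
    tau0: float
    tau: np.ndarray
    study_intercepts: np.ndarray        # (S,)
    study_coefs: np.ndarray             # (S, m)
    imputed_theta: np.ndarray = field(default_factory=lambda: np.empty(0))
    imputed_icc: np.ndarray = field(default_factory=lambda: np.empty(0))
    gamma: np.ndarray | None = None
    phi: float | None = None
    psi: np.ndarray | None = None


def _normal_logpdf(x, mean, var):
    return -0.5 * (np.log(2 * np.pi * var) + (x - mean) ** 2 / var)


def log_joint(ds: StudyDataset, state: ParameterState, priors: PriorSpec) -> float:
    """Log of the joint density: arm likelihoods x study-level coefficient
    densities x priors. Returns ``-inf`` outside the prior support (e.g. a
    between-study SD above ``tau_upper``)."""
    data = _prepare(ds, priors)
    m = data.m
    if len(state.beta) != m or len(state.tau) != m:
        raise ValidationError("state dimensions do not match dataset components")
    if state.study_coefs.shape != (data.n_studies, m):
        raise ValidationError("study_coefs shape mismatch")
    taus = np.concatenate([[state.tau0], np.asarray(state.tau, dtype=float)])
    if np.any(taus < 0) or np.any(taus > priors.tau_upper):
        return -np.inf
    if state.imputed_theta.size != data.needs_theta.size:
        raise ValidationError("imputed_theta length mismatch")
    if state.imputed_icc.size != data.needs_icc.size:
        raise ValidationError("imputed_icc length mismatch")
    if np.any(state.imputed_theta <= 0):
        return -np.inf
    if state.imputed_icc.size and (
        np.any(state.imputed_icc < 0) or np.any(state.imputed_icc >= priors.icc_upper)
    ):
        return -np.inf

    s = data.s_obs.copy()
    s[data.needs_theta] = state.imputed_theta
    deff = data.deff_base.copy()
    if data.needs_icc.size:
        deff[data.needs_icc] *= (
            1.0 + (data.csize[data.needs_icc] - 1.0) * state.imputed_icc
        )
    var = s**2 * deff
    b = np.column_stack([state.study_intercepts, state.study_coefs])  # (S, m+1)
    mu = np.sum(data.D * b[data.study_index], axis=1)
    if state.gamma is not None or state.phi is not None:
        raise NotImplementedError(
            "log_joint covers the base model; extension fits evaluate their "
            "own likelihood internally"
        )
    total = float(np.sum(_normal_logpdf(data.y, mu, var)))
    mu_pop = np.concatenate([[state.beta0], np.asarray(state.beta, dtype=float)])
    with np.errstate(divide="ignore"):
        if np.any(taus == 0):
            return -np.inf
        total += float(np.sum(_normal_logpdf(b, mu_pop, taus**2)))
    total += float(_normal_logpdf(state.beta0, priors.beta0_mean, priors.beta0_var))
    total += float(np.sum(_normal_logpdf(state.beta, 0.0, priors.betak_var)))
    total += -(m + 1) * math.log(priors.tau_upper)  # uniform tau densities
    if data.needs_theta.size:
        total += float(
            np.sum(
                _normal_logpdf(
                    np.log(state.imputed_theta),
                    data.theta_logmean,
                    data.theta_logsd**2,
                )
            )
        )
    if data.needs_icc.size:
        total += -data.needs_icc.size * math.log(priors.icc_upper)
    return total


# ---------------------------------------------------------------------------
# sampler engine
# ---------------------------------------------------------------------------

def _sample_trunc_tau(rng, S_k: np.ndarray, n: int, upper: float) -> np.ndarray:
    """Draw between-study SDs from their exact conditional under a U(0, upper)
    prior on tau: tau^2 follows an inverse-gamma truncated to (0, upper^2).

    Sampled by CDF inversion on the precision scale: 1/tau^2 ~ Gamma((n-1)/2,
    rate S_k/2) truncated to (1/upper^2, inf).
    """
    a = (n - 1) / 2.0
    S_k = np.maximum(np.asarray(S_k, dtype=float), 1e-300)
    rate = S_k / 2.0
    x0 = 1.0 / upper**2
    # Draw unconditionally; a draw already in the truncation region follows
    # the truncated law, and violations are redrawn by CDF inversion within
    # the region — the mixture is exactly the truncated distribution.
    x = rng.gamma(a, size=S_k.shape) / rate
    bad = x < x0
    if np.any(bad):
        F0 = special.gammainc(a, x0 * rate[bad])
        u = rng.uniform(size=int(bad.sum()))
        w = np.clip(F0 + u * (1.0 - F0), None, 1.0 - 1e-16)
        x[bad] = np.maximum(special.gammaincinv(a, w) / rate[bad], x0)
    return 1.0 / np.sqrt(x)


def _chain_init(rng, data: _FitData, priors: PriorSpec, q: int):
    m1 = data.m + 1
    prior_mean = np.concatenate([[priors.beta0_mean], np.zeros(data.m)])
    prior_sd = np.sqrt(
        np.concatenate([[priors.beta0_var], np.full(data.m, priors.betak_var)])
    )
    mu_pop = prior_mean + 0.25 * prior_sd * rng.standard_normal(m1)
    hi = min(1.0, priors.tau_upper)
    tau = rng.uniform(0.05 * hi, hi, size=m1)
    b = mu_pop + tau * rng.standard_normal((data.n_studies, m1))
    c = np.zeros(q)
    log_s = data.theta_logmean + 0.2 * rng.standard_normal(data.needs_theta.size)
    icc = rng.uniform(0, priors.icc_upper, size=data.needs_icc.size)
    return mu_pop, tau, b, c, log_s, icc


def _run_chain(
    rng,
    data: _FitData,
    config: ModelConfig,
    priors: PriorSpec,
    F: np.ndarray | None,
    fixed_prior_var: np.ndarray | None,
    store_study: bool,
):
    """One MCMC chain for the arm-based model (base or fixed-effect-extended).

    Returns dict of draw arrays. ``F`` is an optional (n_arms, q) design of
    population-level fixed coefficients (product terms / modifier terms) with
    independent N(0, fixed_prior_var) priors.
    """
    n, m = data.n_arms, data.m
    m1 = m + 1
    S = data.n_studies
    q = 0 if F is None else F.shape[1]
    mu_pop, tau, b, c, log_s, icc = _chain_init(rng, data, priors, q)

    prior_mean_pop = np.concatenate([[priors.beta0_mean], np.zeros(m)])
    prior_var_pop = np.concatenate([[priors.beta0_var], np.full(m, priors.betak_var)])
    nt, ni = data.needs_theta, data.needs_icc
    has_theta, has_icc = nt.size > 0, ni.size > 0
    lm, ls = data.theta_logmean, data.theta_logsd
    mh_step = 0.4

    s_base = data.s_obs.copy()
    if has_theta:
        s_base[nt] = np.exp(log_s)

    def var_eff():
        v = s_base**2 * data.deff_base
        if has_icc:
            v[ni] *= 1.0 + (data.csize[ni] - 1.0) * icc
        return v

    Dpad = data.D[data.pad_arm] * data.pad_mask[:, :, None]  # (S, A, m+1)
    DpadT = np.ascontiguousarray(np.swapaxes(Dpad, 1, 2))
    eye = np.eye(m1)
    prior_prec_pop = 1.0 / prior_var_pop
    A_slots = Dpad.shape[1]
    diag_idx = np.arange(A_slots)
    maskb = data.pad_mask > 0
    # weights and the study-block Gram matrix are constant unless some
    # dispersion or ICC is being imputed
    static_w = not (has_theta or has_icc)
    static_y = F is None

    kept = config.n_kept
    out = {
        "beta0": np.empty(kept),
        "beta": np.empty((kept, m)),
        "tau0": np.empty(kept),
        "tau": np.empty((kept, m)),
    }
    if q:
        out["fixed"] = np.empty((kept, q))
    if store_study:
        out["b0"] = np.empty((kept, S))
        out["b"] = np.empty((kept, S, m))
    if has_theta:
        out["theta"] = np.empty((kept, nt.size))
    if has_icc:
        out["icc"] = np.empty((kept, ni.size))

    total = config.burnin + config.iterations
    v = var_eff()
    A_mat = None
    h_base = None
    for it in range(total):
        if A_mat is None or not static_w:
            w = 1.0 / v
            wpad = w[data.pad_arm] * data.pad_mask       # (S, A)
            vpad = v[data.pad_arm]
            vpad[~maskb] = 1.0
            Awt = Dpad * wpad[:, :, None]
            A_mat = np.einsum("sak,sal->skl", Awt, Dpad)
        if h_base is None or not (static_w and static_y):
            y_adj = data.y - (F @ c if q else 0.0)
            ypad = y_adj[data.pad_arm] * data.pad_mask
            h_base = np.einsum("sak,sa->sk", Awt, ypad)
        # joint (mu_pop, b) block: first mu_pop from its conditional with the
        # study effects integrated out (per-study marginal covariance
        # Theta_i + D_i diag(tau^2) D_i^T), then b | mu_pop — this mixes well
        # even as the between-study SDs approach zero
        V = (Dpad * tau[None, None, :] ** 2) @ DpadT
        V[:, diag_idx, diag_idx] += vpad
        rhs = np.concatenate([Dpad, ypad[:, :, None]], axis=2)
        sol = np.linalg.solve(V, rhs)                    # (S, A, m+2)
        G, Vy = sol[:, :, :m1], sol[:, :, m1]
        P_pop = np.einsum("sak,sal->kl", Dpad, G) + np.diag(prior_prec_pop)
        h_pop = np.einsum("sak,sa->k", Dpad, Vy) + prior_prec_pop * prior_mean_pop
        Lp = np.linalg.cholesky(P_pop)
        mu_pop = np.linalg.solve(P_pop, h_pop + Lp @ rng.standard_normal(m1))
        # study-level coefficient block: conditionally MVN per study
        prior_prec = 1.0 / tau**2
        P = A_mat + prior_prec * eye
        h = h_base + prior_prec * mu_pop
        # b = P^{-1}(h + L z) has mean P^{-1}h and covariance P^{-1}
        L = np.linalg.cholesky(P)
        z = rng.standard_normal((S, m1, 1))
        b = np.linalg.solve(P, h[:, :, None] + L @ z)[:, :, 0]
        # between-study SDs
        S_k = np.sum((b - mu_pop) ** 2, axis=0)
        tau = _sample_trunc_tau(rng, S_k, S, priors.tau_upper)
        # fixed-coefficient block
        study_part = np.sum(data.D * b[data.study_index], axis=1)
        if q:
            resid = data.y - study_part
            Fw = F * w[:, None]
            Q = F.T @ Fw + np.diag(1.0 / fixed_prior_var)
            hq = Fw.T @ resid
            Lq = np.linalg.cholesky(Q)
            c = np.linalg.solve(Q, hq + Lq @ rng.standard_normal(q))
        mu_arm = study_part + (F @ c if q else 0.0)
        # missing dispersions: log-scale random-walk Metropolis
        if has_theta:
            prop = log_s + mh_step * rng.standard_normal(nt.size)
            deff_t = v[nt] / np.exp(2 * log_s)  # current total design effect
            var_cur = v[nt]
            var_prop = np.exp(2 * prop) * deff_t
            r2 = (data.y[nt] - mu_arm[nt]) ** 2
            logacc = (
                -0.5 * np.log(var_prop) - r2 / (2 * var_prop)
                + 0.5 * np.log(var_cur) + r2 / (2 * var_cur)
                - 0.5 * ((prop - lm) / ls) ** 2
                + 0.5 * ((log_s - lm) / ls) ** 2
            )
            accept = np.log(rng.uniform(size=nt.size)) < logacc
            log_s = np.where(accept, prop, log_s)
            s_base[nt] = np.exp(log_s)
            v = var_eff()
        # missing ICCs: independence proposals from the uniform prior
        if has_icc:
            prop = rng.uniform(0, priors.icc_upper, size=ni.size)
            base = s_base[ni] ** 2 * data.deff_base[ni]
            var_cur = base * (1.0 + (data.csize[ni] - 1.0) * icc)
            var_prop = base * (1.0 + (data.csize[ni] - 1.0) * prop)
            r2 = (data.y[ni] - mu_arm[ni]) ** 2
            logacc = (
                -0.5 * np.log(var_prop) - r2 / (2 * var_prop)
                + 0.5 * np.log(var_cur) + r2 / (2 * var_cur)
            )
            accept = np.log(rng.uniform(size=ni.size)) < logacc
            icc = np.where(accept, prop, icc)
            v = var_eff()
        k = it - config.burnin
        if k >= 0 and k % config.thin == 0:
            k //= config.thin
            if k >= kept:
                continue
            out["beta0"][k] = mu_pop[0]
            out["beta"][k] = mu_pop[1:]
            out["tau0"][k] = tau[0]
            out["tau"][k] = tau[1:]
            if q:
                out["fixed"][k] = c
            if store_study:
                out["b0"][k] = b[:, 0]
                out["b"][k] = b[:, 1:]
            if has_theta:
                out["theta"][k] = np.exp(log_s)
            if has_icc:
                out["icc"][k] = icc
    return out


def _fit_arm_model(
    ds: StudyDataset,
    config: ModelConfig,
    priors: PriorSpec,
    *,
    F: np.ndarray | None = None,
    fixed_prior_var: np.ndarray | None = None,
    fixed_split: list | None = None,
    variant: str = "base",
    meta_extra: dict | None = None,
    store_study: bool = True,
) -> PosteriorDraws:
    data = _prepare(ds, priors)
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chains = [
        _run_chain(
            np.random.default_rng(s), data, config, priors, F, fixed_prior_var,
            store_study,
        )
        for s in seeds
    ]

    def stack(key):
        return np.stack([ch[key] for ch in chains])

    population = {
        "beta0": stack("beta0"),
        "beta": stack("beta"),
        "tau0": stack("tau0"),
        "tau": stack("tau"),
    }
    if F is not None and fixed_split:
        fixed = stack("fixed")
        pos = 0
        for name, ncols in fixed_split:
            block = fixed[:, :, pos:pos + ncols]
            population[name] = block[:, :, 0] if ncols == 1 and name == "phi" else block
            pos += ncols
    study = {}
    if store_study:
        study = {"b0": stack("b0"), "b": stack("b")}
    imputed = {}
    if data.needs_theta.size:
        imputed["theta"] = stack("theta")
    if data.needs_icc.size:
        imputed["icc"] = stack("icc")
    meta = {
        "variant": variant,
        "component_names": data.component_names,
        "study_ids": data.study_ids,
        "study_index": data.study_index.tolist(),
        "imputed_theta_arms": data.needs_theta.tolist(),
        "imputed_icc_arms": data.needs_icc.tolist(),
        "s_obs": np.where(np.isnan(data.s_obs), -1.0, data.s_obs).tolist(),
        "deff_base": data.deff_base.tolist(),
        "csize": data.csize.tolist(),
        "theta_logmean": data.theta_logmean,
        "theta_logsd": data.theta_logsd,
    }
    if F is not None:
        meta["fixed_design"] = F.tolist()
    if meta_extra:
        meta.update(meta_extra)
    return PosteriorDraws(population, study, imputed, meta, config, priors)


def fit_base_model(
    ds: StudyDataset,
    config: ModelConfig,
    priors: PriorSpec | None = None,
    store_study: bool = True,
) -> PosteriorDraws:
    """Fit the additive arm-based response-surface model by MCMC.

    Every arm must have a resolvable dispersion: an observed standard error,
    a participant SD (converted to ``sd/sqrt(n)``), or a missing value to be
    imputed under the log-normal dispersion prior. Unadjusted cluster arms
    are design-effect corrected, using their observed ICC where present and
    an imputed ICC otherwise. Reproducible given ``config.seed``.
    """
    priors = priors or PriorSpec()
    return _fit_arm_model(ds, config, priors, store_study=store_study)


# ---------------------------------------------------------------------------
# posterior summaries and convergence diagnostics
# ---------------------------------------------------------------------------

def summarize_posterior(
    draws: PosteriorDraws, include_study: bool = False
) -> pd.DataFrame:
    """Posterior median and central 95% credible interval per parameter."""
    rows = []
    for name, arr in draws.by_name(include_study=include_study).items():
        flat = arr.reshape(-1)
        lo, med, hi = np.quantile(flat, [0.025, 0.5, 0.975])
        rows.append({"parameter": name, "median": med, "lo2.5": lo, "hi97.5": hi})
    return pd.DataFrame(rows).set_index("parameter")


@dataclass(frozen=True)
class GelmanRubinResult:
    """Brooks–Gelman corrected potential scale reduction factors."""

    table: pd.DataFrame           # per-parameter psrf and upper 97.5% bound
    frac_below_1_1: float         # fraction of parameters with upper < 1.1
    frac_below_1_2: float

    def summary(self) -> str:
        return (
            f"upper PSRF bound < 1.1 for {100 * self.frac_below_1_1:.0f}% and "
            f"< 1.2 for {100 * self.frac_below_1_2:.0f}% of parameters monitored"
        )


def _bgr(x: np.ndarray) -> tuple[float, float]:
    """Corrected PSRF point estimate and upper 97.5% bound for one parameter.

    ``x`` has shape (chains, iterations). Follows Brooks & Gelman (1998):
    the corrected statistic carries a (d+3)/(d+1) degrees-of-freedom factor,
    and the upper bound replaces the between-chain variance ratio with its
    97.5% F-quantile.
    """
    mchain, niter = x.shape
    means = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    W = s2.mean()
    B = niter * means.var(ddof=1)
    muhat = x.mean()
    if W <= 0:
        return (1.0, 1.0) if B <= 0 else (np.inf, np.inf)
    var_w = s2.var(ddof=1) / mchain
    var_b = 2.0 * B**2 / (mchain - 1)
    cov_wb = (niter / mchain) * (
        np.cov(s2, means**2, ddof=1)[0, 1]
        - 2.0 * muhat * np.cov(s2, means, ddof=1)[0, 1]
    )
    V = (niter - 1) / niter * W + (1.0 + 1.0 / mchain) * B / niter
    var_V = (
        ((niter - 1) ** 2) * var_w
        + ((1.0 + 1.0 / mchain) ** 2) * var_b
        + 2.0 * (niter - 1) * (1.0 + 1.0 / mchain) * cov_wb
    ) / niter**2
    df_V = 2.0 * V**2 / var_V if var_V > 0 else np.inf
    df_factor = (df_V + 3.0) / (df_V + 1.0) if np.isfinite(df_V) else 1.0
    psrf = math.sqrt(df_factor * V / W)
    r2_fixed = (niter - 1) / niter
    r2_random = (1.0 + 1.0 / mchain) / niter * B / W
    dfw = 2.0 * W**2 / var_w if var_w > 0 else np.inf
    fq = stats.f.ppf(0.975, mchain - 1, dfw) if np.isfinite(dfw) else 1.0
    upper = math.sqrt(df_factor * (r2_fixed + fq * r2_random))
    return psrf, upper


def gelman_rubin(
    draws: PosteriorDraws, include_study: bool = False
) -> GelmanRubinResult:
    """Brooks–Gelman–Rubin convergence diagnostic across chains.

    Reports, per monitored parameter, the corrected PSRF point estimate with
    its upper 97.5% bound, plus the fraction of parameters whose upper bound
    falls below 1.1 and 1.2.
    """
    if draws.n_chains < 2:
        raise ValidationError("gelman_rubin requires at least 2 chains")
    rows = []
    for name, arr in draws.by_name(include_study=include_study).items():
        psrf, upper = _bgr(arr)
        rows.append({"parameter": name, "psrf": psrf, "upper": upper})
    table = pd.DataFrame(rows).set_index("parameter")
    finite = table["upper"].to_numpy()
    return GelmanRubinResult(
        table,
        float(np.mean(finite < 1.1)),
        float(np.mean(finite < 1.2)),
    )


# ---------------------------------------------------------------------------
# conventional pairwise comparator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseResult:
    """DerSimonian–Laird random-effects pooled mean difference for one
    component (conventional comparator; unadjusted for co-occurring
    components by design)."""

    component: str
    estimate: float
    ci_low: float
    ci_high: float
    tau2: float
    i2: float
    q: float
    n_studies: int


def dersimonian_laird(md: np.ndarray, var: np.ndarray):
    """Random-effects pooling via the DerSimonian–Laird moment estimator.

    Returns (pooled estimate, pooled SE, tau2, I2 in percent, Q).
    """
    md = np.asarray(md, dtype=float)
    var = np.asarray(var, dtype=float)
    w = 1.0 / var
    fixed = np.sum(w * md) / np.sum(w)
    qstat = float(np.sum(w * (md - fixed) ** 2))
    df = md.size - 1
    cval = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (qstat - df) / cval) if cval > 0 else 0.0
    wstar = 1.0 / (var + tau2)
    est = float(np.sum(wstar * md) / np.sum(wstar))
    se = float(math.sqrt(1.0 / np.sum(wstar)))
    i2 = max(0.0, (qstat - df) / qstat) * 100.0 if qstat > 0 else 0.0
    return est, se, tau2, i2, qstat


def _resolve_se_fixed(
    arm: ArmRecord, sd_impute: float, icc_impute: float
) -> float:
    """Analysis-I dispersion resolution with fixed imputations."""
    se = arm.resolved_se
    if se is None:
        se = sd_impute / math.sqrt(arm.n_participants)
    if arm.needs_cluster_adjustment:
        icc = arm.icc if not arm.icc_missing else icc_impute
        csize = arm.avg_cluster_size if arm.avg_cluster_size else 1.0
        se *= math.sqrt(1.0 + (csize - 1.0) * icc)
    return se


def fit_conventional_pairwise(
    ds: StudyDataset,
    component: str,
    sd_impute: float = 2.22,
    icc_impute: float = 0.027,
) -> PairwiseResult:
    """Conventional per-component random-effects meta-analysis.

    Expects a dataset already reduced to two arms per study (see
    :func:`rsmeta.dataio.select_extreme_arms`). For each study the mean
    difference between the experimental arm (more components; ties broken by
    higher arm label) and its comparator is computed with variance
    ``se_e^2 + se_c^2``; missing dispersions and ICCs are filled with the
    fixed values ``sd_impute`` and ``icc_impute``. Studies whose experimental
    arm contains ``component`` are pooled by DerSimonian–Laird — the sole
    predictor is the component's presence in the experimental arm, with no
    adjustment for co-occurring components (by design, to mirror the
    conventional approach and its bias).
    """
    if component not in ds.component_names:
        raise ValidationError(f"unknown component {component!r}")
    kidx = ds.component_names.index(component)
    mds, vars_ = [], []
    for sid in ds.study_ids:
        arms = ds.arms_of(sid)
        if len(arms) != 2:
            raise ValidationError(
                f"study {sid!r} has {len(arms)} arms; reduce to 2 with "
                "select_extreme_arms first"
            )
        a, barm = sorted(
            arms, key=lambda r: (r.n_components_active, r.arm_id)
        )  # control first
        exp_arm, ctl_arm = barm, a
        if not exp_arm.components[kidx]:
            continue
        se_e = _resolve_se_fixed(exp_arm, sd_impute, icc_impute)
        se_c = _resolve_se_fixed(ctl_arm, sd_impute, icc_impute)
        mds.append(exp_arm.y - ctl_arm.y)
        vars_.append(se_e**2 + se_c**2)
    if len(mds) < 2:
        raise ValidationError(
            f"component {component!r}: fewer than 2 studies with the component "
            "in the experimental arm"
        )
    est, se, tau2, i2, qstat = dersimonian_laird(np.array(mds), np.array(vars_))
    return PairwiseResult(
        component=component,
        estimate=est,
        ci_low=est - _Z975 * se,
        ci_high=est + _Z975 * se,
        tau2=tau2,
        i2=i2,
        q=qstat,
        n_studies=len(mds),
    )
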