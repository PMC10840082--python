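"""Model evaluation: mixed posterior predictive checks, DIC, and a
prior-sensitivity harness.

The *mixed* posterior predictive check replicates each arm as if it came
from a new study: fresh study-level intercept and component coefficients are
drawn from their population distributions per posterior draw (rather than
conditioning on the fitted study effects), then arm sampling noise is added.
The one-sided probability P(Y_rep <= y_obs) is computed per arm; for a
well-specified model these probabilities concentrate around 0.5, while
misspecification pushes mass towards 0 and 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import fit_base_model, summarize_posterior
from .types import (
    ModelConfig,
    PosteriorDraws,
    PriorSpec,
    StudyDataset,
    ValidationError,
)

__all__ = [
    "PpcResult",
    "mixed_ppc",
    "DicResult",
    "dic",
    "SensitivityResult",
    "prior_sensitivity",
]


def _subsample(n_total: int, max_draws: int) -> np.ndarray:
    if n_total <= max_draws:
        return np.arange(n_total)
    return np.linspace(0, n_total - 1, max_draws).astype(int)


def _fixed_part(draws: PosteriorDraws, idx: np.ndarray) -> np.ndarray | float:
    """Per-draw fixed-coefficient contribution to each arm mean, (N, n_arms)."""
    if "fixed_design" not in draws.meta:
        return 0.0
    F = np.asarray(draws.meta["fixed_design"], dtype=float)
    if "gamma" in draws:
        coef = draws.stacked("gamma")[idx]
    elif "phi" in draws:
        coef = np.column_stack(
            [draws.stacked("phi")[idx, None], draws.stacked("psi")[idx]]
        )
    else:  # pragma: no cover - defensive
        raise ValidationError("fixed design present but no fixed coefficients")
    return coef @ F.T


def _arm_variance(
    draws: PosteriorDraws, idx: np.ndarray, n_arms: int
) -> np.ndarray:
    """Effective sampling variance per draw and arm, (N, n_arms)."""
    meta = draws.meta
    s_obs = np.asarray(meta["s_obs"], dtype=float)
    if s_obs.size != n_arms:
        raise ValidationError("draws and dataset arm counts do not match")
    s = np.broadcast_to(s_obs, (idx.size, n_arms)).copy()
    t_arms = list(meta.get("imputed_theta_arms", []))
    if t_arms:
        s[:, t_arms] = draws.stacked("theta")[idx]
    if np.any(s <= 0):
        raise ValidationError("unresolved (missing) dispersion in draws metadata")
    var = s**2 * np.asarray(meta["deff_base"], dtype=float)
    i_arms = list(meta.get("imputed_icc_arms", []))
    if i_arms:
        csize = np.asarray(meta["csize"], dtype=float)[i_arms]
        icc = draws.stacked("icc")[idx]
        var[:, i_arms] *= 1.0 + (csize - 1.0) * icc
    return var


@dataclass
class PpcResult:
    """Per-arm one-sided posterior predictive probabilities."""

    probabilities: np.ndarray            # (n_arms,)
    table: pd.DataFrame                  # study, arm, probability
    by_component: dict                   # component -> probs of arms containing it
    frac_extreme: float                  # mass below 0.05 or above 0.95

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# mixed posterior predictive check, P(Y_rep <= y_obs)\n")
            self.table.to_csv(fh, index=False)


def mixed_ppc(
    draws: PosteriorDraws,
    ds: StudyDataset,
    seed: int = 0,
    max_draws: int = 2000,
) -> PpcResult:
    """Mixed posterior predictive check of a fitted arm-based model.

    For every arm, replicate outcomes are generated as from a *new* study
    with the same component vector: per posterior draw,
    ``b_0,new ~ N(beta_0, tau_0^2)``, ``b_k,new ~ N(beta_k, tau_k^2)``, then
    ``y_rep ~ N(b_0,new + sum_k b_k,new x_k + [fixed terms], theta^2)`` with
    the arm's (possibly imputed) sampling variance. Reports the one-sided
    probability P(Y_rep <= y_obs) per arm, with ties counted as half.
    """
    if draws.variant == "difference":
        raise ValidationError("mixed_ppc requires an arm-based model fit")
    if list(draws.meta["study_ids"]) != list(ds.study_ids) or ds.n_arms != len(
        draws.meta["s_obs"]
    ):
        raise ValidationError("draws and dataset do not describe the same arms")
    idx = _subsample(draws.n_chains * draws.n_draws, max_draws)
    N = idx.size
    rng = np.random.default_rng(seed)
    beta0 = draws.stacked("beta0")[idx]
    beta = draws.stacked("beta")[idx]
    tau0 = draws.stacked("tau0")[idx]
    tau = draws.stacked("tau")[idx]
    X = ds.X
    n_arms = ds.n_arms
    b0_new = beta0[:, None] + tau0[:, None] * rng.standard_normal((N, n_arms))
    b_new = (
        beta[:, None, :]
        + tau[:, None, :] * rng.standard_normal((N, n_arms, ds.m))
    )
    mu_rep = b0_new + np.einsum("nak,ak->na", b_new, X) + _fixed_part(draws, idx)
    var = _arm_variance(draws, idx, n_arms)
    y_rep = mu_rep + np.sqrt(var) * rng.standard_normal((N, n_arms))
    y_obs = ds.y
    probs = (
        np.mean(y_rep < y_obs, axis=0) + 0.5 * np.mean(y_rep == y_obs, axis=0)
    )
    table = pd.DataFrame(
        {
            "study": [a.study_id for a in ds.arms],
            "arm": [a.arm_id for a in ds.arms],
            "probability": probs,
        }
    )
    by_comp = {
        name: probs[X[:, k] == 1]
        for k, name in enumerate(ds.component_names)
    }
    frac_extreme = float(np.mean((probs < 0.05) | (probs > 0.95)))
    return PpcResult(probs, table, by_comp, frac_extreme)


@dataclass(frozen=True)
class DicResult:
    """Deviance information criterion, DIC = D̄ + pD.

    The deviance is -2 x the arm-level log-likelihood; the plug-in point is
    the posterior mean of the arm means mu_ij (and of the effective sampling
    variances), i.e. the focused, prediction-oriented parameterisation.
    """

    dic: float
    p_d: float
    mean_deviance: float
    plugin_deviance: float

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {
                "dic": self.dic,
                "pD": self.p_d,
                "mean_deviance": self.mean_deviance,
                "plugin_deviance": self.plugin_deviance,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _deviance(y: np.ndarray, mu: np.ndarray, var: np.ndarray) -> np.ndarray:
    ll = -0.5 * (np.log(2 * np.pi * var) + (y - mu) ** 2 / var)
    return -2.0 * ll.sum(axis=-1)


def dic(
    draws: PosteriorDraws, ds: StudyDataset, max_draws: int = 4000
) -> DicResult:
    """DIC of a fitted arm-based model on its dataset."""
    if "b0" not in draws.study:
        raise ValidationError("dic requires stored study-level draws")
    idx = _subsample(draws.n_chains * draws.n_draws, max_draws)
    si = np.asarray(draws.meta["study_index"], dtype=int)
    if si.size != ds.n_arms:
        raise ValidationError("draws and dataset arm counts do not match")
    b0 = draws.stacked("b0")[idx]                      # (N, S)
    b = draws.stacked("b")[idx]                        # (N, S, m)
    X = ds.X
    mu = b0[:, si] + np.einsum("nak,ak->na", b[:, si, :], X)
    mu = mu + _fixed_part(draws, idx)
    var = _arm_variance(draws, idx, ds.n_arms)
    y = ds.y
    dev = _deviance(y, mu, var)
    mean_dev = float(dev.mean())
    plugin = float(_deviance(y, mu.mean(axis=0), var.mean(axis=0)))
    p_d = mean_dev - plugin
    return DicResult(mean_dev + p_d, p_d, mean_dev, plugin)


@dataclass
class SensitivityResult:
    """Side-by-side posterior summaries under alternative priors."""

    table: pd.DataFrame          # parameter x (spec, statistic)
    max_median_shift: float
    flagged: list                # params whose CrI excludes 0 under some
                                 # specs but not others

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# prior sensitivity comparison\n")
            self.table.to_csv(fh)


def prior_sensitivity(
    ds: StudyDataset,
    specs: list[PriorSpec],
    config: ModelConfig,
    fitter=fit_base_model,
) -> SensitivityResult:
    """Refit the model under each prior specification (shared seed) and
    compare population-level posterior medians and CrIs.

    Reports the maximum absolute median shift across specs per parameter and
    flags parameters whose 95% CrI excludes zero under some specs but not
    others."""
    if len(specs) < 2:
        raise ValidationError("prior_sensitivity requires at least 2 specs")
    frames = []
    for i, spec in enumerate(specs):
        draws = fitter(ds, config, spec, store_study=False)
        summ = summarize_posterior(draws)
        summ.columns = pd.MultiIndex.from_product([[f"spec{i}"], summ.columns])
        frames.append(summ)
    table = pd.concat(frames, axis=1)
    medians = table.loc[:, pd.IndexSlice[:, "median"]].to_numpy()
    max_shift = float(np.max(medians.max(axis=1) - medians.min(axis=1)))
    flagged = []
    for param in table.index:
        excludes = []
        for i in range(len(specs)):
            lo = table.loc[param, (f"spec{i}", "lo2.5")]
            hi = table.loc[param, (f"spec{i}", "hi97.5")]
            excludes.append(lo > 0 or hi < 0)
        if len(set(excludes)) > 1:
            flagged.append(param)
    return SensitivityResult(table, max_shift, flagged)
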