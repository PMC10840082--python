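"""Posterior and posterior-predictive inference for component combinations,
and probabilistic ranking of components.

Prediction distinguishes two scales. The *posterior* scale summarises the
population-mean response surface, ``beta_0 + sum_k beta_k X_k``. The
*predictive* scale describes a future study: fresh study-level coefficients
are drawn per posterior draw, ``b_k,new ~ N(beta_k, tau_k^2)`` for
``k = 0..m``, so predictive intervals are wider whenever between-study
heterogeneity is non-zero. Supplying a planned sampling SD ``theta_new``
additionally yields the predictive distribution of the observed mean
``Y_new ~ N(mu_new, theta_new^2)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import PosteriorDraws, ValidationError

__all__ = [
    "NewIntervention",
    "PredictionResult",
    "predict_combination",
    "predictive_new_study",
    "RankMatrix",
    "rankogram",
]


@dataclass(frozen=True)
class NewIntervention:
    """A (possibly untested) component combination for a new study.

    ``components`` lists the active component labels; ``theta_new`` is the
    planned sampling SD of the new study (optional, needed only for the
    observed-mean predictive distribution)."""

    components: tuple
    theta_new: float | None = None

    def __post_init__(self):
        if self.theta_new is not None and self.theta_new <= 0:
            raise ValidationError("theta_new must be positive when supplied")

    def indicator(self, component_names: list[str]) -> np.ndarray:
        x = np.zeros(len(component_names))
        for c in self.components:
            if c not in component_names:
                raise ValidationError(f"unknown component {c!r}")
            x[component_names.index(c)] = 1.0
        return x


def _ci(v: np.ndarray) -> tuple[float, float, float]:
    lo, med, hi = np.quantile(v, [0.025, 0.5, 0.975])
    return float(med), float(lo), float(hi)


@dataclass
class PredictionResult:
    """Draws and summaries for one component combination.

    ``posterior_mu``: population-mean scale. ``predictive_mu``: new-study
    mean scale (fresh study-level coefficients). ``predictive_y``: observed
    mean of a new study with sampling SD ``theta_new`` (``None`` when no
    ``theta_new`` was supplied). The ``contrast_*`` draws compare against the
    all-zero (no intervention) combination per draw, sharing the new-study
    intercept draw so that the null combination's contrast is exactly zero.
    """

    combination: tuple
    posterior_mu: np.ndarray
    predictive_mu: np.ndarray
    contrast_posterior: np.ndarray
    contrast_predictive: np.ndarray
    predictive_y: np.ndarray | None = None
    contrast_y: np.ndarray | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        pairs = [
            ("posterior_mu", self.posterior_mu),
            ("predictive_mu", self.predictive_mu),
            ("contrast_posterior", self.contrast_posterior),
            ("contrast_predictive", self.contrast_predictive),
        ]
        if self.predictive_y is not None:
            pairs += [("predictive_y", self.predictive_y)]
        if self.contrast_y is not None:
            pairs += [("contrast_y", self.contrast_y)]
        for name, v in pairs:
            med, lo, hi = _ci(v)
            rows.append({"quantity": name, "median": med, "lo2.5": lo, "hi97.5": hi})
        return pd.DataFrame(rows).set_index("quantity")

    def to_json(self, path=None) -> str:
        payload = {"combination": list(self.combination)}
        for name, row in self.summary().iterrows():
            payload[name] = {
                "median": row["median"],
                "ci": [row["lo2.5"], row["hi97.5"]],
            }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def predict_combination(
    draws: PosteriorDraws,
    combo: NewIntervention,
    seed: int = 0,
) -> PredictionResult:
    """Posterior and posterior-predictive distributions of the posttreatment
    mean for an arbitrary component combination.

    Per posterior draw the posterior-scale value is
    ``beta_0 + sum_k beta_k x_k``; the predictive-scale value draws fresh
    study-level coefficients ``b_k,new ~ N(beta_k, tau_k^2)`` (k = 0..m,
    seeded). Contrasts against the all-zero combination share the intercept
    draw, so they reduce to ``sum_k beta_k x_k`` (posterior) and
    ``sum_k b_k,new x_k`` (predictive) and vanish identically for the null
    combination.
    """
    if draws.variant == "difference":
        raise ValidationError(
            "difference-model draws carry no intercept; absolute posttreatment "
            "means are not predictable from them"
        )
    x = combo.indicator(draws.component_names)
    beta0 = draws.stacked("beta0")
    beta = draws.stacked("beta")
    tau0 = draws.stacked("tau0")
    tau = draws.stacked("tau")
    rng = np.random.default_rng(seed)
    n = beta0.size
    post_mu = beta0 + beta @ x
    b0_new = beta0 + tau0 * rng.standard_normal(n)
    b_new = beta + tau * rng.standard_normal(beta.shape)
    if draws.variant == "interaction":
        # product terms contribute when the combination includes the focal
        # component together with a partner
        names = draws.component_names
        focal = draws.meta["focal"]
        partners = draws.meta["gamma_partners"]
        gamma = draws.stacked("gamma")
        xg = np.array(
            [x[names.index(focal)] * x[names.index(l)] for l in partners]
        )
        post_mu = post_mu + gamma @ xg
        gterm = gamma @ xg
    else:
        gterm = 0.0
    pred_mu = b0_new + b_new @ x + gterm
    contrast_post = post_mu - beta0
    contrast_pred = pred_mu - b0_new
    result = PredictionResult(
        combination=tuple(combo.components),
        posterior_mu=post_mu,
        predictive_mu=pred_mu,
        contrast_posterior=contrast_post,
        contrast_predictive=contrast_pred,
    )
    if combo.theta_new is not None:
        noise = combo.theta_new * rng.standard_normal(n)
        result.predictive_y = pred_mu + noise
        result.contrast_y = contrast_pred + noise
    return result


def predictive_new_study(
    draws: PosteriorDraws, combo: NewIntervention, seed: int = 0
) -> np.ndarray:
    """Draws of the observed posttreatment mean ``Y_new`` of a planned study:
    predictive-mean draws plus ``N(0, theta_new^2)`` sampling noise."""
    if combo.theta_new is None:
        raise ValidationError(
            "theta_new is required; for the mean-only predictive distribution "
            "use predict_combination"
        )
    res = predict_combination(draws, combo, seed=seed)
    return res.predictive_y


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankMatrix:
    """Probabilities P(component k has rank r); rank 1 is "best".

    Rows (components) and columns (ranks) each sum to one: every posterior
    draw assigns a full permutation. ``direction`` records whether lower
    coefficients rank first (the default, appropriate for outcomes where a
    reduction is beneficial)."""

    probabilities: pd.DataFrame     # index: component, columns: rank 1..m
    cumulative: pd.DataFrame        # P(rank <= j)
    direction: str

    def p_best(self) -> pd.Series:
        return self.probabilities.iloc[:, 0]

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# rankogram (direction={self.direction})\n")
            self.probabilities.to_csv(fh)


def rankogram(
    draws: PosteriorDraws, direction: str = "lower", seed: int = 0
) -> RankMatrix:
    """Rank components by their population mean differences, per draw.

    For each posterior draw the components are ordered by ``beta_k``
    (ascending when ``direction="lower"``, i.e. a larger reduction ranks
    first); ties are broken by a seeded random permutation, which keeps the
    rank matrix exactly doubly stochastic. Frequencies across draws give
    P(component k has rank r) and the cumulative curves P(rank <= j).
    """
    if direction not in ("lower", "higher"):
        raise ValidationError("direction must be 'lower' or 'higher'")
    beta = draws.stacked("beta")
    n, m = beta.shape
    if m < 2:
        raise ValidationError("ranking requires at least 2 components")
    keys = beta if direction == "lower" else -beta
    rng = np.random.default_rng(seed)
    tie = rng.uniform(size=keys.shape)
    order = np.lexsort((tie, keys), axis=1)        # component index per rank slot
    counts = np.zeros((m, m))
    for r in range(m):
        counts[:, r] = np.bincount(order[:, r], minlength=m)
    probs = counts / n
    comp = draws.component_names
    ranks = [f"rank{r + 1}" for r in range(m)]
    prob_df = pd.DataFrame(probs, index=comp, columns=ranks)
    cum_df = pd.DataFrame(np.cumsum(probs, axis=1), index=comp, columns=ranks)
    return RankMatrix(prob_df, cum_df, direction)
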