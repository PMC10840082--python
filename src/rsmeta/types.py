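"""Core data containers for arm-level meta-regression datasets and model runs.

The central objects are :class:`ArmRecord` (one trial arm: posttreatment mean,
its sampling dispersion, binary component indicators, cluster-design metadata)
and :class:`StudyDataset` (a validated collection of arms grouped by study).
Model configuration lives in :class:`PriorSpec` and :class:`ModelConfig`;
posterior output in :class:`PosteriorDraws`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArmRecord",
    "StudyDataset",
    "ComponentCodebook",
    "PriorSpec",
    "ModelConfig",
    "PosteriorDraws",
    "ValidationError",
    "SchemaError",
]


class ValidationError(ValueError):
    """Raised when an arm table or dataset violates a structural invariant."""


class SchemaError(ValidationError):
    """Raised when an input table is missing required columns."""


def _is_missing(x) -> bool:
    if x is None:
        return True
    try:
        return bool(np.isnan(x))
    except TypeError:
        return False


@dataclass(frozen=True)
class ArmRecord:
    """One trial arm.

    Parameters
    ----------
    study_id, arm_id
        Opaque labels; the pair must be unique within a dataset.
    n_participants
        Number of participants analysed in the arm.
    y
        Posttreatment outcome mean (outcome units, e.g. %HbA1c).
    components
        Length-``m`` vector of 0/1 indicators, one per intervention component.
        An all-zero row is a legal control ("no intervention") arm.
    se, sd
        Standard error of ``y`` and participant-level SD. Either may be
        missing (``None``); when only ``sd`` is available the standard error
        is derived as ``sd / sqrt(n)``.
    baseline_cov
        Optional arm/study-level baseline covariate (e.g. baseline mean HbA1c).
    is_cluster, avg_cluster_size, icc, variance_adjusted
        Cluster-randomisation metadata. When ``is_cluster`` is true and the
        reported variance is not already cluster-adjusted, the standard error
        must be inflated by the design effect ``1 + (m̄ - 1)·ICC``; a missing
        ICC is represented explicitly and resolved by imputation at fit time.
    """

    study_id: str
    arm_id: str
    n_participants: int
    y: float
    components: tuple
    se: float | None = None
    sd: float | None = None
    baseline_cov: float | None = None
    is_cluster: bool = False
    avg_cluster_size: float | None = None
    icc: float | None = None
    variance_adjusted: bool = False

    def __post_init__(self):
        comps = tuple(int(c) for c in self.components)
        if any(c not in (0, 1) for c in comps):
            raise ValidationError(
                f"arm ({self.study_id}, {self.arm_id}): component indicators "
                f"must be 0/1, got {self.components}"
            )
        object.__setattr__(self, "components", comps)
        if self.n_participants <= 0:
            raise ValidationError(
                f"arm ({self.study_id}, {self.arm_id}): n_participants must be positive"
            )
        if not _is_missing(self.icc) and not (0.0 <= self.icc < 1.0):
            raise ValidationError(
                f"arm ({self.study_id}, {self.arm_id}): icc must lie in [0, 1)"
            )
        if self.is_cluster and not _is_missing(self.avg_cluster_size):
            if self.avg_cluster_size < 1.0:
                raise ValidationError(
                    f"arm ({self.study_id}, {self.arm_id}): avg_cluster_size must be >= 1"
                )

    @property
    def resolved_se(self) -> float | None:
        """Standard error of ``y``: reported, or derived as sd/sqrt(n)."""
        if not _is_missing(self.se):
            return float(self.se)
        if not _is_missing(self.sd):
            return float(self.sd) / math.sqrt(self.n_participants)
        return None

    @property
    def se_missing(self) -> bool:
        return self.resolved_se is None

    @property
    def icc_missing(self) -> bool:
        return _is_missing(self.icc)

    @property
    def needs_cluster_adjustment(self) -> bool:
        return self.is_cluster and not self.variance_adjusted

    @property
    def n_components_active(self) -> int:
        return int(sum(self.components))


class StudyDataset:
    """A validated collection of :class:`ArmRecord` grouped by study.

    Studies are ordered by first appearance; arms keep input order. All arms
    must share the same number of components ``m`` and component names must
    be unique.
    """

    def __init__(self, arms: Sequence[ArmRecord], component_names: Sequence[str]):
        arms = list(arms)
        component_names = list(component_names)
        if not arms:
            raise ValidationError("dataset must contain at least one arm")
        if len(set(component_names)) != len(component_names):
            raise ValidationError("component_names must be unique")
        m = len(component_names)
        seen = set()
        for a in arms:
            if len(a.components) != m:
                raise ValidationError(
                    f"arm ({a.study_id}, {a.arm_id}) has {len(a.components)} "
                    f"component indicators, expected {m}"
                )
            key = (a.study_id, a.arm_id)
            if key in seen:
                raise ValidationError(f"duplicate (study_id, arm_id): {key}")
            seen.add(key)
        self.arms: list[ArmRecord] = arms
        self.component_names: list[str] = component_names
        self.study_ids: list[str] = list(dict.fromkeys(a.study_id for a in arms))

    # -- basic shape ------------------------------------------------------
    @property
    def n_arms(self) -> int:
        return len(self.arms)

    @property
    def n_studies(self) -> int:
        return len(self.study_ids)

    @property
    def m(self) -> int:
        return len(self.component_names)

    def arms_of(self, study_id: str) -> list[ArmRecord]:
        return [a for a in self.arms if a.study_id == study_id]

    # -- array views ------------------------------------------------------
    @property
    def y(self) -> np.ndarray:
        return np.array([a.y for a in self.arms], dtype=float)

    @property
    def X(self) -> np.ndarray:
        """Arm-by-component indicator matrix (n_arms, m)."""
        return np.array([a.components for a in self.arms], dtype=float)

    @property
    def study_index(self) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.study_ids)}
        return np.array([lookup[a.study_id] for a in self.arms], dtype=int)

    def component_prevalence(self) -> np.ndarray:
        """Fraction of arms in which each component is present."""
        return self.X.mean(axis=0)

    def replace_arms(self, arms: Sequence[ArmRecord]) -> "StudyDataset":
        return StudyDataset(arms, self.component_names)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.arms:
            row = {
                "study": a.study_id,
                "arm": a.arm_id,
                "n": a.n_participants,
                "y": a.y,
                "se": np.nan if _is_missing(a.se) else a.se,
                "sd": np.nan if _is_missing(a.sd) else a.sd,
                "baseline": np.nan if _is_missing(a.baseline_cov) else a.baseline_cov,
                "cluster": int(a.is_cluster),
                "cluster_size": (
                    np.nan if _is_missing(a.avg_cluster_size) else a.avg_cluster_size
                ),
                "icc": np.nan if _is_missing(a.icc) else a.icc,
                "var_adjusted": int(a.variance_adjusted),
            }
            for name, val in zip(self.component_names, a.components):
                row[f"c_{name}"] = val
            rows.append(row)
        return pd.DataFrame(rows)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"StudyDataset(n_studies={self.n_studies}, n_arms={self.n_arms}, "
            f"m={self.m})"
        )


@dataclass(frozen=True)
class ComponentCodebook:
    """Record of component pooling: original label -> retained label.

    Components whose arm-prevalence fell below ``pooling_threshold`` map to
    the pooled label (default ``"other"``); all others map to themselves.
    """

    mapping: Mapping[str, str]
    pooling_threshold: float
    pooled_label: str = "other"

    @property
    def pooled(self) -> list[str]:
        return [k for k, v in self.mapping.items() if v == self.pooled_label and k != v]

    def to_dict(self) -> dict:
        return {
            "mapping": dict(self.mapping),
            "pooling_threshold": self.pooling_threshold,
            "pooled_label": self.pooled_label,
        }


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters for the hierarchical meta-regression.

    All normal priors are parameterised by mean and VARIANCE. Defaults match
    a minimally informative specification for a percent-scale outcome such as
    HbA1c: ``beta_0 ~ N(8, 100)``, component coefficients ``beta_k ~ N(0, 4)``,
    all between-study SDs ``tau ~ U(0, 2)``, interaction (product-term)
    coefficients ``gamma_l ~ N(0, 2)`` and modifier coefficients
    ``phi, psi_k ~ N(0, 4)``.

    ``icc_upper`` bounds the uniform prior used to impute missing ICCs in
    unadjusted cluster-randomised arms. ``dispersion_logmean``/``_logsd``
    optionally fix the log-normal prior for missing sampling SDs; when left
    ``None`` they are estimated empirically from the arms with observed
    dispersion at fit time.
    """

    beta0_mean: float = 8.0
    beta0_var: float = 100.0
    betak_var: float = 4.0
    tau_upper: float = 2.0
    gamma_var: float = 2.0
    phi_psi_var: float = 4.0
    icc_upper: float = 0.1
    dispersion_logmean: float | None = None
    dispersion_logsd: float | None = None

    def __post_init__(self):
        for name in ("beta0_var", "betak_var", "gamma_var", "phi_psi_var"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.tau_upper <= 0:
            raise ValidationError("tau_upper must be strictly positive")
        if not (0 < self.icc_upper < 1):
            raise ValidationError("icc_upper must lie in (0, 1)")


@dataclass(frozen=True)
class ModelConfig:
    """MCMC run configuration.

    Defaults mirror a long production run (100,000 burn-in + 100,000 kept
    iterations); exploratory work and the test suite use far shorter runs.
    At least two chains are required so convergence diagnostics are defined.
    """

    chains: int = 2
    burnin: int = 100_000
    iterations: int = 100_000
    seed: int = 0
    thin: int = 1

    def __post_init__(self):
        if self.chains < 2:
            raise ValidationError("chains must be >= 2 (convergence diagnostics)")
        if self.iterations <= 0:
            raise ValidationError("iterations must be positive")
        if self.burnin < 0 or self.thin < 1:
            raise ValidationError("burnin must be >= 0 and thin >= 1")

    @property
    def n_kept(self) -> int:
        return self.iterations // self.thin


class PosteriorDraws:
    """Per-chain, per-iteration posterior samples from a fitted model.

    Draw arrays are keyed by block name:

    ``population``
        ``beta0 (C,T)``, ``beta (C,T,m)``, ``tau0 (C,T)``, ``tau (C,T,m)``
        plus, depending on the model variant, ``gamma``, ``phi``, ``psi``.
        The difference variant omits ``beta0``/``tau0``.
    ``study``
        ``b0 (C,T,S)`` and ``b (C,T,S,m)`` — study-level intercepts and
        component coefficients.
    ``imputed``
        ``theta (C,T,#missing)`` sampled sampling-SDs and ``icc`` draws for
        unadjusted cluster arms with missing ICC.

    ``meta`` carries everything needed to re-evaluate arm-level means and
    variances (component names, study ids, fixed-effect design, imputation
    index maps) without refitting.
    """

    def __init__(
        self,
        population: dict[str, np.ndarray],
        study: dict[str, np.ndarray],
        imputed: dict[str, np.ndarray],
        meta: dict,
        config: ModelConfig,
        priors: PriorSpec,
    ):
        self.population = population
        self.study = study
        self.imputed = imputed
        self.meta = meta
        self.config = config
        self.priors = priors
        shapes = {v.shape[:2] for v in population.values()}
        if len(shapes) != 1:
            raise ValidationError("all draw arrays must share (chains, draws) shape")
        self.n_chains, self.n_draws = shapes.pop()

    @property
    def variant(self) -> str:
        return self.meta.get("variant", "base")

    @property
    def component_names(self) -> list[str]:
        return list(self.meta["component_names"])

    @property
    def m(self) -> int:
        return len(self.component_names)

    def stacked(self, name: str) -> np.ndarray:
        """Draws for ``name`` with chains concatenated along axis 0."""
        for block in (self.population, self.study, self.imputed):
            if name in block:
                arr = block[name]
                return arr.reshape((-1,) + arr.shape[2:])
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(name in b for b in (self.population, self.study, self.imputed))

    def parameter_names(self, include_study: bool = False) -> list[str]:
        """Flat registry of scalar parameter names, stable across chains."""
        names: list[str] = []
        comp = self.component_names
        for key, arr in self.population.items():
            if arr.ndim == 2:
                names.append(key)
            elif key in ("beta", "tau", "psi"):
                names.extend(f"{key}[{c}]" for c in comp)
            elif key == "gamma":
                names.extend(f"gamma[{p}]" for p in self.meta["gamma_partners"])
            else:
                names.extend(f"{key}[{i}]" for i in range(arr.shape[2]))
        for key, arr in self.imputed.items():
            idx = self.meta.get(f"imputed_{key}_arms", range(arr.shape[2]))
            names.extend(f"{key}_mis[{i}]" for i in idx)
        if include_study:
            sids = self.meta["study_ids"]
            if "b0" in self.study:
                names.extend(f"b0[{s}]" for s in sids)
            if "b" in self.study:
                names.extend(f"b[{s},{c}]" for s in sids for c in comp)
        return names

    def by_name(self, include_study: bool = False) -> dict[str, np.ndarray]:
        """Mapping of scalar parameter name -> (chains, draws) array."""
        out: dict[str, np.ndarray] = {}
        comp = self.component_names

        def expand(key, arr, labels):
            for i, lab in enumerate(labels):
                out[f"{key}[{lab}]"] = arr[:, :, i]

        for key, arr in self.population.items():
            if arr.ndim == 2:
                out[key] = arr
            elif key in ("beta", "tau", "psi"):
                expand(key, arr, comp)
            elif key == "gamma":
                expand(key, arr, self.meta["gamma_partners"])
            else:
                expand(key, arr, range(arr.shape[2]))
        for key, arr in self.imputed.items():
            idx = self.meta.get(f"imputed_{key}_arms", range(arr.shape[2]))
            for j, i in enumerate(idx):
                out[f"{key}_mis[{i}]"] = arr[:, :, j]
        if include_study:
            sids = self.meta["study_ids"]
            if "b0" in self.study:
                for i, s in enumerate(sids):
                    out[f"b0[{s}]"] = self.study["b0"][:, :, i]
            if "b" in self.study:
                for i, s in enumerate(sids):
                    for k, c in enumerate(comp):
                        out[f"b[{s},{c}]"] = self.study["b"][:, :, i, k]
        return out

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        """Serialise draws + metadata to an ``.npz`` archive."""
        import json

        payload = {}
        for block, d in (
            ("population", self.population),
            ("study", self.study),
            ("imputed", self.imputed),
        ):
            for k, v in d.items():
                payload[f"{block}__{k}"] = v
        meta = dict(self.meta)
        for k, v in meta.items():
            if isinstance(v, np.ndarray):
                meta[k] = v.tolist()
        payload["__meta__"] = np.frombuffer(
            json.dumps(
                {
                    "meta": meta,
                    "config": self.config.__dict__,
                    "priors": self.priors.__dict__,
                }
            ).encode(),
            dtype=np.uint8,
        )
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        import json

        with np.load(path) as z:
            blob = json.loads(bytes(z["__meta__"].tobytes()).decode())
            blocks = {"population": {}, "study": {}, "imputed": {}}
            for key in z.files:
                if key == "__meta__":
                    continue
                block, name = key.split("__", 1)
                blocks[block][name] = z[key]
        return cls(
            blocks["population"],
            blocks["study"],
            blocks["imputed"],
            blob["meta"],
            ModelConfig(**blob["config"]),
            PriorSpec(**blob["priors"]),
        )
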