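"""Reading, validating and transforming arm-level extraction tables.

An arm table is delimited text with one row per trial arm: study and arm
labels, sample size, posttreatment outcome mean with its standard error or
participant-level SD (possibly missing), one 0/1 column per intervention
component, an optional baseline covariate, and cluster-randomisation
metadata (flag, average cluster size, ICC, whether reported variances were
already cluster-adjusted).

Operations here cover the standard pre-model transformations: pooling rarely
observed components into an "other" category, tabulating observed component
combinations, reducing multi-arm trials to their most/least intensive arms,
and inflating standard errors of unadjusted cluster-randomised arms by the
design effect.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .types import (
    ArmRecord,
    ComponentCodebook,
    SchemaError,
    StudyDataset,
    ValidationError,
)

__all__ = [
    "DEFAULT_SCHEMA",
    "read_arm_table",
    "write_arm_table",
    "pool_rare_components",
    "count_nonempty_combinations",
    "tabulate_combinations",
    "CombinationTable",
    "select_extreme_arms",
    "adjust_cluster_variance",
    "design_effect",
    "write_codebook",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "rsmeta-arm-table v1"

#: Default column-name mapping for :func:`read_arm_table`. Component columns
#: are identified by the ``component_prefix`` entry (columns named
#: ``<prefix><label>``) unless an explicit ``components`` list is given.
DEFAULT_SCHEMA: dict = {
    "study": "study",
    "arm": "arm",
    "n": "n",
    "y": "y",
    "se": "se",
    "sd": "sd",
    "baseline": "baseline",
    "cluster": "cluster",
    "cluster_size": "cluster_size",
    "icc": "icc",
    "var_adjusted": "var_adjusted",
    "component_prefix": "c_",
}

_REQUIRED = ("study", "arm", "n", "y")
_OPTIONAL = ("se", "sd", "baseline", "cluster", "cluster_size", "icc", "var_adjusted")


def _opt_float(value):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if pd.isna(value):
        return None
    return float(value)


def read_arm_table(path, schema: dict | None = None, sep: str = ",") -> StudyDataset:
    """Read a delimited arm table into a validated :class:`StudyDataset`.

    ``schema`` maps canonical field names to column names (see
    :data:`DEFAULT_SCHEMA`); component columns are either listed explicitly
    under ``schema["components"]`` or discovered by the
    ``schema["component_prefix"]`` prefix. Missing ``se``/``sd``/``icc``
    cells are kept as explicit missing values, never silently zeroed.
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    df = pd.read_csv(path, sep=sep, comment="#")

    for key in _REQUIRED:
        if sch[key] not in df.columns:
            raise SchemaError(f"required column {sch[key]!r} (field {key!r}) missing")

    if "components" in sch:
        comp_cols = list(sch["components"])
        for c in comp_cols:
            if c not in df.columns:
                raise SchemaError(f"component column {c!r} missing")
        comp_names = [str(c) for c in comp_cols]
    else:
        prefix = sch["component_prefix"]
        comp_cols = [c for c in df.columns if str(c).startswith(prefix)]
        comp_names = [str(c)[len(prefix):] for c in comp_cols]
    if not comp_cols:
        raise SchemaError("no component columns found")

    for col in comp_cols:
        vals = df[col]
        bad = ~vals.isin([0, 1])
        if bad.any():
            idx = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValidationError(
                f"non-binary component value in column {col!r} at row {idx}"
            )

    def col(key):
        name = sch.get(key)
        return df[name] if name in df.columns else pd.Series([None] * len(df))

    arms = []
    for i in range(len(df)):
        arms.append(
            ArmRecord(
                study_id=str(df[sch["study"]].iloc[i]),
                arm_id=str(df[sch["arm"]].iloc[i]),
                n_participants=int(df[sch["n"]].iloc[i]),
                y=float(df[sch["y"]].iloc[i]),
                components=tuple(int(df[c].iloc[i]) for c in comp_cols),
                se=_opt_float(col("se").iloc[i]),
                sd=_opt_float(col("sd").iloc[i]),
                baseline_cov=_opt_float(col("baseline").iloc[i]),
                is_cluster=bool(_opt_float(col("cluster").iloc[i]) or 0),
                avg_cluster_size=_opt_float(col("cluster_size").iloc[i]),
                icc=_opt_float(col("icc").iloc[i]),
                variance_adjusted=bool(_opt_float(col("var_adjusted").iloc[i]) or 0),
            )
        )
    ds = StudyDataset(arms, comp_names)
    for a in ds.arms:
        if not a.se_missing and a.se is not None and a.sd is not None:
            derived = a.sd / math.sqrt(a.n_participants)
            if not math.isclose(a.se, derived, rel_tol=0.25):
                logger.warning(
                    "arm (%s, %s): reported se=%.4g disagrees with sd/sqrt(n)=%.4g; "
                    "using reported se",
                    a.study_id,
                    a.arm_id,
                    a.se,
                    derived,
                )
    return ds


def write_arm_table(ds: StudyDataset, path, sep: str = ",") -> None:
    """Write ``ds`` back to delimited text (round-trips through
    :func:`read_arm_table` with the default schema)."""
    df = ds.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        df.to_csv(fh, sep=sep, index=False)


def pool_rare_components(
    ds: StudyDataset, threshold: float, pooled_label: str = "other"
) -> tuple[StudyDataset, ComponentCodebook]:
    """Pool components with arm-prevalence below ``threshold`` into one
    ``"other"`` indicator.

    The pooled indicator is the logical OR of the pooled components on every
    arm; retained components are unchanged. Prevalence is computed over arms
    (not studies). The operation is idempotent at a fixed threshold.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError("threshold must lie in [0, 1]")
    prev = ds.component_prevalence()
    pooled_idx = [k for k in range(ds.m) if prev[k] < threshold]
    mapping = {
        name: (pooled_label if k in set(pooled_idx) else name)
        for k, name in enumerate(ds.component_names)
    }
    codebook = ComponentCodebook(mapping, threshold, pooled_label)
    if not pooled_idx:
        return ds, codebook
    kept_idx = [k for k in range(ds.m) if k not in set(pooled_idx)]
    if not kept_idx:
        raise ValidationError(
            "all components fall below the pooling threshold; the model would "
            "contain only the pooled category"
        )
    new_names = [ds.component_names[k] for k in kept_idx] + [pooled_label]
    new_arms = []
    for a in ds.arms:
        pooled_val = int(any(a.components[k] for k in pooled_idx))
        comps = tuple(a.components[k] for k in kept_idx) + (pooled_val,)
        new_arms.append(replace(a, components=comps))
    return StudyDataset(new_arms, new_names), codebook


def count_nonempty_combinations(m: int) -> int:
    """Number of distinct non-empty component combinations, ``2**m - 1``."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    return 2**m - 1


@dataclass(frozen=True)
class CombinationTable:
    """Frequency table of observed non-zero component combinations."""

    table: pd.DataFrame  # columns: combination, count (+ one 0/1 col per comp)
    n_unique: int
    n_singletons: int
    percent_of_possible: float

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {SCHEMA_VERSION}\n")
            self.table.to_csv(fh, index=False)


def tabulate_combinations(ds: StudyDataset) -> CombinationTable:
    """Tabulate distinct non-zero component vectors and their arm counts.

    Also reports how many combinations were observed exactly once and what
    percent of the ``2**m - 1`` possible non-empty combinations was observed
    at all.
    """
    X = ds.X.astype(int)
    active = X[X.sum(axis=1) > 0]
    counts: dict[tuple, int] = {}
    for row in map(tuple, active):
        counts[row] = counts.get(row, 0) + 1
    rows = []
    for combo, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        label = "+".join(
            name for name, bit in zip(ds.component_names, combo) if bit
        )
        rows.append({"combination": label, "count": cnt, **dict(zip(ds.component_names, combo))})
    table = pd.DataFrame(rows, columns=["combination", "count", *ds.component_names])
    n_unique = len(counts)
    n_singletons = sum(1 for c in counts.values() if c == 1)
    pct = 100.0 * n_unique / count_nonempty_combinations(ds.m)
    return CombinationTable(table, n_unique, n_singletons, pct)


def _extreme_pair(arms: list[ArmRecord]) -> list[ArmRecord]:
    # most intensive first by component count, ties broken by lowest arm_id
    by_count_desc = sorted(arms, key=lambda a: (-a.n_components_active, a.arm_id))
    top = by_count_desc[0]
    rest = [a for a in arms if a is not top]
    by_count_asc = sorted(rest, key=lambda a: (a.n_components_active, a.arm_id))
    bottom = by_count_asc[0]
    return [bottom, top]


def select_extreme_arms(ds: StudyDataset) -> StudyDataset:
    """Reduce every multi-arm study to its least and most intensive arms.

    Intensity is the number of active components; ties are broken by lowest
    arm label, which makes the selection deterministic under row permutation.
    Two-arm studies pass through unchanged.
    """
    new_arms: list[ArmRecord] = []
    for sid in ds.study_ids:
        arms = ds.arms_of(sid)
        if len(arms) < 2:
            raise ValidationError(f"study {sid!r} has a single arm")
        if len(arms) == 2:
            new_arms.extend(arms)
        else:
            new_arms.extend(_extreme_pair(arms))
    return ds.replace_arms(new_arms)


def design_effect(avg_cluster_size: float, icc: float) -> float:
    """Design effect ``DEFF = 1 + (m̄ - 1)·ICC`` for cluster-randomised arms."""
    if not (0.0 <= icc < 1.0):
        raise ValidationError("icc must lie in [0, 1)")
    if avg_cluster_size < 1.0:
        raise ValidationError("avg_cluster_size must be >= 1")
    return 1.0 + (avg_cluster_size - 1.0) * icc


def adjust_cluster_variance(arm: ArmRecord, icc: float | None = None) -> ArmRecord:
    """Inflate an unadjusted cluster-randomised arm's standard error by the
    design effect, ``se_adj = se · sqrt(1 + (m̄ - 1)·ICC)``.

    ``icc`` defaults to the arm's own recorded ICC. Already-adjusted arms are
    returned unchanged with a warning.
    """
    if arm.variance_adjusted or not arm.is_cluster:
        logger.warning(
            "arm (%s, %s) is not an unadjusted cluster arm; no correction applied",
            arm.study_id,
            arm.arm_id,
        )
        return arm
    if icc is None:
        if arm.icc_missing:
            raise ValidationError(
                f"arm ({arm.study_id}, {arm.arm_id}): no ICC available for "
                "cluster adjustment"
            )
        icc = arm.icc
    if arm.avg_cluster_size is None:
        raise ValidationError(
            f"arm ({arm.study_id}, {arm.arm_id}): avg_cluster_size required"
        )
    deff = design_effect(arm.avg_cluster_size, icc)
    se = arm.resolved_se
    if se is None:
        raise ValidationError(
            f"arm ({arm.study_id}, {arm.arm_id}): cannot adjust a missing se"
        )
    return replace(
        arm, se=se * math.sqrt(deff), sd=None, icc=icc, variance_adjusted=True
    )


def write_codebook(codebook: ComponentCodebook, path) -> None:
    payload = {"schema": SCHEMA_VERSION, **codebook.to_dict()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
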