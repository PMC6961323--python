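"""Pediatric drug-safety levels and their aggregation over drug clusters.

The 0-5 scale maps the youngest pediatric population covered by a drug's
labeling:

    5  preterm newborn infants
    4  full-term newborn infants (0 to 28 days)
    3  infants and toddlers (>28 days to 23 months)
    2  children (2 to 11 years), or a pediatric indication with no age
    1  adolescents (12 to 18 years)
    0  no pediatric labeling / contraindicated / safety not established

When the labeling states a numeric minimum age, that age is binned to the
scale; the minimum age across indications is used.  A caution or
contraindication dominates any age range.  Cluster-level safety is the
arithmetic mean of member-drug levels with a sample (n-1) standard
deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .io import DrugLabelTable, _age_in_months

_CLASS_LEVEL = {
    "preterm": 5,
    "full_term_newborn": 4,
    "infant_toddler": 3,
    "child": 2,
    "child_no_age": 2,
    "adolescent": 1,
    "not_established": 0,
    "no_pediatric_labeling": 0,
    "contraindicated": 0,
}

# classes that zero out any accompanying age range
_DOMINANT_ZERO = {"contraindicated", "not_established", "no_pediatric_labeling"}


@dataclass(frozen=True)
class SafetyLevel:
    """An assigned level plus the label statement that produced it."""

    level: int
    provenance: str

    def __int__(self) -> int:
        return self.level


class MissingLabelError(KeyError):
    """Clustered drugs lack a safety level."""


def _level_for_age(value: float, unit: str) -> int:
    months = _age_in_months(value, unit)
    if value < 0:  # gestational age before term
        return 5
    if unit == "days" and value <= 28:
        return 4
    if months <= 28 / 30.4375:
        return 4
    if months < 24:
        return 3
    if months < 144:  # 2-11 years
        return 2
    if months <= 216:  # 12-18 years
        return 1
    warnings.warn(
        f"minimum labeled age {value} {unit} exceeds 18 years; "
        "treated as no pediatric labeling (level 0)"
    )
    return -1  # sentinel: caller maps to 0


def assign_safety_level(
    label=None,
    *,
    statement_class: str | None = None,
    min_age_value: float | None = None,
    min_age_unit: str | None = None,
) -> SafetyLevel:
    """Map one drug-label row to its pediatric safety level.

    Accepts either a row object / mapping with ``statement_class``,
    ``min_age_value`` and ``min_age_unit`` fields, or those fields as
    keyword arguments.  Pure and deterministic: the class dictates the
    level, except that a stated numeric minimum age is binned to the scale
    (and a contraindication/not-established statement always wins with
    level 0).
    """
    if label is not None:
        get = label.get if isinstance(label, Mapping) else lambda f, d=None: getattr(label, f, d)
        statement_class = get("statement_class")
        min_age_value = get("min_age_value")
        min_age_unit = get("min_age_unit")
    if statement_class is None:
        raise ValueError("label row needs a statement_class")
    cls = str(statement_class).strip().lower()
    if cls not in _CLASS_LEVEL:
        raise ValueError(f"unknown label statement class {cls!r}")
    if cls in _DOMINANT_ZERO:
        return SafetyLevel(0, cls)
    if min_age_value is not None and not pd.isna(min_age_value):
        unit = (min_age_unit or "years").strip().lower()
        lvl = _level_for_age(float(min_age_value), unit)
        if lvl < 0:
            return SafetyLevel(0, "no_pediatric_labeling")
        return SafetyLevel(lvl, cls)
    return SafetyLevel(_CLASS_LEVEL[cls], cls)


def assign_safety_levels(labels: DrugLabelTable) -> pd.DataFrame:
    """Vector form: one row per drug with its level and provenance."""
    rows = [
        (r.drug_code, *((lambda s: (s.level, s.provenance))(assign_safety_level(r))))
        for r in labels.rows()
    ]
    return pd.DataFrame(rows, columns=["drug_code", "safety_level", "provenance"])


def _levels_series(levels) -> pd.Series:
    if isinstance(levels, pd.DataFrame):
        s = levels.set_index("drug_code")["safety_level"]
    elif isinstance(levels, pd.Series):
        s = levels
    else:
        s = pd.Series({d: int(v) for d, v in dict(levels).items()})
    return s.astype(float)


def cluster_safety(clustering, levels) -> pd.DataFrame:
    """Per-cluster mean and sample SD of member-drug safety levels.

    ``clustering`` is a DrugClustering (or a drug -> cluster Series);
    ``levels`` a drug -> level mapping, Series, or the DataFrame from
    :func:`assign_safety_levels`.  Singleton clusters get SD 0.  Raises
    :class:`MissingLabelError` listing any clustered drug without a level.
    """
    labels = clustering.labels if hasattr(clustering, "labels") else clustering
    lv = _levels_series(levels)
    missing = labels.index.difference(lv.index)
    if len(missing):
        raise MissingLabelError(
            f"no safety level for drugs: {sorted(missing)[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    df = pd.DataFrame({"cluster_id": labels, "level": lv.reindex(labels.index)})
    agg = df.groupby("cluster_id")["level"].agg(
        n_drugs="size", mean_level="mean", sd_level=lambda x: x.std(ddof=1)
    )
    agg["sd_level"] = agg["sd_level"].fillna(0.0)
    return agg.reset_index()


def safety_distribution(clustering, levels, normalize: bool = True) -> pd.DataFrame:
    """Per-cluster distribution of drugs over safety levels 0..5.

    Rows are clusters, columns levels; with ``normalize`` the rows are
    proportions summing to 1, otherwise integer counts.
    """
    labels = clustering.labels if hasattr(clustering, "labels") else clustering
    lv = _levels_series(levels)
    missing = labels.index.difference(lv.index)
    if len(missing):
        raise MissingLabelError(f"no safety level for drugs: {sorted(missing)[:10]}")
    df = pd.DataFrame(
        {"cluster_id": labels, "level": lv.reindex(labels.index).astype(int)}
    )
    counts = (
        df.groupby(["cluster_id", "level"]).size().unstack(fill_value=0)
        .reindex(columns=range(6), fill_value=0)
    )
    counts.columns.name = "safety_level"
    if normalize:
        return counts.div(counts.sum(axis=1), axis=0)
    return counts


def overall_safety(levels) -> dict:
    """Grand mean / SD over all drugs (the Table-style 'Total' row)."""
    lv = _levels_series(levels)
    return {
        "n_drugs": int(lv.size),
        "mean_level": float(lv.mean()),
        "sd_level": float(lv.std(ddof=1)) if lv.size > 1 else 0.0,
    }
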