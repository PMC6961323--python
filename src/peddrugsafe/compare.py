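"""Two-cohort comparison of drug-diagnosis association datasets.

Aligning the significant associations of two cohorts (e.g. a children's
hospital vs a general hospital) by diagnosis shows, for each diagnosis,
how many drugs are significantly associated with it in each cohort and how
many are shared; aligning by drug mirrors the view.  Hierarchical
clustering of the alignment rows then yields diagnosis groups and drug
groups whose composition can be profiled by ICD-10 chapter or ATC first
level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.preprocessing import StandardScaler

from .enrichment import AssociationTable
from .io import EncounterTable


def incidence(encounters: EncounterTable) -> pd.Series:
    """Per-diagnosis incidence in per mille of encounters:
    1000 x (encounters carrying the diagnosis) / (total encounters)."""
    per_dx = encounters.diagnosis_events.groupby("diagnosis_code")[
        "encounter_id"
    ].nunique()
    return (1000.0 * per_dx / encounters.n_encounters).rename("incidence_permille")


def _sig_sets(assoc: AssociationTable, by: str) -> dict:
    other = "diagnosis_code" if by == "drug_code" else "drug_code"
    sig = assoc.significant_pairs()
    return {k: set(g) for k, g in sig.groupby(by)[other]}


def align_by_diagnosis(
    assoc_a: AssociationTable,
    assoc_b: AssociationTable,
    enc_a: EncounterTable,
    enc_b: EncounterTable,
) -> pd.DataFrame:
    """One row per diagnosis in the union of the two cohorts.

    Columns: presence flags, per-mille incidences, the number of
    significantly associated drugs in each cohort, and the size of the
    intersection of those drug sets.
    """
    sets_a = _sig_sets(assoc_a, "diagnosis_code")
    sets_b = _sig_sets(assoc_b, "diagnosis_code")
    inc_a = incidence(enc_a)
    inc_b = incidence(enc_b)
    all_dx = sorted(set(enc_a.diagnoses) | set(enc_b.diagnoses))
    rows = []
    for g in all_dx:
        sa, sb = sets_a.get(g, set()), sets_b.get(g, set())
        rows.append(
            {
                "diagnosis_code": g,
                "present_in_A": g in enc_a.diagnoses,
                "present_in_B": g in enc_b.diagnoses,
                "incidence_A": float(inc_a.get(g, 0.0)),
                "incidence_B": float(inc_b.get(g, 0.0)),
                "n_assoc_drugs_A": len(sa),
                "n_assoc_drugs_B": len(sb),
                "n_assoc_overlap": len(sa & sb),
            }
        )
    return pd.DataFrame(rows)


def align_by_drug(
    assoc_a: AssociationTable,
    assoc_b: AssociationTable,
    enc_a: EncounterTable,
    enc_b: EncounterTable,
) -> pd.DataFrame:
    """Mirror of :func:`align_by_diagnosis` with drug and diagnosis roles
    swapped; use volume is the deduplicated drug-event count."""
    sets_a = _sig_sets(assoc_a, "drug_code")
    sets_b = _sig_sets(assoc_b, "drug_code")
    vol_a = enc_a.drug_events.groupby("drug_code").size()
    vol_b = enc_b.drug_events.groupby("drug_code").size()
    all_drugs = sorted(set(enc_a.drugs) | set(enc_b.drugs))
    rows = []
    for d in all_drugs:
        sa, sb = sets_a.get(d, set()), sets_b.get(d, set())
        rows.append(
            {
                "drug_code": d,
                "present_in_A": d in enc_a.drugs,
                "present_in_B": d in enc_b.drugs,
                "use_volume_A": int(vol_a.get(d, 0)),
                "use_volume_B": int(vol_b.get(d, 0)),
                "n_assoc_dx_A": len(sa),
                "n_assoc_dx_B": len(sb),
                "n_assoc_overlap": len(sa & sb),
            }
        )
    return pd.DataFrame(rows)


_DEFAULT_FEATURES = {
    "diagnosis_code": [
        "present_in_A", "present_in_B",
        "incidence_A", "incidence_B",
        "n_assoc_drugs_A", "n_assoc_drugs_B", "n_assoc_overlap",
    ],
    "drug_code": [
        "present_in_A", "present_in_B",
        "use_volume_A", "use_volume_B",
        "n_assoc_dx_A", "n_assoc_dx_B", "n_assoc_overlap",
    ],
}


def group_alignment(
    table: pd.DataFrame, n_groups: int, features: list | None = None
) -> pd.Series:
    """Cut an average-linkage hierarchy of alignment rows into n_groups.

    Count-like features are log1p-transformed, then all features are
    z-scored before Euclidean agglomerative clustering.  Returns group ids
    1..n_groups aligned with the table's rows; duplicated feature rows
    always share a group.
    """
    if n_groups < 2:
        raise ValueError("need n_groups >= 2")
    if n_groups > len(table):
        raise ValueError(f"n_groups={n_groups} exceeds {len(table)} rows")
    if features is None:
        key = "diagnosis_code" if "diagnosis_code" in table.columns else "drug_code"
        features = [c for c in _DEFAULT_FEATURES[key] if c in table.columns]
    X = table[features].astype(float).copy()
    for c in features:
        if not set(np.unique(X[c])) <= {0.0, 1.0}:
            X[c] = np.log1p(X[c])
    Xs = StandardScaler().fit_transform(X)
    Xs = np.nan_to_num(Xs)  # constant columns scale to 0
    if n_groups == len(table):
        labels = np.arange(len(table))
    else:
        model = AgglomerativeClustering(n_clusters=n_groups, linkage="average")
        labels = model.fit_predict(Xs)
    _, labels = np.unique(labels, return_inverse=True)
    return pd.Series(labels + 1, index=table.index, name="group_id")


def category_composition(
    groups: pd.Series, codes: pd.Series, category_map
) -> pd.DataFrame:
    """Per-group percentage composition over code categories.

    ``codes`` carries the row code (diagnosis or drug) aligned with
    ``groups``; ``category_map`` maps codes to a category (e.g. ICD-10
    chapter or ATC first level).  Codes without a mapping fall into
    ``"unmapped"``.  Each row of the result sums to 100.
    """
    mapper = dict(category_map)
    cats = codes.map(lambda c: mapper.get(c, "unmapped"))
    df = pd.DataFrame({"group_id": groups, "category": cats})
    counts = df.groupby(["group_id", "category"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0) * 100.0
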