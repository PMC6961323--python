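"""Drug-diagnosis co-occurrence counting and hypergeometric enrichment.

Every drug code and diagnosis code recorded under the same inpatient
encounter forms a drug-diagnosis association pair.  The universe of the
enrichment test is the multiset of these encounter-level pairs:

    N    total pairs,  N = sum over encounters of |drugs| x |diagnoses|
    K    pairs involving the drug
    n    pairs involving the diagnosis
    k    pairs matching both (the co-occurrence count)

For each observed pair the upper tail P(X >= k) of the hypergeometric
distribution (population N, K successes, n draws) measures how surprising
the co-occurrence is; Bonferroni correction over the tested family controls
the family-wise error rate, and adjusted P < alpha defines a significant
association.  The significant pairs, binarized, give each drug its
significant-diagnosis set used for the Jaccard drug-drug distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import EncounterTable


class EmptyUniverseError(ValueError):
    """No encounter carries both a drug and a diagnosis."""


@dataclass
class PairCounts:
    """Encounter-level pair counts and their margins.

    ``pairs`` has one row per observed (drug, diagnosis) pair with its count
    ``k``; ``drug_totals`` (K) and ``diagnosis_totals`` (n) are the margins;
    ``N`` the pair-universe size.  ``drugs`` / ``diagnoses`` index the full
    cohort vocabulary (including codes that never co-occur), so downstream
    matrices keep all-zero rows for drugs without associations.
    """

    pairs: pd.DataFrame
    drug_totals: pd.Series
    diagnosis_totals: pd.Series
    N: int
    drugs: pd.Index
    diagnoses: pd.Index

    def validate(self) -> None:
        assert int(self.drug_totals.sum()) == self.N
        assert int(self.diagnosis_totals.sum()) == self.N
        assert int(self.pairs["k"].sum()) == self.N
        merged = self.pairs.assign(
            K=self.drug_totals.reindex(self.pairs["drug_code"]).to_numpy(),
            n=self.diagnosis_totals.reindex(self.pairs["diagnosis_code"]).to_numpy(),
        )
        assert (merged["k"] <= np.minimum(merged["K"], merged["n"])).all()


def build_pairs(encounters: EncounterTable) -> PairCounts:
    """Count encounter-level drug-diagnosis pairs.

    Within each encounter the distinct drugs are crossed with the distinct
    diagnoses; repeated administrations collapse to one event first, so the
    pair universe is well defined.  Encounters lacking either side
    contribute nothing.
    """
    med = encounters.drug_events
    dx = encounters.diagnosis_events
    paired = med.merge(dx, on="encounter_id")
    if paired.empty:
        raise EmptyUniverseError(
            "no encounter carries both a medication and a diagnosis"
        )
    k = (
        paired.groupby(["drug_code", "diagnosis_code"], sort=True)
        .size()
        .rename("k")
        .reset_index()
    )
    K = paired.groupby("drug_code", sort=True).size().rename("K")
    n = paired.groupby("diagnosis_code", sort=True).size().rename("n")
    counts = PairCounts(
        pairs=k,
        drug_totals=K,
        diagnosis_totals=n,
        N=len(paired),
        drugs=encounters.drugs,
        diagnoses=encounters.diagnoses,
    )
    return counts


def hypergeometric_pvalue(k, K, n, N):
    """Upper-tail hypergeometric probability P(X >= k).

    X counts successes when ``n`` items are drawn without replacement from a
    population of ``N`` containing ``K`` successes.  Computed as the
    survival function at k-1 so no cancellation occurs for large k.
    Accepts scalars or aligned arrays; raises on violated bounds.
    """
    k = np.asarray(k)
    K = np.asarray(K)
    n = np.asarray(n)
    N = np.asarray(N)
    if (k < 0).any() or (K > N).any() or (n > N).any() or (k > np.minimum(K, n)).any():
        raise ValueError("hypergeometric bounds violated: need 0 <= k <= min(K, n) <= N")
    p = stats.hypergeom.sf(k - 1, N, K, n)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


@dataclass
class AssociationTable:
    """Per-pair enrichment results.

    ``table`` columns: drug_code, diagnosis_code, k, K, n, N, p_raw, p_adj,
    significant.  ``m`` is the Bonferroni family size; ``alpha`` the FWER
    level; ``drugs``/``diagnoses`` the full cohort vocabulary.
    """

    table: pd.DataFrame
    m: int
    alpha: float
    drugs: pd.Index
    diagnoses: pd.Index

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant_pairs(self) -> pd.DataFrame:
        return self.table.loc[self.table["significant"]]


def enrich(pairs: PairCounts, alpha: float = 0.05, family: str = "nonzero") -> AssociationTable:
    """Hypergeometric enrichment with Bonferroni family-wise correction.

    One hypothesis per pair with k >= 1.  ``family`` sets the Bonferroni
    divisor: ``"nonzero"`` (default) counts only observed pairs;
    ``"all"`` counts every drug x diagnosis cell.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = pairs.pairs.copy()
    df["K"] = pairs.drug_totals.reindex(df["drug_code"]).to_numpy()
    df["n"] = pairs.diagnosis_totals.reindex(df["diagnosis_code"]).to_numpy()
    df["N"] = pairs.N
    df["p_raw"] = hypergeometric_pvalue(
        df["k"].to_numpy(), df["K"].to_numpy(), df["n"].to_numpy(), df["N"].to_numpy()
    )
    if family == "nonzero":
        m = len(df)
    elif family == "all":
        m = len(pairs.drugs) * len(pairs.diagnoses)
    else:
        raise ValueError("family must be 'nonzero' or 'all'")
    df["p_adj"] = np.minimum(1.0, m * df["p_raw"])
    df["significant"] = df["p_adj"] < alpha
    return AssociationTable(
        table=df, m=m, alpha=alpha, drugs=pairs.drugs, diagnoses=pairs.diagnoses
    )


def significance_matrix(
    assoc: AssociationTable,
    drugs: pd.Index | None = None,
    diagnoses: pd.Index | None = None,
) -> pd.DataFrame:
    """Binary drugs x diagnoses matrix, 1 exactly at significant pairs.

    The index covers every drug and diagnosis present in the cohort, not
    just tested pairs, so drugs with no significant association keep an
    all-zero row (they later cluster together at mutual distance 0).
    """
    drugs = assoc.drugs if drugs is None else pd.Index(drugs)
    diagnoses = assoc.diagnoses if diagnoses is None else pd.Index(diagnoses)
    mat = pd.DataFrame(
        np.zeros((len(drugs), len(diagnoses)), dtype=np.int8),
        index=drugs,
        columns=diagnoses,
    )
    sig = assoc.significant_pairs()
    if len(sig):
        ri = mat.index.get_indexer(sig["drug_code"])
        ci = mat.columns.get_indexer(sig["diagnosis_code"])
        mat.values[ri, ci] = 1
    mat.index.name = "drug_code"
    mat.columns.name = "diagnosis_code"
    return mat
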