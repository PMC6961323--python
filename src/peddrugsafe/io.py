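"""Encounter-level EMR tables and delimited-text I/O.

The pipeline consumes long-format event records: one row per
(encounter, drug) medication event and one row per (encounter, diagnosis)
event.  Everything downstream (enrichment, distances, clustering, safety
scoring) works off the validated, deduplicated views exposed here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd


class FormatError(ValueError):
    """A mandatory column is missing or the file dialect is unusable."""


class EmptyInputError(ValueError):
    """The input file contains no data rows."""


class LabelConflictError(ValueError):
    """A drug code appears with conflicting label statements."""


def _normalize_codes(s: pd.Series) -> pd.Series:
    return s.astype("string").str.strip()


@dataclass
class ValidationSummary:
    """Row accounting for one event table: kept + dropped == input."""

    n_rows_in: int = 0
    n_kept: int = 0
    n_dropped_empty_code: int = 0
    n_dropped_unknown_encounter: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_empty_code + self.n_dropped_unknown_encounter

    def as_dict(self) -> dict:
        return {
            "rows_in": self.n_rows_in,
            "kept": self.n_kept,
            "dropped_empty_code": self.n_dropped_empty_code,
            "dropped_unknown_encounter": self.n_dropped_unknown_encounter,
        }


def _clean_events(
    df: pd.DataFrame,
    code_col: str,
    known_encounters: pd.Index | None,
) -> tuple[pd.DataFrame, ValidationSummary]:
    summary = ValidationSummary(n_rows_in=len(df))
    df = df.copy()
    df["encounter_id"] = _normalize_codes(df["encounter_id"])
    df[code_col] = _normalize_codes(df[code_col])
    bad_code = df[code_col].isna() | (df[code_col] == "") | df["encounter_id"].isna() | (
        df["encounter_id"] == ""
    )
    summary.n_dropped_empty_code = int(bad_code.sum())
    df = df.loc[~bad_code]
    if known_encounters is not None:
        unknown = ~df["encounter_id"].isin(known_encounters)
        summary.n_dropped_unknown_encounter = int(unknown.sum())
        df = df.loc[~unknown]
    summary.n_kept = len(df)
    return df.reset_index(drop=True), summary


class EncounterTable:
    """Long-format inpatient encounter events.

    Parameters
    ----------
    drug_events : DataFrame with columns ``encounter_id``, ``drug_code``.
    diagnosis_events : DataFrame with columns ``encounter_id``,
        ``diagnosis_code``.
    encounter_ids : optional explicit encounter index; events referencing
        other encounters are dropped and reported.  When omitted, the index
        is the union of encounter ids seen in either event table.
    atc_map, icd10_map : optional side tables mapping drug codes to ATC and
        diagnosis codes to ICD-10; never required by the core statistics.

    Duplicate (encounter, code) rows are permitted on input; the
    ``drug_events`` / ``diagnosis_events`` properties expose deduplicated
    views, so repeated administrations of one drug in one encounter count
    once when pairs are built.
    """

    def __init__(
        self,
        drug_events: pd.DataFrame,
        diagnosis_events: pd.DataFrame,
        encounter_ids=None,
        atc_map: Mapping[str, str] | None = None,
        icd10_map: Mapping[str, str] | None = None,
    ):
        for df, col in ((drug_events, "drug_code"), (diagnosis_events, "diagnosis_code")):
            for c in ("encounter_id", col):
                if c not in df.columns:
                    raise FormatError(f"missing mandatory column {c!r}")
        known = pd.Index(pd.Series(list(encounter_ids), dtype="string").str.strip()) if encounter_ids is not None else None
        self._drug_raw, self.drug_validation = _clean_events(
            drug_events[["encounter_id", "drug_code"]], "drug_code", known
        )
        self._dx_raw, self.diagnosis_validation = _clean_events(
            diagnosis_events[["encounter_id", "diagnosis_code"]], "diagnosis_code", known
        )
        if known is not None:
            self.encounters = known.unique()
        else:
            self.encounters = pd.Index(
                pd.concat(
                    [self._drug_raw["encounter_id"], self._dx_raw["encounter_id"]]
                ).unique()
            )
        self.atc_map = dict(atc_map) if atc_map else {}
        self.icd10_map = dict(icd10_map) if icd10_map else {}

    @property
    def drug_events(self) -> pd.DataFrame:
        """Deduplicated (encounter_id, drug_code) events."""
        return self._drug_raw.drop_duplicates(ignore_index=True)

    @property
    def diagnosis_events(self) -> pd.DataFrame:
        """Deduplicated (encounter_id, diagnosis_code) events."""
        return self._dx_raw.drop_duplicates(ignore_index=True)

    @property
    def drugs(self) -> pd.Index:
        return pd.Index(sorted(self._drug_raw["drug_code"].unique()))

    @property
    def diagnoses(self) -> pd.Index:
        return pd.Index(sorted(self._dx_raw["diagnosis_code"].unique()))

    @property
    def n_encounters(self) -> int:
        return len(self.encounters)

    def counts(self) -> dict:
        return {
            "encounters": self.n_encounters,
            "drugs": len(self.drugs),
            "diagnoses": len(self.diagnoses),
            "drug_events": len(self.drug_events),
            "diagnosis_events": len(self.diagnosis_events),
            "validation": {
                "drug": self.drug_validation.as_dict(),
                "diagnosis": self.diagnosis_validation.as_dict(),
            },
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<EncounterTable {self.n_encounters} encounters, "
            f"{len(self.drugs)} drugs, {len(self.diagnoses)} diagnoses>"
        )


def _read_delimited(path, sep=None) -> pd.DataFrame:
    if hasattr(path, "read"):
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", dtype=str)
    else:
        if os.path.getsize(path) == 0:
            raise EmptyInputError(f"empty input file: {path}")
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", dtype=str)
    if df.empty and len(df.columns) == 0:
        raise EmptyInputError(f"no data rows in {path}")
    return df


def read_encounters(
    medications=None,
    diagnoses=None,
    events=None,
    sep=None,
    encounter_col="encounter_id",
    drug_col="drug_code",
    diagnosis_col="diagnosis_code",
    type_col="event_type",
    encounter_ids=None,
) -> EncounterTable:
    """Read an :class:`EncounterTable` from delimited text.

    Two input dialects are accepted and normalize to the same table:

    * two files — ``medications`` (encounter_id, drug_code[, atc_code]) and
      ``diagnoses`` (encounter_id, diagnosis_code[, icd10_code]);
    * one long file ``events`` with an event-type column whose values are
      ``drug`` or ``diagnosis`` and a single ``code`` column.

    The delimiter is auto-detected unless ``sep`` is given.
    """
    if events is not None:
        df = _read_delimited(events, sep)
        for c in (encounter_col, type_col, "code"):
            if c not in df.columns:
                raise FormatError(f"missing mandatory column {c!r} in {events}")
        kinds = df[type_col].str.strip().str.lower()
        med = df.loc[kinds == "drug", [encounter_col, "code"]].rename(
            columns={encounter_col: "encounter_id", "code": "drug_code"}
        )
        dx = df.loc[kinds == "diagnosis", [encounter_col, "code"]].rename(
            columns={encounter_col: "encounter_id", "code": "diagnosis_code"}
        )
        return EncounterTable(med, dx, encounter_ids=encounter_ids)

    if medications is None or diagnoses is None:
        raise ValueError("provide either `events` or both `medications` and `diagnoses`")
    med = _read_delimited(medications, sep)
    dx = _read_delimited(diagnoses, sep)
    if encounter_col not in med.columns or drug_col not in med.columns:
        missing = encounter_col if encounter_col not in med.columns else drug_col
        raise FormatError(f"missing mandatory column {missing!r} in medications file")
    if encounter_col not in dx.columns or diagnosis_col not in dx.columns:
        missing = encounter_col if encounter_col not in dx.columns else diagnosis_col
        raise FormatError(f"missing mandatory column {missing!r} in diagnoses file")
    atc_map = None
    if "atc_code" in med.columns:
        atc_map = (
            med.dropna(subset=["atc_code"]).set_index(drug_col)["atc_code"].to_dict()
        )
    icd_map = None
    if "icd10_code" in dx.columns:
        icd_map = (
            dx.dropna(subset=["icd10_code"]).set_index(diagnosis_col)["icd10_code"].to_dict()
        )
    med = med.rename(columns={encounter_col: "encounter_id", drug_col: "drug_code"})
    dx = dx.rename(columns={encounter_col: "encounter_id", diagnosis_col: "diagnosis_code"})
    return EncounterTable(
        med, dx, encounter_ids=encounter_ids, atc_map=atc_map, icd10_map=icd_map
    )


# --- drug label table -------------------------------------------------------

LABEL_CLASSES = (
    "preterm",
    "full_term_newborn",
    "infant_toddler",
    "child",
    "child_no_age",
    "adolescent",
    "not_established",
    "no_pediatric_labeling",
    "contraindicated",
)

_UNIT_ALIASES = {
    "day": "days", "days": "days", "d": "days",
    "month": "months", "months": "months", "mo": "months",
    "year": "years", "years": "years", "y": "years", "yr": "years", "yrs": "years",
    "week": "weeks", "weeks": "weeks", "wk": "weeks",
}


def _parse_statement(text: str) -> tuple[str, float | None, str | None]:
    """Map a statement-class token or free-text labeling phrase to
    (statement_class, min_age_value, min_age_unit)."""
    import re

    t = (text or "").strip()
    if t == "":
        return "no_pediatric_labeling", None, None
    low = t.lower()
    if low in LABEL_CLASSES:
        return low, None, None
    if "contraindicat" in low or "not applicable" in low:
        return "contraindicated", None, None
    if "not been established" in low or "not established" in low:
        return "not_established", None, None
    if "preterm" in low or "premature" in low:
        return "preterm", None, None
    # an explicit age range like "children 6 to 17 years" or "from 28 days";
    # the minimum (first) age of a range sets the level
    unit_pat = r"(days?|weeks?|months?|years?|yrs?|mo|[dy])\b"
    m = re.search(
        r"(\d+(?:\.\d+)?)\s*(?:to|-|through)\s*\d+(?:\.\d+)?\s*" + unit_pat, low
    ) or re.search(r"(\d+(?:\.\d+)?)\s*" + unit_pat, low)
    if m:
        value = float(m.group(1))
        unit = _UNIT_ALIASES[m.group(2)]
        if unit == "weeks":
            value, unit = value * 7.0, "days"
        cls = _class_for_age(value, unit)
        return cls, value, unit
    if "newborn" in low or "neonat" in low:
        return "full_term_newborn", None, None
    if "infant" in low or "toddler" in low:
        return "infant_toddler", None, None
    if "adolescent" in low:
        return "adolescent", None, None
    if "child" in low or "pediatric" in low or "paediatric" in low:
        return "child_no_age", None, None
    return "not_established", None, None


def _age_in_months(value: float, unit: str) -> float:
    if unit == "weeks":
        value, unit = value * 7.0, "days"
    if unit == "days":
        return value / 30.4375
    if unit == "months":
        return value
    if unit == "years":
        return value * 12.0
    raise ValueError(f"unknown age unit {unit!r}")


def _class_for_age(value: float, unit: str) -> str:
    months = _age_in_months(value, unit)
    if value < 0:
        return "preterm"
    if unit == "days" and value <= 28:
        return "full_term_newborn"
    if months < 24:
        return "infant_toddler" if months > 28 / 30.4375 else "full_term_newborn"
    if months < 144:
        return "child"
    if months <= 216:
        return "adolescent"
    return "no_pediatric_labeling"


@dataclass
class DrugLabelTable:
    """Per-drug pediatric labeling metadata.

    ``table`` has one row per drug: drug_code, statement_class,
    min_age_value, min_age_unit.  ``unparsed`` records free-text rows that
    fell back to ``not_established``.
    """

    table: pd.DataFrame
    unparsed: list = field(default_factory=list)

    def __post_init__(self):
        dup = self.table["drug_code"][self.table["drug_code"].duplicated()]
        if len(dup):
            raise LabelConflictError(
                f"duplicate drug codes in label table: {sorted(set(dup))}"
            )
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def rows(self):
        return self.table.itertuples(index=False)


def read_drug_labels(path, sep=None) -> DrugLabelTable:
    """Read a drug-label table from delimited text.

    Columns: ``drug_code``, ``statement_class_or_text`` (either one of the
    statement-class tokens or a free-text labeling phrase), and optionally
    ``min_age_value`` / ``min_age_unit``.  Unparseable free text falls back
    to ``not_established`` and is reported in ``unparsed``.  Duplicate drug
    codes with conflicting classes raise :class:`LabelConflictError`.
    """
    df = _read_delimited(path, sep)
    if "drug_code" not in df.columns:
        raise FormatError("missing mandatory column 'drug_code' in label file")
    text_col = None
    for cand in ("statement_class_or_text", "statement_class", "label_statement", "statement"):
        if cand in df.columns:
            text_col = cand
            break
    if text_col is None:
        raise FormatError("missing statement column in label file")

    rows, unparsed = [], []
    for rec in df.itertuples(index=False):
        code = str(getattr(rec, "drug_code")).strip()
        text = getattr(rec, text_col)
        text = "" if pd.isna(text) else str(text)
        cls, val, unit = _parse_statement(text)
        v = getattr(rec, "min_age_value", None)
        u = getattr(rec, "min_age_unit", None)
        if v is not None and not pd.isna(v):
            val = float(v)
            unit = _UNIT_ALIASES.get(str(u).strip().lower(), "years") if u is not None and not pd.isna(u) else "years"
        if cls == "not_established" and text.strip() and "establish" not in text.lower():
            unparsed.append(code)
        rows.append((code, cls, val, unit))
    out = pd.DataFrame(rows, columns=["drug_code", "statement_class", "min_age_value", "min_age_unit"])
    conflicts = (
        out.groupby("drug_code")["statement_class"].nunique().loc[lambda s: s > 1]
    )
    if len(conflicts):
        raise LabelConflictError(
            f"conflicting label statements for drug codes: {sorted(conflicts.index)}"
        )
    out = out.drop_duplicates(subset="drug_code", keep="first")
    return DrugLabelTable(out, unparsed=unparsed)


# --- generic table / matrix round-trip --------------------------------------

def write_table(table: pd.DataFrame, path, sep="\t") -> None:
    """Write any tabular pipeline artifact as delimited text with header."""
    table.to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_table(path, sep="\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def write_matrix(matrix: pd.DataFrame, path, sep="\t", long_format=False) -> None:
    """Write a labelled matrix, square (header row/column) or as
    long-format (row_id, col_id, value) triplets."""
    if long_format:
        long = matrix.stack().reset_index()
        long.columns = ["row_id", "col_id", "value"]
        long.to_csv(path, sep=sep, index=False, float_format="%.12g")
    else:
        matrix.to_csv(path, sep=sep, index=True, float_format="%.12g")


def read_matrix(path, sep="\t", long_format=False) -> pd.DataFrame:
    if long_format:
        long = pd.read_csv(path, sep=sep, dtype={"row_id": str, "col_id": str})
        return long.pivot(index="row_id", columns="col_id", values="value")
    return pd.read_csv(path, sep=sep, index_col=0)
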