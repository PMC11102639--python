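"""Rating data model: loading, diagnosis standardization, exclusions, scoring.

The unit of observation is one general practitioner's (GP's) diagnosis of one
patient case under one experimental condition. In memory a rating table is a
:class:`pandas.DataFrame` with the columns

    gp_id, case_id, condition, diagnosis_raw, diagnosis_std,
    confidence, seniority_years, correct

``diagnosis_std`` and ``correct`` start out missing and are filled in by
:func:`standardize` and :func:`score`. Missing values are ``NaN``/``pd.NA``
throughout; an empty CSV cell is missing.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "RATING_COLUMNS",
    "StudyDesign",
    "SynonymMap",
    "AnswerKey",
    "normalize_term",
    "load_ratings",
    "standardize",
    "apply_exclusions",
    "score",
]

logger = logging.getLogger(__name__)

#: Canonical column order of a rating table.
RATING_COLUMNS = (
    "gp_id",
    "case_id",
    "condition",
    "diagnosis_raw",
    "diagnosis_std",
    "confidence",
    "seniority_years",
    "correct",
)

_WS = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Deterministic free-text normalization: case-fold, trim, collapse
    internal whitespace.

    Applied to both raw diagnoses and synonym-map keys, so lookup is
    insensitive to capitalization and spacing.
    """
    return _WS.sub(" ", str(term).casefold().strip())


@dataclass(frozen=True)
class StudyDesign:
    """Structure of a diagnostic study.

    Parameters
    ----------
    name:
        Free-form label, e.g. ``"vignette"``.
    assignment:
        ``"between_subject"`` (each GP sees one condition; all conditions use
        the same case set) or ``"within_subject"`` (each GP sees every
        condition; the cases are partitioned across conditions).
    conditions:
        Condition labels, e.g. ``("control", "early_dss", "late_dss")``.
    cases_per_condition:
        Mapping condition -> tuple of case ids diagnosed in that condition.
    confidence_scale:
        Inclusive ``(min, max)`` bounds of the ordinal confidence rating.
    """

    name: str
    assignment: str
    conditions: tuple[str, ...]
    cases_per_condition: dict[str, tuple[str, ...]]
    confidence_scale: tuple[int, int]

    def __post_init__(self) -> None:
        if self.assignment not in ("between_subject", "within_subject"):
            raise ValueError(f"unknown assignment {self.assignment!r}")
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(
            self,
            "cases_per_condition",
            {c: tuple(v) for c, v in self.cases_per_condition.items()},
        )
        missing = set(self.conditions) - set(self.cases_per_condition)
        if missing:
            raise ValueError(f"conditions without case lists: {sorted(missing)}")
        lo, hi = self.confidence_scale
        if not lo < hi:
            raise ValueError("confidence_scale must satisfy min < max")
        case_sets = [set(self.cases_per_condition[c]) for c in self.conditions]
        if self.assignment == "between_subject":
            if any(s != case_sets[0] for s in case_sets[1:]):
                raise ValueError(
                    "between_subject design requires the same case set in every condition"
                )
        else:
            seen: set[str] = set()
            for s in case_sets:
                if s & seen:
                    raise ValueError(
                        "within_subject design requires disjoint case sets across conditions"
                    )
                seen |= s

    @property
    def all_cases(self) -> tuple[str, ...]:
        out: list[str] = []
        for c in self.conditions:
            for case in self.cases_per_condition[c]:
                if case not in out:
                    out.append(case)
        return tuple(out)


@dataclass
class SynonymMap:
    """Many-to-one mapping from normalized free-text terms to standardized
    diagnosis labels.

    Every standardized label maps to itself, so standardization is idempotent.
    Unmapped terms fall back to their own normalized form.
    """

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized = {normalize_term(k): normalize_term(v) for k, v in self.entries.items()}
        # self-closure: standard labels map to themselves
        for label in list(normalized.values()):
            normalized.setdefault(label, label)
        self.entries = normalized

    def lookup(self, term: str) -> str:
        norm = normalize_term(term)
        return self.entries.get(norm, norm)

    @classmethod
    def from_csv(cls, source) -> "SynonymMap":
        """Read a 2-column CSV ``term,standard_label``."""
        df = pd.read_csv(source, dtype=str)
        df.columns = [c.strip() for c in df.columns]
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"term": list(self.entries), "standard_label": list(self.entries.values())}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class AnswerKey:
    """Per-case correct standardized diagnosis (exactly one label per case)."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "entries",
            {str(k): normalize_term(v) for k, v in self.entries.items()},
        )

    def __getitem__(self, case_id: str) -> str:
        return self.entries[case_id]

    def __contains__(self, case_id: str) -> bool:
        return case_id in self.entries

    @classmethod
    def from_csv(cls, source) -> "AnswerKey":
        """Read a 2-column CSV ``case_id,correct_label``."""
        df = pd.read_csv(source, dtype=str)
        df.columns = [c.strip() for c in df.columns]
        cases = df.iloc[:, 0]
        if cases.duplicated().any():
            dup = sorted(cases[cases.duplicated()].unique())
            raise ValueError(f"answer key lists multiple labels for case(s) {dup}")
        return cls(dict(zip(cases, df.iloc[:, 1])))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"case_id": list(self.entries), "correct_label": list(self.entries.values())}
        ).to_csv(path, index=False)


def load_ratings(source, design: StudyDesign) -> pd.DataFrame:
    """Load a ratings CSV into the canonical rating table.

    Expected header: ``gp_id,case_id,condition,diagnosis,confidence,
    seniority_years`` (``diagnosis_raw`` accepted for ``diagnosis``). Empty
    cells become missing values. Condition labels are validated against
    *design* and confidence against its declared scale; violations raise
    ``ValueError`` naming the offending row.
    """
    df = pd.read_csv(source, dtype={"gp_id": str, "case_id": str, "condition": str})
    df.columns = [c.strip() for c in df.columns]
    if "diagnosis" in df.columns and "diagnosis_raw" not in df.columns:
        df = df.rename(columns={"diagnosis": "diagnosis_raw"})
    required = {"gp_id", "case_id", "condition", "diagnosis_raw", "confidence", "seniority_years"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"ratings file missing column(s): {sorted(missing_cols)}")

    bad_cond = ~df["condition"].isin(design.conditions)
    if bad_cond.any():
        row = int(df.index[bad_cond][0])
        raise ValueError(
            f"row {row}: unknown condition {df.loc[row, 'condition']!r} "
            f"(design declares {list(design.conditions)})"
        )

    conf = pd.to_numeric(df["confidence"], errors="coerce")
    unparsed = conf.isna() & df["confidence"].notna() & (df["confidence"].astype(str).str.strip() != "")
    if unparsed.any():
        row = int(df.index[unparsed][0])
        raise ValueError(f"row {row}: non-numeric confidence {df.loc[row, 'confidence']!r}")
    lo, hi = design.confidence_scale
    oob = conf.notna() & ((conf < lo) | (conf > hi))
    if oob.any():
        row = int(df.index[oob][0])
        raise ValueError(
            f"row {row}: confidence {conf[row]:g} outside declared scale [{lo}, {hi}]"
        )
    sen = pd.to_numeric(df["seniority_years"], errors="coerce")
    neg = sen.notna() & (sen < 0)
    if neg.any():
        row = int(df.index[neg][0])
        raise ValueError(f"row {row}: negative seniority_years {sen[row]:g}")

    out = pd.DataFrame(
        {
            "gp_id": df["gp_id"],
            "case_id": df["case_id"],
            "condition": df["condition"],
            "diagnosis_raw": df["diagnosis_raw"],
            "diagnosis_std": pd.Series(pd.NA, index=df.index, dtype="string"),
            "confidence": conf,
            "seniority_years": sen,
            "correct": pd.Series(pd.NA, index=df.index, dtype="boolean"),
        }
    )
    return out


def standardize(records: pd.DataFrame, synonym_map: SynonymMap) -> pd.DataFrame:
    """Fill ``diagnosis_std`` by normalized lookup in *synonym_map*.

    Unmapped terms become their own normalized label (logged, not an error).
    Idempotent: re-standardizing an already standardized table is a no-op.
    """
    out = records.copy()
    raw = out["diagnosis_raw"].astype(str)
    std = raw.map(synonym_map.lookup)
    unmapped = sorted(
        {t for t in raw.map(normalize_term).unique() if t not in synonym_map.entries}
    )
    if unmapped:
        logger.info("standardize: %d unmapped term(s) kept as-is: %s", len(unmapped), unmapped)
    out["diagnosis_std"] = pd.array(std, dtype="string")
    return out


def apply_exclusions(
    records: pd.DataFrame, design: StudyDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop every GP with any missing confidence or seniority rating.

    Group simulation needs each member's confidence and seniority on every
    case, so exclusion is at the GP level: all of an affected GP's rows are
    removed, never a subset. Returns ``(retained records, report)`` where the
    report has one row per condition with columns
    ``condition,n_excluded,n_retained`` (GP counts).
    """
    bad = records["confidence"].isna() | records["seniority_years"].isna()
    excluded_gps = set(records.loc[bad, "gp_id"])
    keep = ~records["gp_id"].isin(excluded_gps)
    retained = records.loc[keep].reset_index(drop=True)

    rows = []
    for cond in design.conditions:
        in_cond = records.loc[records["condition"] == cond, "gp_id"].unique()
        n_exc = sum(g in excluded_gps for g in in_cond)
        rows.append(
            {"condition": cond, "n_excluded": n_exc, "n_retained": len(in_cond) - n_exc}
        )
    report = pd.DataFrame(rows, columns=["condition", "n_excluded", "n_retained"])
    return retained, report


def score(records: pd.DataFrame, key: AnswerKey) -> pd.DataFrame:
    """Set ``correct`` by exact equality of ``diagnosis_std`` with the key.

    Every ``case_id`` must be present in *key*; a missing case is a hard
    error. Requires :func:`standardize` to have run first.
    """
    if records["diagnosis_std"].isna().any():
        raise ValueError("records must be standardized before scoring")
    missing = sorted(set(records["case_id"]) - set(key.entries))
    if missing:
        raise KeyError(f"case(s) absent from answer key: {missing}")
    out = records.copy()
    truth = out["case_id"].map(key.entries)
    out["correct"] = pd.array(out["diagnosis_std"] == truth, dtype="boolean")
    return out
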