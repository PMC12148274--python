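"""Patient-level cohort container, validation, and delimited-table I/O.

One row per hospital admission. Each admission carries two predicted
adverse-event probabilities — ``p_vte``, the 14-day venous-thromboembolism
risk, and ``p_bleed``, the in-hospital major-bleeding risk — two point-based
risk scores (Padua for VTE, IMPROVE for bleeding), and the observed flag of
whether the physician administered pharmacological prophylaxis within 48
hours of admission.

Probabilities are stored as fractions in (0, 1) everywhere inside the
package; percent values appear only in rendered reports. A predicted risk of
exactly 0 or 1 is rejected as a data error (a logistic risk model cannot
emit either).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SCHEMA",
    "PatientRecord",
    "Cohort",
    "CohortSummary",
    "ValidationIssue",
    "CohortValidationError",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
]

#: Default mapping from canonical field names to file column names.
DEFAULT_SCHEMA: dict[str, str] = {
    "patient_id": "patient_id",
    "p_vte": "p_vte",
    "p_bleed": "p_bleed",
    "padua_score": "padua",
    "improve_score": "improve",
    "physician_prophylaxis": "physician_ppx",
}

#: Columns that must always be present in a cohort table.
REQUIRED_FIELDS = ("patient_id", "p_vte", "p_bleed", "physician_prophylaxis")

#: Score columns; optional because the probability-threshold strategies do
#: not need them (only the guidelines strategy does).
SCORE_FIELDS = ("padua_score", "improve_score")

_TRUE_TOKENS = {"true", "t", "1", "yes", "y"}
_FALSE_TOKENS = {"false", "f", "0", "no", "n"}


class SchemaError(ValueError):
    """A required column is missing or the schema mapping is malformed."""


@dataclasses.dataclass(frozen=True)
class ValidationIssue:
    """One (row, field, violation) entry of a validation report.

    ``row`` is the 1-based data-row number (header and comment lines do not
    count). ``patient_id`` is included when it could be parsed.
    """

    row: int
    field: str
    message: str
    patient_id: str | None = None


class CohortValidationError(ValueError):
    """Raised when one or more rows violate the cohort invariants."""

    def __init__(self, issues: Sequence[ValidationIssue]):
        self.issues = list(issues)
        lines = [
            f"row {i.row} [{i.field}]"
            + (f" (patient {i.patient_id})" if i.patient_id else "")
            + f": {i.message}"
            for i in self.issues[:20]
        ]
        if len(self.issues) > 20:
            lines.append(f"... and {len(self.issues) - 20} more")
        super().__init__(
            f"{len(self.issues)} validation issue(s):\n" + "\n".join(lines)
        )


@dataclasses.dataclass(frozen=True)
class PatientRecord:
    """A single admission."""

    patient_id: str
    p_vte: float
    p_bleed: float
    physician_prophylaxis: bool
    padua_score: int | None = None
    improve_score: int | None = None


def _validate_table(df: pd.DataFrame) -> list[ValidationIssue]:
    issues: list[ValidationIssue] = []
    if len(df) == 0:
        return [ValidationIssue(0, "cohort", "cohort must be non-empty")]

    ids = df["patient_id"].astype(str)

    def _flag(mask: np.ndarray, field: str, message: str) -> None:
        for pos in np.flatnonzero(np.asarray(mask)):
            issues.append(
                ValidationIssue(int(pos) + 1, field, message, ids.iloc[int(pos)])
            )

    dup = ids.duplicated(keep=False) & ~ids.duplicated(keep="first")
    _flag(dup.to_numpy(), "patient_id", "duplicate patient_id")

    for field in ("p_vte", "p_bleed"):
        vals = pd.to_numeric(df[field], errors="coerce")
        _flag(vals.isna().to_numpy(), field, "not a number")
        ok = vals.notna()
        bad = ok & ~((vals > 0.0) & (vals < 1.0))
        _flag(
            bad.to_numpy(),
            field,
            "probability must lie strictly in (0, 1)",
        )

    for field in SCORE_FIELDS:
        if field not in df.columns:
            continue
        vals = df[field]
        present = vals.notna()
        if present.any():
            as_float = pd.to_numeric(vals, errors="coerce")
            nonnum = present & as_float.isna()
            _flag(nonnum.to_numpy(), field, "not a number")
            numeric = present & as_float.notna()
            nonint = numeric & (as_float != as_float.round())
            _flag(nonint.to_numpy(), field, "score must be an integer")
            neg = numeric & (as_float < 0)
            _flag(neg.to_numpy(), field, "score must be >= 0")

    return issues


def _normalise(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=pd.RangeIndex(len(df)))
    out["patient_id"] = df["patient_id"].astype(str).to_numpy()
    # astype(float) parses decimal strings exactly (pd.to_numeric's fast
    # parser can lose the last couple of significant digits)
    out["p_vte"] = df["p_vte"].astype(float).to_numpy()
    out["p_bleed"] = df["p_bleed"].astype(float).to_numpy()
    for field in SCORE_FIELDS:
        if field in df.columns and df[field].notna().any():
            out[field] = pd.to_numeric(df[field]).round().astype("Int64").to_numpy(
                dtype=object
            )
            out[field] = out[field].astype("Int64")
    out["physician_prophylaxis"] = df["physician_prophylaxis"].astype(bool).to_numpy()
    return out


class Cohort:
    """An ordered, validated collection of :class:`PatientRecord`.

    Parameters
    ----------
    table
        Frame with canonical columns ``patient_id``, ``p_vte``, ``p_bleed``,
        ``physician_prophylaxis`` and optionally ``padua_score`` /
        ``improve_score``.
    metadata
        Free-form provenance tags (source, seed, generator config digest).
    """

    def __init__(
        self, table: pd.DataFrame, metadata: Mapping[str, str] | None = None
    ):
        missing = [f for f in REQUIRED_FIELDS if f not in table.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        issues = _validate_table(table)
        if issues:
            raise CohortValidationError(issues)
        self._table = _normalise(table)
        self.metadata: dict[str, str] = {
            str(k): str(v) for k, v in (metadata or {}).items()
        }

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[PatientRecord],
        metadata: Mapping[str, str] | None = None,
    ) -> "Cohort":
        rows = list(records)
        df = pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in rows],
                "p_vte": [r.p_vte for r in rows],
                "p_bleed": [r.p_bleed for r in rows],
                "padua_score": pd.array(
                    [r.padua_score for r in rows], dtype="Int64"
                ),
                "improve_score": pd.array(
                    [r.improve_score for r in rows], dtype="Int64"
                ),
                "physician_prophylaxis": [r.physician_prophylaxis for r in rows],
            }
        )
        for field in SCORE_FIELDS:
            if df[field].isna().all():
                df = df.drop(columns=[field])
        return cls(df, metadata)

    # -- accessors ----------------------------------------------------------

    @property
    def table(self) -> pd.DataFrame:
        """The underlying frame (copy; mutating it does not affect the cohort)."""
        return self._table.copy()

    @property
    def n(self) -> int:
        return len(self._table)

    def __len__(self) -> int:
        return self.n

    @property
    def patient_id(self) -> np.ndarray:
        return self._table["patient_id"].to_numpy()

    @property
    def p_vte(self) -> np.ndarray:
        return self._table["p_vte"].to_numpy()

    @property
    def p_bleed(self) -> np.ndarray:
        return self._table["p_bleed"].to_numpy()

    @property
    def physician_prophylaxis(self) -> np.ndarray:
        return self._table["physician_prophylaxis"].to_numpy()

    @property
    def has_scores(self) -> bool:
        return all(f in self._table.columns for f in SCORE_FIELDS)

    @property
    def padua_score(self) -> np.ndarray | None:
        if "padua_score" not in self._table.columns:
            return None
        return self._table["padua_score"].to_numpy(dtype=int)

    @property
    def improve_score(self) -> np.ndarray | None:
        if "improve_score" not in self._table.columns:
            return None
        return self._table["improve_score"].to_numpy(dtype=int)

    def records(self) -> list[PatientRecord]:
        padua = self.padua_score
        improve = self.improve_score
        return [
            PatientRecord(
                patient_id=str(self._table["patient_id"].iloc[i]),
                p_vte=float(self._table["p_vte"].iloc[i]),
                p_bleed=float(self._table["p_bleed"].iloc[i]),
                physician_prophylaxis=bool(
                    self._table["physician_prophylaxis"].iloc[i]
                ),
                padua_score=None if padua is None else int(padua[i]),
                improve_score=None if improve is None else int(improve[i]),
            )
            for i in range(self.n)
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        if set(self._table.columns) != set(other._table.columns):
            return False
        return (
            self._table[sorted(self._table.columns)].equals(
                other._table[sorted(other._table.columns)]
            )
            and self.metadata == other.metadata
        )

    def __repr__(self) -> str:
        return f"Cohort(n={self.n}, scores={self.has_scores})"


# -- I/O --------------------------------------------------------------------


def _invert_schema(schema: Mapping[str, str]) -> dict[str, str]:
    unknown = set(schema) - set(DEFAULT_SCHEMA)
    if unknown:
        raise SchemaError(f"unknown schema field(s): {', '.join(sorted(unknown))}")
    merged = {**DEFAULT_SCHEMA, **schema}
    return merged


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    return ","


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def _parse_bool_column(col: pd.Series) -> tuple[pd.Series, np.ndarray]:
    """Return (bool series, mask of unparseable entries)."""
    tokens = col.astype(str).str.strip().str.lower()
    is_true = tokens.isin(_TRUE_TOKENS)
    is_false = tokens.isin(_FALSE_TOKENS)
    bad = ~(is_true | is_false)
    return is_true, bad.to_numpy()


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> Cohort:
    """Read a delimited cohort table.

    Leading ``# key: value`` comment lines are parsed as metadata. Comma and
    tab delimiters are auto-detected unless ``delimiter`` is given. Column
    names follow :data:`DEFAULT_SCHEMA` unless overridden by ``schema``
    (canonical field name -> file column name).

    Raises
    ------
    SchemaError
        If a required mapped column is absent.
    CohortValidationError
        If any row violates an invariant; the error lists the offending
        rows, fields and patient ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = _invert_schema(schema or {})
    sep = delimiter or _sniff_delimiter(path)
    meta = _read_metadata(path)
    raw = pd.read_csv(path, sep=sep, comment="#", dtype=str)

    for field in REQUIRED_FIELDS:
        if colmap[field] not in raw.columns:
            raise SchemaError(
                f"column '{colmap[field]}' (field '{field}') not found in {path.name}"
            )

    df = pd.DataFrame(index=raw.index)
    df["patient_id"] = raw[colmap["patient_id"]]
    df["p_vte"] = raw[colmap["p_vte"]]
    df["p_bleed"] = raw[colmap["p_bleed"]]
    for field in SCORE_FIELDS:
        if colmap[field] in raw.columns:
            df[field] = raw[colmap[field]]

    flags, bad = _parse_bool_column(raw[colmap["physician_prophylaxis"]])
    if bad.any():
        ids = raw[colmap["patient_id"]].astype(str)
        raise CohortValidationError(
            [
                ValidationIssue(
                    int(pos) + 1,
                    "physician_prophylaxis",
                    "not a boolean (use true/false or 0/1)",
                    ids.iloc[int(pos)],
                )
                for pos in np.flatnonzero(bad)
            ]
        )
    df["physician_prophylaxis"] = flags

    return Cohort(df, metadata=meta)


def write_cohort(
    cohort: Cohort,
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> None:
    """Write a cohort as UTF-8 delimited text with a header row.

    Metadata is emitted as leading ``# key: value`` lines so that
    ``read_cohort(write_cohort(c)) == c``. Probabilities are written with
    ``repr``-style shortest round-trip formatting (exact to the last bit,
    well beyond 10 significant digits).
    """
    path = Path(path)
    colmap = _invert_schema(schema or {})
    df = cohort.table
    out = pd.DataFrame(index=df.index)
    for field in df.columns:
        out[colmap[field]] = df[field]
    out[colmap["physician_prophylaxis"]] = (
        df["physician_prophylaxis"].map({True: "true", False: "false"})
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, value in cohort.metadata.items():
            fh.write(f"# {key}: {value}\n")
        out.to_csv(fh, sep=delimiter, index=False, lineterminator="\n")


# -- summaries --------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CohortSummary:
    """Location statistics of both predicted risks plus the observed
    prophylaxis fraction. Probabilities are fractions; multiply by 100 for
    percent."""

    n: int
    p_vte_mean: float
    p_vte_median: float
    p_vte_min: float
    p_vte_max: float
    p_bleed_mean: float
    p_bleed_median: float
    p_bleed_min: float
    p_bleed_max: float
    observed_prophylaxis: float

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """n, mean/median/min/max of both risks, and the observed prophylaxis
    fraction."""
    pv, pb = cohort.p_vte, cohort.p_bleed
    return CohortSummary(
        n=cohort.n,
        p_vte_mean=float(np.mean(pv)),
        p_vte_median=float(np.median(pv)),
        p_vte_min=float(np.min(pv)),
        p_vte_max=float(np.max(pv)),
        p_bleed_mean=float(np.mean(pb)),
        p_bleed_median=float(np.median(pb)),
        p_bleed_min=float(np.min(pb)),
        p_bleed_max=float(np.max(pb)),
        observed_prophylaxis=float(np.mean(cohort.physician_prophylaxis)),
    )
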