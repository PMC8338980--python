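"""Cohort table schema, I/O, quartile coding of scale totals, and summaries.

A cohort table is a pandas DataFrame with one row per subject:

* ``PHQ_1`` .. ``PHQ_9``, ``GAD_1`` .. ``GAD_7`` — ordinal item levels in {1,2,3,4};
* ``STAI_T``, ``RAS_T``, ``RSES_T`` — raw integer totals of the state-anxiety,
  resilience and self-esteem scales;
* ``lifetime_SA``, ``gender_female``, ``institution_hospital`` — binary 0/1;
* ``acute_SI`` — the binary target (suicidal ideation within 2 weeks), never missing;
* ``MaDE_label`` — major-depressive-episode diagnosis for the labeled subset,
  missing elsewhere;
* ``KSSI_total`` — optional continuous suicide-ideation scale score for a subset.

Raw questionnaires score items 0-3; the package works on the shifted 1-4 coding so
that one-hot level slots and level-resolved attention rows are 1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

PHQ_COLS = tuple(f"PHQ_{i}" for i in range(1, 10))
GAD_COLS = tuple(f"GAD_{i}" for i in range(1, 8))
ITEM_COLS = PHQ_COLS + GAD_COLS
TOTAL_COLS = ("STAI_T", "RAS_T", "RSES_T")
BINARY_COLS = ("lifetime_SA", "gender_female", "institution_hospital")
TARGET_COL = "acute_SI"
OPTIONAL_COLS = ("MaDE_label", "KSSI_total", "lifetime_SI")
ID_COL = "subject_id"

#: columns that must be present and fully observed
REQUIRED_COLS = (ID_COL,) + ITEM_COLS + TOTAL_COLS + BINARY_COLS + (TARGET_COL,)


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table in place and return it.

    Raises :class:`SchemaError` naming the offending row and column for
    out-of-range levels, non-binary flags, or missing required cells.
    """
    missing_cols = [c for c in REQUIRED_COLS if c not in table.columns]
    if missing_cols:
        raise SchemaError(f"missing required columns: {missing_cols}")
    known = set(REQUIRED_COLS) | set(OPTIONAL_COLS) | {"MaDE", "center"} | {
        c + "_q" for c in TOTAL_COLS
    }
    unknown = [c for c in table.columns if c not in known]
    if unknown:
        raise SchemaError(f"unknown columns: {unknown}")

    def _first_bad(col: str, ok: pd.Series) -> None:
        if not ok.all():
            row = int(np.flatnonzero(~ok.to_numpy())[0])
            raise SchemaError(
                f"column {col!r}, row {row} (subject "
                f"{table[ID_COL].iloc[row]!r}): value {table[col].iloc[row]!r} "
                "out of range or missing"
            )

    for col in ITEM_COLS:
        _first_bad(col, table[col].isin([1, 2, 3, 4]))
    for col in BINARY_COLS + (TARGET_COL,):
        _first_bad(col, table[col].isin([0, 1]))
    for col in TOTAL_COLS:
        _first_bad(col, table[col].notna() & np.isfinite(table[col]))
    if "MaDE_label" in table.columns:
        present = table["MaDE_label"].notna()
        bad = present & ~table["MaDE_label"].isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"column 'MaDE_label', row {row}: not binary")
    if "KSSI_total" in table.columns:
        present = table["KSSI_total"].notna()
        bad = present & (table["KSSI_total"] < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"column 'KSSI_total', row {row}: negative score")
    return table


def read_cohort(
    path,
    schema: dict[str, str] | None = None,
    recode_items: bool = False,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read and validate a cohort CSV/TSV.

    Parameters
    ----------
    schema
        Optional mapping from canonical column names to the names used in the
        file (``{"PHQ_1": "phq1", ...}``).
    recode_items
        If True, item responses are stored on the raw 0-3 questionnaire scale
        and are shifted to the 1-4 level coding on read.
    delimiter
        Explicit delimiter; sniffed from the extension/content when omitted.
    """
    if delimiter is None:
        delimiter = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    table = pd.read_csv(path, sep=delimiter)
    if schema:
        table = table.rename(columns={v: k for k, v in schema.items()})
    if recode_items:
        for col in ITEM_COLS:
            if col in table.columns:
                table[col] = table[col] + 1
    return validate_cohort(table)


def write_cohort(table: pd.DataFrame, path, sidecar: dict | None = None) -> None:
    """Write a cohort table as CSV; optionally record provenance in a JSON sidecar."""
    table.to_csv(path, index=False)
    if sidecar is not None:
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(sidecar, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Quartile coding of scale totals
# ---------------------------------------------------------------------------


@dataclass
class QuartileCoder:
    """Maps raw scale totals to quartile levels 1-4.

    Cut points are the empirical 25/50/75 percentiles (linear interpolation
    between order statistics) of a reference split; they are fitted once on the
    training split and applied unchanged elsewhere. A value equal to a cut
    point takes the lower level; values beyond the reference range clamp to
    levels 1/4. Columns flagged as reversed (the resilience scale, where high
    raw scores are protective) map the top raw quartile to level 1.
    """

    cuts: dict[str, tuple[float, float, float]]
    reverse: dict[str, bool] = field(default_factory=dict)

    def code_values(self, values, column: str) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        cuts = np.asarray(self.cuts[column], dtype=float)
        levels = np.searchsorted(cuts, values, side="left") + 1
        if self.reverse.get(column, False):
            levels = 5 - levels
        return levels.astype(int)

    def transform(self, table: pd.DataFrame, suffix: str = "_q") -> pd.DataFrame:
        out = table.copy()
        for col in self.cuts:
            out[col + suffix] = self.code_values(out[col].to_numpy(), col)
        return out

    def to_dict(self) -> dict:
        return {
            "cuts": {k: list(v) for k, v in self.cuts.items()},
            "reverse": dict(self.reverse),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuartileCoder":
        return cls(
            cuts={k: tuple(v) for k, v in d["cuts"].items()},
            reverse=dict(d.get("reverse", {})),
        )


def fit_quartile_coder(
    table: pd.DataFrame,
    columns=TOTAL_COLS,
    reverse: dict[str, bool] | None = None,
) -> QuartileCoder:
    """Fit quartile cut points on a reference (training) split.

    Raises :class:`SchemaError` for constant columns, which cannot be coded
    into quartiles.
    """
    reverse = reverse or {}
    cuts: dict[str, tuple[float, float, float]] = {}
    for col in columns:
        vals = np.asarray(table[col], dtype=float)
        if vals.size < 4:
            raise SchemaError(f"column {col!r}: need at least 4 values to fit quartiles")
        if np.ptp(vals) == 0:
            raise SchemaError(f"column {col!r} is constant; quartile coder degenerate")
        q = np.percentile(vals, [25, 50, 75], method="linear")
        cuts[col] = (float(q[0]), float(q[1]), float(q[2]))
    return QuartileCoder(cuts=cuts, reverse={c: bool(reverse.get(c, False)) for c in columns})


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------


@dataclass
class CohortSummary:
    """Counts and 2-decimal percentages of the rare binary outcomes."""

    n: int
    counts: dict[str, int]

    @property
    def percentages(self) -> dict[str, float]:
        return {k: round(100.0 * v / self.n, 2) for k, v in self.counts.items()}

    def to_dict(self) -> dict:
        return {"n": self.n, "counts": self.counts, "percentages": self.percentages}


def summarize_cohort(table: pd.DataFrame) -> CohortSummary:
    """Count acute SI, lifetime SA, labeled MaDE positives (and lifetime SI if present)."""
    if len(table) == 0:
        raise SchemaError("empty cohort")
    counts = {
        "acute_SI": int(table[TARGET_COL].sum()),
        "lifetime_SA": int(table["lifetime_SA"].sum()),
    }
    if "MaDE_label" in table.columns:
        counts["MaDE_labeled_positive"] = int((table["MaDE_label"] == 1).sum())
    if "lifetime_SI" in table.columns:
        counts["lifetime_SI"] = int((table["lifetime_SI"] == 1).sum())
    return CohortSummary(n=len(table), counts=counts)
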