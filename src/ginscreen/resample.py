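"""Class-imbalance correction on the tabular cohort representation.

Two strategies, applied to the training partition only (never to validation
or test data):

* majority under-sampling to a target balance ratio (negatives per positive);
  the three ensemble members use ratios 10, 5 and 1;
* SMOTE-NC over-sampling of the minority class for mixed ordinal/nominal
  features: synthetic positives are interpolated between a minority seed row
  and one of its k nearest minority neighbors for ordinal/continuous columns
  (then rounded back to the valid level grid), while nominal columns take the
  majority vote of the k neighbors. Distances are Euclidean on the
  continuous columns plus the SMOTE-NC nominal penalty (the median of the
  continuous columns' standard deviations, added once per differing nominal
  attribute).

Resampling happens before graph encoding, and the edge matrix is fitted on
the original (un-resampled) training split so synthetic rows cannot distort
the population correlation structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .cohort import ITEM_COLS
from .errors import ResamplingError

#: columns never used as SMOTE interpolation features
_NON_FEATURE = ("subject_id", "acute_SI", "MaDE_label", "KSSI_total", "lifetime_SI", "center")


@dataclass
class ResampleSpec:
    strategy: str  # "under" | "smote-nc"
    ratio: float  # negatives per positive in the resampled data
    k: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in ("under", "smote-nc"):
            raise ResamplingError("strategy must be 'under' or 'smote-nc'")
        if self.ratio <= 0:
            raise ResamplingError("balance ratio must be > 0")
        if self.k < 1:
            raise ResamplingError("k must be >= 1")


def undersample(table: pd.DataFrame, spec: ResampleSpec, target: str = "acute_SI") -> pd.DataFrame:
    """Keep all positives; sample negatives without replacement to round(ratio * n_pos)."""
    if spec.strategy != "under":
        raise ResamplingError("undersample requires strategy='under'")
    rng = np.random.default_rng(spec.seed)
    pos = table[table[target] == 1]
    neg = table[table[target] == 0]
    if len(pos) == 0:
        raise ResamplingError("no positive cases to anchor under-sampling")
    n_neg = int(round(spec.ratio * len(pos)))
    if n_neg > len(neg):
        warnings.warn(
            f"requested {n_neg} negatives but only {len(neg)} exist; keeping all negatives"
        )
        n_neg = len(neg)
    keep = rng.choice(len(neg), size=n_neg, replace=False)
    out = pd.concat([pos, neg.iloc[np.sort(keep)]], ignore_index=True)
    return out.iloc[rng.permutation(len(out))].reset_index(drop=True)


def _feature_columns(table: pd.DataFrame, nominal_columns) -> list[str]:
    return [
        c
        for c in table.columns
        if c not in _NON_FEATURE and c not in nominal_columns and pd.api.types.is_numeric_dtype(table[c])
    ]


def smote_nc(
    table: pd.DataFrame,
    spec: ResampleSpec,
    nominal_columns,
    target: str = "acute_SI",
    continuous_columns=None,
    return_provenance: bool = False,
):
    """Append synthetic minority rows until n_neg / n_pos equals the balance ratio.

    With ``return_provenance=True`` also returns, per synthetic row, the
    minority seed position, the chosen neighbor's minority position, the
    interpolation gap, and the seed row's k-nearest-neighbor positions —
    enough for an independent oracle to recompute every synthetic row.
    """
    if spec.strategy != "smote-nc":
        raise ResamplingError("smote_nc requires strategy='smote-nc'")
    nominal_columns = [c for c in nominal_columns if c in table.columns]
    cont = list(continuous_columns) if continuous_columns is not None else _feature_columns(
        table, nominal_columns
    )
    rng = np.random.default_rng(spec.seed)
    minority = table[table[target] == 1].reset_index(drop=True)
    n_pos, n_neg = len(minority), int((table[target] == 0).sum())
    if n_pos < spec.k + 1:
        raise ResamplingError(
            f"SMOTE-NC needs at least k+1 = {spec.k + 1} minority rows, found {n_pos}"
        )
    n_new = int(round(n_neg / spec.ratio)) - n_pos
    if n_new <= 0:
        return (table.copy(), []) if return_provenance else table.copy()

    X = minority[cont].to_numpy(dtype=float)
    Nom = minority[nominal_columns].to_numpy()
    stds = X.std(axis=0, ddof=1) if n_pos > 1 else np.zeros(X.shape[1])
    med = float(np.median(stds))
    d2 = cdist(X, X, metric="sqeuclidean")
    if nominal_columns:
        mismatch = (Nom[:, None, :] != Nom[None, :, :]).sum(axis=2)
        d2 = d2 + mismatch * med * med
    np.fill_diagonal(d2, np.inf)
    neighbors = np.argsort(d2, axis=1, kind="stable")[:, : spec.k]

    rows, provenance = [], []
    for _ in range(n_new):
        i = int(rng.integers(n_pos))
        j_pos = int(rng.integers(spec.k))
        j = int(neighbors[i, j_pos])
        gap = float(rng.random())
        new_cont = X[i] + gap * (X[j] - X[i])
        row = {}
        for c, v in zip(cont, new_cont):
            v = float(np.rint(v))
            if c in ITEM_COLS or c.endswith("_q"):
                v = float(np.clip(v, 1, 4))
            row[c] = v
        for ci, c in enumerate(nominal_columns):
            vals, counts = np.unique(Nom[neighbors[i], ci], return_counts=True)
            top = counts.max()
            winners = vals[counts == top]
            row[c] = Nom[i, ci] if Nom[i, ci] in winners else winners[0]
        row[target] = 1
        rows.append(row)
        provenance.append(
            {"seed_pos": i, "neighbor_pos": j, "gap": gap, "knn": neighbors[i].tolist()}
        )

    synth = pd.DataFrame(rows)
    synth["subject_id"] = [f"syn_{i}" for i in range(len(synth))]
    for c in table.columns:
        if c not in synth.columns:
            synth[c] = np.nan
    out = pd.concat([table, synth[table.columns]], ignore_index=True)
    # keep integer dtypes where the original table had them
    for c in cont + list(nominal_columns):
        if pd.api.types.is_integer_dtype(table[c]):
            out[c] = out[c].astype(table[c].dtype)
    return (out, provenance) if return_provenance else out
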