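"""Shared correlation edge matrix and per-subject graph encoding.

All subjects share one edge matrix: pairwise correlations between the integer
node codes on the training split, thresholded so that only coefficients with
|rho| >= threshold (default 0.6) survive. A subject's graph is the shared
adjacency plus a node-by-6 one-hot feature matrix: ordinal nodes (items and
quartile-coded totals, levels 1-4) occupy slots 0-3, binary nodes (lifetime
suicide attempt, MaDE, gender, institution type) occupy slots 4-5.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import GAD_COLS, PHQ_COLS
from .errors import VocabularyError

FEATURE_DIM = 6
ORDINAL_TOTAL_NODES = ("STAI_T_q", "RAS_T_q", "RSES_T_q")
ORDINAL_NODES = PHQ_COLS + GAD_COLS + ORDINAL_TOTAL_NODES


@dataclass(frozen=True)
class NodeVocabulary:
    """Ordered node names with per-node kind (ordinal-4 or binary)."""

    names: tuple[str, ...]
    kinds: dict[str, str] = field(hash=False)

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise VocabularyError("node names must be unique")
        for n in self.names:
            if self.kinds.get(n) not in ("ordinal", "binary"):
                raise VocabularyError(f"node {n!r} must be kind 'ordinal' or 'binary'")

    @classmethod
    def acute_si_default(cls) -> "NodeVocabulary":
        """23 nodes: 19 ordinal items/totals + lifetime_SA, MaDE, gender, institution."""
        names = ORDINAL_NODES + ("lifetime_SA", "MaDE", "gender_female", "institution_hospital")
        kinds = {n: ("ordinal" if n in ORDINAL_NODES else "binary") for n in names}
        return cls(names=names, kinds=kinds)

    @classmethod
    def made_default(cls) -> "NodeVocabulary":
        """21 nodes for the MaDE model: 19 ordinal + gender, institution.

        Lifetime SA and the MaDE node itself are excluded: the label model
        sees only the questionnaires and basic demographics.
        """
        names = ORDINAL_NODES + ("gender_female", "institution_hospital")
        kinds = {n: ("ordinal" if n in ORDINAL_NODES else "binary") for n in names}
        return cls(names=names, kinds=kinds)

    @property
    def ordinal_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if self.kinds[n] == "ordinal")

    @property
    def binary_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if self.kinds[n] == "binary")

    def restrict(self, drop) -> "NodeVocabulary":
        """Vocabulary without the dropped nodes (ablation); edges must be re-fitted."""
        drop = tuple(drop)
        unknown = [d for d in drop if d not in self.names]
        if unknown:
            raise VocabularyError(f"cannot drop non-member nodes: {unknown}")
        remaining = tuple(n for n in self.names if n not in drop)
        if not remaining:
            raise VocabularyError("cannot drop all nodes")
        return NodeVocabulary(names=remaining, kinds={n: self.kinds[n] for n in remaining})

    def content_hash(self) -> str:
        payload = json.dumps([list(self.names), self.kinds], sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {"names": list(self.names), "kinds": dict(self.kinds)}

    @classmethod
    def from_dict(cls, d: dict) -> "NodeVocabulary":
        return cls(names=tuple(d["names"]), kinds=dict(d["kinds"]))


def restrict_vocabulary(vocab: NodeVocabulary, drop) -> NodeVocabulary:
    return vocab.restrict(drop)


@dataclass
class EdgeMatrix:
    """Symmetric signed adjacency of retained correlations, shared by all subjects."""

    names: tuple[str, ...]
    weights: np.ndarray
    threshold: float
    method: str
    split_id: str = ""

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(json.dumps(list(self.names)).encode())
        h.update(np.ascontiguousarray(self.weights).tobytes())
        return h.hexdigest()[:16]

    def save(self, path) -> None:
        pd.DataFrame(self.weights, index=self.names, columns=self.names).to_csv(path, sep="\t")
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(
                {"method": self.method, "threshold": self.threshold, "split_id": self.split_id},
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, path) -> "EdgeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        with open(str(path) + ".meta.json") as fh:
            meta = json.load(fh)
        return cls(
            names=tuple(df.columns),
            weights=df.to_numpy(dtype=float),
            threshold=meta["threshold"],
            method=meta["method"],
            split_id=meta.get("split_id", ""),
        )


def _node_codes(table: pd.DataFrame, vocab: NodeVocabulary) -> np.ndarray:
    missing = [n for n in vocab.names if n not in table.columns]
    if missing:
        if "MaDE" in missing:
            raise VocabularyError(
                "table lacks the 'MaDE' node column; run pseudo-labeling first to "
                "fill MaDE from true labels and model predictions"
            )
        raise VocabularyError(f"table lacks node columns: {missing}")
    return table[list(vocab.names)].to_numpy(dtype=float)


def fit_edge_matrix(
    table: pd.DataFrame,
    vocab: NodeVocabulary,
    method: str = "spearman",
    threshold: float = 0.6,
    split_id: str = "",
) -> EdgeMatrix:
    """Pairwise correlations on integer node codes, thresholded at |rho| >= threshold.

    The table must come from the training split only. Constant columns get
    zero correlations with a warning. Sign is preserved; the diagonal is zero.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    codes = _node_codes(table, vocab)
    constant = np.ptp(codes, axis=0) == 0
    if constant.any():
        warnings.warn(
            f"constant node columns {[vocab.names[i] for i in np.flatnonzero(constant)]}: "
            "their correlations are set to 0"
        )
    corr = pd.DataFrame(codes, columns=vocab.names).corr(method=method).to_numpy()
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 0.0)
    corr[np.abs(corr) < threshold] = 0.0
    corr = 0.5 * (corr + corr.T)  # guard symmetry against float asymmetry
    return EdgeMatrix(
        names=vocab.names, weights=corr, threshold=threshold, method=method, split_id=split_id
    )


def one_hot_features(table: pd.DataFrame, vocab: NodeVocabulary) -> np.ndarray:
    """(n_subjects, n_nodes, 6) one-hot node features for every row of the table."""
    codes = _node_codes(table, vocab)
    n, N = codes.shape
    feats = np.zeros((n, N, FEATURE_DIM))
    for j, name in enumerate(vocab.names):
        v = codes[:, j]
        if vocab.kinds[name] == "ordinal":
            if not np.isin(v, [1, 2, 3, 4]).all():
                raise VocabularyError(f"ordinal node {name!r} has levels outside 1..4")
            feats[np.arange(n), j, v.astype(int) - 1] = 1.0
        else:
            if not np.isin(v, [0, 1]).all():
                raise VocabularyError(f"binary node {name!r} has values outside {{0,1}}")
            feats[np.arange(n), j, 4 + v.astype(int)] = 1.0
    return feats


@dataclass
class SubjectGraph:
    """One subject: one-hot node features plus a reference to the shared edges."""

    features: np.ndarray  # (n_nodes, 6), each row sums to 1
    edges: EdgeMatrix
    subject_id: str
    label: int | None = None


@dataclass
class SubjectGraphSet:
    """A batch of subject graphs sharing one edge matrix (the dataset currency)."""

    features: np.ndarray  # (n_subjects, n_nodes, 6)
    edges: EdgeMatrix
    vocab: NodeVocabulary
    subject_ids: np.ndarray
    labels: np.ndarray | None = None

    def __len__(self) -> int:
        return self.features.shape[0]

    def subset(self, idx) -> "SubjectGraphSet":
        return SubjectGraphSet(
            features=self.features[idx],
            edges=self.edges,
            vocab=self.vocab,
            subject_ids=self.subject_ids[idx],
            labels=None if self.labels is None else self.labels[idx],
        )


def encode_subject(row: pd.Series, vocab: NodeVocabulary, edges: EdgeMatrix) -> SubjectGraph:
    """Encode a single validated cohort row as a graph."""
    table = row.to_frame().T
    feats = one_hot_features(table, vocab)[0]
    label = int(row["acute_SI"]) if "acute_SI" in row.index else None
    return SubjectGraph(
        features=feats, edges=edges, subject_id=str(row.get("subject_id", "")), label=label
    )


def encode_table(
    table: pd.DataFrame,
    vocab: NodeVocabulary,
    edges: EdgeMatrix,
    label_col: str | None = "acute_SI",
) -> SubjectGraphSet:
    """Encode every row of a cohort table against the shared edge matrix."""
    if tuple(edges.names) != tuple(vocab.names):
        raise VocabularyError("edge matrix was fitted on a different vocabulary")
    feats = one_hot_features(table, vocab)
    labels = None
    if label_col is not None:
        vals = table[label_col].to_numpy()
        if np.isnan(np.asarray(vals, dtype=float)).any():
            raise VocabularyError(f"label column {label_col!r} has missing values")
        labels = np.asarray(vals, dtype=int)
    return SubjectGraphSet(
        features=feats,
        edges=edges,
        vocab=vocab,
        subject_ids=table["subject_id"].to_numpy(),
        labels=labels,
    )
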