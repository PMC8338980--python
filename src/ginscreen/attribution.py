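"""Population attention plots from input gradients, plus odds ratios.

The saliency of input slot (node, level) is the gradient of the raw
(pre-sigmoid) model output with respect to that one-hot slot, averaged over a
subject set; for an ensemble the member gradients are averaged as well. Three
display normalizations are provided:

* ``row-wise`` — each level row (slots 1-4) divided by its maximum absolute
  entry over the 19 ordinal nodes, preserving sign (item comparison);
* ``column-wise`` — each binary node's two slots min-max scaled to [0, 1]
  (binary-item comparison);
* ``l1-column`` — per ordinal node, the L1 norm over its four level slots,
  scaled so the top node is exactly 1 (overall item saliency ranking).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import VocabularyError
from .graphs import FEATURE_DIM, NodeVocabulary, SubjectGraphSet


@dataclass
class AttentionMatrix:
    """Level-by-node mean gradients with a declared normalization state.

    ``values`` is (6, n_nodes) for matrix states and (n_ordinal,) for the
    ``l1-column`` state.
    """

    values: np.ndarray
    vocab: NodeVocabulary
    normalization: str = "raw"
    subject_set: str = ""
    ensemble_averaged: bool = False

    def to_frame(self) -> pd.DataFrame:
        if self.normalization == "l1-column":
            return pd.DataFrame({"l1_saliency": self.values}, index=self.vocab.ordinal_names)
        rows = ["level_1", "level_2", "level_3", "level_4", "binary_0", "binary_1"]
        return pd.DataFrame(self.values, index=rows, columns=self.vocab.names)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class OddsRatioTable:
    """Per binary item: the 2x2 counts against acute SI and the odds ratio."""

    rows: pd.DataFrame  # columns: item, a, b, c, d, odds_ratio, corrected

    def save(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def population_attention(models, graphs: SubjectGraphSet, subject_set: str = "") -> AttentionMatrix:
    """Mean input gradient over subjects, averaged across ensemble members.

    ``models`` may be a single model or an iterable of members sharing one
    vocabulary. Gradients are taken with respect to the raw output.
    """
    members = list(models) if isinstance(models, (list, tuple)) else [models]
    if len(graphs) == 0:
        raise ValueError("empty subject set")
    vocab = members[0].vocab
    for m in members:
        if tuple(m.vocab.names) != tuple(vocab.names):
            raise VocabularyError("ensemble members disagree on vocabulary")
    acc = np.zeros((len(vocab.names), FEATURE_DIM))
    for m in members:
        acc += m.input_gradient(graphs).mean(axis=0)
    acc /= len(members)
    return AttentionMatrix(
        values=acc.T.copy(),
        vocab=vocab,
        normalization="raw",
        subject_set=subject_set,
        ensemble_averaged=len(members) > 1,
    )


def normalize_attention(matrix: AttentionMatrix, mode: str) -> AttentionMatrix:
    """Apply one of the display normalizations to a raw attention matrix.

    Each mode is idempotent: re-normalizing a matrix already in the requested
    state leaves it unchanged. All-zero rows/columns are left as zeros with a
    warning.
    """
    if matrix.normalization not in ("raw", mode):
        raise ValueError(f"expected a raw matrix, got {matrix.normalization!r}")
    vocab = matrix.vocab
    ordinal_idx = [i for i, n in enumerate(vocab.names) if vocab.kinds[n] == "ordinal"]
    binary_idx = [i for i, n in enumerate(vocab.names) if vocab.kinds[n] == "binary"]

    if mode == "l1-column":
        if matrix.normalization == "l1-column":
            vec = matrix.values.astype(float)
        else:
            vec = np.abs(matrix.values[:4][:, ordinal_idx]).sum(axis=0)
        top = vec.max()
        if top == 0:
            warnings.warn("all-zero saliency; leaving zeros")
        else:
            vec = vec / top
        return AttentionMatrix(
            values=vec, vocab=vocab, normalization="l1-column",
            subject_set=matrix.subject_set, ensemble_averaged=matrix.ensemble_averaged,
        )

    values = matrix.values.astype(float).copy()
    if mode == "row-wise":
        for r in range(4):
            denom = np.max(np.abs(values[r, ordinal_idx])) if ordinal_idx else 0.0
            if denom == 0:
                warnings.warn(f"level row {r + 1} is all zero over ordinal nodes")
                continue
            values[r, :] = values[r, :] / denom
    elif mode == "column-wise":
        for i in binary_idx:
            col = values[4:6, i]
            lo, hi = col.min(), col.max()
            if hi == lo:
                if hi == 0:
                    warnings.warn(f"binary column {vocab.names[i]!r} is all zero")
                    continue
                values[4:6, i] = 0.0 if hi != 1.0 else col
                continue
            values[4:6, i] = (col - lo) / (hi - lo)
    else:
        raise ValueError("mode must be 'row-wise', 'column-wise' or 'l1-column'")
    return AttentionMatrix(
        values=values, vocab=vocab, normalization=mode,
        subject_set=matrix.subject_set, ensemble_averaged=matrix.ensemble_averaged,
    )


def binary_odds_ratios(table: pd.DataFrame, items, target: str = "acute_SI") -> OddsRatioTable:
    """Odds ratio of each binary item against the target from its 2x2 table.

    OR = (a*d)/(b*c) with a = exposed positive, b = exposed negative,
    c = unexposed positive, d = unexposed negative. When any cell is zero the
    Haldane-Anscombe +0.5 correction is applied to all four cells and the row
    is flagged.
    """
    records = []
    for item in items:
        if item not in table.columns:
            raise KeyError(f"binary item {item!r} not in table")
        x = table[item].to_numpy(dtype=int)
        y = table[target].to_numpy(dtype=int)
        a = int(((x == 1) & (y == 1)).sum())
        b = int(((x == 1) & (y == 0)).sum())
        c = int(((x == 0) & (y == 1)).sum())
        d = int(((x == 0) & (y == 0)).sum())
        corrected = 0 in (a, b, c, d)
        if corrected:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        records.append(
            {"item": item, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": float(orr), "corrected": corrected}
        )
    return OddsRatioTable(rows=pd.DataFrame(records))
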