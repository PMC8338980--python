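"""Two-stage training workflow.

Stage 1 trains a GIN on the labeled subset to predict the major depressive
episode (MaDE) diagnosis from the questionnaires and demographics, then
pseudo-labels every unlabeled subject (true labels are never overwritten).
Stage 2 trains three acute-SI GIN members on differently resampled training
data (under-sampling at ratios 10 and 5, SMOTE-NC at ratio 1), selects each
member's checkpoint under the validation sensitivity/specificity rule, and
averages the members' sigmoid scores into a soft-voting ensemble.

Split hygiene: quartile cut points, edge matrices, pseudo-label models and
resampling all derive from the training partition only; the validation
partition and the external test set are never resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PipelineError, VocabularyError
from .gin import CheckpointRule, GinConfig, GinModel, TrainConfig, TrainLog, train_gin
from .graphs import EdgeMatrix, NodeVocabulary, SubjectGraphSet, encode_table
from .resample import ResampleSpec, smote_nc, undersample


@dataclass
class SplitPlan:
    """Stratified training/validation partition; the test set is held external."""

    val_fraction: float = 0.2
    seed: int = 0


def stratified_split(table: pd.DataFrame, plan: SplitPlan, target: str = "acute_SI"):
    """Disjoint stratified train/val row partitions; both classes land in the
    validation fold whenever the class has at least 2 members."""
    rng = np.random.default_rng(plan.seed)
    y = table[target].to_numpy(dtype=int)
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        n_val = int(round(plan.val_fraction * len(idx)))
        if len(idx) >= 2:
            n_val = min(max(n_val, 1), len(idx) - 1)
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return (
        table.iloc[np.sort(train_idx)].reset_index(drop=True),
        table.iloc[np.sort(val_idx)].reset_index(drop=True),
    )


@dataclass
class PseudoLabelSet:
    """Per-subject MaDE probability, binarized value, and provenance flag."""

    frame: pd.DataFrame  # subject_id, probability, MaDE, provenance

    def made_values(self) -> pd.Series:
        return self.frame.set_index("subject_id")["MaDE"]


def train_made_model(
    labeled: pd.DataFrame,
    config: GinConfig,
    split: SplitPlan,
    edges: EdgeMatrix,
    train_config: TrainConfig,
    rule: CheckpointRule | None = None,
    vocab: NodeVocabulary | None = None,
) -> tuple[GinModel, TrainLog]:
    """Train the MaDE model on the labeled subset (label column ``MaDE_label``)."""
    vocab = vocab or NodeVocabulary.made_default()
    labeled = labeled[labeled["MaDE_label"].notna()].reset_index(drop=True)
    if labeled["MaDE_label"].nunique() < 2:
        raise ValueError("labeled MaDE subset contains a single class")
    tr, va = stratified_split(labeled, split, target="MaDE_label")
    tr_set = encode_table(tr, vocab, edges, label_col="MaDE_label")
    va_set = encode_table(va, vocab, edges, label_col="MaDE_label")
    return train_gin(tr_set, va_set, config, train_config, rule or CheckpointRule())


def pseudo_label(
    model: GinModel,
    table: pd.DataFrame,
    edges: EdgeMatrix,
    threshold: float = 0.5,
) -> PseudoLabelSet:
    """Give every subject a MaDE value: the true label where available, else
    the model pseudo-label 1[probability >= threshold]."""
    graphs = encode_table(table, model.vocab, edges, label_col=None)
    prob = model.predict(graphs)
    has_true = table["MaDE_label"].notna().to_numpy() if "MaDE_label" in table.columns else np.zeros(len(table), bool)
    true_vals = table["MaDE_label"].to_numpy(dtype=float) if "MaDE_label" in table.columns else np.full(len(table), np.nan)
    made = np.where(has_true, true_vals, (prob >= threshold).astype(float)).astype(int)
    frame = pd.DataFrame(
        {
            "subject_id": table["subject_id"].to_numpy(),
            "probability": prob,
            "MaDE": made,
            "provenance": np.where(has_true, "true-label", "pseudo-label"),
        }
    )
    return PseudoLabelSet(frame=frame)


def attach_made(table: pd.DataFrame, pseudo: PseudoLabelSet) -> pd.DataFrame:
    """Add the MaDE node column to a cohort table from a pseudo-label set."""
    out = table.copy()
    made = pseudo.made_values()
    out["MaDE"] = made.loc[out["subject_id"]].to_numpy()
    return out


def resample_training(table: pd.DataFrame, spec: ResampleSpec, target: str = "acute_SI"):
    nominal = [c for c in ("lifetime_SA", "gender_female", "institution_hospital", "MaDE") if c in table.columns]
    if spec.strategy == "under":
        return undersample(table, spec, target=target)
    return smote_nc(table, spec, nominal_columns=nominal, target=target)


def train_si_member(
    table: pd.DataFrame,
    resample: ResampleSpec,
    config: GinConfig,
    rule: CheckpointRule,
    split: SplitPlan,
    edges: EdgeMatrix,
    train_config: TrainConfig,
    vocab: NodeVocabulary | None = None,
) -> tuple[GinModel, TrainLog]:
    """Train one SI ensemble member.

    The table must already carry the MaDE node column (true or pseudo).
    Resampling is applied to the training partition only; the validation
    partition keeps its natural class balance.
    """
    vocab = vocab or NodeVocabulary.acute_si_default()
    tr, va = stratified_split(table, split, target="acute_SI")
    if resample is not None:
        tr = resample_training(tr, resample)
    if len(tr) == 0:
        raise PipelineError("empty training partition after resampling")
    tr_set = encode_table(tr, vocab, edges, label_col="acute_SI")
    va_set = encode_table(va, vocab, edges, label_col="acute_SI")
    return train_gin(tr_set, va_set, config, train_config, rule)


@dataclass
class EnsembleModel:
    """Soft-voting ensemble: the arithmetic mean of member sigmoid scores."""

    members: dict[str, GinModel] = field(default_factory=dict)

    def __post_init__(self):
        names = [tuple(m.vocab.names) for m in self.members.values()]
        if len(set(names)) > 1:
            raise VocabularyError("ensemble members must share one vocabulary")

    @property
    def vocab(self) -> NodeVocabulary:
        return next(iter(self.members.values())).vocab

    def predict(self, graphs: SubjectGraphSet) -> np.ndarray:
        scores = [m.predict(graphs) for m in self.members.values()]
        return np.mean(scores, axis=0)


def ensemble_predict(ensemble: EnsembleModel, graphs: SubjectGraphSet) -> np.ndarray:
    """Functional alias for :meth:`EnsembleModel.predict`."""
    return ensemble.predict(graphs)


#: the three member resampling strategies: ratios 10 and 5 for
#: under-sampling, ratio 1 for SMOTE-NC over-sampling
def default_member_specs(seed: int = 0) -> dict[str, ResampleSpec]:
    return {
        "u1": ResampleSpec(strategy="under", ratio=10, seed=seed),
        "u2": ResampleSpec(strategy="under", ratio=5, seed=seed + 1),
        "smote": ResampleSpec(strategy="smote-nc", ratio=1, seed=seed + 2),
    }


def train_si_ensemble(
    table: pd.DataFrame,
    config: GinConfig,
    rule: CheckpointRule,
    split: SplitPlan,
    edges: EdgeMatrix,
    train_config: TrainConfig,
    member_specs: dict[str, ResampleSpec] | None = None,
    vocab: NodeVocabulary | None = None,
) -> tuple[EnsembleModel, dict[str, TrainLog]]:
    """Train the three members and assemble the soft-voting ensemble."""
    member_specs = member_specs or default_member_specs(train_config.seed)
    members, logs = {}, {}
    for i, (name, spec) in enumerate(member_specs.items()):
        tc = TrainConfig(
            lr=train_config.lr,
            batch_size=train_config.batch_size,
            epochs=train_config.epochs,
            seed=train_config.seed + 101 * (i + 1),
        )
        members[name], logs[name] = train_si_member(
            table, spec, config, rule, split, edges, tc, vocab=vocab
        )
    return EnsembleModel(members=members), logs
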