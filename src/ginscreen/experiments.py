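"""End-to-end study orchestration on synthetic cohorts.

``run_study`` executes the full workflow the package implements — generate a
cohort, hold out an external test split, fit quartile coders and the shared
edge matrix on the training split, train the MaDE model and pseudo-label,
train the three resampled SI members plus an un-resampled reference member,
soft-vote, evaluate against the baselines, and compute attention — and
returns every measured quantity in one result object. It is the engine
behind the recovery experiments and the reproduction script.

Problem sizes and training budgets here are deliberately modest (they are
study-design choices recorded in the methods note): default n = 20,000
subjects at 1% outcome prevalence, a 16-unit five-layer GIN, and short Adam
schedules sized per member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .attribution import binary_odds_ratios, normalize_attention, population_attention
from .cohort import fit_quartile_coder, summarize_cohort
from .gin import CheckpointRule, GinConfig, TrainConfig
from .graphs import NodeVocabulary, encode_table, fit_edge_matrix, one_hot_features
from .pipeline import (
    EnsembleModel,
    SplitPlan,
    attach_made,
    default_member_specs,
    pseudo_label,
    train_made_model,
    train_si_member,
)
from .stats import auc_delong, baseline_fit, confusion_metrics, delong_paired_test, dependent_correlation_test
from .synthetic import default_outcome_spec, default_trait_spec, generate_cohort


@dataclass
class StudySettings:
    """Study-design knobs for a synthetic end-to-end run."""

    n: int = 20000
    test_fraction: float = 0.3
    edge_method: str = "spearman"
    edge_threshold: float = 0.6
    gin: GinConfig = field(default_factory=lambda: GinConfig(n_layers=5, hidden_dim=16))
    rule: CheckpointRule = field(default_factory=CheckpointRule)
    val_fraction: float = 0.2
    lr: float = 1e-3
    batch_size: int = 128
    member_epochs: dict = field(
        default_factory=lambda: {"u1": 60, "u2": 60, "smote": 12, "raw": 8}
    )
    made_epochs: int = 60
    svm_subsample: int = 6000
    baselines: tuple = ("lasso-logistic", "max-margin")
    attention_subsample: int | None = None
    with_raw_member: bool = True
    with_ablation: bool = False


@dataclass
class StudyResult:
    seed: int
    settings: StudySettings
    summary: dict
    ensemble_metrics: dict
    member_metrics: dict[str, dict]
    raw_member_metrics: dict | None
    baseline_metrics: dict[str, dict]
    pseudo_label_accuracy: float
    attention_train: np.ndarray
    attention_test: np.ndarray
    attention_nodes: tuple[str, ...]
    saliency_rho_train_test: float
    top_item: str
    odds_ratio_lifetime_sa: float
    kssi_comparison: dict | None
    ablation: dict | None
    ensemble_scores: np.ndarray
    test_labels: np.ndarray


def permutation_null_sd(scores, labels, n_perm: int = 200, seed: int = 0) -> float:
    """SD of the AUC under random reassignment of the labels (rank shortcut)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    ranks = rankdata(scores)
    m = int(labels.sum())
    n = labels.size - m
    aucs = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.choice(labels.size, size=m, replace=False)
        aucs[b] = (ranks[idx].sum() - m * (m + 1) / 2) / (m * n)
    return float(aucs.std(ddof=1))


def external_split(table: pd.DataFrame, test_fraction: float, seed: int):
    """Random external test split (emulating the held-out fourth center)."""
    rng = np.random.default_rng(seed)
    n_test = int(round(test_fraction * len(table)))
    idx = rng.permutation(len(table))
    test_idx, train_idx = np.sort(idx[:n_test]), np.sort(idx[n_test:])
    return (
        table.iloc[train_idx].reset_index(drop=True),
        table.iloc[test_idx].reset_index(drop=True),
        train_idx,
        test_idx,
    )


def _metrics(scores, labels, threshold=0.5) -> dict:
    rep = confusion_metrics(scores, labels, threshold)
    auc, var, ci = auc_delong(scores, labels)
    d = rep.to_dict()
    d.update({"auc": auc, "auc_var": var, "auc_ci": list(ci)})
    return d


def run_study(
    seed: int,
    settings: StudySettings | None = None,
    trait_spec=None,
    outcome_spec=None,
) -> StudyResult:
    """One full synthetic study at the given master seed."""
    st = settings or StudySettings()
    keys = np.random.SeedSequence(seed).generate_state(12) % (2**31 - 1)
    trait_spec = trait_spec or default_trait_spec()
    outcome_spec = outcome_spec or default_outcome_spec()

    cohort = generate_cohort(trait_spec, outcome_spec, n=st.n, seed=int(keys[0]))
    table = cohort.table
    train_tab, test_tab, train_idx, test_idx = external_split(
        table, st.test_fraction, seed=int(keys[1])
    )

    coder = fit_quartile_coder(train_tab, reverse={"RAS_T": True})
    train_tab = coder.transform(train_tab)
    test_tab = coder.transform(test_tab)

    # ----- stage 1: MaDE model + pseudo-labels ---------------------------
    made_vocab = NodeVocabulary.made_default()
    made_edges = fit_edge_matrix(
        train_tab, made_vocab, method=st.edge_method, threshold=st.edge_threshold, split_id="train"
    )
    made_model, _ = train_made_model(
        train_tab,
        st.gin,
        SplitPlan(val_fraction=st.val_fraction, seed=int(keys[2])),
        made_edges,
        TrainConfig(lr=st.lr, batch_size=64, epochs=st.made_epochs, seed=int(keys[3])),
    )
    pseudo_train = pseudo_label(made_model, train_tab, made_edges)
    pseudo_test = pseudo_label(made_model, test_tab, made_edges)
    train_tab = attach_made(train_tab, pseudo_train)
    test_tab = attach_made(test_tab, pseudo_test)

    made_true = cohort.latents["MaDE_true"].to_numpy()
    unlabeled = table["MaDE_label"].isna().to_numpy()
    all_made = pd.concat([pseudo_train.frame, pseudo_test.frame]).set_index("subject_id")
    made_hat = all_made["MaDE"].loc[table["subject_id"]].to_numpy()
    pseudo_acc = float(np.mean(made_hat[unlabeled] == made_true[unlabeled]))

    # ----- stage 2: SI ensemble ------------------------------------------
    si_vocab = NodeVocabulary.acute_si_default()
    si_edges = fit_edge_matrix(
        train_tab, si_vocab, method=st.edge_method, threshold=st.edge_threshold, split_id="train"
    )
    split = SplitPlan(val_fraction=st.val_fraction, seed=int(keys[4]))
    member_specs = default_member_specs(int(keys[5]))
    members, logs = {}, {}
    for i, (name, spec) in enumerate(member_specs.items()):
        tc = TrainConfig(
            lr=st.lr,
            batch_size=st.batch_size,
            epochs=st.member_epochs.get(name, 20),
            seed=int(keys[6]) + 101 * i,
        )
        members[name], logs[name] = train_si_member(
            train_tab, spec, st.gin, st.rule, split, si_edges, tc, vocab=si_vocab
        )
    ensemble = EnsembleModel(members=members)

    test_set = encode_table(test_tab, si_vocab, si_edges, label_col="acute_SI")
    train_set = encode_table(train_tab, si_vocab, si_edges, label_col="acute_SI")
    y_test = test_set.labels
    ens_scores = ensemble.predict(test_set)
    ensemble_metrics = _metrics(ens_scores, y_test)
    member_metrics = {
        name: _metrics(m.predict(test_set), y_test) for name, m in members.items()
    }

    raw_metrics = None
    if st.with_raw_member:
        raw_model, _ = train_si_member(
            train_tab,
            None,
            st.gin,
            st.rule,
            split,
            si_edges,
            TrainConfig(
                lr=st.lr,
                batch_size=st.batch_size,
                epochs=st.member_epochs.get("raw", 8),
                seed=int(keys[7]),
            ),
            vocab=si_vocab,
        )
        raw_metrics = _metrics(raw_model.predict(test_set), y_test)

    # ----- baselines ------------------------------------------------------
    baseline_metrics = {}
    if st.baselines:
        Xtr = one_hot_features(train_tab, si_vocab).reshape(len(train_tab), -1)
        Xte = one_hot_features(test_tab, si_vocab).reshape(len(test_tab), -1)
        ytr = train_tab["acute_SI"].to_numpy(dtype=int)
    if "lasso-logistic" in st.baselines:
        lasso_scores = baseline_fit(Xtr, ytr, Xte, "lasso-logistic", seed=int(keys[8]))
        baseline_metrics["lasso-logistic"] = _metrics(lasso_scores, y_test)
    if "max-margin" in st.baselines:
        rng = np.random.default_rng(int(keys[9]))
        n_sub = min(st.svm_subsample, len(train_tab))
        sub = rng.choice(len(train_tab), size=n_sub, replace=False)
        if ytr[sub].sum() == 0:  # keep at least the positives in the subsample
            sub = np.union1d(sub, np.flatnonzero(ytr == 1))
        svm_scores = baseline_fit(Xtr[sub], ytr[sub], Xte, "max-margin", seed=int(keys[8]))
        baseline_metrics["max-margin"] = _metrics(svm_scores, y_test)

    # ----- attribution ----------------------------------------------------
    att_train_set, att_test_set = train_set, test_set
    if st.attention_subsample is not None:
        rng = np.random.default_rng(int(keys[11]))
        if len(train_set) > st.attention_subsample:
            att_train_set = train_set.subset(
                np.sort(rng.choice(len(train_set), st.attention_subsample, replace=False))
            )
        if len(test_set) > st.attention_subsample:
            att_test_set = test_set.subset(
                np.sort(rng.choice(len(test_set), st.attention_subsample, replace=False))
            )
    att_train = normalize_attention(
        population_attention(list(members.values()), att_train_set, "train"), "l1-column"
    )
    att_test = normalize_attention(
        population_attention(list(members.values()), att_test_set, "test"), "l1-column"
    )
    rho = float(spearmanr(att_train.values, att_test.values).statistic)
    top_item = att_test.vocab.ordinal_names[int(np.argmax(att_test.values))]
    ors = binary_odds_ratios(table, ["lifetime_SA"])
    or_sa = float(ors.rows["odds_ratio"].iloc[0])

    # ----- KSSI criterion validity ---------------------------------------
    kssi = None
    has_kssi = test_tab["KSSI_total"].notna()
    if has_kssi.sum() >= 10:
        cc = dependent_correlation_test(
            pred=ens_scores[has_kssi.to_numpy()],
            alt=test_tab.loc[has_kssi, "PHQ_9"].to_numpy(),
            criterion=test_tab.loc[has_kssi, "KSSI_total"].to_numpy(),
        )
        kssi = {
            "rho_pred": cc.rho_pred,
            "rho_phq9": cc.rho_alt,
            "z": cc.z,
            "p_one_sided": cc.p_one_sided,
            "n": cc.n,
        }

    # ----- ablation of the suicide item ----------------------------------
    ablation = None
    if st.with_ablation:
        ab_vocab = si_vocab.restrict(["PHQ_9"])
        ab_edges = fit_edge_matrix(
            train_tab, ab_vocab, method=st.edge_method, threshold=st.edge_threshold,
            split_id="train",
        )
        ab_members = {}
        for i, (name, spec) in enumerate(default_member_specs(int(keys[5])).items()):
            tc = TrainConfig(
                lr=st.lr,
                batch_size=st.batch_size,
                epochs=st.member_epochs.get(name, 20),
                seed=int(keys[10]) + 101 * i,
            )
            ab_members[name], _ = train_si_member(
                train_tab, spec, st.gin, st.rule, split, ab_edges, tc, vocab=ab_vocab
            )
        ab_scores = EnsembleModel(members=ab_members).predict(
            encode_table(test_tab, ab_vocab, ab_edges, label_col="acute_SI")
        )
        cmp = delong_paired_test(ens_scores, ab_scores, y_test)
        ablation = {
            "metrics": _metrics(ab_scores, y_test),
            "auc_full": cmp.auc_a,
            "auc_ablated": cmp.auc_b,
            "delong_p": cmp.p,
        }

    return StudyResult(
        seed=seed,
        settings=st,
        summary=summarize_cohort(table).to_dict(),
        ensemble_metrics=ensemble_metrics,
        member_metrics=member_metrics,
        raw_member_metrics=raw_metrics,
        baseline_metrics=baseline_metrics,
        pseudo_label_accuracy=pseudo_acc,
        attention_train=att_train.values,
        attention_test=att_test.values,
        attention_nodes=att_test.vocab.ordinal_names,
        saliency_rho_train_test=rho,
        top_item=top_item,
        odds_ratio_lifetime_sa=or_sa,
        kssi_comparison=kssi,
        ablation=ablation,
        ensemble_scores=ens_scores,
        test_labels=y_test,
    )


def light_settings(**overrides) -> StudySettings:
    """Reduced-budget profile for the multi-seed recovery suite.

    Same cohort size, prevalence and model family as the default profile;
    shorter Adam schedules and attention averaged over a 2,000-subject
    subsample keep a multi-seed suite affordable on one CPU. The SVM is the
    only baseline retrained per seed (the sensitivity-collapse comparator).
    """
    st = StudySettings(
        member_epochs={"u1": 30, "u2": 30, "smote": 8, "raw": 8},
        made_epochs=40,
        baselines=("max-margin",),
        attention_subsample=2000,
    )
    for k, v in overrides.items():
        setattr(st, k, v)
    return st


def recovery_suite(seeds, settings: StudySettings | None = None) -> list[StudyResult]:
    """Run the planted-signal recovery experiment over several master seeds."""
    st = settings or light_settings()
    return [run_study(seed=s, settings=st) for s in seeds]


def pseudo_label_experiment(seed: int, n: int = 20000, labeled_fraction: float | None = None) -> float:
    """Pseudo-label accuracy against a deterministic synthetic MaDE rule.

    MaDE is planted as the indicator of the depression trait exceeding its
    90th percentile; accuracy is measured on the unlabeled subjects.
    """
    keys = np.random.SeedSequence(seed).generate_state(4) % (2**31 - 1)
    outcome = default_outcome_spec()
    outcome.made_deterministic_quantile = 0.9
    if labeled_fraction is not None:
        outcome.made_labeled_fraction = labeled_fraction
    cohort = generate_cohort(default_trait_spec(), outcome, n=n, seed=int(keys[0]))
    table = cohort.table
    coder = fit_quartile_coder(table, reverse={"RAS_T": True})
    table = coder.transform(table)
    vocab = NodeVocabulary.made_default()
    edges = fit_edge_matrix(table, vocab)
    model, _ = train_made_model(
        table,
        GinConfig(n_layers=5, hidden_dim=16),
        SplitPlan(val_fraction=0.2, seed=int(keys[1])),
        edges,
        TrainConfig(lr=1e-3, batch_size=64, epochs=60, seed=int(keys[2])),
    )
    pseudo = pseudo_label(model, table, edges)
    unlabeled = table["MaDE_label"].isna().to_numpy()
    made_true = cohort.latents["MaDE_true"].to_numpy()
    made_hat = pseudo.frame["MaDE"].to_numpy()
    return float(np.mean(made_hat[unlabeled] == made_true[unlabeled]))
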