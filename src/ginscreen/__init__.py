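"""ginscreen: graph-isomorphism-network screening of acute suicidal ideation
from multi-dimensional questionnaire data.

Per-subject graphs are built on a shared thresholded correlation edge matrix
over questionnaire items, quartile-coded scale totals and binary
clinico-demographic nodes; a GIN classifies each subject's graph, extreme
class imbalance is handled by an ensemble of differently resampled members
with soft voting, a missing diagnosis is pseudo-labeled by an auxiliary
model, and gradient attention interprets the predictions.
"""

from .attribution import (
    AttentionMatrix,
    OddsRatioTable,
    binary_odds_ratios,
    normalize_attention,
    population_attention,
)
from .cohort import (
    CohortSummary,
    QuartileCoder,
    fit_quartile_coder,
    read_cohort,
    summarize_cohort,
    validate_cohort,
    write_cohort,
)
from .gin import (
    CheckpointRule,
    GinConfig,
    GinModel,
    GraphEmbedding,
    PredictionScore,
    TrainConfig,
    bce_loss,
    select_checkpoint,
    train_gin,
)
from .graphs import (
    EdgeMatrix,
    NodeVocabulary,
    SubjectGraph,
    SubjectGraphSet,
    encode_subject,
    encode_table,
    fit_edge_matrix,
    one_hot_features,
    restrict_vocabulary,
)
from .pipeline import (
    EnsembleModel,
    PseudoLabelSet,
    SplitPlan,
    attach_made,
    ensemble_predict,
    pseudo_label,
    stratified_split,
    train_made_model,
    train_si_ensemble,
    train_si_member,
)
from .resample import ResampleSpec, smote_nc, undersample
from .stats import (
    AucComparison,
    CorrelationComparison,
    MetricsReport,
    auc_delong,
    baseline_fit,
    confusion_metrics,
    delong_paired_test,
    dependent_correlation_test,
)
from .synthetic import (
    LatentTraitSpec,
    OutcomeSpec,
    SyntheticCohort,
    calibrate_intercept,
    default_outcome_spec,
    default_trait_spec,
    generate_cohort,
)

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]
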