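"""Interpret a trained ensemble: gradient attention, odds ratios, and the
criterion-validity comparison against the continuous suicide-ideation scale.

Saliency is the gradient of the raw (pre-sigmoid) ensemble output with
respect to each one-hot input slot, averaged over subjects and members; the
L1-column view ranks the 19 questionnaire items.
"""

import warnings

from ginscreen.experiments import StudySettings, run_study
from ginscreen.gin import GinConfig

warnings.simplefilter("ignore")

# study conditions: 20,000 subjects, 1% prevalence, ~1.1% labeled MaDE
res = run_study(
    seed=4,
    settings=StudySettings(
        n=20000,
        gin=GinConfig(n_layers=5, hidden_dim=16),
        member_epochs={"u1": 30, "u2": 30, "smote": 8},
        with_raw_member=False,
        baselines=(),
        attention_subsample=2000,
    ),
)

ranking = sorted(
    zip(res.attention_nodes, res.attention_test), key=lambda kv: kv[1], reverse=True
)
print("top questionnaire items by L1 saliency (test split):")
for name, val in ranking[:5]:
    print(f"  {name:8s} {val:.3f}")
print(f"train-vs-test saliency ranking agreement (Spearman rho): "
      f"{res.saliency_rho_train_test:.3f}")
print(f"lifetime suicide attempt odds ratio for acute SI: "
      f"{res.odds_ratio_lifetime_sa:.2f}")
if res.kssi_comparison:
    k = res.kssi_comparison
    print(f"criterion validity on the KSSI subset (n={k['n']}): "
          f"rho_pred = {k['rho_pred']:.3f} vs rho_PHQ9 = {k['rho_phq9']:.3f} "
          f"(one-sided p = {k['p_one_sided']:.2g})")

# The anhedonia item (PHQ_2) carries the strongest planted effect, but the
# nine depression items are near-exchangeable by construction and their L1
# saliencies agree to within ~1%, so the exact rank-1 item varies with the
# cohort draw (see docs/methods.md on this limitation of gradient attention
# within homogeneous item clusters). The train/test rankings agree closely,
# and the ensemble score correlates with the continuous ideation scale more
# strongly than the single suicide item does.
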