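"""One full experiment: features -> selection -> five classifiers -> report.

Runs the complete stack for the disease-vs-control contrast on a synthetic
static-task cohort and prints the cross-validated performance per
architecture, the common features chosen by at least 3 of the 5 models,
and each model's top Shapley feature.
"""

import warnings

from soleposture import simulate_cohort
from soleposture.pipeline import ExperimentConfig, run_experiment
from soleposture.synthetic import pd_vs_control_preset

warnings.filterwarnings("ignore")

cohort = simulate_cohort(
    {"pd": 8, "age_matched_control": 8},
    pd_vs_control_preset(effect_scale=1.0, tasks=("EO", "EC", "OF")),
    seed=2,
)
config = ExperimentConfig(
    classification="pd_vs_age_matched", task_set="static", seed=2,
    sfs_max_features=4,
)
bundle = run_experiment(cohort.recordings, cohort.meta, config)

print(bundle.summary()[
    ["architecture", "accuracy_mean", "f1_mean", "auc_mean", "auc_sem"]
].to_string(index=False))
print("\ncommon features (>=3/5 models):", bundle.common)
print("top Shapley per model:", bundle.top_shapley)
print("misclassified subjects (>=3/5 models):", bundle.misclassified or "none")
# AUC near 1 reflects the injected lateral-shift / sway / asymmetry effects;
# the common and top-Shapley features show *which* stabilometric measures
# carry that separation.
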