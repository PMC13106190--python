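"""Run the task-specific algorithm selection on a small synthetic cohort.

Ranks features, greedily selects a subset, tunes the seven candidate models
inside every leave-one-subject-out fold (SMOTE-balanced training folds),
builds the four ensembles, and reports the chosen algorithm with bootstrap
confidence intervals and McNemar comparisons.
"""

from bradykin import generate_cohort
from bradykin.pipeline import extract_task_features, run_task_pipeline

cohort = generate_cohort(10, {0: 0.3, 1: 0.3, 2: 0.2, 3: 0.2}, seed=0,
                         exact_counts=True)
table = extract_task_features(cohort, task="FT", side="R")
report = run_task_pipeline(table, scenario="precise", seed=0,
                           bootstrap_reps=500)

print("selected features:", report["selected_features"])
print("per-model record-level weighted F1:")
for model, f1 in sorted(report["model_f1"].items(), key=lambda kv: -kv[1]):
    print(f"  {model:5s} {f1:.4f}")
print("ensembles:", {k: round(v, 4) for k, v in report["ensemble_f1"].items()})
choice = report["choice"]
print(f"\nchosen: {choice['name']} ({choice['kind']}), members {choice['members']}")
f1 = report["metrics"]["f1"]
print(f"weighted F1 {f1['value']:.4f} "
      f"(95% CI {f1['ci_lower']:.4f}-{f1['ci_upper']:.4f})")
sig = [m for m, r in report["mcnemar"].items() if r["significant"]]
print("significantly worse alternatives (Bonferroni):", sig or "none")
# The chosen algorithm's margin over the alternatives is usually not
# significant on a cohort this small — exactly what the McNemar matrix shows.
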