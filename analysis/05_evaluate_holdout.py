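"""Final model validation: permutation test and the single holdout pass.

For each feature type, re-runs the selection-and-training closure under
label permutation to obtain a permutation p-value for the training-data
model, then scores the final SVM exactly once on the untouched 15% holdout
subjects: per-group one-vs-rest accuracy (%), one-vs-rest ROC-AUC and the
confusion matrix. Writes results/evaluation/<feature type>.json and a
combined accuracy table.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from megstrat.evaluation import SplitSpec, evaluate_holdout, permutation_test
from megstrat.features import FeatureMatrix
from megstrat.pipeline import make_screen_svm_statistic, run_selection_and_evaluation
from megstrat.selection import CVScheme

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--features-dir", default=str(ROOT / "results" / "features"))
    ap.add_argument("--models-dir", default=str(ROOT / "results" / "models"))
    ap.add_argument("--out-dir", default=str(ROOT / "results" / "evaluation"))
    ap.add_argument("--n-perm", type=int, default=99)
    ap.add_argument("--n-trees", type=int, default=100)
    args = ap.parse_args()

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for ftype in ("power", "aec"):
        fm = FeatureMatrix.from_csv(Path(args.features_dir) / f"features_{ftype}.csv")
        sp = json.loads((Path(args.models_dir) / ftype / "split.json").read_text())
        split = SplitSpec(tuple(sp["train_ids"]), tuple(sp["holdout_ids"]),
                          sp["fraction"], sp["seed"])
        res = run_selection_and_evaluation(
            fm, split, scheme=CVScheme(n_folds=10, seed=args.seed),
            two_step=True, n_trees=args.n_trees, n_perm=0, run_plsda=False)

        train_fm = fm.subset_subjects(list(split.train_ids))
        statistic = make_screen_svm_statistic(train_fm, seed=args.seed)
        obs, p, _ = permutation_test(statistic, train_fm.labels.to_numpy(),
                                     n_perm=args.n_perm, seed=args.seed)
        holdout_fm = fm.subset_subjects(list(split.holdout_ids))
        report = evaluate_holdout(res["model"], holdout_fm, fm, split,
                                  permutation_p=p)
        (out / f"{ftype}.json").write_text(report.to_json())
        print(f"{ftype}: permutation p = {p:.3f} "
              f"(observed CV statistic {obs:.3f}, {args.n_perm} permutations)")
        print(f"  holdout per-group accuracy (%): "
              f"{ {g: round(a, 1) for g, a in report.group_accuracy.items()} }")
        print(f"  holdout one-vs-rest AUC: "
              f"{ {g: (round(a, 3) if a is not None else None) for g, a in report.group_auc.items()} }")
        for g in report.group_accuracy:
            rows.append({"feature_type": ftype, "group": g,
                         "holdout_accuracy_pct": report.group_accuracy[g],
                         "holdout_auc": report.group_auc[g],
                         "permutation_p": p})

    table = pd.DataFrame(rows)
    table.to_csv(out / "holdout_accuracy_table.tsv", sep="\t", index=False)
    print(f"\nwrote {out / 'holdout_accuracy_table.tsv'}")


if __name__ == "__main__":
    main()
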