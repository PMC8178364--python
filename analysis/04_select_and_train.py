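"""Feature selection and final model training on the training partition.

Applies the stratified 85/15 holdout split, runs the two-step
CV-SVM-rRF-FS loop (training-only raw-p screen, recursive random-forest
elimination, per-fold SVM scoring) separately for the power and AEC
feature sets, extracts consensus features, trains the final tuned SVM on
all training data, and verifies the consensus with PLS-DA. Outputs under
results/models/<feature type>/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from megstrat.evaluation import stratified_split
from megstrat.features import FeatureMatrix
from megstrat.pipeline import run_selection_and_evaluation
from megstrat.selection import CVScheme

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--features-dir", default=str(ROOT / "results" / "features"))
    ap.add_argument("--out-dir", default=str(ROOT / "results" / "models"))
    ap.add_argument("--n-trees", type=int, default=100)
    ap.add_argument("--one-step", action="store_true",
                    help="skip the univariate pre-reduction")
    args = ap.parse_args()

    for ftype in ("power", "aec"):
        fm = FeatureMatrix.from_csv(Path(args.features_dir) / f"features_{ftype}.csv")
        split = stratified_split(fm.labels, 0.85, seed=args.seed)
        res = run_selection_and_evaluation(
            fm, split, scheme=CVScheme(n_folds=10, seed=args.seed),
            two_step=not args.one_step, n_trees=args.n_trees,
            n_perm=0, run_plsda=True)
        out = Path(args.out_dir) / ftype
        out.mkdir(parents=True, exist_ok=True)
        (out / "selection.json").write_text(res["selection"].to_json())
        (out / "model.json").write_text(res["model"].to_json())
        (out / "split.json").write_text(json.dumps(
            {"train_ids": list(split.train_ids),
             "holdout_ids": list(split.holdout_ids),
             "fraction": split.fraction, "seed": split.seed}, sort_keys=True))
        sel = res["selection"]
        print(f"{ftype}: mean CV 4-class accuracy "
              f"{np.mean(sel.fold_accuracy):.3f}; consensus "
              f"{len(sel.consensus_features)} features: {sel.consensus_features}")
        if "plsda" in res:
            pl = res["plsda"]
            flag = " (flagged SVM-only)" if pl["svm_only"] else ""
            print(f"  PLS-DA check: CV accuracy {pl['cv_accuracy']:.3f}, "
                  f"permutation p = {pl['p_value']:.3f}{flag}")
            (out / "plsda.json").write_text(json.dumps(pl, sort_keys=True))


if __name__ == "__main__":
    main()
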