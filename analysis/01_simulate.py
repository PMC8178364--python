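"""Generate the synthetic four-group cohort used by the downstream stages.

Writes an HDF5 cohort container plus the ground-truth effect map (which
regions/edges were planted, for which groups) under results/cohort/.
The cohort is reduced-scale — 20 regions, alpha band, 80 subjects — so the
whole analysis chain runs on a laptop; the planted structure follows the
standard configuration: three regional alpha power elevations and two
alpha envelope couplings distributed over the PTSD, mTBI and
trauma-exposed-control groups.
"""

import argparse
import json
from pathlib import Path

from megstrat.cohort import save_cohort_hdf5
from megstrat.pipeline import simulate_standard_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", default=str(ROOT / "results" / "cohort"))
    args = ap.parse_args()

    config, (cohort, ground_truth) = simulate_standard_cohort(seed=args.seed)
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_cohort_hdf5(out / "cohort.h5", cohort, ground_truth)
    (out / "ground_truth.json").write_text(
        json.dumps(ground_truth, indent=2, sort_keys=True))

    n = len(cohort)
    counts = {}
    for rec in cohort:
        counts[rec.group] = counts.get(rec.group, 0) + 1
    print(f"wrote {n} subjects ({counts}) at fs={config.fs} Hz, "
          f"{config.n_epochs} epochs x {config.epoch_len} s, "
          f"{config.n_regions} regions -> {out / 'cohort.h5'}")
    print(f"planted effects: {len(ground_truth['effects'])} "
          f"(see {out / 'ground_truth.json'})")


if __name__ == "__main__":
    main()
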