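"""Derive the two neural feature sets from the cohort.

Regional alpha band power (Welch, log10) and alpha-band amplitude envelope
correlation edges (leakage-corrected) are written as subjects x features
CSVs under results/features/. With 20 regions this gives 20 power features
and 190 AEC edges per band (the 90-region study scale would give 90 and
4005).
"""

import argparse
from pathlib import Path

from megstrat.bands import BAND_MAP
from megstrat.cohort import load_cohort_hdf5
from megstrat.pipeline import compute_features

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default=str(ROOT / "results" / "cohort" / "cohort.h5"))
    ap.add_argument("--bands", default="alpha")
    ap.add_argument("--out-dir", default=str(ROOT / "results" / "features"))
    args = ap.parse_args()

    cohort, _ = load_cohort_hdf5(args.cohort)
    bands = tuple(BAND_MAP[b] for b in args.bands.split(","))
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ftype in ("power", "aec"):
        fm = compute_features(cohort, bands, ftype)
        fm.to_csv(out / f"features_{ftype}.csv")
        print(f"{ftype}: {fm.n_subjects} subjects x {fm.n_features} features "
              f"-> {out / f'features_{ftype}.csv'}")


if __name__ == "__main__":
    main()
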