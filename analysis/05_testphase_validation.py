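"""Does end-of-round uncertainty predict test performance?

Validates the observer model on the threshold cohort's simulated test phase:
bins test accuracy by the observer's end-of-round entropy (10 equal-count
bins), fits a logistic curve of accuracy on entropy, and summarizes
confidence for correct versus error answers.  Accuracy should fall from
near-perfect at low entropy to chance at the entropy ceiling (ln 2).

Writes results/validation_bins.csv and results/validation.json.
"""

import argparse
import json
from pathlib import Path

from cardexplore.agents import SimDataset
from cardexplore.testphase import validate_observer


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=15)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    ds = SimDataset.read(args.out / "datasets" / "threshold")
    v = validate_observer(ds.tests, n_bins=10)
    v.bins.to_csv(args.out / "validation_bins.csv", index=False)
    with open(args.out / "validation.json", "w") as fh:
        json.dump({"slope": v.slope, "slope_se": v.slope_se,
                   "intercept": v.intercept, "n_records": v.n_records,
                   "monotone_decreasing": v.is_monotone_decreasing(se_tol=2.0)},
                  fh, indent=2)

    print(v.bins[["mean_entropy", "accuracy", "accuracy_se",
                  "confidence_correct", "confidence_error"]].round(3).to_string())
    print(f"\naccuracy ~ entropy logistic slope: {v.slope:+.2f} "
          f"(SE {v.slope_se:.2f}); monotone decline: "
          f"{v.is_monotone_decreasing(se_tol=2.0)}")


if __name__ == "__main__":
    main()
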