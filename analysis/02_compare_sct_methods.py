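"""Run the four sCT methods over the cohort and score each against CT.

For every case: build the bulk-density, tissue-class, multi-atlas
(leave-one-out) and cGAN (cross-validated desk profile) synthetic CTs,
recompute the arc dose on CT and on each sCT with frozen beam weights,
and collect ICRU-point and DVH percentage dose differences, 3D gamma
pass rates at 3%/2 mm, 2%/2 mm and 1%/1 mm, and HU mean / mean-absolute
errors by region.  An identity method (sCT := CT) runs alongside as the
pipeline null control.

Writes results/experiment/per_case_metrics.csv and cohort_summary.csv.

Usage: python analysis/02_compare_sct_methods.py [--n 4] [--seed 1]
"""

import argparse
import importlib.util
import logging
import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mrisct.pipeline import ExperimentConfig, run_experiment  # noqa: E402

_spec = importlib.util.spec_from_file_location(
    "cohort_builder", Path(__file__).parent / "01_simulate_cohort.py"
)
cohort_builder = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(cohort_builder)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=4)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument(
        "--methods", default="identity,bulk,tissue_class,atlas,cgan",
        help="comma-separated subset of the methods to run",
    )
    ap.add_argument("--out", type=Path, default=Path("results/experiment"))
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

    cases, groups = cohort_builder.build_cohort(args.n, args.seed)
    cfg = ExperimentConfig(methods=tuple(args.methods.split(",")), seed=args.seed)
    t0 = time.perf_counter()
    per_case, summary = run_experiment(cases, cfg, groups=groups, out_dir=args.out)
    elapsed = time.perf_counter() - t0

    print(f"\nScored {len(cases)} cases x {len(cfg.methods)} methods "
          f"in {elapsed / 60:.1f} min; {per_case.attrs['failures']} failures.")
    wide = per_case.pivot_table(index="metric", columns="method", values="value", aggfunc="mean")
    print(wide.round(2).to_string())
    print("\nExpected pattern: the identity control is exactly zero-error; the "
          "density-assignment methods carry the largest HU and dose errors, the "
          "atlas method the smallest; every method degrades monotonically along "
          "the gamma criteria ladder. Tables under", args.out)


if __name__ == "__main__":
    main()
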