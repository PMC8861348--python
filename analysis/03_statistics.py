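"""Cohort statistics over the per-case metrics of the method comparison.

Summarizes each metric as median (IQR) or mean +/- SD per method, tests
each sCT method's ICRU percentage dose difference against the identity
control and between methods with the Mann-Whitney U test (alpha = 0.05),
and writes results/method_statistics.csv.

Run analysis/02_compare_sct_methods.py first.
"""

import argparse
import itertools
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mrisct.evaluation import mann_whitney_u, summarize_cohort  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--metrics", type=Path, default=Path("results/experiment/per_case_metrics.csv"))
    args = ap.parse_args()

    per_case = pd.read_csv(args.metrics)
    per_case = per_case[per_case.metric != "failed"]
    summary = summarize_cohort(per_case)
    summary.to_csv("results/method_statistics.csv", index=False)

    methods = [m for m in per_case.method.unique() if m != "identity"]
    print("ICRU %DD by method (median [IQR]):")
    icru = per_case[per_case.metric == "icru_pdd"]
    for m in methods:
        row = summary[(summary.method == m) & (summary.metric == "icru_pdd")].iloc[0]
        print(f"  {m:>12}: {row['median']:+.2f}%  [{row['iqr_low']:+.2f}, {row['iqr_high']:+.2f}]")

    print("\nPairwise Mann-Whitney U on ICRU %DD (two-sided):")
    any_sig = False
    for a, b in itertools.combinations(methods, 2):
        res = mann_whitney_u(
            icru[icru.method == a].value.to_numpy(),
            icru[icru.method == b].value.to_numpy(),
        )
        flag = " *" if res.p_value < 0.05 else ""
        any_sig |= res.p_value < 0.05
        print(f"  {a} vs {b}: U={res.u:.1f}, p={res.p_value:.3f} ({res.method}){flag}")
    print("\n" + ("At least one method pair differs significantly at alpha = 0.05."
                  if any_sig else
                  "No method pair reaches significance at alpha = 0.05 at this cohort size."))
    print("Full summary table: results/method_statistics.csv")


if __name__ == "__main__":
    main()
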