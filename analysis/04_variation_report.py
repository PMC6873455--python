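"""Rank HRRs, form quintiles, and report inter-quintile cost variation.

Reads the per-HRR adjusted-mean estimates from 03_fit_models.py, re-ranks
HRRs separately for every procedure x analysis (totals standardized-only,
totals case-mix adjusted, and each payment component), bootstraps quintile
confidence intervals, and prints the top-vs-bottom quintile spread in dollars
and as a percentage of the bottom quintile.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from bundlevar.payment_allocation import readmission_rate
from bundlevar.variation_report import build_report, render_text


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--estimates", type=Path, default=Path("results/estimates"))
    ap.add_argument("--episodes", type=Path, default=Path("results/episodes.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--boot", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    estimates = {}
    for path in sorted(args.estimates.glob("*_*.csv")):
        proc, label = path.stem.split("_", 1)
        estimates[(proc, label)] = pd.read_csv(path, dtype={"hrr_id": str})

    episodes = pd.read_csv(args.episodes)
    report = build_report(
        estimates,
        readmission_rates=readmission_rate(episodes),
        n_boot=args.boot,
        seed=args.seed,
    )
    report["quintiles"].to_csv(args.out / "report_quintiles.csv", index=False)
    (args.out / "report_summary.json").write_text(json.dumps(report["summary"], indent=1))
    text = render_text(report)
    (args.out / "report.txt").write_text(text)
    print(text)


if __name__ == "__main__":
    main()
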