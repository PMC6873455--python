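"""Standardize payments, build 90-day episodes, allocate the four components.

Reads the tables written by 01_simulate.py, price-standardizes every paid
amount against the wage-index crosswalk, identifies index admissions, applies
the exclusion cascade and the five-case HRR minimum, attaches the six-month
lookback, and buckets every in-window claim into index hospitalization /
readmissions / post-acute care / professional fees.  Writes the episode table
and the exclusion tallies under results/.
"""

import argparse
from pathlib import Path

from bundlevar.config import default_procedure_defs
from bundlevar.episode_builder import build_episodes
from bundlevar.io_cli import read_table, write_table
from bundlevar.payment_allocation import allocate_payments, readmission_rate
from bundlevar.price_standardizer import standardize_claims


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    claims = read_table(args.data / "claims.csv", "claims")
    beneficiaries = read_table(args.data / "beneficiaries.csv", "beneficiaries")
    crosswalk = read_table(args.data / "crosswalk.csv", "crosswalk")

    std = standardize_claims(claims, crosswalk)
    built = build_episodes(std, beneficiaries, crosswalk, default_procedure_defs())
    episodes, assignments = allocate_payments(built["episodes"], std)

    write_table(episodes, args.out / "episodes.csv")
    write_table(assignments, args.out / "claim_assignments.csv")
    write_table(built["exclusion_tally"], args.out / "exclusion_tally.csv")
    write_table(built["small_hrr_tally"], args.out / "small_hrr_tally.csv")

    inc = episodes[episodes["status"] == "included"]
    print(f"{built['n_candidates']} candidates -> {len(inc)} included episodes")
    excl = episodes.loc[episodes["status"] == "excluded", "exclusion_reason"].value_counts()
    print(f"  exclusions by reason: {excl.to_dict()}")
    rates = readmission_rate(episodes)
    print("  readmission rates: " + ", ".join(f"{p} {100*r:.0f}%" for p, r in rates.items()))
    print(f"  mean standardized episode total: ${inc['total'].mean():,.0f}")


if __name__ == "__main__":
    main()
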