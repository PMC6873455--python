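"""Fit the case-mix model and shrink regional cost ratios, per procedure.

For each procedure with at least five qualifying HRRs this fits: the
intercept-only model (price-standardized-only analysis), the full case-mix
model for episode totals, and the four payment-component models.  Each fit
yields per-HRR observed/expected totals, reliability weights, empirical-Bayes
ratios and adjusted mean costs, written under results/estimates/.
"""

import argparse
from pathlib import Path

import pandas as pd

from bundlevar.casemix_shrinkage import compute_hrr_estimates, fit_casemix_model
from bundlevar.io_cli import _ANALYSES, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--episodes", type=Path, default=Path("results/episodes.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    episodes = pd.read_csv(args.episodes, dtype={"hrr_id": str, "race": str})
    inc = episodes[episodes["status"] == "included"]
    fit_rows = []
    for proc in sorted(inc["procedure"].unique()):
        sub = inc[inc["procedure"] == proc]
        if sub["hrr_id"].nunique() < 5:
            print(f"{proc}: fewer than 5 HRRs, skipped")
            continue
        casemix_fit = None
        for label, outcome, covs in _ANALYSES:
            fit = fit_casemix_model(
                sub, outcome, covariates=covs,
                total_fit=casemix_fit if outcome != "total" else None,
            )
            if label == "casemix":
                casemix_fit = fit
            est = compute_hrr_estimates(fit)
            write_table(est, args.out / "estimates" / f"{proc}_{label}.csv")
            fit_rows.append(
                {"procedure": proc, "analysis": label, "phi": fit.phi,
                 "tau_hat": fit.tau_hat, "n_iter": fit.n_iter,
                 "converged": fit.converged,
                 **{f"beta.{k}": v for k, v in fit.beta.items()}}
            )
            flag = "" if fit.converged else "  [not converged]"
            print(f"{proc:10s} {label:22s} tau_hat={fit.tau_hat:.4f} "
                  f"phi={fit.phi:.3g} iters={fit.n_iter}{flag}")
    write_table(pd.DataFrame(fit_rows), args.out / "fit_summary.csv")


if __name__ == "__main__":
    main()
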