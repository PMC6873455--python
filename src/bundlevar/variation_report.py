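"""Quintile ranking of HRRs and inter-quintile variation statistics.

HRRs are sorted ascending by adjusted mean cost (ties broken by HRR id) and
cut into five near-equal groups: rank ``k`` of ``J`` falls in the smallest
quintile ``q`` with ``k <= ceil(q*J/5)``.  Quintile averages are unweighted
means of member-HRR adjusted means, with seeded percentile-bootstrap
confidence intervals.  The headline statistic is the spread between the top
and bottom quintile, in dollars (Q5 - Q1) and as a percentage of Q1 — both
rounded half away from zero, dollars to whole dollars and percentages to
whole percent, as cost tables conventionally print them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass
class VariationStat:
    abs_difference: int  # dollars, Q5 mean - Q1 mean
    pct_difference: int | None  # percent of Q1 mean; None when Q1 <= 0


def rank_and_quintile(estimates: pd.DataFrame, quantity: str = "adjusted_mean") -> pd.DataFrame:
    """Assign each HRR a rank and quintile on the chosen quantity.

    Requires at least 5 HRRs.  Deterministic: equal values order by
    ``hrr_id``.
    """
    J = len(estimates)
    if J < 5:
        raise ValueError(f"need at least 5 HRRs to form quintiles, got {J}")
    out = estimates.sort_values([quantity, "hrr_id"]).reset_index(drop=True)
    ranks = np.arange(1, J + 1)
    cutoffs = [math.ceil(q * J / 5) for q in range(1, 6)]
    out["rank"] = ranks
    out["quintile"] = [next(q + 1 for q, c in enumerate(cutoffs) if k <= c) for k in ranks]
    return out


def quintile_means(
    assignment: pd.DataFrame,
    quantity: str = "adjusted_mean",
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Unweighted quintile means with seeded percentile-bootstrap 95% CIs.

    A single-member quintile gets a degenerate CI equal to its mean and is
    flagged.  Fixed seed and input give identical CIs across runs.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for q in range(1, 6):
        members = assignment.loc[assignment["quintile"] == q, quantity].to_numpy(float)
        hrrs = assignment.loc[assignment["quintile"] == q, "hrr_id"].tolist()
        mean = float(members.mean())
        if len(members) > 1:
            boots = rng.choice(members, size=(n_boot, len(members)), replace=True).mean(axis=1)
            lo, hi = np.percentile(boots, [2.5, 97.5])
            degenerate = False
        else:
            lo = hi = mean
            degenerate = True
        rows.append(
            {
                "quintile": q,
                "hrr_count": len(members),
                "mean_payment": mean,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "ci_degenerate": degenerate,
                "member_hrrs": hrrs,
            }
        )
    return pd.DataFrame(rows)


def interquintile_stats(q1_mean: float, q5_mean: float) -> VariationStat:
    """Top-minus-bottom quintile spread in dollars and percent of Q1.

    The percentage is undefined (None) when the bottom-quintile mean is not
    positive; the dollar difference is still returned.
    """
    abs_diff = round_half_away(q5_mean - q1_mean)
    pct = round_half_away(100.0 * (q5_mean - q1_mean) / q1_mean) if q1_mean > 0 else None
    return VariationStat(abs_difference=abs_diff, pct_difference=pct)


def summarize_estimates(
    estimates: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> tuple[pd.DataFrame, VariationStat]:
    """Rank -> quintile -> means + CIs -> inter-quintile spread, in one call."""
    assignment = rank_and_quintile(estimates)
    qm = quintile_means(assignment, n_boot=n_boot, seed=seed)
    stat = interquintile_stats(
        float(qm.loc[qm["quintile"] == 1, "mean_payment"].iloc[0]),
        float(qm.loc[qm["quintile"] == 5, "mean_payment"].iloc[0]),
    )
    return qm, stat


def build_report(
    estimates_by_key: dict[tuple[str, str], pd.DataFrame],
    readmission_rates: pd.Series | None = None,
    exclusion_tally: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Assemble the variation tables for every procedure x analysis key.

    ``estimates_by_key`` maps ``(procedure, label)`` to an HRR-estimates
    table, where ``label`` is ``"price_std"`` (standardized only),
    ``"casemix"`` (total, fully adjusted) or a payment component.  Each
    procedure gets a totals block (standardized and adjusted rows, Table-1
    shape) and a per-component block with its own re-ranked quintiles
    (Table-2 shape).  Missing components are omitted with a warning row in
    the summary.  Every quintile set is re-ranked on its own quantity.
    """
    quintile_rows = []
    summary: dict[str, float | int | None] = {}
    warnings_list = []
    for (proc, label), est in sorted(estimates_by_key.items()):
        if est is None or est.empty:
            warnings_list.append(f"missing estimates for {proc}/{label}; row omitted")
            continue
        qm, stat = summarize_estimates(est, n_boot=n_boot, seed=seed)
        for row in qm.itertuples(index=False):
            quintile_rows.append(
                {
                    "procedure": proc,
                    "analysis": label,
                    "quintile": row.quintile,
                    "hrr_count": row.hrr_count,
                    "mean_payment": round_half_away(row.mean_payment),
                    "ci_low": round_half_away(row.ci_low),
                    "ci_high": round_half_away(row.ci_high),
                }
            )
        summary[f"{proc}.{label}.abs_difference"] = stat.abs_difference
        summary[f"{proc}.{label}.pct_difference"] = stat.pct_difference
    if readmission_rates is not None:
        for proc, rate in readmission_rates.items():
            summary[f"{proc}.readmission_rate_pct"] = round_half_away(100.0 * rate)
    report = {
        "quintiles": pd.DataFrame(quintile_rows),
        "summary": summary,
        "warnings": warnings_list,
    }
    if exclusion_tally is not None:
        report["exclusions"] = exclusion_tally
    return report


def render_text(report: dict) -> str:
    """Plain-text rendering of the quintile tables and headline spreads."""
    lines = []
    q = report["quintiles"]
    for (proc, label), grp in q.groupby(["procedure", "analysis"], sort=True):
        lines.append(f"{proc} [{label}]")
        for row in grp.sort_values("quintile").itertuples(index=False):
            lines.append(
                f"  Q{row.quintile}: ${row.mean_payment:,}  "
                f"(95% CI ${row.ci_low:,}-${row.ci_high:,}; {row.hrr_count} HRRs)"
            )
        a = report["summary"].get(f"{proc}.{label}.abs_difference")
        p = report["summary"].get(f"{proc}.{label}.pct_difference")
        pct = f"{p}%" if p is not None else "undefined"
        lines.append(f"  Q5-Q1 difference: ${a:,} ({pct} of Q1)")
    return "\n".join(lines)
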