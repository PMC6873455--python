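"""Case-mix model and empirical-Bayes reliability adjustment per HRR.

Model
-----
Episode cost ``y_ij`` (episode ``i``, region ``j``) follows a log-link model
with a multiplicative regional effect:

    E[y_ij | u_j] = exp(x_ij' beta) * u_j,     u_j ~ Gamma(mean 1, variance tau)

with conditional variance ``phi * mu^2`` (gamma-type).  Estimation is an
iterative moment / quasi-likelihood scheme:

1. holding the regional effects fixed, estimate ``beta`` by a gamma-family
   log-link GLM with offset ``log u_hat_j``;
2. form case-mix-predicted costs ``mu_ij = exp(x_ij' beta)`` and the regional
   totals ``O_j = sum_i y_ij`` (observed) and ``E_j = sum_i mu_ij``
   (expected), giving indirectly standardized ratios ``r_j = O_j / E_j``;
3. ``phi`` = Pearson dispersion of the full fit;
4. ``tau_hat`` = moment estimate of the between-region variance,
   ``mean_j[(r_j - 1)^2 - phi * sum_i mu_ij^2 / E_j^2]``, floored;
5. shrink: ``u_hat_j = (alpha + O_j/phi) / (alpha + E_j/phi)`` with
   ``alpha = 1/tau_hat`` — equivalently ``w_j r_j + (1 - w_j)`` with
   reliability ``w_j = (E_j/phi) / (E_j/phi + alpha)``;

repeated until ``beta`` is stable.  The reliability weight grows with a
region's expected volume, so small regions are pulled harder toward the
national mean.  A region's adjusted mean cost is its shrunken ratio scaled by
the national average predicted cost (indirect standardization).

Payment components with zero-cost episodes (readmissions, post-acute care)
are handled by a share-scaled expected cost: ``mu_c = s_c * mu`` with ``s_c``
the national component share of predicted cost, followed by the same moment
steps 3-5 on component totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

TAU_FLOOR = 1e-8
PHI_FLOOR = 1e-12

#: outcome label -> episodes column
OUTCOME_COLUMNS = {
    "total": "total",
    "index": "index_hospitalization",
    "index_hospitalization": "index_hospitalization",
    "readmission": "readmissions",
    "readmissions": "readmissions",
    "postacute": "post_acute",
    "post_acute": "post_acute",
    "professional": "professional_fees",
    "professional_fees": "professional_fees",
}

DEFAULT_COVARIATES = (
    "intercept",
    "age10",
    "age10_sq",
    "female",
    "junior_enlisted",
    "charlson",
    "log1p_prior",
)


class SingularDesignError(ValueError):
    """The design matrix is rank deficient; names the offending columns."""


@dataclass
class ShrinkageFit:
    """Fitted case-mix model plus regional moment estimates."""

    beta: pd.Series
    phi: float
    tau_hat: float
    alpha_hat: float
    n_iter: int
    converged: bool
    outcome_label: str
    covariates: list[str]
    # per-episode / per-region internals used by compute_hrr_estimates
    mu: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    hrr: np.ndarray = field(repr=False, default=None)
    u_hat: pd.Series = field(repr=False, default=None)
    O: pd.Series = field(repr=False, default=None)
    E: pd.Series = field(repr=False, default=None)

    @property
    def at_floor(self) -> bool:
        """True when no between-HRR variation was detectable."""
        return self.tau_hat <= TAU_FLOOR


def default_covariates(episodes: pd.DataFrame, procedure: str | None = None) -> list[str]:
    """Covariate list for a procedure: demographics, comorbidity, prior
    spending, plus DRG weight / acuity / cancer management where applicable."""
    terms = list(DEFAULT_COVARIATES)
    sub = episodes if procedure is None else episodes[episodes["procedure"] == procedure]
    if "race" in sub.columns:
        # dummies only for non-reference categories actually observed
        cats = [c for c in sorted(sub["race"].unique()) if c not in ("white", "")]
        terms[4:4] = [f"race_{c}" for c in cats]
    if "drg_weight" in sub.columns and sub["drg_weight"].notna().all() and sub["drg_weight"].std() > 0:
        terms.append("drg_weight")
    if "emergent" in sub.columns and sub["emergent"].nunique() > 1:
        terms.append("emergent")
    if "cancer_management" in sub.columns and sub["cancer_management"].nunique() > 1:
        terms.append("cancer")
    return terms


def design_matrix(episodes: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Encode the case-mix vector: age linear+quadratic (decades, centered at
    45), indicator dummies, Charlson as integer, log1p of prior six-month
    payments (in $1000), DRG weight centered at 1."""
    cols = {}
    for term in covariates:
        if term == "intercept":
            cols[term] = np.ones(len(episodes))
        elif term == "age10":
            cols[term] = (episodes["age"].to_numpy(float) - 45.0) / 10.0
        elif term == "age10_sq":
            cols[term] = ((episodes["age"].to_numpy(float) - 45.0) / 10.0) ** 2
        elif term == "female":
            cols[term] = (episodes["sex"] == "F").to_numpy(float)
        elif term.startswith("race_"):
            cols[term] = (episodes["race"] == term[5:]).to_numpy(float)
        elif term == "junior_enlisted":
            cols[term] = (episodes["sponsor_rank_category"] == "junior_enlisted").to_numpy(float)
        elif term == "charlson":
            cols[term] = episodes["charlson"].to_numpy(float)
        elif term == "log1p_prior":
            cols[term] = np.log1p(episodes["prior_6mo_payments"].to_numpy(float) / 1000.0)
        elif term == "drg_weight":
            cols[term] = episodes["drg_weight"].to_numpy(float) - 1.0
        elif term == "emergent":
            cols[term] = episodes["emergent"].to_numpy(float)
        elif term == "cancer":
            cols[term] = episodes["cancer_management"].to_numpy(float)
        else:
            raise ValueError(f"unknown covariate term {term!r}")
    return pd.DataFrame(cols, index=episodes.index)


def _check_rank(X: pd.DataFrame) -> None:
    """Raise SingularDesignError naming columns adding no rank."""
    A = X.to_numpy(float)
    bad = []
    rank = 0
    kept = np.empty((A.shape[0], 0))
    for name, col in zip(X.columns, A.T):
        cand = np.column_stack([kept, col])
        r = np.linalg.matrix_rank(cand, tol=1e-8 * max(1.0, np.abs(A).max()))
        if r > rank:
            kept, rank = cand, r
        else:
            bad.append(name)
    if bad:
        raise SingularDesignError(f"collinear covariates: {bad}")


def eb_shrink(O: float, E: float, phi: float, alpha: float) -> float:
    """Empirical-Bayes shrunken observed/expected ratio.

    ``(alpha + O/phi) / (alpha + E/phi)``: exactly 1 when ``O == E``, pulled
    toward 1 as ``alpha`` (inverse between-region variance) grows, and never
    beyond the raw ratio ``O/E``.
    """
    if E <= 0 or phi <= 0 or alpha <= 0:
        raise ValueError(f"require E > 0, phi > 0, alpha > 0 (got {E=}, {phi=}, {alpha=})")
    if O < 0:
        raise ValueError(f"require O >= 0, got {O}")
    return (alpha + O / phi) / (alpha + E / phi)


def reliability_weight(E: float, phi: float, alpha: float) -> float:
    """Signal-to-(signal+noise) weight: ``(E/phi) / (E/phi + alpha)``."""
    if E <= 0 or phi <= 0 or alpha <= 0:
        raise ValueError(f"require E > 0, phi > 0, alpha > 0 (got {E=}, {phi=}, {alpha=})")
    return (E / phi) / (E / phi + alpha)


def _moment_steps(
    y: np.ndarray, mu: np.ndarray, hrr: pd.Series, phi: float, variance: str = "gamma"
) -> tuple[pd.Series, pd.Series, pd.Series, float]:
    """Steps 2, 4, 5: regional totals, tau-hat, shrunken ratios.

    ``variance`` names the conditional variance function behind the sampling
    term subtracted in the tau moment: ``"gamma"`` (var = phi mu^2, episode
    totals) or ``"linear"`` (var = phi mu, zero-inflated component totals).
    """
    df = pd.DataFrame({"y": y, "mu": mu, "mu2": mu**2, "hrr": np.asarray(hrr)})
    g = df.groupby("hrr")
    O = g["y"].sum()
    E = g["mu"].sum()
    r = O / E
    c = g["mu2"].sum() / E**2 if variance == "gamma" else 1.0 / E
    tau = max(TAU_FLOOR, float(np.mean((r - 1.0) ** 2 - phi * c)))
    alpha = 1.0 / tau
    u_hat = (alpha + O / phi) / (alpha + E / phi)
    return O, E, u_hat, tau


def fit_casemix_model(
    episodes: pd.DataFrame,
    outcome_label: str = "total",
    covariates: list[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
    total_fit: "ShrinkageFit | None" = None,
) -> ShrinkageFit:
    """Fit the log-link case-mix model with a multiplicative HRR effect.

    Operates on included episodes only.  For the episode total (strictly
    positive) the full iterative scheme runs; for a payment component with
    zeros the expected component cost is the national component share of the
    total-model prediction and only the moment/shrinkage steps iterate (the
    documented single approach for zero-inflated components).

    Returns a :class:`ShrinkageFit`; non-convergence yields ``converged=False``
    plus a warning rather than an exception.
    """
    if outcome_label not in OUTCOME_COLUMNS:
        raise ValueError(f"unknown outcome_label {outcome_label!r}")
    col = OUTCOME_COLUMNS[outcome_label]
    inc = episodes[episodes["status"] == "included"] if "status" in episodes.columns else episodes
    if inc["hrr_id"].nunique() < 2:
        raise ValueError("need episodes from at least 2 HRRs")
    if covariates is None:
        covariates = default_covariates(inc)

    y_comp = inc[col].to_numpy(float)
    if (y_comp <= 0).any() and col != "total":
        if total_fit is None:
            total_fit = fit_casemix_model(inc, "total", covariates=covariates,
                                          max_iter=max_iter, tol=tol)
        return _fit_component_from_total(total_fit, inc, col, outcome_label)
    if (y_comp <= 0).any():
        raise ValueError("episode totals must be strictly positive")

    X = design_matrix(inc, covariates)
    _check_rank(X)
    y = y_comp
    hrr = inc["hrr_id"].to_numpy()
    hrr_s = pd.Series(hrr)

    # Offsets carry a gauge-fixed copy of the regional effects: the intercept
    # and a common scale of all u_j trade off along a neutral direction (all
    # fitted means invariant), which otherwise drifts indefinitely.  Pinning
    # mean(log u) = 0 in the offsets removes the drift; the reported u_hat,
    # O, E, phi, tau come from the shrinkage formula itself on the final beta.
    u_gauge = pd.Series(1.0, index=pd.unique(hrr))
    u_hat = u_gauge
    beta_prev = None
    n, p = X.shape
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        offset = np.log(u_gauge.loc[hrr].to_numpy())
        if beta_prev is None:
            # log-scale least squares: robust start even for degenerate
            # zero-residual outcomes where the IRLS default guess fails
            start = np.linalg.lstsq(X.to_numpy(float), np.log(y) - offset, rcond=None)[0]
        else:
            start = beta_prev.to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(
                y, X, family=sm.families.Gamma(link=sm.families.links.Log()), offset=offset
            ).fit(tol=1e-12, start_params=start)
        beta = glm.params
        mu = np.exp(X.to_numpy(float) @ beta.to_numpy())
        mu_full = mu * u_gauge.loc[hrr].to_numpy()
        phi = max(PHI_FLOOR, float(np.sum((y - mu_full) ** 2 / mu_full**2) / max(n - p, 1)))
        O, E, u_hat, tau = _moment_steps(y, mu, hrr_s, phi)
        u_gauge = u_hat / np.exp(np.mean(np.log(u_hat)))
        if beta_prev is not None and np.max(np.abs(beta - beta_prev)) < tol:
            converged = True
            break
        beta_prev = beta
    if not converged:
        warnings.warn(
            f"case-mix fit for {outcome_label!r} did not converge in {max_iter} iterations",
            RuntimeWarning,
        )
    return ShrinkageFit(
        beta=beta,
        phi=phi,
        tau_hat=tau,
        alpha_hat=1.0 / tau,
        n_iter=it,
        converged=converged,
        outcome_label=outcome_label,
        covariates=list(covariates),
        mu=mu,
        y=y,
        hrr=hrr,
        u_hat=u_hat,
        O=O,
        E=E,
    )


def _fit_component_from_total(
    total_fit: ShrinkageFit, inc: pd.DataFrame, col: str, outcome_label: str
) -> ShrinkageFit:
    """Component moment fit: share-scaled expected costs, iterated steps 3-5.

    Component totals are zero for many episodes (most episodes have no
    readmission), so the conditional variance is taken linear in the mean
    (quasi-Poisson-type, ``phi * mu``) rather than gamma-type; the shrinkage
    formula is then exactly the gamma-Poisson conjugate posterior mean on
    dispersion-scaled totals.
    """
    y = inc[col].to_numpy(float)
    share = float(y.sum() / total_fit.mu.sum())
    if share <= 0:
        raise ValueError(f"component {outcome_label!r} has no payments anywhere")
    mu = share * total_fit.mu
    hrr_s = pd.Series(total_fit.hrr)
    n = len(y)
    J = hrr_s.nunique()
    # within-region dispersion: residuals against mu * r_j so the between-HRR
    # signal does not inflate the sampling term subtracted in the tau moment
    r_by_hrr = (
        pd.DataFrame({"y": y, "mu": mu, "hrr": hrr_s.to_numpy()})
        .groupby("hrr")
        .sum()
        .eval("y / mu")
    )
    mu_r = mu * r_by_hrr.loc[total_fit.hrr].to_numpy()
    # an HRR with r_j = 0 has every component outcome at zero: its residuals
    # are identically zero and contribute nothing to the dispersion
    resid = np.where(mu_r > 0, (y - mu_r) ** 2 / np.where(mu_r > 0, mu_r, 1.0), 0.0)
    phi = max(PHI_FLOOR, float(np.sum(resid) / max(n - J, 1)))
    O, E, u_hat, tau = _moment_steps(y, mu, hrr_s, phi, variance="linear")
    it = 1
    beta = total_fit.beta.copy()
    beta["intercept"] = beta.get("intercept", 0.0) + np.log(share)
    return ShrinkageFit(
        beta=beta,
        phi=phi,
        tau_hat=tau,
        alpha_hat=1.0 / tau,
        n_iter=it,
        converged=True,
        outcome_label=outcome_label,
        covariates=list(total_fit.covariates),
        mu=mu,
        y=y,
        hrr=total_fit.hrr,
        u_hat=u_hat,
        O=O,
        E=E,
    )


def compute_hrr_estimates(fit: ShrinkageFit, hrr_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-HRR observed/expected totals, reliability, EB ratio, adjusted mean.

    ``adjusted_mean_j = u_hat_j * mean(mu)`` — the shrunken ratio scaled by
    the national average case-mix-predicted cost, so a region with
    ``u_hat = 1`` sits exactly at the national mean.
    """
    national_mean = float(np.mean(fit.mu))
    df = pd.DataFrame({"hrr_id": fit.O.index})
    if hrr_ids is not None:
        missing = set(hrr_ids) - set(fit.O.index)
        if missing:
            raise KeyError(f"HRRs absent from fit: {sorted(missing)}")
        df = pd.DataFrame({"hrr_id": list(hrr_ids)})
    counts = pd.Series(fit.hrr).value_counts()
    df["n_episodes"] = df["hrr_id"].map(counts).astype(int)
    df["observed_total"] = df["hrr_id"].map(fit.O)
    df["expected_total"] = df["hrr_id"].map(fit.E)
    df["ratio"] = df["observed_total"] / df["expected_total"]
    df["reliability"] = [
        reliability_weight(e, fit.phi, fit.alpha_hat) for e in df["expected_total"]
    ]
    df["eb_ratio"] = df["hrr_id"].map(fit.u_hat)
    df["adjusted_mean"] = df["eb_ratio"] * national_mean
    return df.sort_values("hrr_id").reset_index(drop=True)
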