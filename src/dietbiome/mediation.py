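"""Quasi-Bayesian causal mediation for continuous mediator and outcome.

For each (exposure X, mediator M) pair with outcome Y and covariates C,
two OLS models are fitted:

    mediator model:  M ~ X + C        (coefficient a)
    outcome  model:  Y ~ X + M + C    (coefficients c' and b)

``n_sims`` coefficient vectors are then drawn from each model's
asymptotic multivariate normal (mean = estimates, covariance = estimated
classical covariance; robust covariance by flag), and per draw

    ACME = a·b,   ADE = c',   total = a·b + c'.

Point estimates are across-draw means, intervals are percentile
intervals, and the ACME p-value is the two-sided simulation p
``2·min(frac ≤ 0, frac ≥ 0)`` floored at ``1/n_sims``. The proportion
mediated is the across-draw median of ACME/total, computed only on draws
whose total effect agrees in sign with the point-estimate total (ratio
instability guard); results where most draws are sign-discordant are
flagged unstable rather than raised.

In this linear–linear case the identity ``ACME + ADE = total`` holds for
every draw, hence also for the point estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._utils import child_rng
from .associations import _design, bh_fdr, bonferroni

logger = logging.getLogger("dietbiome.mediation")

__all__ = ["MediationResult", "fit_mediation", "proportion_mediated",
           "mediation_scan"]


@dataclass
class MediationResult:
    exposure: str
    mediator: str
    outcome: str
    acme: float
    acme_ci: tuple[float, float]
    ade: float
    ade_ci: tuple[float, float]
    total: float
    total_ci: tuple[float, float]
    prop_mediated_pct: float
    prop_mediated_ci_pct: tuple[float, float]
    p_acme: float
    n: int
    n_sims: int
    unstable: bool
    q_acme: float | None = None
    family: str | None = None


def _percentile_ci(draws: np.ndarray, level: float) -> tuple[float, float]:
    lo = 100 * (1 - level) / 2
    return (float(np.percentile(draws, lo)),
            float(np.percentile(draws, 100 - lo)))


def proportion_mediated(acme_draws: np.ndarray, total_draws: np.ndarray,
                        ci_level: float = 0.95):
    """Median and percentile CI of ACME/total across draws, restricted to
    draws whose total effect matches the sign of the point-estimate
    total. Returns (median_pct, ci_pct, unstable_flag)."""
    total_point = total_draws.mean()
    concordant = np.sign(total_draws) == np.sign(total_point)
    unstable = concordant.mean() < 0.5 or total_point == 0
    if not concordant.any():
        return float("nan"), (float("nan"), float("nan")), True
    ratio = acme_draws[concordant] / total_draws[concordant]
    ci = _percentile_ci(100 * ratio, ci_level)
    return float(100 * np.median(ratio)), ci, bool(unstable)


def fit_mediation(data: pd.DataFrame, outcome: str, exposure: str,
                  mediator: str, covariates=(), n_sims: int = 1000,
                  seed: int = 0, ci_level: float = 0.95,
                  robust: bool = False) -> MediationResult:
    """Quasi-Bayesian Monte-Carlo mediation estimate for one pair."""
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    if mediator in covariates:
        raise ValueError("mediator must not appear among covariates")
    cols = [outcome, exposure, mediator, *covariates]
    df = data[cols].dropna()
    n = len(df)
    C = _design(df, list(covariates))

    Xm = sm.add_constant(pd.concat([df[[exposure]].astype(float), C], axis=1))
    Xy = sm.add_constant(pd.concat([df[[exposure]].astype(float),
                                    df[[mediator]].astype(float), C], axis=1))
    for name, X in (("mediator", Xm), ("outcome", Xy)):
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError(f"{name} model design is rank-deficient")

    mfit = sm.OLS(df[mediator].astype(float), Xm).fit()
    yfit = sm.OLS(df[outcome].astype(float), Xy).fit()
    mcov = mfit.cov_HC1 if robust else mfit.cov_params().to_numpy()
    ycov = yfit.cov_HC1 if robust else yfit.cov_params().to_numpy()

    # one stream per seed (not per pair): duplicate mediator columns then
    # reproduce identical draws and hence identical estimates
    rng = child_rng(seed, "mediation-draws")
    mdraws = rng.multivariate_normal(mfit.params.to_numpy(), mcov,
                                     size=n_sims, method="cholesky")
    ydraws = rng.multivariate_normal(yfit.params.to_numpy(), ycov,
                                     size=n_sims, method="cholesky")
    a = mdraws[:, Xm.columns.get_loc(exposure)]
    b = ydraws[:, Xy.columns.get_loc(mediator)]
    cp = ydraws[:, Xy.columns.get_loc(exposure)]

    acme = a * b
    ade = cp
    total = acme + ade
    frac_le = (acme <= 0).mean()
    frac_ge = (acme >= 0).mean()
    p_acme = max(2 * min(frac_le, frac_ge), 1.0 / n_sims)
    prop, prop_ci, unstable = proportion_mediated(acme, total, ci_level)
    if unstable:
        logger.warning("mediation %s->%s->%s: proportion mediated unstable "
                       "(near-zero total effect)", exposure, mediator,
                       outcome)
    return MediationResult(
        exposure=exposure, mediator=mediator, outcome=outcome,
        acme=float(acme.mean()), acme_ci=_percentile_ci(acme, ci_level),
        ade=float(ade.mean()), ade_ci=_percentile_ci(ade, ci_level),
        total=float(total.mean()), total_ci=_percentile_ci(total, ci_level),
        prop_mediated_pct=prop, prop_mediated_ci_pct=prop_ci,
        p_acme=float(min(p_acme, 1.0)), n=n, n_sims=n_sims,
        unstable=unstable)


def mediation_scan(data: pd.DataFrame, outcome: str, exposures,
                   mediators, covariates=(), taxa_mediators=(),
                   n_sims: int = 1000, seed: int = 0) -> pd.DataFrame:
    """One mediation fit per (exposure, mediator) pair, with adjusted
    ACME p-values per exposure: BH across non-taxa mediators, Bonferroni
    across taxa mediators (separate families). Failing pairs are logged
    and skipped."""
    taxa = set(taxa_mediators)
    rows = []
    for exposure in exposures:
        for mediator in mediators:
            try:
                res = fit_mediation(data, outcome, exposure, mediator,
                                    covariates=covariates, n_sims=n_sims,
                                    seed=seed)
            except Exception as exc:
                logger.warning("mediation %s -> %s failed: %s", exposure,
                               mediator, exc)
                continue
            res.family = ("taxa" if mediator in taxa else "features")
            rows.append(res)
    out = pd.DataFrame([{
        "exposure": r.exposure, "mediator": r.mediator, "outcome": r.outcome,
        "family": r.family, "acme": r.acme,
        "acme_ci_low": r.acme_ci[0], "acme_ci_high": r.acme_ci[1],
        "ade": r.ade, "ade_ci_low": r.ade_ci[0], "ade_ci_high": r.ade_ci[1],
        "total": r.total, "total_ci_low": r.total_ci[0],
        "total_ci_high": r.total_ci[1],
        "prop_mediated_pct": r.prop_mediated_pct,
        "p_acme": r.p_acme, "n": r.n, "n_sims": r.n_sims,
        "unstable": r.unstable,
    } for r in rows])
    if out.empty:
        return out
    out["q_acme"] = np.nan
    for exposure in out["exposure"].unique():
        for fam, adjust in (("features", bh_fdr), ("taxa", bonferroni)):
            mask = (out["exposure"] == exposure) & (out["family"] == fam)
            if mask.any():
                out.loc[mask, "q_acme"] = adjust(
                    out.loc[mask, "p_acme"].to_numpy())
    return out
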