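"""Covariate-adjusted association testing.

Four engines shared by the analysis stages:

* multiple linear regression with standardized beta coefficients
  (``β·SD(x)/SD(y)``) and delta-method confidence intervals;
* multiple-testing adjustment (Benjamini–Hochberg step-up FDR and
  Bonferroni) with the test family always an explicit argument;
* distance-based PERMANOVA with covariate adjustment: marginal
  (type-III-like) sums of squares with Freedman–Lane permutation of
  reduced-model residuals by default, sequential decomposition by flag;
* partial Spearman correlation (rank, residualize on covariates, Pearson
  on residuals) and a two-part (hurdle) differential-abundance model
  (logistic presence/absence sub-model + OLS on log relative abundance
  among non-zero samples).

Categorical covariates (sex, study cohort) are expanded to indicator
columns with the first observed level as reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import child_rng
from .features import filter_genera, tss

logger = logging.getLogger("dietbiome.associations")

__all__ = [
    "AssociationResult", "PermanovaResult", "fit_adjusted_lm", "bh_fdr",
    "bonferroni", "permanova", "partial_spearman", "hurdle_diff_abundance",
]


@dataclass
class AssociationResult:
    exposure: str
    outcome: str
    std_beta: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    beta_raw: float
    se_raw: float
    q: float | None = None
    family: str | None = None


@dataclass
class PermanovaResult:
    term: str
    r2: float
    pseudo_f: float
    p_perm: float
    df: int
    n_perm: int
    q: float | None = None
    terms: pd.DataFrame | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# design helpers

def _design(data: pd.DataFrame, cols) -> pd.DataFrame:
    """Numeric design block for the named columns; categoricals become
    indicator columns (reference = first observed level, logged)."""
    if not cols:
        return pd.DataFrame(index=data.index)
    blocks = []
    for c in cols:
        s = data[c]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=c, drop_first=True,
                                     dtype=float)
            logger.debug("column %r encoded with reference level %r", c,
                         sorted(s.dropna().unique())[0])
            blocks.append(dummies)
        else:
            blocks.append(s.astype(float).to_frame(c))
    return pd.concat(blocks, axis=1)


def fit_adjusted_lm(data: pd.DataFrame, outcome: str, exposure: str,
                    covariates=(), family: str | None = None
                    ) -> AssociationResult:
    """OLS of outcome on exposure + covariates with standardized beta.

    ``std_beta = β̂·SD(exposure)/SD(outcome)``; its CI is the raw
    coefficient CI mapped through the same (fixed-SD delta-method) scale.
    """
    if exposure in covariates:
        raise ValueError("exposure must not appear among covariates")
    cols = [outcome, exposure, *covariates]
    df = data[cols].dropna()
    X = pd.concat([df[[exposure]].astype(float),
                   _design(df, list(covariates))], axis=1)
    if df[exposure].nunique() < 2:
        raise ValueError("exposure is constant")
    if len(df) < X.shape[1] + 2:
        raise ValueError("too few complete cases for the model")
    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # name the aliased columns for the caller
        aliased = []
        keep: list[str] = []
        for c in Xc.columns:
            trial = Xc[keep + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) < len(keep) + 1:
                aliased.append(c)
            else:
                keep.append(c)
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    fit = sm.OLS(df[outcome].astype(float), Xc).fit()
    b = fit.params[exposure]
    se = fit.bse[exposure]
    scale = df[exposure].std(ddof=1) / df[outcome].std(ddof=1)
    tcrit = stats.t.ppf(0.975, fit.df_resid)
    return AssociationResult(
        exposure=exposure, outcome=outcome,
        std_beta=b * scale,
        ci_low=(b - tcrit * se) * scale, ci_high=(b + tcrit * se) * scale,
        p=float(fit.pvalues[exposure]), n=len(df),
        beta_raw=float(b), se_raw=float(se), family=family)


# ---------------------------------------------------------------------------
# multiple testing

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni(pvalues) -> np.ndarray:
    """q = min(1, m·p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p.size * p, 1.0)


# ---------------------------------------------------------------------------
# PERMANOVA

def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def permanova(D, data: pd.DataFrame, exposure: str, covariates=(),
              n_perm: int = 999, seed: int = 0,
              by: str = "margin") -> PermanovaResult:
    """Distance-based multivariate ANOVA for one exposure term.

    The squared distance matrix is Gower-centered; the exposure's pseudo-F
    uses marginal sums of squares given the covariates (``by="margin"``,
    default) or sequential SS with the exposure last (``by="terms"``).
    The permutation p-value follows the Freedman–Lane scheme: residuals
    of the covariate-only model are permuted, p = (1 + #{F* >= F}) /
    (1 + n_perm). The ``terms`` attribute carries the full sequential
    R² decomposition (terms + residual sum to 1).
    """
    D = np.asarray(D, dtype=float)
    n = len(D)
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")

    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    ss_total = np.trace(G)

    ones = np.ones((n, 1))
    Zr = np.column_stack([ones, _design(data, list(covariates)).to_numpy()])
    Xf = np.column_stack([Zr, _design(data, [exposure]).to_numpy()])
    Hr, Hf = _hat(Zr), _hat(Xf)
    rank_r = np.linalg.matrix_rank(Zr)
    rank_f = np.linalg.matrix_rank(Xf)
    df_x = rank_f - rank_r
    df_res = n - rank_f
    if df_x < 1 or df_res < 1:
        raise ValueError("degenerate design for PERMANOVA")

    Hd = Hf - Hr
    Mres = np.eye(n) - Hf

    # sequential decomposition for reporting (terms + residual sum to 1)
    seq = []
    X_cum = ones
    H_prev, r_prev = _hat(ones), 1
    for term_name in [*covariates, exposure]:
        X_cum = np.column_stack([X_cum,
                                 _design(data, [term_name]).to_numpy()])
        H_cur = _hat(X_cum)
        r_cur = np.linalg.matrix_rank(X_cum)
        seq.append({"term": term_name,
                    "df": r_cur - r_prev,
                    "ss": float(np.trace((H_cur - H_prev) @ G))})
        H_prev, r_prev = H_cur, r_cur
    seq.append({"term": "Residual", "df": n - r_prev,
                "ss": float(np.trace((np.eye(n) - H_prev) @ G))})
    terms = pd.DataFrame(seq)
    terms["r2"] = terms["ss"] / ss_total

    if by == "terms":
        ss_x = float(terms.loc[terms["term"] == exposure, "ss"].iloc[0])
    elif by == "margin":
        ss_x = float(np.sum(Hd * G))
    else:
        raise ValueError("by must be 'margin' or 'terms'")
    ss_res = float(np.sum(Mres * G))
    f_obs = (ss_x / df_x) / (ss_res / df_res)

    # Freedman-Lane: permute reduced-model residual structure
    R = np.eye(n) - Hr
    E = R @ G @ R
    rng = child_rng(seed, f"permanova-{exposure}")
    count = 0
    for _ in range(n_perm):
        pi = rng.permutation(n)
        Ep = E[np.ix_(pi, pi)]
        num = np.sum(Hd * Ep) / df_x
        den = np.sum(Mres * Ep) / df_res
        f_perm = num / den if den > 0 else np.inf
        if f_perm >= f_obs - 1e-12:
            count += 1
    p_perm = (1 + count) / (1 + n_perm)
    return PermanovaResult(term=exposure, r2=ss_x / ss_total,
                           pseudo_f=f_obs, p_perm=p_perm, df=df_x,
                           n_perm=n_perm, terms=terms)


# ---------------------------------------------------------------------------
# partial Spearman

def partial_spearman(x, y, covariates: pd.DataFrame | None = None):
    """Partial Spearman correlation: rank-transform x and y, residualize
    both on the covariates by OLS, Pearson-correlate the residuals.
    Returns (rho, p) with the t approximation on n − 2 − k df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    n = len(x)
    k = 0 if covariates is None else covariates.shape[1]
    if n < k + 4:
        raise ValueError("too few observations for the covariate count")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if covariates is not None and k:
        Cd = _design(covariates, list(covariates.columns)).to_numpy()
        # rank numeric covariates as well (all-variable rank transform)
        Cd = np.apply_along_axis(stats.rankdata, 0, Cd)
        C = np.column_stack([np.ones(n), Cd])
    else:
        C = np.ones((n, 1))
    rx = rx - C @ np.linalg.lstsq(C, rx, rcond=None)[0]
    ry = ry - C @ np.linalg.lstsq(C, ry, rcond=None)[0]
    rho = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 2 - k
    rho_c = min(max(rho, -1 + 1e-15), 1 - 1e-15)
    tstat = rho_c * np.sqrt(df / (1 - rho_c ** 2))
    p = float(2 * stats.t.sf(abs(tstat), df))
    return rho, p


# ---------------------------------------------------------------------------
# hurdle differential abundance

def hurdle_diff_abundance(counts: pd.DataFrame, data: pd.DataFrame,
                          exposure: str, covariates=(),
                          min_prevalence: float = 0.10,
                          min_mean_rel_abund: float = 0.01,
                          prefilter: bool = True) -> pd.DataFrame:
    """Two-part (hurdle) differential abundance per genus.

    Presence part: logistic regression of presence/absence on exposure +
    covariates. Abundance part: OLS of log TSS relative abundance among
    non-zero samples (no pseudocount) on the same design. BH adjustment
    runs across genera separately within each part. Genera present in
    every sample skip the presence part; genera with too few non-zero
    samples skip the abundance part (both noted in the output).
    """
    if prefilter:
        counts = filter_genera(counts, min_prevalence, min_mean_rel_abund)
    rel = tss(counts)
    df = data.loc[counts.index] if data.index.equals(counts.index) \
        else data.set_index("subject_id").loc[counts.index]
    X = pd.concat([df[[exposure]].astype(float),
                   _design(df, list(covariates))], axis=1)
    Xc = sm.add_constant(X)
    if df[exposure].nunique() < 2:
        raise ValueError("exposure is constant")

    records = []
    for genus in counts.columns:
        present = (counts[genus] > 0).to_numpy().astype(float)
        rec = {"genus": genus, "n": len(present),
               "prevalence": present.mean()}
        # presence part; near-saturated genera carry no usable
        # presence/absence signal and routinely separate
        prev = present.mean()
        if prev == 0 or prev == 1:
            rec.update(presence_beta=np.nan, presence_p=np.nan,
                       presence_note="present in all or no samples")
        elif not 0.05 <= prev <= 0.95:
            rec.update(presence_beta=np.nan, presence_p=np.nan,
                       presence_note="presence nearly constant; part skipped")
        else:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    lf = sm.Logit(present, Xc).fit(disp=0, maxiter=200)
                if not lf.mle_retvals.get("converged", False):
                    raise RuntimeError("no convergence (separation?)")
                rec.update(presence_beta=float(lf.params[exposure]),
                           presence_p=float(lf.pvalues[exposure]),
                           presence_note="")
            except Exception as exc:  # separation etc.
                rec.update(presence_beta=np.nan, presence_p=np.nan,
                           presence_note=f"logit failed: {exc}")
        # abundance part among non-zero samples
        nz = present.astype(bool)
        if nz.sum() < Xc.shape[1] + 2:
            rec.update(abundance_beta=np.nan, abundance_p=np.nan,
                       abundance_note="too few non-zero samples")
        else:
            idx = rel.index[nz]
            yv = np.log(rel.loc[idx, genus].astype(float).to_numpy())
            of = sm.OLS(yv, Xc.loc[idx]).fit()
            rec.update(abundance_beta=float(of.params[exposure]),
                       abundance_p=float(of.pvalues[exposure]),
                       abundance_note="")
        records.append(rec)
    out = pd.DataFrame(records)
    for part in ("presence", "abundance"):
        pcol, qcol = f"{part}_p", f"{part}_q"
        mask = out[pcol].notna()
        out[qcol] = np.nan
        if mask.any():
            out.loc[mask, qcol] = bh_fdr(out.loc[mask, pcol].to_numpy())
    return out
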