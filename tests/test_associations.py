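"""Association engine: standardized betas, multiple testing, PERMANOVA,
partial Spearman and the hurdle differential-abundance model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from dietbiome.associations import (bh_fdr, bonferroni, fit_adjusted_lm,
                                    hurdle_diff_abundance, partial_spearman,
                                    permanova)


# ---------------------------------------------------------------------------
# standardized-beta linear models

def test_univariate_std_beta_equals_pearson_r():
    rng = np.random.default_rng(0)
    x = rng.normal(size=300)
    y = 0.4 * x + rng.normal(size=300)
    df = pd.DataFrame({"x": x, "y": y})
    res = fit_adjusted_lm(df, "y", "x")
    r, _ = stats.pearsonr(x, y)
    assert res.std_beta == pytest.approx(r, abs=1e-10)
    assert res.ci_low <= res.std_beta <= res.ci_high


def test_orthogonal_covariate_leaves_std_beta_unchanged():
    rng = np.random.default_rng(1)
    x = rng.normal(size=200)
    y = 0.5 * x + rng.normal(size=200)
    c = rng.normal(size=200)
    X = np.column_stack([np.ones(200), x])
    c_perp = c - X @ np.linalg.lstsq(X, c, rcond=None)[0]
    df = pd.DataFrame({"x": x, "y": y, "c": c_perp})
    base = fit_adjusted_lm(df, "y", "x")
    with_cov = fit_adjusted_lm(df, "y", "x", covariates=["c"])
    assert with_cov.std_beta == pytest.approx(base.std_beta, abs=1e-10)


def test_null_exposure_std_beta_near_zero_p_uniform():
    rng = np.random.default_rng(2)
    betas, ps = [], []
    for _ in range(200):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        res = fit_adjusted_lm(pd.DataFrame({"x": x, "y": y}), "y", "x")
        betas.append(res.std_beta)
        ps.append(res.p)
    assert abs(np.mean(betas)) < 0.02
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_rank_deficient_design_names_aliased_columns():
    rng = np.random.default_rng(3)
    x = rng.normal(size=50)
    df = pd.DataFrame({"x": x, "y": rng.normal(size=50), "dup": 2 * x})
    with pytest.raises(ValueError, match="dup"):
        fit_adjusted_lm(df, "y", "x", covariates=["dup"])
    with pytest.raises(ValueError, match="covariates"):
        fit_adjusted_lm(df, "y", "x", covariates=["x"])


# ---------------------------------------------------------------------------
# multiple testing

def test_bh_small_cases_and_step_up_example():
    assert bh_fdr([0.03]) == pytest.approx([0.03])
    np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    assert bh_fdr([]).size == 0
    with pytest.raises(ValueError):
        bh_fdr([1.2])


def test_bh_matches_brute_force_oracle(bh_oracle):
    rng = np.random.default_rng(4)
    for _ in range(200):
        m = rng.integers(1, 40)
        p = rng.random(m)
        np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=50))
def test_bh_oracle_property(ps):
    """BH equals the step-up oracle and dominates the raw p-values on
    arbitrary p-vectors, including ties and endpoints."""
    from tests.conftest import bh_step_up_oracle
    q = bh_fdr(ps)
    np.testing.assert_allclose(q, bh_step_up_oracle(ps), atol=1e-12)
    assert (q >= np.asarray(ps) - 1e-12).all()
    assert (q <= 1.0).all()


def test_bonferroni_and_dominance_over_bh():
    assert bonferroni([0.02]) == pytest.approx([0.02])
    np.testing.assert_allclose(
        bonferroni([0.02] + [0.5] * 9)[:1], [0.2])
    rng = np.random.default_rng(5)
    p = rng.random(25)
    assert (bonferroni(p) >= bh_fdr(p) - 1e-12).all()
    assert (bh_fdr(p) >= p - 1e-12).all()


# ---------------------------------------------------------------------------
# PERMANOVA

def _gauss_distance(n, seed, shift=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 5))
    if shift is not None:
        X[: n // 2] += shift
    from scipy.spatial.distance import pdist, squareform
    return squareform(pdist(X))


def test_permanova_matches_skbio_without_covariates():
    n = 40
    D = _gauss_distance(n, 6, shift=1.0)
    group = ["a"] * (n // 2) + ["b"] * (n // 2)
    df = pd.DataFrame({"group": group})
    ours = permanova(D, df, "group", n_perm=99, seed=0)
    ref = skbio_permanova(DistanceMatrix(D), group, permutations=99)
    assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-8)


def test_permanova_sequential_r2_decomposition_sums_to_one():
    n = 50
    D = _gauss_distance(n, 7)
    rng = np.random.default_rng(7)
    df = pd.DataFrame({"x": rng.normal(size=n), "age": rng.normal(size=n),
                       "sex": rng.choice(["F", "M"], n)})
    res = permanova(D, df, "x", covariates=["age", "sex"], n_perm=99, seed=1)
    assert res.terms["r2"].sum() == pytest.approx(1.0, abs=1e-10)
    assert 0 <= res.r2 <= 1
    assert res.p_perm >= 1 / 100


def test_permanova_relabeling_invariance():
    n = 30
    D = _gauss_distance(n, 8)
    rng = np.random.default_rng(8)
    df = pd.DataFrame({"x": rng.normal(size=n), "age": rng.normal(size=n)})
    res = permanova(D, df, "x", covariates=["age"], n_perm=99, seed=2)
    perm = rng.permutation(n)
    res_p = permanova(D[np.ix_(perm, perm)], df.iloc[perm].reset_index(
        drop=True), "x", covariates=["age"], n_perm=99, seed=2)
    assert res_p.pseudo_f == pytest.approx(res.pseudo_f, rel=1e-9)
    assert res_p.r2 == pytest.approx(res.r2, rel=1e-9)


def test_permanova_rejects_malformed_inputs():
    D = _gauss_distance(10, 9)
    df = pd.DataFrame({"x": np.arange(10.0)})
    with pytest.raises(ValueError):
        permanova(D[:9], df, "x", n_perm=99)
    with pytest.raises(ValueError):
        permanova(D, df, "x", n_perm=10)
    Dns = D.copy()
    Dns[0, 1] += 1
    with pytest.raises(ValueError):
        permanova(Dns, df, "x", n_perm=99)


# ---------------------------------------------------------------------------
# partial Spearman

def test_partial_spearman_reduces_to_spearman():
    rng = np.random.default_rng(10)
    x = rng.normal(size=100)
    y = x + rng.normal(size=100)
    rho, p = partial_spearman(x, y)
    ref_rho, ref_p = stats.spearmanr(x, y)
    assert rho == pytest.approx(ref_rho, abs=1e-12)
    assert p == pytest.approx(ref_p, rel=1e-6)
    rho1, _ = partial_spearman(x, np.exp(x))  # strictly monotone
    assert rho1 == pytest.approx(1.0)


def test_partial_spearman_removes_planted_confounder():
    rng = np.random.default_rng(11)
    marginal, partial = [], []
    for _ in range(30):
        z = rng.normal(size=300)
        x = z + 0.5 * rng.normal(size=300)
        y = z + 0.5 * rng.normal(size=300)
        marginal.append(stats.spearmanr(x, y).statistic)
        rho, _ = partial_spearman(x, y, pd.DataFrame({"z": z}))
        partial.append(rho)
    assert np.mean(marginal) > 0.5
    assert abs(np.mean(partial)) < 0.05


def test_partial_spearman_rejects_constants():
    with pytest.raises(ValueError):
        partial_spearman(np.ones(20), np.arange(20.0))


# ---------------------------------------------------------------------------
# hurdle differential abundance

def _hurdle_sim(n, fold, seed, n_genera=12, depth=5000):
    """Counts with one genus enriched `fold`-x in exposed subjects."""
    rng = np.random.default_rng(seed)
    exposure = rng.integers(0, 2, size=n).astype(float)
    base = np.full(n_genera, 1.0)
    comps = np.tile(base, (n, 1))
    comps[exposure == 1, 0] *= fold
    comps *= rng.lognormal(0, 0.3, size=comps.shape)
    comps /= comps.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, comps[i]) for i in range(n)])
    cols = [f"g{i}" for i in range(n_genera)]
    idx = pd.Index([f"s{i}" for i in range(n)], name="subject_id")
    return (pd.DataFrame(counts, index=idx, columns=cols),
            pd.DataFrame({"exposure": exposure}, index=idx))


def test_hurdle_detects_planted_enrichment_and_permutation_kills_it():
    counts, data = _hurdle_sim(300, fold=2.0, seed=12)
    out = hurdle_diff_abundance(counts, data, "exposure", prefilter=False)
    hit = out.set_index("genus").loc["g0"]
    assert hit["abundance_beta"] > 0
    assert hit["abundance_q"] < 0.1
    rng = np.random.default_rng(12)
    data_perm = data.copy()
    data_perm["exposure"] = rng.permutation(data["exposure"].to_numpy())
    out_p = hurdle_diff_abundance(counts, data_perm, "exposure",
                                  prefilter=False)
    assert out_p.set_index("genus").loc["g0", "abundance_q"] > 0.1


def test_hurdle_skips_saturated_presence_and_flags_it():
    counts, data = _hurdle_sim(120, fold=1.0, seed=13)
    out = hurdle_diff_abundance(counts, data, "exposure", prefilter=False)
    # deep sequencing of an even community: every genus always present
    assert out["presence_note"].str.contains("present in all").all()
    assert out["abundance_p"].notna().all()
    assert (out["abundance_q"].dropna()
            >= out["abundance_p"].dropna() - 1e-12).all()
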