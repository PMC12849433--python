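"""Microbiome feature engineering: normalization, diversity, distances,
enterotype clustering and the dysbiosis analog."""

import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from dietbiome.features import (beta_diversity, bray_curtis, clr,
                                dysbiosis_score, enterotype, faith_pd,
                                filter_genera, jsd_matrix, pam, pb_ratio,
                                shannon, tss)


def _frame(rows, cols=None):
    cols = cols or [f"g{i}" for i in range(len(rows[0]))]
    return pd.DataFrame(rows, columns=cols,
                        index=[f"s{i}" for i in range(len(rows))])


def test_tss_rows_sum_to_one_and_scale_invariance():
    m = _frame([[2, 2], [1, 3]])
    out = tss(m)
    np.testing.assert_allclose(out.sum(axis=1), 1.0)
    np.testing.assert_allclose(out.iloc[0], [0.5, 0.5])
    out10 = tss(m * 10)
    np.testing.assert_allclose(out, out10)
    single = tss(_frame([[7]]))
    assert single.iloc[0, 0] == 1.0


def test_tss_drops_zero_depth_rows(caplog):
    m = _frame([[2, 2], [0, 0]])
    with caplog.at_level("WARNING", logger="dietbiome.features"):
        out = tss(m)
    assert len(out) == 1


def test_clr_identity_zero_sum_and_arithmetic():
    uniform = clr(_frame([[5, 5, 5]]))
    np.testing.assert_allclose(uniform.iloc[0], 0.0, atol=1e-12)
    rng = np.random.default_rng(0)
    m = _frame(rng.integers(0, 50, size=(6, 8)))
    out = clr(m)
    np.testing.assert_allclose(out.sum(axis=1), 0.0, atol=1e-12)
    # row [9, 99]: log(10), log(100) centered -> -/+ half of ln 10
    row = clr(_frame([[9, 99]]))
    np.testing.assert_allclose(row.iloc[0], [-np.log(10) / 2,
                                             np.log(10) / 2], atol=1e-12)
    assert row.iloc[0, 1] == pytest.approx(1.151, abs=1e-3)


def test_filter_genera_matches_exhaustive_rule_evaluation():
    counts = _frame([
        [90, 5, 0, 0, 4, 1],
        [80, 10, 0, 1, 9, 0],
        [85, 8, 0, 0, 7, 0],
        [70, 20, 1, 0, 9, 0],
    ], cols=list("ABCDEF"))
    rel = counts.div(counts.sum(axis=1), axis=0)
    keep_oracle = [c for c in counts.columns
                   if (counts[c] > 0).mean() >= 0.5
                   and rel[c].mean() >= 0.05]
    out = filter_genera(counts, min_prevalence=0.5, min_mean_rel_abund=0.05)
    assert list(out.columns) == keep_oracle
    # rare genus present once in 20 subjects dies at the default filter
    m = _frame([[100, 1 if i == 0 else 0] for i in range(20)],
               cols=["common", "rare"])
    assert list(filter_genera(m).columns) == ["common"]
    sparse = _frame([[1, 0], [0, 1]])
    with pytest.raises(ValueError, match="relax"):
        filter_genera(sparse, min_prevalence=0.9, min_mean_rel_abund=0.01)


def test_shannon_closed_forms():
    assert shannon([1, 1, 1, 1]) == pytest.approx(np.log(4))
    assert shannon([10, 0, 0]) == 0.0
    assert shannon([0.25, 0.25, 0.5]) == pytest.approx(1.0397, abs=1e-4)
    # maximal at uniform for fixed genus count
    assert shannon([1, 1, 1, 1]) > shannon([4, 1, 1, 1])


def test_faith_pd_star_and_caterpillar():
    # star topology encoded with zero-length internal branches (skbio
    # requires a bifurcating root): PD of k present unit tips = k
    star = TreeNode.read(io.StringIO("((A:1,B:1):0,(C:1,D:1):0);"))
    for k in (1, 2, 3, 4):
        presence = [1] * k + [0] * (4 - k)
        assert faith_pd(presence, list("ABCD"), star) == pytest.approx(k)
    cat = TreeNode.read(io.StringIO(
        "((((A:1,B:1):1,C:1):1,D:1):1,E:1);"))
    # A and E span: A's tip + three internals + E's tip = 5
    assert faith_pd([1, 0, 0, 0, 1], list("ABCDE"), cat) == pytest.approx(5)
    # monotone under adding a present tip
    assert faith_pd([1, 1, 0, 0, 1], list("ABCDE"), cat) > 5
    with pytest.raises(ValueError, match="missing"):
        faith_pd([1], ["Z"], star)


def test_bray_curtis_bounds_and_formula():
    m = _frame([[1, 2, 3], [3, 2, 1], [1, 2, 3], [0, 0, 5]])
    D = bray_curtis(m)
    assert np.allclose(np.diag(D), 0)
    assert np.allclose(D, D.T)
    assert D.iloc[0, 2] == pytest.approx(0.0)
    assert D.iloc[0, 1] == pytest.approx(4 / 12)
    disjoint = bray_curtis(_frame([[1, 0], [0, 3]]))
    assert disjoint.iloc[0, 1] == pytest.approx(1.0)
    assert ((D.values >= 0) & (D.values <= 1)).all()
    with pytest.raises(ValueError):
        bray_curtis(_frame([[-1, 2]]))


def test_beta_diversity_methods(small_cohort):
    D = beta_diversity(small_cohort.genus_counts)
    assert np.allclose(np.diag(D), 0)
    assert (D.values >= 0).all()
    Da = beta_diversity(small_cohort.genus_counts, method="aitchison")
    assert Da.shape == D.shape
    with pytest.raises(ValueError):
        beta_diversity(small_cohort.genus_counts, method="nope")


def test_pb_ratio_symmetry_and_sign():
    rel = _frame([[0.3, 0.3, 0.4], [0.4, 0.2, 0.4], [0.1, 0.8, 0.1]],
                 cols=["Prevotella", "Bacteroides", "Other"])
    out = pb_ratio(rel, epsilon=1e-12)
    assert out.iloc[0] == pytest.approx(0.0, abs=1e-9)
    assert out.iloc[1] == pytest.approx(np.log(2), abs=1e-3)
    swapped = pb_ratio(rel.rename(columns={
        "Prevotella": "Bacteroides", "Bacteroides": "Prevotella"}),
        epsilon=1e-12)
    np.testing.assert_allclose(out, -swapped, atol=1e-12)
    with pytest.raises(ValueError):
        pb_ratio(_frame([[1.0]], cols=["Other"]))


def _blob_rel(n_per=20, seed=0):
    """Two well-separated composition blobs."""
    rng = np.random.default_rng(seed)
    a = rng.dirichlet([20, 2, 2, 2], n_per)
    b = rng.dirichlet([2, 20, 2, 2], n_per)
    rel = pd.DataFrame(np.vstack([a, b]),
                       columns=["Bacteroides", "Prevotella", "x", "y"],
                       index=[f"s{i}" for i in range(2 * n_per)])
    labels = np.array([0] * n_per + [1] * n_per)
    return rel, labels


def test_pam_is_locally_optimal_and_deterministic():
    rel, _ = _blob_rel()
    D = jsd_matrix(rel)
    medoids, labels, obj = pam(D, 2, seed=0)
    assert obj == pytest.approx(D[:, medoids].min(axis=1).sum())
    # no single-medoid swap improves the objective (local optimality)
    for mi in range(2):
        for h in range(len(D)):
            if h in medoids:
                continue
            trial = np.array([h if i == mi else m
                              for i, m in enumerate(medoids)])
            assert D[:, trial].min(axis=1).sum() >= obj - 1e-12


def test_enterotype_recovers_planted_blobs():
    rel, truth = _blob_rel()
    out = enterotype(rel, k=2, seed=0)
    memb_cols = [c for c in out.columns if c.startswith("membership_")]
    np.testing.assert_allclose(out[memb_cols].sum(axis=1), 1.0, atol=1e-9)
    assert (out[memb_cols].values >= 0).all()
    # hard labels agree perfectly with the planted blocks
    lab = pd.factorize(out["cluster"])[0]
    agreement = max((lab == truth).mean(), (lab == 1 - truth).mean())
    assert agreement == 1.0
    # cluster names reflect the dominant genus of each medoid
    assert set(out["cluster"]) == {"Bacteroides", "Prevotella"}


def test_enterotype_invariant_to_duplicating_subjects():
    rel, _ = _blob_rel()
    out1 = enterotype(rel, k=2, seed=0)
    dup = pd.concat([rel, rel.set_axis([f"d{i}" for i in range(len(rel))])])
    out2 = enterotype(dup, k=2, seed=0)
    assert list(out2["cluster"][:len(rel)]) == list(out1["cluster"])


def test_enterotype_degenerate_and_bad_k():
    rel = _frame([[0.5, 0.5]] * 5)
    with pytest.raises(ValueError):
        enterotype(rel, k=2, seed=0)
    good, _ = _blob_rel(5)
    with pytest.raises(ValueError):
        enterotype(good, k=4, seed=0)


def test_dysbiosis_score_contracts():
    rel, _ = _blob_rel(n_per=15, seed=3)
    D = jsd_matrix(rel)
    out = dysbiosis_score(D, seed=0, k=2, n_boot=8)
    assert out["eds"].between(0, 1).all()
    # monotone non-decreasing in the raw instability score
    order = out.sort_values("eds_raw")
    assert (np.diff(order["eds"].to_numpy()) >= -1e-12).all()
    # a medoid-like subject (deep inside a blob) is less dysbiotic than
    # a subject equidistant from both blobs
    mid = rel.mean(axis=0) / rel.mean(axis=0).sum()
    rel2 = pd.concat([rel, pd.DataFrame([mid], index=["between"])])
    D2 = jsd_matrix(rel2)
    out2 = dysbiosis_score(D2, seed=0, k=2, n_boot=8)
    assert out2["eds_raw"].iloc[-1] > out2["eds_raw"].iloc[:-1].median()
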