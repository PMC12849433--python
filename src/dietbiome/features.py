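"""Genus-level microbiome feature engineering.

Normalization (TSS, CLR with pseudocount 1), prevalence/abundance
filtering, alpha diversity (Shannon in nats, Faith's phylogenetic
diversity), beta diversity (Bray–Curtis on CLR values), the
Prevotella/Bacteroides log-ratio, PAM enterotype clustering on
Jensen–Shannon divergence with fuzzy memberships, and a bootstrap
enterotype-dysbiosis score.

Bray–Curtis is undefined for negative values, so the default beta
pipeline min-shifts the CLR matrix (one global shift per matrix) before
computing dissimilarities; Euclidean-on-CLR (Aitchison distance) is
available via ``method="aitchison"``. The active choice is logged.

The dysbiosis score here is an *EDS-analog*: the mean, over bootstrap
re-clusterings, of one minus a subject's maximum fuzzy enterotype
membership, z-standardized and min–max rescaled to [0, 1]. It matches
the published score's scale and intent (weak/inconsistent enterotype
membership = dysbiosis) but not necessarily its values, which come from
a proprietary reference-trained classifier.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy
from skbio import TreeNode
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from ._utils import child_rng

logger = logging.getLogger("dietbiome.features")

__all__ = [
    "tss", "clr", "filter_genera", "shannon", "faith_pd", "faith_pd_frame",
    "bray_curtis", "beta_diversity", "pb_ratio", "jsd_matrix", "pam",
    "enterotype", "dysbiosis_score", "feature_table",
]


# ---------------------------------------------------------------------------
# normalization and filtering

def tss(counts: pd.DataFrame) -> pd.DataFrame:
    """Total-sum scaling: each row divided by its sum (zero-depth rows
    are dropped with a logged warning)."""
    sums = counts.sum(axis=1)
    keep = sums > 0
    if not keep.all():
        logger.warning("tss: dropping %d zero-depth subject(s)",
                       int((~keep).sum()))
    c = counts.loc[keep]
    return c.div(c.sum(axis=1), axis=0)


def clr(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform of counts: per row,
    ``log(x + pseudocount)`` minus the row mean of the same. Rows sum to
    zero exactly."""
    if (np.asarray(counts) < 0).any():
        raise ValueError("counts must be non-negative")
    logged = np.log(np.asarray(counts, dtype=float) + pseudocount)
    centered = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=counts.index, columns=counts.columns)


def filter_genera(counts: pd.DataFrame, min_prevalence: float = 0.10,
                  min_mean_rel_abund: float = 0.01,
                  rule: str = "mean") -> pd.DataFrame:
    """Keep genera with prevalence >= ``min_prevalence`` AND mean (or, with
    ``rule='max'``, maximum) TSS relative abundance >= ``min_mean_rel_abund``.
    Genus order is preserved."""
    rel = tss(counts)
    prevalence = (counts > 0).mean(axis=0)
    abund = rel.max(axis=0) if rule == "max" else rel.mean(axis=0)
    keep = (prevalence >= min_prevalence) & (abund >= min_mean_rel_abund)
    if not keep.any():
        raise ValueError("no genera pass the prevalence/abundance filter; "
                         "relax min_prevalence or min_mean_rel_abund")
    return counts.loc[:, keep[keep].index]


# ---------------------------------------------------------------------------
# diversity

def shannon(row) -> float:
    """Shannon diversity H = −Σ p ln p (nats) of one count/abundance row."""
    x = np.asarray(row, dtype=float)
    if x.sum() <= 0:
        raise ValueError("row sum must be > 0")
    return float(entropy(x))  # scipy normalizes and uses natural log


def faith_pd(presence_row, taxa, tree: TreeNode) -> float:
    """Faith's phylogenetic diversity: total branch length of the minimal
    rooted subtree spanning the present taxa."""
    tips = {t.name for t in tree.tips()}
    missing = [t for t, x in zip(taxa, presence_row) if x > 0
               and t not in tips]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    return float(_skbio_faith_pd(np.asarray(presence_row) > 0,
                                 taxa=list(taxa), tree=tree))


def faith_pd_frame(counts: pd.DataFrame, tree: TreeNode) -> pd.Series:
    """Per-subject Faith PD for a counts matrix."""
    vals = [faith_pd(counts.iloc[i].to_numpy(), counts.columns, tree)
            for i in range(len(counts))]
    return pd.Series(vals, index=counts.index, name="faith_pd")


# ---------------------------------------------------------------------------
# beta diversity

def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarity; requires non-negative input."""
    X = np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values; "
                         "min-shift the matrix or use Aitchison distance")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


def beta_diversity(counts: pd.DataFrame, pseudocount: float = 1.0,
                   method: str = "bc_shifted_clr") -> pd.DataFrame:
    """Subject x subject dissimilarity of CLR-transformed genus counts.

    ``bc_shifted_clr``: Bray–Curtis after shifting the CLR matrix by its
    global minimum (default); ``aitchison``: Euclidean on CLR.
    """
    z = clr(counts, pseudocount=pseudocount)
    if method == "bc_shifted_clr":
        logger.info("beta_diversity: Bray-Curtis on min-shifted CLR values "
                    "(use method='aitchison' for Euclidean-on-CLR)")
        shifted = z - np.asarray(z).min()
        return bray_curtis(shifted)
    if method == "aitchison":
        logger.info("beta_diversity: Euclidean distance on CLR values")
        D = squareform(pdist(np.asarray(z), metric="euclidean"))
        return pd.DataFrame(D, index=counts.index, columns=counts.index)
    raise ValueError(f"unknown beta-diversity method {method!r}")


def pb_ratio(rel: pd.DataFrame,
             prevotella=("Prevotella",),
             bacteroides=("Bacteroides", "Phocaeicola"),
             epsilon: float | None = None) -> pd.Series:
    """Natural-log ratio of summed Prevotella vs Bacteroides/Phocaeicola
    relative abundances, ln((P+ε)/(B+ε)); ε defaults to half the smallest
    nonzero relative abundance in the matrix."""
    p_cols = [c for c in prevotella if c in rel.columns]
    b_cols = [c for c in bacteroides if c in rel.columns]
    if not p_cols and not b_cols:
        raise ValueError("neither Prevotella nor Bacteroides/Phocaeicola "
                         "genera found in the matrix")
    if epsilon is None:
        vals = np.asarray(rel)
        nz = vals[vals > 0]
        epsilon = float(nz.min()) / 2.0 if nz.size else 1e-6
    P = rel[p_cols].sum(axis=1) if p_cols else 0.0
    B = rel[b_cols].sum(axis=1) if b_cols else 0.0
    out = np.log((P + epsilon) / (B + epsilon))
    out.name = "pb_ratio"
    return out


# ---------------------------------------------------------------------------
# enterotypes

def jsd_matrix(rel: pd.DataFrame) -> np.ndarray:
    """Pairwise Jensen–Shannon divergence (natural log) between
    relative-abundance profiles; machine-epsilon mass is added before
    mixing to handle zeros."""
    P = np.asarray(rel, dtype=float) + np.finfo(float).eps
    P /= P.sum(axis=1, keepdims=True)
    n = len(P)
    H = -np.sum(P * np.log(P), axis=1)
    D = np.zeros((n, n))
    for i in range(n - 1):
        mix = (P[i] + P[i + 1:]) / 2.0
        Hm = -np.sum(mix * np.log(mix), axis=1)
        d = Hm - (H[i] + H[i + 1:]) / 2.0
        D[i, i + 1:] = D[i + 1:, i] = np.maximum(d, 0.0)
    return D


def pam(D: np.ndarray, k: int, seed: int = 0, max_iter: int = 100):
    """Partitioning around medoids on a precomputed dissimilarity matrix.

    Greedy BUILD initialization followed by best-improvement SWAP passes;
    the objective (sum of dissimilarity to the assigned medoid) never
    increases across iterations. Returns (medoid indices, labels,
    objective).
    """
    n = len(D)
    if not 2 <= k < n:
        raise ValueError("need 2 <= k < n subjects")
    # BUILD: first medoid minimizes total distance, then greedy gain
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        # total cost if candidate j is added
        gain = np.minimum(current[:, None], D).sum(axis=0)
        gain[medoids] = np.inf
        medoids.append(int(np.argmin(gain)))
    medoids = np.array(sorted(medoids))

    def cost(meds):
        return D[:, meds].min(axis=1).sum()

    best = cost(medoids)
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            others = np.delete(medoids, mi)
            d_rest = (D[:, others].min(axis=1) if len(others)
                      else np.full(n, np.inf))
            cand = np.setdiff1d(np.arange(n), medoids)
            # cost of replacing medoid mi by each candidate, vectorized
            new_costs = np.minimum(d_rest[:, None], D[:, cand]).sum(axis=0)
            j = int(np.argmin(new_costs))
            if new_costs[j] < best - 1e-12:
                medoids = np.sort(np.append(others, cand[j]))
                best = new_costs[j]
                improved = True
        if not improved:
            break
    labels = np.argmin(D[:, medoids], axis=1)
    return medoids, labels, float(best)


def _fuzzy_memberships(D_to_medoids: np.ndarray,
                       fuzzifier: float = 2.0) -> np.ndarray:
    """Memberships from normalized inverse divergence to each medoid."""
    d = np.maximum(D_to_medoids, 0.0)
    exact = d < 1e-15
    w = (1.0 / (d + 1e-15)) ** (1.0 / (fuzzifier - 1.0))
    w[exact.any(axis=1)] = exact[exact.any(axis=1)].astype(float)
    return w / w.sum(axis=1, keepdims=True)


def enterotype(rel: pd.DataFrame, k: int, seed: int = 0,
               fuzzifier: float = 2.0,
               D: np.ndarray | None = None) -> pd.DataFrame:
    """PAM enterotypes of relative-abundance profiles on JSD.

    Returns a frame with the hard ``cluster`` label (named after the
    dominant genus of each cluster medoid), fuzzy membership columns and
    ``max_membership``.
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    if D is None:
        D = jsd_matrix(rel)
    if np.allclose(D, 0):
        raise ValueError("all profiles identical; enterotyping is degenerate")
    medoids, labels, _ = pam(D, k, seed=seed)
    names = []
    for m in medoids:
        dom = rel.columns[int(np.argmax(rel.iloc[m].to_numpy()))]
        name = str(dom)
        while name in names:          # two medoids dominated by same genus
            name += "_"
        names.append(name)
    memb = _fuzzy_memberships(D[:, medoids], fuzzifier=fuzzifier)
    out = pd.DataFrame({"subject_id": rel.index,
                        "cluster": [names[l] for l in labels]})
    for ci, name in enumerate(names):
        out[f"membership_{name}"] = memb[:, ci]
    out["max_membership"] = memb.max(axis=1)
    return out


def dysbiosis_score(D: np.ndarray, seed: int, k: int = 3, n_boot: int = 20,
                    fuzzifier: float = 2.0,
                    reference_stats: tuple[float, float] | None = None
                    ) -> pd.DataFrame:
    """EDS-analog: bootstrap instability of fuzzy enterotype membership.

    Raw score per subject = mean over the full-sample clustering plus
    ``n_boot`` bootstrap re-clusterings of (1 − max membership to that
    iteration's medoids); z-standardized against ``reference_stats``
    (default: this sample) and min–max rescaled to [0, 1].
    """
    n = len(D)
    rng = child_rng(seed, "eds-bootstrap")
    raw = np.zeros(n)
    iters = 0
    for it in range(n_boot + 1):
        if it == 0:
            idx = np.arange(n)
        else:
            idx = rng.choice(n, size=n, replace=True)
        sub = D[np.ix_(idx, idx)]
        if np.allclose(sub, 0):
            logger.warning("dysbiosis_score: degenerate bootstrap sample "
                           "skipped")
            continue
        medoids_local, _, _ = pam(sub, k, seed=seed)
        medoids = np.unique(idx[medoids_local])
        memb = _fuzzy_memberships(D[:, medoids], fuzzifier=fuzzifier)
        raw += 1.0 - memb.max(axis=1)
        iters += 1
    raw /= max(iters, 1)
    if reference_stats is None:
        mu, sd = float(raw.mean()), float(raw.std(ddof=0))
    else:
        mu, sd = reference_stats
    z = (raw - mu) / (sd if sd > 0 else 1.0)
    span = np.ptp(z)
    eds = (z - z.min()) / span if span > 0 else np.zeros(n)
    return pd.DataFrame({"eds_raw": raw, "eds_z": z, "eds": eds})


# ---------------------------------------------------------------------------
# one-call feature table

def feature_table(counts: pd.DataFrame, tree: TreeNode, seed: int = 0,
                  n_boot: int = 20) -> pd.DataFrame:
    """Standard per-subject feature set: alpha diversity, PB ratio,
    enterotype labels (k=2 and 3), EDS-analog and sequencing depth."""
    rel = tss(counts)
    D = jsd_matrix(rel)
    ent2 = enterotype(rel, k=2, seed=seed, D=D)
    ent3 = enterotype(rel, k=3, seed=seed, D=D)
    eds = dysbiosis_score(D, seed=seed, k=3, n_boot=n_boot)
    depth = counts.sum(axis=1)
    out = pd.DataFrame({
        "subject_id": counts.index,
        "shannon": [shannon(counts.iloc[i]) for i in range(len(counts))],
        "faith_pd": faith_pd_frame(counts, tree).values,
        "pb_ratio": pb_ratio(rel).values,
        "enterotype_k2": ent2["cluster"].values,
        "enterotype_k3": ent3["cluster"].values,
        "eds": eds["eds"].values,
        "depth": depth.values,
        "log_depth": np.log(depth.values),
    })
    return out
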