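"""Community-level SCFA-pathway potential from a taxon trait table.

Upstream phylogenetic placement and hidden-state prediction are assumed
done: the input is a taxon x pathway table of (possibly fractional)
pathway presences for the five short-chain-fatty-acid biosynthesis routes
(butyrate: but, buk, acetyl-CoA; propionate: pdiol, succinate). A
sample's pathway potential is the abundance-weighted share of carrier
taxa — trait values summed over taxa weighted by counts, normalized by
sample depth — so it lies in [0, 1] and is invariant to sequencing depth.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("dietbiome.scfa")

__all__ = ["PATHWAYS", "pathway_abundance", "pathway_contributors"]

PATHWAYS = ["but", "buk", "acetyl_coa", "pdiol", "succinate"]


def _aligned_traits(counts: pd.DataFrame, traits: pd.DataFrame
                    ) -> pd.DataFrame:
    if not set(traits.columns) <= set(PATHWAYS):
        unknown = sorted(set(traits.columns) - set(PATHWAYS))
        raise ValueError(f"unknown pathway column(s): {unknown}")
    if ((traits < 0) | (traits > 1)).any().any():
        raise ValueError("trait values must lie in [0, 1]")
    missing = [t for t in counts.columns if t not in traits.index]
    if missing:
        logger.warning("pathway_abundance: %d taxa absent from trait table "
                       "treated as non-carriers (e.g. %s)", len(missing),
                       missing[:3])
    return traits.reindex(counts.columns).fillna(0.0)


def pathway_abundance(counts: pd.DataFrame,
                      traits: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundance of carriers of each SCFA pathway.

    ``value(s, p) = Σ_t trait(t, p)·count(s, t) / Σ_t count(s, t)``;
    zero-depth samples are excluded with a logged warning.
    """
    tr = _aligned_traits(counts, traits)
    depth = counts.sum(axis=1)
    keep = depth > 0
    if not keep.all():
        logger.warning("pathway_abundance: dropping %d zero-depth sample(s)",
                       int((~keep).sum()))
    c = counts.loc[keep]
    carrier = c.to_numpy(dtype=float) @ tr.to_numpy(dtype=float)
    out = pd.DataFrame(carrier / depth[keep].to_numpy()[:, None],
                       index=c.index, columns=tr.columns)
    return out


def pathway_contributors(counts: pd.DataFrame, traits: pd.DataFrame,
                         pathway: str) -> pd.DataFrame:
    """Per-taxon share of a pathway's total carrier abundance, descending.

    Shares sum to 1 whenever the pathway has any carrier abundance; an
    everywhere-absent pathway yields an empty table with a warning.
    """
    if pathway not in PATHWAYS:
        raise ValueError(f"unknown pathway {pathway!r}; choose from "
                         f"{PATHWAYS}")
    tr = _aligned_traits(counts, traits)
    rel = counts.div(counts.sum(axis=1), axis=0)
    weighted = rel * tr[pathway].to_numpy()[None, :]
    total = weighted.to_numpy().sum()
    if total == 0:
        logger.warning("pathway %r has zero carrier abundance everywhere",
                       pathway)
        return pd.DataFrame(columns=["taxon", "share"])
    share = weighted.sum(axis=0) / total
    out = (share[share > 0].sort_values(ascending=False)
           .rename_axis("taxon").reset_index(name="share"))
    return out
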