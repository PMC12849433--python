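"""Shared helpers: deterministic RNG streams and TSV round-tripping.

All randomness in the package flows from one root integer seed. Each
consumer asks for a named child stream via :func:`child_rng`; the stream
seed is ``SeedSequence([root_seed, crc32(label)])`` so adding a new stream
never perturbs existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

__all__ = ["child_rng", "child_seed", "write_tsv", "read_tsv"]


def child_seed(root_seed: int, label: str) -> np.random.SeedSequence:
    """Deterministic named sub-seed of ``root_seed``."""
    return np.random.SeedSequence([int(root_seed), zlib.crc32(label.encode())])


def child_rng(root_seed: int, label: str) -> np.random.Generator:
    """Generator for the named child stream of ``root_seed``."""
    return np.random.default_rng(child_seed(root_seed, label))


# Fixed float formatting so that identical frames serialize to identical
# bytes on every platform (end-to-end determinism contract).
_FLOAT_FMT = "%.10g"


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT,
              lineterminator="\n")


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
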