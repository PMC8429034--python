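"""Rank-based lncRNA pair matrix and the stability filter.

For every unordered pair {A, B} of DEirlncRNAs, taken once in canonical
lexicographic order A < B, the pair feature is the within-sample rank
comparison: 1 if A's expression exceeds B's in that sample, else 0 (ties
score 0).  Because only the within-sample ordering matters, the pair
matrix is invariant under any strictly increasing per-sample transform
of expression — the signature built on it is independent of the exact
expression level.

The stability filter keeps a pair only when its "1" fraction across the
cohort lies strictly between the low and high bounds (default 0.2/0.8):
near-constant pairs carry no contrast to model.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix


@dataclass
class PairMatrix:
    """Binary pairs x samples matrix of within-sample rank comparisons."""

    values: pd.DataFrame  # int8, index "A|B" pair ids

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.isin(v, (0, 1)).all():
            raise ValueError("pair matrix values must be 0/1")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate pair ids")

    @property
    def pair_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def ones_fraction(self) -> pd.Series:
        return self.values.mean(axis=1)

    def subset(self, pair_ids) -> "PairMatrix":
        return PairMatrix(self.values.loc[list(pair_ids)].copy())

    def write(self, path) -> None:
        out = self.values.copy()
        out.index.name = "pair_id"
        out.to_csv(path, sep="\t")


def build_pair_matrix(expr: ExpressionMatrix | pd.DataFrame) -> PairMatrix:
    """All k(k-1)/2 canonical rank-pair features over the given samples.

    Features are sorted lexicographically before pairing, so the output
    does not depend on the input row order.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if values.shape[0] < 2:
        raise ValueError("need at least 2 features to build pairs")
    feats = sorted(values.index)
    mat = values.loc[feats].to_numpy()
    rows, ids = [], []
    for i, j in combinations(range(len(feats)), 2):
        rows.append((mat[i] > mat[j]).astype(np.int8))
        ids.append(f"{feats[i]}|{feats[j]}")
    return PairMatrix(pd.DataFrame(np.vstack(rows), index=ids,
                                   columns=values.columns))


def filter_stable_pairs(pm: PairMatrix, low: float = 0.2,
                        high: float = 0.8) -> PairMatrix:
    """Keep pairs with ones-fraction strictly inside (low, high)."""
    if not 0 <= low < high <= 1:
        raise ValueError("require 0 <= low < high <= 1")
    frac = pm.ones_fraction
    keep = frac.index[(frac > low) & (frac < high)]
    return pm.subset(keep)
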