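"""Multiple testing, midranks and rank-concordance (CAT) curves."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_qvalues", "midranks", "CatCurve", "cat_curve"]


def bh_qvalues(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values (step-up FDR adjustment), capped at 1.

    q_(i) = min_{j >= i} K p_(j) / j in sorted-P order, mapped back to the
    input order.  Valid P-values must lie in (0, 1]; a zero P-value signals
    an inconsistency upstream (e.g. an observed event where the null assigns
    zero probability) and is rejected.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        raise ValueError("empty P-value vector")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("P-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def midranks(p: Sequence[float]) -> np.ndarray:
    """Ascending ranks with ties sharing the average of their positions."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        raise ValueError("empty vector")
    return rankdata(arr, method="average")


@dataclass
class CatCurve:
    """Correspondence-at-the-top curve between two rankings.

    ``fraction[k-1]`` is |top-k(A) intersect top-k(B)| / k for k = 1..k_max.
    """

    k: np.ndarray
    fraction: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k, "fraction": self.fraction})


def cat_curve(
    order_a: Sequence[str],
    order_b: Sequence[str],
    k_max: int | None = None,
) -> CatCurve:
    """Running top-k intersection fraction between two total orders.

    Both orders must rank the same universe of set ids; ties should already
    be resolved by a deterministic secondary key (we use set_id elsewhere).
    O(K) with a membership table.
    """
    a = list(order_a)
    b = list(order_b)
    if set(a) != set(b) or len(a) != len(set(a)) or len(b) != len(set(b)):
        raise ValueError("orders must be permutations of the same set universe")
    K = len(a)
    if k_max is None:
        k_max = K
    k_max = min(k_max, K)
    frac = np.empty(k_max)
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    shared = 0
    for k in range(k_max):
        xa, xb = a[k], b[k]
        if xa == xb:
            shared += 1
        else:
            if xa in seen_b:
                shared += 1
            if xb in seen_a:
                shared += 1
        seen_a.add(xa)
        seen_b.add(xb)
        frac[k] = shared / (k + 1)
    return CatCurve(np.arange(1, k_max + 1), frac)
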