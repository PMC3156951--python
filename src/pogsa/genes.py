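"""Gene-oriented comparator: per-gene likelihood-ratio scores against the
passenger expectation, followed by a competitive Wilcoxon rank-sum set test.

Each gene j is scored with a one-sided Poisson likelihood-ratio statistic
for its total mutation count n_j across samples against the passenger
expectation lambda_j = sum_i f_i sum_c L_jc r_c:

    LRT_j = 2 [ n_j log(n_j / lambda_j) - (n_j - lambda_j) ]   if n_j > lambda_j,
    LRT_j = 0                                                  otherwise.

A gene set is then tested by comparing the score ranks of its genes against
all genes outside it (one-sided: in-set genes rank higher).  Because the
scores aggregate counts over patients, this pipeline is blind to how a fixed
per-gene mutation total is distributed across patients — the property the
patient-oriented methods are designed to exploit.
"""
from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .io import (
    RESULT_COLUMNS,
    GeneModelTable,
    GeneSetCollection,
    MutationCatalog,
    PassengerModel,
    sort_results,
)
from .ranking import bh_qvalues, midranks

log = logging.getLogger(__name__)

#: Feasibility bounds for the exact rank-sum enumeration branch.
EXACT_MIN_GROUP = 10
EXACT_MAX_SUBSETS = 200_000


def gene_lrt_scores(
    catalog: MutationCatalog,
    gene_models: GeneModelTable,
    rates: PassengerModel,
) -> pd.DataFrame:
    """Per-gene one-sided Poisson LRT scores and descending midranks.

    Returns a DataFrame indexed by gene with columns ``n_obs`` (total events
    across samples, multiplicity included), ``expected`` (lambda_j), ``score``
    and ``rank`` (midrank, rank 1 = highest score).  A gene with observed
    events but zero passenger expectation gets an infinite score (ranked
    first) and is logged.
    """
    gene_models.require_genes(catalog.gene_universe)
    n_obs = catalog.gene_event_counts().astype(float)
    f_total = rates.multipliers_for(catalog.samples).sum()
    lam = (
        gene_models.expected_counts(rates)
        .reindex(catalog.gene_universe)
        .to_numpy()
        * f_total
    )
    score = np.zeros_like(n_obs)
    degenerate = (lam == 0) & (n_obs > 0)
    if np.any(degenerate):
        log.warning(
            "%d gene(s) with observed mutations but zero passenger expectation",
            int(degenerate.sum()),
        )
        score[degenerate] = np.inf
    excess = (n_obs > lam) & ~degenerate
    ne, le = n_obs[excess], lam[excess]
    score[excess] = 2.0 * (ne * np.log(ne / le) - (ne - le))
    return pd.DataFrame(
        {
            "n_obs": n_obs.astype(int),
            "expected": lam,
            "score": score,
            "rank": rankdata(-score, method="average"),
        },
        index=pd.Index(catalog.gene_universe, name="gene"),
    )


def _ranksum_normal_pvalues(
    asc_ranks: np.ndarray,
    tie_term: float,
    w_stats: np.ndarray,
    m_sizes: np.ndarray,
) -> np.ndarray:
    """Vectorized one-sided rank-sum P-values (normal approximation).

    ``asc_ranks`` are ascending midranks of the gene scores, ``tie_term`` is
    sum(t^3 - t) over tied groups, ``w_stats``/``m_sizes`` are the per-set
    in-set rank sums and sizes.  Tie and continuity corrections included.
    """
    N = asc_ranks.size
    m = m_sizes.astype(float)
    mean = m * (N + 1) / 2.0
    var = m * (N - m) / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    p = np.ones_like(mean)
    ok = var > 0
    z = (w_stats[ok] - mean[ok] - 0.5) / np.sqrt(var[ok])
    p[ok] = norm.sf(z)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _exact_feasible(m: int, N: int) -> bool:
    small = min(m, N - m)
    return small <= EXACT_MIN_GROUP and comb(N, small) <= EXACT_MAX_SUBSETS


def _ranksum_exact_pvalue(asc_ranks: np.ndarray, in_set: np.ndarray) -> float:
    """Exact permutation P(W >= W_obs) over all C(N, m) rank subsets.

    Conditional on the observed midrank pattern.  When the complement is the
    smaller group, enumerate it instead via the reflection
    W_set >= w  <=>  W_comp <= total - w.
    """
    N = asc_ranks.size
    m = int(in_set.sum())
    w_obs = float(asc_ranks[in_set].sum())
    total = float(asc_ranks.sum())
    eps = 1e-9
    if m <= N - m:
        hits = sum(
            1 for c in combinations(asc_ranks, m) if sum(c) >= w_obs - eps
        )
        return hits / comb(N, m)
    target = total - w_obs
    hits = sum(
        1 for c in combinations(asc_ranks, N - m) if sum(c) <= target + eps
    )
    return hits / comb(N, N - m)


def wilcoxon_set_test(scores: pd.DataFrame, set_genes: list[str]) -> float:
    """One-sided rank-sum P-value that in-set genes score higher than out-set.

    Uses exact enumeration over rank subsets when the smaller group has at
    most 10 genes and the subset count is tractable, otherwise the normal
    approximation with tie and continuity corrections.  All scores tied
    yields P = 1 (no evidence under midranks).
    """
    genes = list(scores.index)
    in_set = np.isin(genes, list(set_genes))
    m = int(in_set.sum())
    N = len(genes)
    if m == 0:
        raise ValueError("gene set has no genes among the scored universe")
    if m == N:
        raise ValueError("gene set equals the whole universe")
    vals = scores["score"].to_numpy()
    asc_ranks = rankdata(vals, method="average")
    if _exact_feasible(m, N):
        return _ranksum_exact_pvalue(asc_ranks, in_set)
    _, counts = np.unique(vals, return_counts=True)
    tie_term = float((counts.astype(float) ** 3 - counts).sum())
    w = np.array([asc_ranks[in_set].sum()])
    return float(
        _ranksum_normal_pvalues(asc_ranks, tie_term, w, np.array([m]))[0]
    )


def run_gene_gsa(
    catalog: MutationCatalog,
    sets: GeneSetCollection,
    gene_models: GeneModelTable,
    rates: PassengerModel,
) -> pd.DataFrame:
    """Full gene-oriented analysis: LRT scores, per-set Wilcoxon P, BH q.

    The result table mirrors the patient-oriented schema; the ``score``
    column holds the in-set rank-sum statistic W and the null moments are
    its rank-sum mean and SD.
    """
    scores = gene_lrt_scores(catalog, gene_models, rates)
    membership, set_ids = sets.membership_matrix(catalog.gene_universe)
    sizes = membership.sum(axis=0)
    N = len(catalog.gene_universe)
    if np.any(sizes < 1) or np.any(sizes >= N):
        raise ValueError("each set must be a nonempty proper subset of the universe")
    vals = scores["score"].to_numpy()
    asc_ranks = rankdata(vals, method="average")
    w_stats = asc_ranks @ membership
    _, counts = np.unique(vals, return_counts=True)
    tie_term = float((counts.astype(float) ** 3 - counts).sum())
    p = _ranksum_normal_pvalues(asc_ranks, tie_term, w_stats, sizes)
    # exact branch for tiny groups where enumeration is tractable
    for k, sid in enumerate(set_ids):
        if _exact_feasible(int(sizes[k]), N):
            p[k] = _ranksum_exact_pvalue(asc_ranks, membership[:, k])
    m = sizes.astype(float)
    mean = m * (N + 1) / 2.0
    var = m * (N - m) / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    table = pd.DataFrame(
        {
            "set_id": set_ids,
            "size": sizes.astype(int),
            "score": w_stats,
            "null_mean": mean,
            "null_sd": np.sqrt(np.maximum(var, 0.0)),
            "p_value": p,
            "note": "",
        }
    )
    table["q_value"] = bh_qvalues(table["p_value"].to_numpy())
    table["rank"] = midranks(table["p_value"].to_numpy())
    return sort_results(table[list(RESULT_COLUMNS)])
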