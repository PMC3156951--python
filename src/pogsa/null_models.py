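"""Null models for per-patient gene set alteration.

Two null hypotheses are supported for "set s is altered in patient i":

* **permutation null** — each patient's n_i mutation events are reassigned
  to n_i distinct genes drawn uniformly (optionally weighted) without
  replacement from the G-gene universe.  The alteration probability of an
  m-gene set has the hypergeometric-complement closed form
  ``pi = 1 - C(G-m, n_i) / C(G, n_i)``.
* **passenger null** — each gene mutates independently with a Poisson count
  whose mean is the patient-scaled passenger expectation
  ``lambda_ij = f_i * sum_c L_jc * r_c``; a set is altered when at least one
  of its genes is hit, ``pi = 1 - prod_j exp(-lambda_ij)``.

Both the probability calculators and whole-catalog samplers live here; all
samplers are pure functions of their inputs and an explicit seed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import (
    GeneModelTable,
    GeneSetCollection,
    MutationCatalog,
    MutationEvent,
    PassengerModel,
)

__all__ = [
    "NullAlterationProfile",
    "perm_alteration_prob",
    "passenger_gene_prob",
    "passenger_set_prob",
    "build_profile",
    "sample_permutation_null",
    "sample_passenger_null",
    "weighted_sample_without_replacement",
]


@dataclass
class NullAlterationProfile:
    """Matrix of per-patient, per-set null alteration probabilities.

    ``pi`` is a samples x sets DataFrame; ``null`` tags which mechanism the
    probabilities describe ("permutation" or "passenger").
    """

    pi: pd.DataFrame
    null: str

    def column(self, set_id: str) -> np.ndarray:
        return self.pi[set_id].to_numpy()


def _log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def perm_alteration_prob(n_events, G: int, m) -> np.ndarray | float:
    """Probability that >=1 of ``n_events`` distinct uniformly chosen genes
    falls in a fixed set of ``m`` genes out of ``G``.

    Computed in log space as ``-expm1(log C(G-m, n) - log C(G, n))`` so it
    stays accurate for exome-scale G.  Returns exactly 1 when n > G - m.
    Accepts scalars or broadcastable arrays for ``n_events`` and ``m``.
    """
    n = np.asarray(n_events, dtype=float)
    mm = np.asarray(m, dtype=float)
    if np.any(n < 0) or np.any(n > G):
        raise ValueError(f"need 0 <= n_events <= G={G}")
    if np.any(mm < 1) or np.any(mm > G):
        raise ValueError(f"need 1 <= m <= G={G}")
    n, mm = np.broadcast_arrays(n, mm)
    out = np.ones(n.shape, dtype=float)
    feasible = n <= G - mm
    if np.any(feasible):
        nf = n[feasible]
        mf = mm[feasible]
        log_ratio = _log_comb(G - mf, nf) - _log_comb(np.full_like(nf, G), nf)
        out[feasible] = -np.expm1(log_ratio)
    out = np.clip(out, 0.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def passenger_gene_prob(
    counts: Mapping[str, float] | pd.Series,
    rates: PassengerModel,
    sample_multiplier: float = 1.0,
) -> float:
    """Poisson probability that a gene receives >=1 passenger mutation.

    ``q = 1 - exp(-f * sum_c L_c * r_c)``.
    """
    if sample_multiplier <= 0:
        raise ValueError("sample multiplier must be positive")
    lam = 0.0
    for c, count in dict(counts).items():
        if count < 0:
            raise ValueError(f"negative nucleotide count for context {c!r}")
        lam += count * rates.rates[c]
    return float(-np.expm1(-sample_multiplier * lam))


def passenger_set_prob(gene_probs: Sequence[float]) -> float:
    """Probability that >=1 of several independent genes is altered.

    ``pi = 1 - prod_j (1 - q_j)``, accumulated as a sum of ``log1p(-q)``
    terms for stability.
    """
    q = np.asarray(gene_probs, dtype=float)
    if q.size == 0:
        raise ValueError("passenger_set_prob: empty gene probability list")
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("gene probabilities must lie in [0, 1]")
    if np.any(q == 1.0):
        return 1.0
    return float(-np.expm1(np.log1p(-q).sum()))


def build_profile(
    catalog: MutationCatalog,
    sets: GeneSetCollection,
    null: str,
    gene_models: GeneModelTable | None = None,
    rates: PassengerModel | None = None,
) -> NullAlterationProfile:
    """Fill the samples x sets matrix of null alteration probabilities.

    Under the permutation null the probability depends only on the patient
    load n_i, the universe size G and the post-intersection set size m_s.
    Under the passenger null it is the complement of no Poisson hit across
    the set's genes, at the patient's rate multiplier.
    """
    membership, set_ids = sets.membership_matrix(catalog.gene_universe)
    sizes = membership.sum(axis=0)
    if null == "permutation":
        n = catalog.event_counts()
        if np.any(sizes < 1):
            empty = [set_ids[k] for k in np.nonzero(sizes < 1)[0]]
            raise ValueError(f"sets with no genes in the universe: {empty[:10]}")
        pi = np.empty((catalog.n_samples, len(set_ids)))
        # pi depends on (n_i, m_s) only; compute one column per distinct size
        for size in np.unique(sizes):
            cols = np.nonzero(sizes == size)[0]
            col = perm_alteration_prob(n, catalog.n_genes, int(size))
            pi[:, cols] = np.asarray(col).reshape(-1, 1)
    elif null == "passenger":
        if gene_models is None or rates is None:
            raise ValueError("passenger null requires gene_models and rates")
        gene_models.require_genes(catalog.gene_universe)
        lam = (
            gene_models.expected_counts(rates)
            .reindex(catalog.gene_universe)
            .to_numpy()
        )
        set_lam = lam @ membership
        f = rates.multipliers_for(catalog.samples)
        pi = -np.expm1(-np.outer(f, set_lam))
    else:
        raise ValueError(f"unknown null {null!r}; expected permutation|passenger")
    frame = pd.DataFrame(pi, index=catalog.samples, columns=set_ids)
    return NullAlterationProfile(frame, null)


def weighted_sample_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, size: int
) -> np.ndarray:
    """Indices of ``size`` items drawn without replacement, P(first) ~ weights.

    Uses exponential sort keys (Efraimidis-Spirakis): the ``size`` smallest
    values of Exp(1)/w_j reproduce sequential weighted sampling.
    """
    w = np.asarray(weights, dtype=float)
    if size > np.count_nonzero(w > 0):
        # degenerate weights cannot yield enough distinct genes; fall back to
        # uniform for the remainder
        positive = np.count_nonzero(w > 0)
        chosen = weighted_sample_without_replacement(rng, w, positive)
        rest_pool = np.setdiff1d(np.arange(w.size), chosen)
        extra = rng.choice(rest_pool, size=size - positive, replace=False)
        return np.concatenate([chosen, extra])
    keys = np.full(w.size, np.inf)
    pos = w > 0
    keys[pos] = rng.exponential(size=int(pos.sum())) / w[pos]
    return np.argpartition(keys, size - 1)[:size] if size > 0 else np.empty(0, int)


def sample_permutation_null(
    catalog: MutationCatalog,
    seed: int | np.random.Generator,
    weights: np.ndarray | None = None,
) -> MutationCatalog:
    """Draw one catalog from the permutation null.

    Each patient's n_i events are reassigned to n_i distinct genes chosen
    uniformly (or proportional to ``weights``) without replacement from the
    universe; each original event keeps its context label.  Per-sample event
    counts are conserved.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    G = catalog.n_genes
    per_sample: dict[str, list[MutationEvent]] = {s: [] for s in catalog.samples}
    for ev in catalog.events:
        per_sample[ev.sample_id].append(ev)
    new_events: list[MutationEvent] = []
    for s in catalog.samples:
        evs = per_sample[s]
        n = len(evs)
        if n > G:
            raise ValueError(f"sample {s!r} has {n} events but only {G} genes")
        if n == 0:
            continue
        if weights is None:
            idx = rng.choice(G, size=n, replace=False)
        else:
            idx = weighted_sample_without_replacement(rng, weights, n)
        for ev, j in zip(evs, idx):
            new_events.append(
                MutationEvent(s, catalog.gene_universe[int(j)], ev.context_class)
            )
    return MutationCatalog(catalog.samples, catalog.gene_universe, new_events)


def sample_passenger_null(
    samples: Sequence[str],
    gene_models: GeneModelTable,
    rates: PassengerModel,
    seed: int | np.random.Generator,
) -> MutationCatalog:
    """Draw one catalog from the passenger null.

    Event counts per (sample, gene, context) are independent Poisson with
    mean ``f_i * L_jc * r_c``; every drawn event is materialized with its
    context label.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = gene_models.genes
    contexts = gene_models.contexts
    r = np.array([rates.rates[c] for c in contexts])
    lam = gene_models.table.to_numpy(dtype=float) * r  # genes x contexts
    events: list[MutationEvent] = []
    for s in samples:
        counts = rng.poisson(rates.multiplier(s) * lam)
        gi, ci = np.nonzero(counts)
        for j, c, k in zip(gi, ci, counts[gi, ci]):
            events.extend([MutationEvent(s, genes[j], contexts[c])] * int(k))
    return MutationCatalog(list(samples), genes, events)
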