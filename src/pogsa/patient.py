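"""Patient-oriented gene set statistics and exact null distributions.

For each gene set s the analysis starts from a binary per-patient indicator
z_i (1 iff any gene of the set is altered in patient i) and scores the set by

    T_s = sum_i w_i * z_i ,

the (optionally weighted) number of patients in which the set is altered.
Under either null model the z_i are independent Bernoulli(pi_is), so the
unweighted T_s follows a Poisson-binomial distribution whose upper tail is
computed exactly by dynamic programming; weighted scores are handled by
exact enumeration of the 2^n outcome space (meet-in-the-middle) or Monte
Carlo.  Four methods arise from crossing the two nulls (permutation,
passenger) with heterogeneity weighting off/on.

The heterogeneity weights default to the self-information w_i = -log(pi_is):
an alteration observed in a patient who is unlikely to be altered by chance
carries more evidence, which down-weights heavily mutated tumors.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import (
    RESULT_COLUMNS,
    GeneModelTable,
    GeneSetCollection,
    MutationCatalog,
    PassengerModel,
    sort_results,
)
from .null_models import build_profile
from .ranking import bh_qvalues, midranks

log = logging.getLogger(__name__)

#: Largest cohort for which the weighted exact tail is enumerated.
ENUMERATION_LIMIT = 25


@dataclass(frozen=True)
class MethodSpec:
    """Configuration naming one of the four patient-oriented methods."""

    null: str = "permutation"  # permutation | passenger
    heterogeneity: bool = False
    p_value_mode: str = "exact"  # exact | monte_carlo
    mc_reps: int = 100_000
    seed: int = 0
    weight_strategy: str = "neglog"

    def __post_init__(self) -> None:
        if self.null not in {"permutation", "passenger"}:
            raise ValueError(f"unknown null {self.null!r}")
        if self.p_value_mode not in {"exact", "monte_carlo"}:
            raise ValueError(f"unknown p_value_mode {self.p_value_mode!r}")

    @property
    def name(self) -> str:
        het = "with" if self.heterogeneity else "without"
        return f"{self.null} null {het} heterogeneity"


def _neglog_weights(pi: np.ndarray) -> np.ndarray:
    w = np.zeros_like(pi)
    interior = (pi > 0) & (pi < 1)
    w[interior] = -np.log(pi[interior])
    return w


#: Pluggable heterogeneity weight strategies (pi column -> weight vector).
WEIGHT_STRATEGIES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "neglog": _neglog_weights,
    "unit": lambda pi: np.ones_like(pi),
    "one_minus_pi": lambda pi: 1.0 - pi,
}


def heterogeneity_weights(
    pi_column: Sequence[float], strategy: str = "neglog"
) -> np.ndarray:
    """Per-patient weights from the null alteration probabilities.

    Patients with pi = 0 cannot be altered under the null and get weight 0;
    patients with pi = 1 carry no evidence and also get weight 0 (boundary
    convention — a set with pi = 1 everywhere is untestable).
    """
    pi = np.asarray(pi_column, dtype=float)
    if np.any(pi < 0) or np.any(pi > 1):
        raise ValueError("alteration probabilities must lie in [0, 1]")
    try:
        fn = WEIGHT_STRATEGIES[strategy]
    except KeyError:
        raise ValueError(
            f"unknown weight strategy {strategy!r}; known: {sorted(WEIGHT_STRATEGIES)}"
        ) from None
    w = np.asarray(fn(pi), dtype=float)
    if np.any(~np.isfinite(w)) or np.any(w < 0):
        raise ValueError("weights must be finite and non-negative")
    return w


def alteration_indicator(
    catalog: MutationCatalog, set_genes: Sequence[str]
) -> np.ndarray:
    """Binary vector over patients: 1 iff any gene of the set is altered."""
    idx = [catalog.gene_index[g] for g in set_genes if g in catalog.gene_index]
    if not idx:
        raise ValueError("gene set has no genes in the catalog universe")
    x = catalog.binary_matrix()
    return x[:, idx].any(axis=1).astype(np.int64)


def set_score(z: Sequence[int], w: Sequence[float] | None = None) -> float:
    """T_s = sum_i w_i z_i; an integer patient count when weights are 1."""
    z = np.asarray(z, dtype=float)
    if w is None:
        w = np.ones_like(z)
    w = np.asarray(w, dtype=float)
    if z.shape != w.shape:
        raise ValueError("indicator and weight vectors differ in length")
    return float(w @ z)


# ---------------------------------------------------------------------------
# exact null distributions
# ---------------------------------------------------------------------------


def poisson_binomial_pmf(pi: Sequence[float]) -> np.ndarray:
    """Exact pmf of T = sum_i Bernoulli(pi_i) by iterative convolution."""
    p = np.asarray(pi, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for k, pk in enumerate(p):
        pmf[1 : k + 2] = pmf[1 : k + 2] * (1 - pk) + pmf[: k + 1] * pk
        pmf[0] *= 1 - pk
    return pmf


def poisson_binomial_tail(pi: Sequence[float], t_obs: int) -> float:
    """Exact P(T >= t_obs), including the observed point mass."""
    if t_obs < 0:
        raise ValueError("t_obs must be >= 0")
    p = np.asarray(pi, dtype=float)
    if t_obs == 0:
        return 1.0
    if t_obs > p.size:
        return 0.0
    pmf = poisson_binomial_pmf(p)
    return float(np.clip(pmf[t_obs:].sum(), 0.0, 1.0))


def _enumerate_outcomes(w: np.ndarray, pi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All 2^n subset sums of w with their joint probabilities."""
    sums = np.zeros(1)
    probs = np.ones(1)
    for wk, pk in zip(w, pi):
        sums = np.concatenate([sums, sums + wk])
        probs = np.concatenate([probs * (1 - pk), probs * pk])
    return sums, probs


def weighted_score_tail(
    pi: Sequence[float],
    w: Sequence[float],
    t_obs: float,
    mode: str = "enumerate",
    mc_reps: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """P(sum_i w_i B_i >= t_obs) with independent B_i ~ Bernoulli(pi_i).

    ``enumerate`` computes the exact sum over all 2^n outcomes via a
    meet-in-the-middle split (feasible up to n = 25); ``monte_carlo`` returns
    the add-one estimator (1 + #{replicates >= t}) / (reps + 1), which is
    never exactly zero.  Outcome sums within 1e-9 * (1 + |t|) of the
    threshold count as ties, so the observed point mass is retained under
    floating-point re-association.
    """
    p = np.asarray(pi, dtype=float)
    ww = np.asarray(w, dtype=float)
    if p.shape != ww.shape:
        raise ValueError("probability and weight vectors differ in length")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if t_obs <= 0:
        return 1.0
    eps = 1e-9 * (1.0 + abs(t_obs))
    if mode == "enumerate":
        n = p.size
        if n > ENUMERATION_LIMIT:
            raise ValueError(
                f"enumeration limited to n <= {ENUMERATION_LIMIT}; "
                "use mode='monte_carlo'"
            )
        half = n // 2
        sa, pa = _enumerate_outcomes(ww[:half], p[:half])
        sb, pb = _enumerate_outcomes(ww[half:], p[half:])
        order = np.argsort(sb)
        sb = sb[order]
        pb = pb[order]
        tail_pb = np.concatenate([np.cumsum(pb[::-1])[::-1], [0.0]])
        idx = np.searchsorted(sb, t_obs - sa - eps, side="left")
        return float(np.clip(pa @ tail_pb[idx], 0.0, 1.0))
    if mode == "monte_carlo":
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        hits = 0
        chunk = max(1, min(mc_reps, 2_000_000 // max(1, p.size)))
        done = 0
        while done < mc_reps:
            b = min(chunk, mc_reps - done)
            draws = rng.random((b, p.size)) < p
            hits += int(np.count_nonzero(draws @ ww >= t_obs - eps))
            done += b
        return (1 + hits) / (mc_reps + 1)
    raise ValueError(f"unknown mode {mode!r}; expected enumerate|monte_carlo")


def null_moments(
    pi: Sequence[float], w: Sequence[float] | None = None
) -> tuple[float, float]:
    """Mean and SD of T_s under the null: sum w pi, sqrt(sum w^2 pi (1-pi))."""
    p = np.asarray(pi, dtype=float)
    ww = np.ones_like(p) if w is None else np.asarray(w, dtype=float)
    if p.shape != ww.shape:
        raise ValueError("probability and weight vectors differ in length")
    mean = float(ww @ p)
    sd = float(np.sqrt((ww**2) @ (p * (1 - p))))
    return mean, sd


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------


def run_patient_gsa(
    catalog: MutationCatalog,
    sets: GeneSetCollection,
    spec: MethodSpec = MethodSpec(),
    gene_models: GeneModelTable | None = None,
    rates: PassengerModel | None = None,
) -> pd.DataFrame:
    """Score every gene set with one patient-oriented method.

    Returns the result table (one row per set) with the observed score T_s,
    its null mean and SD, the exact or Monte-Carlo P-value, BH q-value and
    ascending-P midrank, sorted by (P, set_id).  Sets whose null alteration
    probability is 1 in every patient carry no information and are flagged
    ``untestable`` with P = 1.
    """
    profile = build_profile(catalog, sets, spec.null, gene_models, rates)
    membership, set_ids = sets.membership_matrix(catalog.gene_universe)
    sizes = membership.sum(axis=0)
    if np.any(sizes < 1):
        empty = [set_ids[k] for k in np.nonzero(sizes < 1)[0]]
        raise ValueError(
            f"sets with no genes in the universe (filter first): {empty[:10]}"
        )
    x = catalog.binary_matrix()
    z_all = (x.astype(np.float32) @ membership.astype(np.float32)) > 0.5
    pi_all = profile.pi.to_numpy()
    n = catalog.n_samples
    ss = np.random.SeedSequence([spec.seed, 0x706F67])
    mc_rngs = [np.random.default_rng(s) for s in ss.spawn(len(set_ids))]

    rows = []
    for k, sid in enumerate(set_ids):
        pi = pi_all[:, k]
        z = z_all[:, k].astype(np.int64)
        note = ""
        if spec.heterogeneity:
            w = heterogeneity_weights(pi, spec.weight_strategy)
        else:
            w = np.ones(n)
        t = set_score(z, w)
        mean, sd = null_moments(pi, w)
        if np.all(pi >= 1.0) or (spec.heterogeneity and not np.any(w > 0)):
            p_val = 1.0
            note = "untestable"
        elif spec.p_value_mode == "exact":
            if not spec.heterogeneity:
                p_val = poisson_binomial_tail(pi, int(round(t)))
            elif n <= ENUMERATION_LIMIT:
                p_val = weighted_score_tail(pi, w, t, mode="enumerate")
            else:
                log.info(
                    "set %s: cohort of %d exceeds enumeration limit; "
                    "falling back to Monte Carlo",
                    sid, n,
                )
                p_val = weighted_score_tail(
                    pi, w, t, mode="monte_carlo",
                    mc_reps=spec.mc_reps, seed=mc_rngs[k],
                )
        else:
            p_val = weighted_score_tail(
                pi, w, t, mode="monte_carlo",
                mc_reps=spec.mc_reps, seed=mc_rngs[k],
            )
        rows.append((sid, int(sizes[k]), t, mean, sd, p_val, note))

    table = pd.DataFrame(
        rows,
        columns=["set_id", "size", "score", "null_mean", "null_sd", "p_value", "note"],
    )
    table["q_value"] = bh_qvalues(table["p_value"].to_numpy())
    table["rank"] = midranks(table["p_value"].to_numpy())
    return sort_results(table[list(RESULT_COLUMNS)])
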