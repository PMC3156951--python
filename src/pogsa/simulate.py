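"""Controlled simulation framework: synthetic cohorts, null data-generating
mechanisms, spike-in gene sets, and power/calibration evaluation.

The synthetic cohort generator emulates an exome sequencing study of the
scale used throughout the package's validation: 21 tumors over a ~20,661
gene universe with per-patient mutation loads between 12 and 63 events, and
a collection of overlapping gene sets of 3 to 2,096 genes.  Simulated
benchmark datasets combine

* a *null* catalog drawn either by permuting events among genes (weighted
  by passenger expectation, with optional "mountain" genes excluded first)
  or directly from the passenger rate model, and
* 12 *spiked-in* gene sets of hypothetical genes with known per-patient
  alteration probabilities (sizes 25/100/250 crossed with probabilities
  0.25/0.50/0.75/0.90) which constitute the ground-truth signal.

Power is summarized as the average number of spiked sets among the top-X
ranked sets; calibration as the average realized false-discovery proportion
against the average q-value.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genes import run_gene_gsa
from .io import (
    DEFAULT_CONTEXTS,
    GeneModelTable,
    GeneSetCollection,
    MutationCatalog,
    MutationEvent,
    PassengerModel,
)
from .null_models import (
    sample_passenger_null,
    weighted_sample_without_replacement,
)
from .patient import MethodSpec, run_patient_gsa

__all__ = [
    "SpikeInConfig",
    "SimulationResult",
    "synth_cohort",
    "null_mechanism_permute",
    "spike_in",
    "run_simulation",
    "subsample_power",
    "calibration_at",
]

#: Fraction of a gene's sequenced nucleotides falling in each context class.
CONTEXT_FRACTIONS = {
    "CG_to_TA_CpG": 0.02,
    "CG_to_TA_other": 0.18,
    "CG_transversion": 0.20,
    "TA_any": 0.55,
    "indel": 0.05,
}

#: Relative passenger rates per context (CpG transitions dominate).
RELATIVE_RATES = {
    "CG_to_TA_CpG": 20.0,
    "CG_to_TA_other": 4.0,
    "CG_transversion": 1.5,
    "TA_any": 1.0,
    "indel": 0.8,
}


@dataclass(frozen=True)
class SpikeInConfig:
    """Sizes and per-patient alteration probabilities of the spiked sets.

    The defaults cross three sizes with four probabilities, yielding exactly
    12 spiked sets per simulated dataset.
    """

    sizes: tuple[int, ...] = (25, 100, 250)
    alteration_probabilities: tuple[float, ...] = (0.25, 0.50, 0.75, 0.90)

    def __post_init__(self) -> None:
        if len(set(self.sizes)) != len(self.sizes) or len(
            set(self.alteration_probabilities)
        ) != len(self.alteration_probabilities):
            raise ValueError("spike-in sizes and probabilities must be distinct")
        for p in self.alteration_probabilities:
            if not 0 <= p < 1:
                raise ValueError(f"alteration probability out of [0, 1): {p}")

    def pairs(self) -> list[tuple[int, float]]:
        return [(s, p) for s in self.sizes for p in self.alteration_probabilities]

    @staticmethod
    def set_id(size: int, prob: float) -> str:
        return f"spike_m{size}_p{int(round(prob * 100)):02d}"

    def set_ids(self) -> list[str]:
        return [self.set_id(s, p) for s, p in self.pairs()]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# synthetic cohort
# ---------------------------------------------------------------------------


def synth_cohort(
    n_patients: int = 21,
    n_genes: int = 20661,
    load_range: tuple[int, int] = (12, 63),
    set_count: int = 3071,
    set_size_range: tuple[int, int] = (3, 2096),
    set_size_log_median: float = 10.0,
    set_size_sigma: float = 1.4,
    reuse_strength: float = 1.0,
    seed: int = 0,
) -> tuple[MutationCatalog, GeneSetCollection, GeneModelTable, PassengerModel]:
    """Generate a synthetic exome cohort with gene models, rates and sets.

    Gene coding lengths follow a log-normal size model (median ~1.3 kb);
    context-specific passenger rates are scaled so the expected passenger
    load per tumor at multiplier 1 equals the midpoint of ``load_range``,
    and each patient's observed load is drawn uniformly from that range
    (with its rate multiplier set accordingly).  Observed events land on
    distinct genes chosen proportionally to passenger expectation, so the
    catalog is null apart from sampling noise.  Gene sets are built with
    preferential gene reuse to mimic the heavy overlap of curated pathway
    collections.
    """
    lo, hi = load_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid load_range")
    if hi > n_genes:
        raise ValueError(
            f"load_range {load_range} infeasible for {n_genes} genes "
            "(events must hit distinct genes)"
        )
    rng = _as_rng(seed)
    samples = [f"P{i + 1:02d}" for i in range(n_patients)]
    genes = [f"g{j + 1:05d}" for j in range(n_genes)]
    lengths = rng.lognormal(mean=math.log(1300.0), sigma=0.6, size=n_genes)
    fracs = np.array([CONTEXT_FRACTIONS[c] for c in DEFAULT_CONTEXTS])
    table = pd.DataFrame(
        lengths[:, None] * fracs[None, :],
        index=pd.Index(genes, name="gene"),
        columns=list(DEFAULT_CONTEXTS),
    )
    models = GeneModelTable(table)

    target_load = (lo + hi) / 2.0
    rel = np.array([RELATIVE_RATES[c] for c in DEFAULT_CONTEXTS])
    total_rel = float((table.to_numpy() * rel).sum())
    scale = target_load / total_rel
    rates_map = {c: RELATIVE_RATES[c] * scale for c in DEFAULT_CONTEXTS}

    loads = rng.integers(lo, hi + 1, size=n_patients)
    multipliers = {s: float(loads[i]) / target_load for i, s in enumerate(samples)}
    rates = PassengerModel(rates_map, multipliers)

    lam = models.expected_counts(rates).to_numpy()
    ctx_exp = models.context_expectations(rates).to_numpy()
    ctx_probs = ctx_exp / ctx_exp.sum(axis=1, keepdims=True)
    n_ctx = len(DEFAULT_CONTEXTS)
    events: list[MutationEvent] = []
    for i, s in enumerate(samples):
        idx = weighted_sample_without_replacement(rng, lam, int(loads[i]))
        for j in idx:
            c = rng.choice(n_ctx, p=ctx_probs[int(j)])
            events.append(MutationEvent(s, genes[int(j)], DEFAULT_CONTEXTS[c]))
    catalog = MutationCatalog(samples, genes, events)

    smin, smax = set_size_range
    smax = min(smax, n_genes - 1)
    sizes = np.clip(
        np.round(
            rng.lognormal(math.log(set_size_log_median), set_size_sigma, set_count)
        ).astype(int),
        smin,
        smax,
    )
    usage = np.ones(n_genes)
    sets: dict[str, tuple[str, ...]] = {}
    width = max(4, len(str(set_count)))
    for k in range(set_count):
        keys = reuse_strength * np.log(usage) + rng.gumbel(size=n_genes)
        size = int(sizes[k])
        top = np.argpartition(-keys, size - 1)[:size]
        usage[top] += 1.0
        sets[f"BG{k + 1:0{width}d}"] = tuple(genes[j] for j in np.sort(top))
    return catalog, GeneSetCollection(sets), models, rates


# ---------------------------------------------------------------------------
# null data-generating mechanisms
# ---------------------------------------------------------------------------


def null_mechanism_permute(
    catalog: MutationCatalog,
    mountain_genes: Sequence[str],
    gene_models: GeneModelTable,
    rates: PassengerModel,
    seed,
    weighted: bool = True,
) -> MutationCatalog:
    """Null catalog by permuting non-mountain events among genes.

    Events in ``mountain_genes`` (recurrently mutated drivers) are removed;
    each patient's remaining events are reassigned to distinct genes with
    selection probability proportional to the gene's passenger expectation
    (or uniformly when ``weighted=False``), and contexts are resampled from
    the overall passenger context proportions.  Total event count equals the
    original minus the mountain events.
    """
    rng = _as_rng(seed)
    gene_models.require_genes(catalog.gene_universe)
    mountains = set(mountain_genes)
    lam = (
        gene_models.expected_counts(rates).reindex(catalog.gene_universe).to_numpy()
    )
    ctx_tot = (
        gene_models.context_expectations(rates)
        .reindex(catalog.gene_universe)
        .to_numpy()
        .sum(axis=0)
    )
    ctx_probs = ctx_tot / ctx_tot.sum()
    contexts = gene_models.contexts
    kept_counts = {s: 0 for s in catalog.samples}
    for ev in catalog.events:
        if ev.gene_id not in mountains:
            kept_counts[ev.sample_id] += 1
    events: list[MutationEvent] = []
    for s in catalog.samples:
        n = kept_counts[s]
        if n == 0:
            continue
        if weighted:
            idx = weighted_sample_without_replacement(rng, lam, n)
        else:
            idx = rng.choice(catalog.n_genes, size=n, replace=False)
        ctx = rng.choice(len(contexts), size=n, p=ctx_probs)
        for j, c in zip(idx, ctx):
            events.append(
                MutationEvent(s, catalog.gene_universe[int(j)], contexts[int(c)])
            )
    return MutationCatalog(catalog.samples, catalog.gene_universe, events)


def spike_in(
    sets_cfg: SpikeInConfig,
    gene_pool: GeneModelTable,
    samples: Sequence[str],
    rates: PassengerModel,
    seed,
) -> tuple[GeneSetCollection, list[MutationEvent], GeneModelTable]:
    """Create the spiked-in sets of hypothetical genes and their events.

    Each spiked set gets fresh gene ids whose nucleotide-context models are
    resampled (with replacement) from ``gene_pool``, so they are realistic
    but never collide with background sets.  Per (set, sample) a
    Bernoulli(p) coin decides alteration; an altered pair contributes
    exactly one mutation, on a set gene chosen proportionally to passenger
    expectation, with context drawn from that gene's passenger proportions.
    """
    rng = _as_rng(seed)
    pool = gene_pool.table.to_numpy(dtype=float)
    contexts = gene_pool.contexts
    r = np.array([rates.rates[c] for c in contexts])
    sets: dict[str, tuple[str, ...]] = {}
    events: list[MutationEvent] = []
    frames = []
    for size, prob in sets_cfg.pairs():
        sid = sets_cfg.set_id(size, prob)
        rows = rng.integers(0, pool.shape[0], size=size)
        gene_ids = [f"{sid}_g{j + 1:03d}" for j in range(size)]
        sub = pool[rows]
        frames.append(
            pd.DataFrame(sub, index=pd.Index(gene_ids, name="gene"), columns=contexts)
        )
        sets[sid] = tuple(gene_ids)
        lam = sub @ r
        gene_probs = lam / lam.sum()
        ctx_probs = sub * r
        ctx_probs = ctx_probs / ctx_probs.sum(axis=1, keepdims=True)
        for s in samples:
            if rng.random() < prob:
                j = rng.choice(size, p=gene_probs)
                c = rng.choice(len(contexts), p=ctx_probs[j])
                events.append(MutationEvent(s, gene_ids[int(j)], contexts[int(c)]))
    spike_models = GeneModelTable(pd.concat(frames, axis=0))
    return GeneSetCollection(sets), events, spike_models


# ---------------------------------------------------------------------------
# benchmark driver
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Aggregated output of :func:`run_simulation`."""

    methods: list[str]
    spiked_ids: list[str]
    replicates: pd.DataFrame  # rep, method, set_id, p, q, position, spiked
    power: pd.DataFrame  # method, X, avg_tp
    calibration: pd.DataFrame  # method, k, avg_q, avg_fdp, se_fdp


def _method_label(method) -> str:
    return method if isinstance(method, str) else method.name


def run_simulation(
    n_reps: int,
    mechanism: str,
    methods: Sequence,
    cfg: SpikeInConfig = SpikeInConfig(),
    *,
    catalog: MutationCatalog,
    sets: GeneSetCollection,
    gene_models: GeneModelTable,
    rates: PassengerModel,
    mountain_genes: Sequence[str] = (),
    top_x_max: int = 50,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SimulationResult:
    """Spike-in benchmark: repeated null datasets with known true positives.

    Per replicate, a null catalog is drawn with the chosen mechanism
    (``"permute"`` or ``"passenger"``), the 12 spiked sets are added, and
    every requested method (MethodSpec instances and/or the string
    ``"gene-oriented"``) is run on the combined data.  Replicate seeds are
    spawned from the master seed, so any replicate is reproducible in
    isolation.  ``out_dir`` optionally streams per-replicate tables to disk.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if mechanism not in {"permute", "passenger"}:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    labels = [_method_label(m) for m in methods]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate method labels")
    spiked_ids = cfg.set_ids()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(seed)
    rep_seeds = master.spawn(n_reps)
    records = []
    for rep, rep_ss in enumerate(rep_seeds):
        rng = np.random.default_rng(rep_ss)
        if mechanism == "permute":
            null_cat = null_mechanism_permute(
                catalog, mountain_genes, gene_models, rates, rng
            )
        else:
            null_cat = sample_passenger_null(
                catalog.samples, gene_models, rates, rng
            )
        spiked_sets, spike_events, spike_models = spike_in(
            cfg, gene_models, catalog.samples, rates, rng
        )
        universe = list(null_cat.gene_universe) + list(spike_models.genes)
        cat_r = MutationCatalog(
            catalog.samples, universe, list(null_cat.events) + spike_events
        )
        models_r = GeneModelTable.concat([gene_models, spike_models])
        all_sets = GeneSetCollection({**sets.sets, **spiked_sets.sets})
        for method, label in zip(methods, labels):
            if isinstance(method, str):
                res = run_gene_gsa(cat_r, all_sets, models_r, rates)
            else:
                res = run_patient_gsa(cat_r, all_sets, method, models_r, rates)
            res = res.reset_index(drop=True)
            spiked = res["set_id"].isin(spiked_ids).to_numpy()
            for pos in range(len(res)):
                records.append(
                    (
                        rep,
                        label,
                        res.at[pos, "set_id"],
                        res.at[pos, "p_value"],
                        res.at[pos, "q_value"],
                        pos + 1,
                        bool(spiked[pos]),
                    )
                )
        if out_path is not None:
            rep_df = pd.DataFrame(
                [r for r in records if r[0] == rep],
                columns=["rep", "method", "set_id", "p", "q", "position", "spiked"],
            )
            rep_df.to_csv(out_path / f"replicate_{rep:04d}.tsv", sep="\t", index=False)

    replicates = pd.DataFrame(
        records, columns=["rep", "method", "set_id", "p", "q", "position", "spiked"]
    )
    power = _aggregate_power(replicates, labels, top_x_max)
    calibration = _aggregate_calibration(replicates, labels)
    if out_path is not None:
        power.to_csv(out_path / "power.tsv", sep="\t", index=False)
        calibration.to_csv(out_path / "calibration.tsv", sep="\t", index=False)
    return SimulationResult(labels, spiked_ids, replicates, power, calibration)


def _aggregate_power(
    replicates: pd.DataFrame, labels: Sequence[str], top_x_max: int
) -> pd.DataFrame:
    rows = []
    for label in labels:
        sub = replicates[replicates["method"] == label]
        reps = sorted(sub["rep"].unique())
        curves = []
        for rep in reps:
            r = sub[sub["rep"] == rep].sort_values("position")
            tp = np.cumsum(r["spiked"].to_numpy())[:top_x_max]
            curves.append(tp)
        avg = np.mean(curves, axis=0)
        for x, val in enumerate(avg, start=1):
            rows.append((label, x, float(val)))
    return pd.DataFrame(rows, columns=["method", "X", "avg_tp"])


def _aggregate_calibration(
    replicates: pd.DataFrame, labels: Sequence[str]
) -> pd.DataFrame:
    rows = []
    for label in labels:
        sub = replicates[replicates["method"] == label]
        reps = sorted(sub["rep"].unique())
        fdp_curves = []
        q_curves = []
        for rep in reps:
            r = sub[sub["rep"] == rep].sort_values("position")
            background = (~r["spiked"].to_numpy()).astype(float)
            k = np.arange(1, len(r) + 1)
            fdp_curves.append(np.cumsum(background) / k)
            q_curves.append(r["q"].to_numpy())
        fdp = np.asarray(fdp_curves)
        q = np.asarray(q_curves)
        n = fdp.shape[0]
        se = fdp.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros(fdp.shape[1])
        for k in range(fdp.shape[1]):
            rows.append(
                (
                    label,
                    k + 1,
                    float(q[:, k].mean()),
                    float(fdp[:, k].mean()),
                    float(se[k]),
                )
            )
    return pd.DataFrame(rows, columns=["method", "k", "avg_q", "avg_fdp", "se_fdp"])


def calibration_at(
    result: SimulationResult, method: str, q_target: float
) -> tuple[float, float, float] | None:
    """Calibration point at the largest list size whose average q-value is
    at or below ``q_target``; None when no such list exists.

    Returns (avg_q, avg_fdp, se_fdp).
    """
    cal = result.calibration[result.calibration["method"] == method]
    ok = cal[cal["avg_q"] <= q_target]
    if len(ok) == 0:
        return None
    row = ok.loc[ok["k"].idxmax()]
    return float(row["avg_q"]), float(row["avg_fdp"]), float(row["se_fdp"])


def subsample_power(
    catalog: MutationCatalog,
    sets: GeneSetCollection,
    n_patients_list: Sequence[int],
    n_reps: int,
    spec: MethodSpec = MethodSpec(),
    q_threshold: float = 0.1,
    seed: int = 0,
    gene_models: GeneModelTable | None = None,
    rates: PassengerModel | None = None,
) -> pd.DataFrame:
    """Sample-size analysis by subsampling patients without replacement.

    For each cohort size n and replicate, n patients are drawn, the method
    is rerun, and each set's frequency of reaching q <= ``q_threshold``
    across replicates is recorded.  Returns rows (n_patients, set_id,
    detection_frequency).
    """
    for n in n_patients_list:
        if n > catalog.n_samples:
            raise ValueError(f"cannot subsample {n} of {catalog.n_samples} patients")
    master = np.random.SeedSequence([seed, 0x5B5])
    rows = []
    for n in n_patients_list:
        hits: dict[str, int] = {sid: 0 for sid in sets}
        for rep_ss in master.spawn(n_reps):
            rng = np.random.default_rng(rep_ss)
            chosen = [
                catalog.samples[i]
                for i in rng.choice(catalog.n_samples, size=n, replace=False)
            ]
            sub = catalog.subset_samples(chosen)
            # adjust passenger multipliers only through the shared rates object
            res = run_patient_gsa(sub, sets, spec, gene_models, rates)
            sig = res.loc[res["q_value"] <= q_threshold, "set_id"]
            for sid in sig:
                hits[sid] += 1
        for sid in sets:
            rows.append((n, sid, hits[sid] / n_reps))
    return pd.DataFrame(
        rows, columns=["n_patients", "set_id", "detection_frequency"]
    )
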