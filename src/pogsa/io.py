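"""Domain types and file formats for mutation gene set analysis.

The package works with four inputs:

* a somatic mutation catalog: tab-separated ``sample  gene  context`` events,
  one row per nonsynonymous point mutation or indel;
* gene set collections in GMT format (``name  description  gene ...``);
* a gene model table: per gene, the number of successfully sequenced
  nucleotides at risk in each mutation-context class (coverage-adjusted);
* passenger mutation rates per context class (YAML/JSON), optionally with
  per-sample rate multipliers.

Results are tab-separated tables with one row per gene set.

All identifiers are case-sensitive exact strings; no symbol aliasing is
performed.  Genes annotated to a set but absent from the sequenced universe
are silently intersected away (with a logged count), since pathway
annotations routinely exceed the sequenced exome.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

#: Default mutation-context vocabulary: transitions at CpG dinucleotides,
#: other C:G transitions, C:G transversions, all changes at T:A pairs, and
#: small insertions/deletions.
DEFAULT_CONTEXTS = (
    "CG_to_TA_CpG",
    "CG_to_TA_other",
    "CG_transversion",
    "TA_any",
    "indel",
)

#: Fixed column order of a gene set result table.
RESULT_COLUMNS = (
    "set_id",
    "size",
    "score",
    "null_mean",
    "null_sd",
    "p_value",
    "q_value",
    "rank",
    "note",
)


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# mutation catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationEvent:
    """A single somatic mutation observed in one tumor sample."""

    sample_id: str
    gene_id: str
    context_class: str


class MutationCatalog:
    """Per-patient somatic mutation events over a fixed gene universe.

    Multiple events in the same (sample, gene) pair are legal; the derived
    binary alteration matrix collapses them to a single 1.
    """

    def __init__(
        self,
        samples: Sequence[str],
        gene_universe: Sequence[str],
        events: Sequence[MutationEvent],
    ) -> None:
        self.samples = list(samples)
        self.gene_universe = list(gene_universe)
        self.events = list(events)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        if len(set(self.gene_universe)) != len(self.gene_universe):
            raise ValueError("duplicate gene identifiers in universe")
        self.sample_index = {s: i for i, s in enumerate(self.samples)}
        self.gene_index = {g: j for j, g in enumerate(self.gene_universe)}
        for ev in self.events:
            if ev.sample_id not in self.sample_index:
                raise ValueError(f"event sample {ev.sample_id!r} not declared")
            if ev.gene_id not in self.gene_index:
                raise ValueError(f"event gene {ev.gene_id!r} not in universe")
        self._matrix: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_genes(self) -> int:
        return len(self.gene_universe)

    def event_counts(self) -> np.ndarray:
        """Total event count n_i per sample (multiplicity included)."""
        counts = np.zeros(self.n_samples, dtype=np.int64)
        for ev in self.events:
            counts[self.sample_index[ev.sample_id]] += 1
        return counts

    def binary_matrix(self) -> np.ndarray:
        """Boolean samples x genes matrix: x[i, j] = 1 iff >=1 event."""
        if self._matrix is None:
            x = np.zeros((self.n_samples, self.n_genes), dtype=bool)
            for ev in self.events:
                x[self.sample_index[ev.sample_id], self.gene_index[ev.gene_id]] = True
            self._matrix = x
        return self._matrix

    def altered_genes(self, sample_id: str) -> set[str]:
        return {ev.gene_id for ev in self.events if ev.sample_id == sample_id}

    def gene_event_counts(self) -> np.ndarray:
        """Total event count per gene across all samples (with multiplicity)."""
        counts = np.zeros(self.n_genes, dtype=np.int64)
        for ev in self.events:
            counts[self.gene_index[ev.gene_id]] += 1
        return counts

    def subset_samples(self, samples: Sequence[str]) -> "MutationCatalog":
        keep = set(samples)
        return MutationCatalog(
            list(samples),
            self.gene_universe,
            [ev for ev in self.events if ev.sample_id in keep],
        )


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def _dedup(genes: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for g in genes:
        seen.setdefault(g, None)
    return tuple(seen)


@dataclass
class GeneSetCollection:
    """Named, possibly overlapping gene sets.

    Membership lists are ordered and deduplicated.  Set sizes used by any
    probability computation are always taken AFTER intersection with the
    gene universe of the catalog at hand.
    """

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: _dedup(genes) for name, genes in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id]

    def items(self):
        return self.sets.items()

    def sizes(self) -> dict[str, int]:
        return {name: len(genes) for name, genes in self.sets.items()}

    def membership_matrix(
        self, universe: Sequence[str]
    ) -> tuple[np.ndarray, list[str]]:
        """Boolean genes x sets matrix over *universe* plus the set id order."""
        gene_index = {g: j for j, g in enumerate(universe)}
        set_ids = list(self.sets)
        m = np.zeros((len(universe), len(set_ids)), dtype=bool)
        for k, sid in enumerate(set_ids):
            for g in self.sets[sid]:
                j = gene_index.get(g)
                if j is not None:
                    m[j, k] = True
        return m, set_ids


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a set are deduplicated; duplicate set names are an
    error.  Lines with fewer than three fields raise :class:`ParseError`
    naming the offending line.
    """
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *genes = fields
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = _dedup(g for g in genes if g)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in coll.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def filter_sets(
    coll: GeneSetCollection,
    universe: Sequence[str],
    min_size: int = 3,
    max_size: int = 2096,
) -> GeneSetCollection:
    """Intersect each set with *universe* and drop sets outside the size bounds.

    Idempotent.  The number of dropped sets and of intersected-away genes is
    logged.
    """
    if min_size < 1 or max_size < min_size:
        raise ValueError("require 1 <= min_size <= max_size")
    if len(universe) == 0:
        raise ValueError("empty gene universe")
    uni = set(universe)
    kept: dict[str, tuple[str, ...]] = {}
    dropped = 0
    lost_genes = 0
    for name, genes in coll.items():
        inter = tuple(g for g in genes if g in uni)
        lost_genes += len(genes) - len(inter)
        if min_size <= len(inter) <= max_size:
            kept[name] = inter
        else:
            dropped += 1
    log.info(
        "filter_sets: kept %d/%d sets (%d dropped, %d out-of-universe genes removed)",
        len(kept), len(coll), dropped, lost_genes,
    )
    return GeneSetCollection(
        kept, {n: coll.descriptions.get(n, "") for n in kept}
    )


# ---------------------------------------------------------------------------
# gene models and passenger rates
# ---------------------------------------------------------------------------


@dataclass
class GeneModelTable:
    """Per-gene nucleotide counts at risk, partitioned by context class.

    ``table`` is indexed by gene id with one column per context class; values
    are coverage-adjusted counts of successfully sequenced nucleotides and
    must be non-negative.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in gene model table")
        values = self.table.to_numpy(dtype=float)
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("gene model counts must be finite and non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def contexts(self) -> list[str]:
        return list(self.table.columns)

    def require_genes(self, genes: Iterable[str]) -> None:
        missing = [g for g in genes if g not in self.table.index]
        if missing:
            head = ", ".join(missing[:10])
            raise KeyError(
                f"{len(missing)} gene(s) missing from the gene model table: {head}"
            )

    def expected_counts(self, rates: "PassengerModel") -> pd.Series:
        """Per-gene expected passenger mutation count per tumor at f = 1.

        lambda_j = sum_c L_jc * r_c.
        """
        r = np.array([rates.rates[c] for c in self.contexts])
        lam = self.table.to_numpy(dtype=float) @ r
        return pd.Series(lam, index=self.table.index, name="lambda")

    def context_expectations(self, rates: "PassengerModel") -> pd.DataFrame:
        """Per (gene, context) expected passenger count, L_jc * r_c at f = 1."""
        r = np.array([rates.rates[c] for c in self.contexts])
        return self.table * r

    def subset(self, genes: Sequence[str]) -> "GeneModelTable":
        self.require_genes(genes)
        return GeneModelTable(self.table.loc[list(genes)].copy())

    @staticmethod
    def concat(parts: Sequence["GeneModelTable"]) -> "GeneModelTable":
        return GeneModelTable(pd.concat([p.table for p in parts], axis=0))


@dataclass
class PassengerModel:
    """Passenger mutation rates per context class.

    ``rates[c]`` is the expected number of passenger mutations per sequenced
    nucleotide of context ``c`` per tumor; ``sample_multipliers`` optionally
    scales the whole rate vector per sample (default 1), accommodating
    patient-to-patient variation in mutation load.
    """

    rates: dict[str, float]
    sample_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c, r in self.rates.items():
            if not (0 <= r < 1):
                raise ValueError(f"rate for context {c!r} must be in [0, 1): {r}")
        for s, f in self.sample_multipliers.items():
            if not f > 0:
                raise ValueError(f"multiplier for sample {s!r} must be > 0: {f}")

    def multiplier(self, sample_id: str) -> float:
        return self.sample_multipliers.get(sample_id, 1.0)

    def multipliers_for(self, samples: Sequence[str]) -> np.ndarray:
        return np.array([self.multiplier(s) for s in samples], dtype=float)


def read_gene_models(path: str | Path) -> GeneModelTable:
    """Read a gene model TSV: ``gene`` column plus one column per context."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ParseError(f"{path}: gene model table requires a 'gene' column")
    return GeneModelTable(df.set_index("gene"))


def write_gene_models(models: GeneModelTable, path: str | Path) -> None:
    models.table.rename_axis("gene").reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_passenger_model(path: str | Path) -> PassengerModel:
    """Read passenger rates from YAML/JSON.

    Accepts either a flat ``{context: rate}`` mapping or a mapping with keys
    ``rates`` and optional ``sample_multipliers``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ParseError(f"{path}: expected a mapping of rates")
    if "rates" in data:
        return PassengerModel(
            {str(k): float(v) for k, v in data["rates"].items()},
            {str(k): float(v) for k, v in (data.get("sample_multipliers") or {}).items()},
        )
    return PassengerModel({str(k): float(v) for k, v in data.items()})


def write_passenger_model(model: PassengerModel, path: str | Path) -> None:
    payload: dict = {"rates": {k: float(v) for k, v in model.rates.items()}}
    if model.sample_multipliers:
        payload["sample_multipliers"] = {
            k: float(v) for k, v in model.sample_multipliers.items()
        }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# mutation tables
# ---------------------------------------------------------------------------


def read_mutations(
    path: str | Path,
    universe: Sequence[str] | None = None,
    contexts: Sequence[str] = DEFAULT_CONTEXTS,
    samples: Sequence[str] | None = None,
    on_unknown_gene: str = "drop",
) -> MutationCatalog:
    """Read a mutation catalog from a 3-column TSV (sample, gene, context).

    Parameters
    ----------
    universe
        Declared gene universe.  When omitted, the universe is the sorted
        list of genes observed in the file.
    samples
        Declared sample list; lets samples with zero events be represented.
        When omitted, samples are those observed in the file, in order of
        first appearance.
    on_unknown_gene
        What to do with events whose gene is outside the universe:
        ``"drop"`` (warn and discard), ``"extend"`` (add the gene to the
        universe) or ``"error"``.
    """
    if on_unknown_gene not in {"drop", "extend", "error"}:
        raise ValueError("on_unknown_gene must be 'drop', 'extend' or 'error'")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "gene", "context"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: mutation table requires columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    permitted = set(contexts)
    bad = sorted(set(df["context"].dropna()) - permitted)
    if bad:
        raise ParseError(
            f"{path}: unknown context label(s) {bad}; permitted: {sorted(permitted)}"
        )
    uni = list(universe) if universe is not None else sorted(set(df["gene"].dropna()))
    known = set(uni)
    events: list[MutationEvent] = []
    unknown = 0
    for row in df.itertuples(index=False):
        if row.gene not in known:
            if on_unknown_gene == "error":
                raise ParseError(f"{path}: gene {row.gene!r} not in universe")
            if on_unknown_gene == "drop":
                unknown += 1
                continue
            uni.append(row.gene)
            known.add(row.gene)
        events.append(MutationEvent(row.sample, row.gene, row.context))
    if unknown:
        log.warning("read_mutations: dropped %d event(s) outside the universe", unknown)
    if samples is not None:
        sample_list = list(samples)
        extra = {ev.sample_id for ev in events} - set(sample_list)
        if extra:
            raise ParseError(f"{path}: undeclared sample(s): {sorted(extra)}")
    else:
        seen: dict[str, None] = {}
        for ev in events:
            seen.setdefault(ev.sample_id, None)
        sample_list = list(seen)
    return MutationCatalog(sample_list, uni, events)


def read_maf_lite(
    path: str | Path,
    context_column: str = "context",
    **kwargs,
) -> MutationCatalog:
    """Convenience adapter for MAF-style column names.

    Maps ``Tumor_Sample_Barcode`` -> sample and ``Hugo_Symbol`` -> gene, then
    defers to :func:`read_mutations` semantics in memory.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(
        columns={
            "Tumor_Sample_Barcode": "sample",
            "Hugo_Symbol": "gene",
            context_column: "context",
        }
    )
    import io as _io

    buf = _io.StringIO()
    df[["sample", "gene", "context"]].to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return read_mutations(buf, **kwargs)


def write_mutations(catalog: MutationCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgene\tcontext\n")
        for ev in catalog.events:
            fh.write(f"{ev.sample_id}\t{ev.gene_id}\t{ev.context_class}\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def sort_results(table: pd.DataFrame) -> pd.DataFrame:
    """Stable result ordering: P-value ascending, ties broken by set_id."""
    return table.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(
        drop=True
    )


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a gene set result table as TSV in the fixed column order."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"result table missing columns: {missing}")
    out = sort_results(table)[list(RESULT_COLUMNS)]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["note"] = df.get("note", pd.Series([""] * len(df))).fillna("")
    return df
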