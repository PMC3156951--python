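"""Null alteration probabilities and catalog samplers."""
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from pogsa import (
    GeneSetCollection,
    MutationCatalog,
    MutationEvent,
    PassengerModel,
    build_profile,
    passenger_gene_prob,
    passenger_set_prob,
    perm_alteration_prob,
    sample_passenger_null,
    sample_permutation_null,
)
from tests.conftest import uniform_gene_models


def enumerated_perm_prob(n: int, G: int, m: int) -> float:
    """Oracle: exhaustive enumeration of all C(G, n) distinct-gene choices."""
    target = set(range(m))
    combos = list(combinations(range(G), n))
    hits = sum(1 for c in combos if target & set(c))
    return hits / len(combos)


class TestPermAlterationProb:
    @pytest.mark.parametrize(
        "n,G,m,expected",
        [
            (0, 100, 10, 0.0),
            (1, 10, 10, 1.0),
            (2, 4, 2, 5 / 6),
        ],
    )
    def test_known_values(self, n, G, m, expected):
        assert perm_alteration_prob(n, G, m) == pytest.approx(expected, abs=1e-12)

    def test_matches_exhaustive_enumeration_small_universes(self):
        for G in range(1, 9):
            for m in range(1, G + 1):
                for n in range(0, G + 1):
                    assert perm_alteration_prob(n, G, m) == pytest.approx(
                        enumerated_perm_prob(n, G, m), abs=1e-10
                    ), (n, G, m)

    def test_monotone_in_n_and_m(self):
        G = 40
        for m in (1, 5, 20, 40):
            vals = [perm_alteration_prob(n, G, m) for n in range(G + 1)]
            assert np.all(np.diff(vals) >= -1e-12)
        for n in (1, 7, 30):
            vals = [perm_alteration_prob(n, G, m) for m in range(1, G + 1)]
            assert np.all(np.diff(vals) >= -1e-12)

    def test_whole_universe_always_hit(self):
        for n in range(1, 12):
            assert perm_alteration_prob(n, 11, 11) == 1.0

    def test_too_many_events_rejected(self):
        with pytest.raises(ValueError):
            perm_alteration_prob(11, 10, 3)


class TestPassengerProbs:
    def test_zero_rates_give_zero(self):
        rates = PassengerModel({"a": 0.0, "b": 0.0})
        assert passenger_gene_prob({"a": 500, "b": 500}, rates) == 0.0

    def test_closed_form_single_context(self):
        rates = PassengerModel({"a": 1e-6})
        q = passenger_gene_prob({"a": 1000.0}, rates)
        assert q == pytest.approx(1 - np.exp(-0.001), rel=1e-12)

    def test_doubling_multiplier_identity(self):
        rates = PassengerModel({"a": 2e-5})
        q1 = passenger_gene_prob({"a": 3000.0}, rates, sample_multiplier=1.0)
        q2 = passenger_gene_prob({"a": 3000.0}, rates, sample_multiplier=2.0)
        assert q2 == pytest.approx(1 - (1 - q1) ** 2, rel=1e-12)

    def test_matches_poisson_simulation(self):
        rates = PassengerModel({"a": 1e-4})
        q = passenger_gene_prob({"a": 1000.0}, rates)  # lambda = 0.1
        rng = np.random.default_rng(5)
        draws = rng.poisson(0.1, size=10**6)
        freq = np.mean(draws >= 1)
        se = np.sqrt(q * (1 - q) / 10**6)
        assert abs(freq - q) < 3 * se

    @pytest.mark.parametrize(
        "probs,expected",
        [((0.5, 0.5), 0.75), ((0.1, 1.0, 0.3), 1.0), ((0.1, 0.2, 0.3), 0.496)],
    )
    def test_set_prob(self, probs, expected):
        assert passenger_set_prob(probs) == pytest.approx(expected, abs=1e-12)

    def test_set_prob_empty_rejected(self):
        with pytest.raises(ValueError):
            passenger_set_prob([])


class TestBuildProfile:
    def test_zero_load_patient_has_zero_row(self):
        universe = [f"g{i}" for i in range(20)]
        cat = MutationCatalog(
            ["p1", "p2"], universe, [MutationEvent("p1", "g0", "c")]
        )
        sets = GeneSetCollection({"s": tuple(universe[:5])})
        prof = build_profile(cat, sets, "permutation")
        assert prof.pi.loc["p2", "s"] == 0.0
        assert prof.pi.loc["p1", "s"] > 0.0

    def test_equal_sizes_give_identical_columns(self):
        universe = [f"g{i}" for i in range(30)]
        events = [MutationEvent("p1", g, "c") for g in universe[:4]]
        cat = MutationCatalog(["p1"], universe, events)
        sets = GeneSetCollection(
            {"a": tuple(universe[:6]), "b": tuple(universe[10:16])}
        )
        prof = build_profile(cat, sets, "permutation")
        assert prof.pi["a"].tolist() == prof.pi["b"].tolist()

    def test_permutation_profile_matches_empirical_frequency(self):
        G, m, n, reps = 50, 5, 10, 100_000
        universe = [f"g{i}" for i in range(G)]
        events = [MutationEvent("p", g, "c") for g in universe[:n]]
        cat = MutationCatalog(["p"], universe, events)
        sets = GeneSetCollection({"s": tuple(universe[:m])})
        pi = build_profile(cat, sets, "permutation").pi.loc["p", "s"]
        rng = np.random.default_rng(11)
        target = set(range(m))
        hits = sum(
            1 for _ in range(reps) if target & set(rng.choice(G, n, replace=False))
        )
        freq = hits / reps
        se = np.sqrt(pi * (1 - pi) / reps)
        assert abs(freq - pi) < 3 * se

    def test_passenger_profile_matches_sampler_frequency(self):
        universe = [f"g{i}" for i in range(10)]
        models = uniform_gene_models(universe, length=1000.0)
        rates = PassengerModel({"ctx": 2e-4}, {"p1": 1.0, "p2": 2.0})
        cat = MutationCatalog(["p1", "p2"], universe, [])
        sets = GeneSetCollection({"s": tuple(universe[:4])})
        prof = build_profile(cat, sets, "passenger", models, rates)
        reps = 20_000
        rng = np.random.default_rng(3)
        hits = np.zeros(2)
        target = set(universe[:4])
        for _ in range(reps):
            drawn = sample_passenger_null(["p1", "p2"], models, rates, rng)
            for i, s in enumerate(["p1", "p2"]):
                if drawn.altered_genes(s) & target:
                    hits[i] += 1
        for i, s in enumerate(["p1", "p2"]):
            pi = prof.pi.loc[s, "s"]
            se = np.sqrt(pi * (1 - pi) / reps)
            assert abs(hits[i] / reps - pi) < 3 * se

    def test_passenger_requires_models(self):
        cat = MutationCatalog(["p"], ["g"], [])
        sets = GeneSetCollection({"s": ("g",)})
        with pytest.raises(ValueError, match="requires"):
            build_profile(cat, sets, "passenger")


class TestPermutationSampler:
    def test_saturated_patient_alters_every_gene(self):
        universe = ["a", "b", "c"]
        events = [MutationEvent("p", g, "c") for g in universe]
        cat = MutationCatalog(["p"], universe, events)
        drawn = sample_permutation_null(cat, seed=0)
        assert drawn.altered_genes("p") == set(universe)

    def test_per_sample_counts_conserved_and_contexts_kept(self):
        universe = [f"g{i}" for i in range(30)]
        events = [
            MutationEvent("p1", "g0", "x"),
            MutationEvent("p1", "g1", "y"),
            MutationEvent("p2", "g2", "z"),
        ]
        cat = MutationCatalog(["p1", "p2"], universe, events)
        drawn = sample_permutation_null(cat, seed=1)
        assert drawn.event_counts().tolist() == cat.event_counts().tolist()
        assert sorted(e.context_class for e in drawn.events) == ["x", "y", "z"]

    def test_seed_determinism(self):
        universe = [f"g{i}" for i in range(30)]
        events = [MutationEvent("p", universe[i], "c") for i in range(6)]
        cat = MutationCatalog(["p"], universe, events)
        a = sample_permutation_null(cat, seed=42)
        b = sample_permutation_null(cat, seed=42)
        assert [e.gene_id for e in a.events] == [e.gene_id for e in b.events]

    def test_uniform_gene_frequencies(self):
        G, n, reps = 20, 5, 10_000
        universe = [f"g{i}" for i in range(G)]
        events = [MutationEvent("p", universe[i], "c") for i in range(n)]
        cat = MutationCatalog(["p"], universe, events)
        rng = np.random.default_rng(9)
        counts = np.zeros(G)
        for _ in range(reps):
            drawn = sample_permutation_null(cat, rng)
            for ev in drawn.events:
                counts[drawn.gene_index[ev.gene_id]] += 1
        freq = counts / reps
        se = np.sqrt((n / G) * (1 - n / G) / reps)
        assert np.all(np.abs(freq - n / G) < 4 * se)

    def test_overfull_patient_rejected(self):
        universe = ["a", "b"]
        events = [MutationEvent("p", "a", "c")] * 3
        cat = MutationCatalog(["p"], universe, events)
        with pytest.raises(ValueError, match="events"):
            sample_permutation_null(cat, seed=0)


class TestPassengerSampler:
    def test_zero_rates_give_empty_catalog(self):
        models = uniform_gene_models(["a", "b"])
        rates = PassengerModel({"ctx": 0.0})
        drawn = sample_passenger_null(["p"], models, rates, seed=0)
        assert drawn.events == []

    def test_mean_total_events(self):
        universe = [f"g{i}" for i in range(50)]
        models = uniform_gene_models(universe, length=800.0)
        rates = PassengerModel({"ctx": 5e-5})  # lambda total = 50*800*5e-5 = 2
        lam_total = 2.0
        reps = 1000
        rng = np.random.default_rng(2)
        totals = [
            len(sample_passenger_null(["p"], models, rates, rng).events)
            for _ in range(reps)
        ]
        se = np.sqrt(lam_total / reps)  # Poisson variance = mean
        assert abs(np.mean(totals) - lam_total) < 3 * se

    def test_seed_determinism(self):
        models = uniform_gene_models([f"g{i}" for i in range(20)], length=5000.0)
        rates = PassengerModel({"ctx": 1e-4})
        a = sample_passenger_null(["p", "q"], models, rates, seed=7)
        b = sample_passenger_null(["p", "q"], models, rates, seed=7)
        assert [(e.sample_id, e.gene_id) for e in a.events] == [
            (e.sample_id, e.gene_id) for e in b.events
        ]
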