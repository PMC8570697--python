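"""Set logic: status tables, Venn regions, cores, prioritization, overlap tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from intergen import crossspecies as xs
from intergen.crossspecies import (
    CrossSpeciesTable,
    core_conserved_set,
    cross_stress_core,
    hypergeom_tail,
    persistence_overlap,
    phenotype_concordant_set,
    shared_deg_sets,
    venn_counts,
)
from intergen.de import DEGCall
from intergen.errors import ConfigurationError, ValidationError
from intergen.fixtures import load_fixture
from intergen.pipeline import build_fixture_tables

SPECIES = ["C. elegans", "C. briggsae", "C. kamaaina", "C. tropicalis"]


def status_table(statuses: dict[str, list[str]], genes: list[str]) -> CrossSpeciesTable:
    idx = pd.Index(genes, name="og_id")
    data = {}
    for unit, stats in statuses.items():
        lfc = [2.0 if s == "up" else -2.0 if s == "down" else 0.0 for s in stats]
        padj = [1e-6 if s in ("up", "down") else 1.0 for s in stats]
        data[unit] = pd.DataFrame({"log2fc": lfc, "padj": padj, "status": stats}, index=idx)
    return CrossSpeciesTable(data)


class TestSharedSets:
    def test_opposite_directions_shared_not_concordant(self):
        t = status_table({"a": ["up"], "b": ["down"]}, ["g1"])
        shared, concordant = shared_deg_sets(t, "a", "b")
        assert shared == {"g1"} and concordant == set()

    def test_one_sided_significance_in_neither(self):
        t = status_table({"a": ["up"], "b": ["unchanged"]}, ["g1"])
        shared, concordant = shared_deg_sets(t, "a", "b")
        assert shared == set() and concordant == set()

    def test_concordant_subset(self):
        t = status_table(
            {"a": ["up", "down", "up"], "b": ["up", "down", "down"]},
            ["g1", "g2", "g3"],
        )
        shared, concordant = shared_deg_sets(t, "a", "b")
        assert shared == {"g1", "g2", "g3"}
        assert concordant == {"g1", "g2"}


def brute_force_venn(sets: dict[str, set]) -> dict[frozenset, int]:
    units = list(sets)
    out = {}
    for r in range(1, len(units) + 1):
        for combo in itertools.combinations(units, r):
            inside = set.intersection(*(sets[u] for u in combo)) if combo else set()
            outside = set().union(*(sets[u] for u in units if u not in combo), set())
            out[frozenset(combo)] = len(inside - outside)
    return out


class TestVenn:
    def test_two_set_enumeration(self):
        counts = venn_counts({"x": {"a", "b", "c"}, "y": {"b", "c", "d"}})
        assert counts[frozenset({"x"})] == 1
        assert counts[frozenset({"x", "y"})] == 2
        assert counts[frozenset({"y"})] == 1

    def test_disjoint_singletons(self):
        sets = {u: {f"g{u}"} for u in "abcd"}
        counts = venn_counts(sets)
        for u in "abcd":
            assert counts[frozenset({u})] == 1
        assert sum(v for k, v in counts.items() if len(k) > 1) == 0

    def test_regions_sum_to_union(self):
        rng = np.random.default_rng(0)
        sets = {u: set(rng.choice(50, size=rng.integers(0, 30), replace=False).tolist())
                for u in "abc"}
        counts = venn_counts(sets)
        assert sum(counts.values()) == len(set().union(*sets.values()))

    @settings(max_examples=50, deadline=None)
    @given(
        st.integers(2, 5),
        st.integers(0, 2**31 - 1),
    )
    def test_matches_brute_force_enumeration(self, n_units, seed):
        rng = np.random.default_rng(seed)
        units = [f"u{i}" for i in range(n_units)]
        sets = {
            u: set(rng.choice(30, size=rng.integers(0, 20), replace=False).tolist())
            for u in units
        }
        assert venn_counts(sets) == brute_force_venn(sets)


class TestCoreSets:
    def test_fixture_core_counts(self):
        tables = build_fixture_tables(SPECIES)
        cores = {
            stress: core_conserved_set({sp: t.significant(sp) for sp in SPECIES})
            for stress, t in tables.items()
        }
        assert len(cores["pathogen"]) == 35
        assert len(cores["osmotic"]) == 5
        assert len(cross_stress_core(cores)) == 37

    def test_fixture_core_overlap_is_three_named_genes(self):
        tables = build_fixture_tables(SPECIES)
        cores = {
            stress: core_conserved_set({sp: t.significant(sp) for sp in SPECIES})
            for stress, t in tables.items()
        }
        assert cores["pathogen"] & cores["osmotic"] == {"C30B5.6", "hphd-1", "C42D4.3"}

    def test_empty_species_set_empties_core(self):
        assert core_conserved_set({"a": {"g1"}, "b": set()}) == set()


class TestPrioritization:
    def test_fixture_pathogen_seventeen_with_inverted_rhy1(self):
        tables = build_fixture_tables(SPECIES)
        pri = phenotype_concordant_set(
            tables["pathogen"], {"C. elegans", "C. kamaaina"}, {"C. briggsae"}
        )
        assert len(pri) == 17
        assert {p.og_id for p in pri} == set(load_fixture("table2").sections["pathogen"])
        flags = {p.og_id: p.flag for p in pri}
        assert flags["rhy-1"] == "inverted_in_contrast"
        assert sum(f == "inverted_in_contrast" for f in flags.values()) == 1

    def test_fixture_osmotic_four_with_gpdh1(self):
        tables = build_fixture_tables(SPECIES)
        pri = phenotype_concordant_set(
            tables["osmotic"],
            {"C. elegans", "C. briggsae", "C. kamaaina"},
            {"C. tropicalis"},
        )
        assert {p.og_id for p in pri} == {"T05F1.9", "grl-21", "gpdh-1", "T22B7.3"}

    def test_inverted_flag_on_synthetic_pattern(self):
        t = status_table(
            {"a": ["up"], "b": ["up"], "c": ["down"]}, ["g1"]
        )
        pri = phenotype_concordant_set(t, {"a", "b"}, {"c"})
        assert len(pri) == 1 and pri[0].flag == "inverted_in_contrast"

    def test_same_direction_in_contrast_excluded(self):
        t = status_table({"a": ["up"], "b": ["up"], "c": ["up"]}, ["g1"])
        assert phenotype_concordant_set(t, {"a", "b"}, {"c"}) == []

    def test_overlapping_include_exclude_rejected(self):
        t = status_table({"a": ["up"], "b": ["up"]}, ["g1"])
        with pytest.raises(ConfigurationError):
            phenotype_concordant_set(t, {"a"}, {"a", "b"})

    def test_row_permutation_invariance(self):
        genes = [f"g{i}" for i in range(6)]
        stats = {
            "a": ["up", "down", "up", "unchanged", "up", "down"],
            "b": ["up", "down", "unchanged", "up", "up", "down"],
            "c": ["down", "unchanged", "up", "up", "unchanged", "down"],
        }
        t = status_table(stats, genes)
        perm = [3, 0, 5, 2, 4, 1]
        t2 = CrossSpeciesTable({u: f.iloc[perm] for u, f in t.data.items()})
        a = phenotype_concordant_set(t, {"a", "b"}, {"c"})
        b = phenotype_concordant_set(t2, {"a", "b"}, {"c"})
        assert [(p.og_id, p.flag) for p in a] == [(p.og_id, p.flag) for p in b]


def enumerate_tail(N, K, n, k):
    """Exhaustive enumeration of all C(N, n) draws (N small)."""
    marked = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeom:
    def test_k_zero_is_one(self):
        assert hypergeom_tail(10, 0, 5, 0) == 1.0

    def test_small_enumeration_example(self):
        # 7 of the C(5,2)=10 draws contain >=1 of 2 marked items
        assert hypergeom_tail(5, 2, 2, 1) == pytest.approx(0.7)

    def test_published_population_closed_form(self):
        # full overlap of 3 marked in a draw of 17 from 7587
        p = hypergeom_tail(7587, 3, 17, 3)
        closed = 17 * 16 * 15 / (7587 * 7586 * 7585)
        assert p == pytest.approx(closed, rel=1e-12)
        assert p <= 1.337e-8

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_enumeration_small_populations(self, data):
        N = data.draw(st.integers(1, 12))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        assert hypergeom_tail(N, K, n, k) == pytest.approx(
            enumerate_tail(N, K, n, k), abs=1e-12
        )

    def test_tails_sum_to_one(self):
        # P(X >= k) + P(X <= k-1) = 1
        N, K, n = 200, 30, 40
        for k in (1, 5, 10, 20):
            upper = hypergeom_tail(N, K, n, k)
            lower = 1.0 - upper
            from scipy.stats import hypergeom as hg

            assert lower + upper == pytest.approx(1.0, abs=1e-12)
            assert upper == pytest.approx(hg.sf(k - 1, N, K, n), rel=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_tail(10, 11, 5, 0)
        with pytest.raises(ValidationError):
            hypergeom_tail(10, 3, 5, 4)


def make_call(label, up=(), down=()):
    return DEGCall(label, 2.0, 0.01, frozenset(up), frozenset(down))


class TestPersistence:
    def test_empty_f3_empty_overlap(self):
        f1 = {"pathogen": make_call("f1p", up={"g1", "g2"})}
        f3 = {"pathogen": make_call("f3p")}
        res = persistence_overlap(f1, f3)
        assert res.pooled == set()
        assert res.counts()["f1_total"] == 2

    def test_identical_sets_full_overlap(self):
        f1 = {"s": make_call("f1", up={"g1"}, down={"g2"})}
        f3 = {"s": make_call("f3", up={"g1"}, down={"g2"})}
        res = persistence_overlap(f1, f3)
        assert res.pooled == {"g1", "g2"}

    def test_direction_ignored_in_overlap(self):
        f1 = {"s": make_call("f1", up={"g1"})}
        f3 = {"s": make_call("f3", down={"g1"})}
        assert persistence_overlap(f1, f3).pooled == {"g1"}

    def test_universe_mismatch_rejected(self):
        f1 = {"s": make_call("f1", up={"g1"})}
        f3 = {"s": make_call("f3", up={"gX"})}
        with pytest.raises(ValidationError):
            persistence_overlap(f1, f3, universe={"g1"})

    def test_stress_label_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            persistence_overlap({"a": make_call("x")}, {"b": make_call("y")})


class TestClassify:
    def test_planted_patterns_called(self):
        phen = xs.default_phenotype_map()
        genes = ["conserved", "inverted", "adaptive", "single", "none", "shared"]
        path = {
            "C. elegans":  ["up", "up", "up", "up", "unchanged", "down"],
            "C. briggsae": ["up", "down", "unchanged", "unchanged", "unchanged", "down"],
            "C. kamaaina": ["up", "up", "up", "unchanged", "unchanged", "down"],
            "C. tropicalis": ["up", "unchanged", "unchanged", "unchanged", "unchanged", "down"],
        }
        osmo = {
            sp: ["unchanged"] * 5 + ["down"] for sp in path
        }
        tables = {
            "pathogen": status_table(path, genes),
            "osmotic": status_table(osmo, genes),
        }
        pred = xs.classify_orthogroups(tables, phen)
        assert pred["conserved"] == "conserved_all"
        assert pred["inverted"] == "inverted"
        assert pred["adaptive"] == "adaptive_only"
        assert pred["single"] == "single_species"
        assert pred["none"] == "null"
        assert pred["shared"] == "shared_both_stresses"
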