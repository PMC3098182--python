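"""Reference construction, pair verification, coverage and significance."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from funmod.evaluation import (
    CHANNELS,
    ReferenceNetwork,
    build_reference,
    combine_channel_scores,
    compare_methods,
    cooccurrence_baseline,
    coverage,
    evaluate_module,
    hypergeom_significance,
    read_reference,
    read_score_table,
    verify_pwf,
    verify_trf,
    write_reference,
)
from funmod.module_extraction import PFModule, module_pairs


def make_module(terms, topic_id=0):
    return PFModule(topic_id=topic_id, run_id=0, terms={t: 0.05 for t in terms})


def make_ref(pairs, vocab):
    return ReferenceNetwork(
        pairs=frozenset(frozenset(p) for p in pairs),
        vocabulary=frozenset(vocab),
    )


class TestCombineChannelScores:
    def test_single_channel_no_prior_is_identity(self):
        assert combine_channel_scores({"database": 0.9}, prior=0.0) == pytest.approx(0.9)

    def test_noisy_or_of_two_half_scores(self):
        s = combine_channel_scores(
            {"database": 0.5, "experimental": 0.5}, prior=0.0
        )
        assert s == pytest.approx(0.75)

    def test_prior_corrected_formula_by_hand(self):
        prior = 0.063
        s1, s2 = 0.6, 0.4
        c1 = (s1 - prior) / (1 - prior)
        c2 = (s2 - prior) / (1 - prior)
        expected = (1 - (1 - c1) * (1 - c2)) * (1 - prior) + prior
        got = combine_channel_scores(
            {"neighborhood": s1, "fusion": s2}, prior=prior
        )
        assert got == pytest.approx(expected)

    def test_excluded_channel_ignored(self):
        s = combine_channel_scores(
            {"cooccurence": 0.99, "database": 0.8}, prior=0.0
        )
        assert s == pytest.approx(0.8)

    def test_all_below_prior_gives_zero(self):
        assert combine_channel_scores({"textmining": 0.05}, prior=0.063) == 0.0

    def test_prior_one_rejected(self):
        with pytest.raises(ValueError):
            combine_channel_scores({"database": 0.5}, prior=1.0)


class TestScoreTable:
    def test_milli_scores_divided(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "term_a\tterm_b\tneighborhood\tcooccurrence\n" "a\tb\t900\t450\n",
            encoding="utf-8",
        )
        df = read_score_table(p)
        assert "cooccurence" in df.columns  # alias normalized to data dialect
        assert df["neighborhood"].iloc[0] == pytest.approx(0.9)
        assert df["cooccurence"].iloc[0] == pytest.approx(0.45)

    def test_missing_term_columns_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("x\ty\n1\t2\n", encoding="utf-8")
        with pytest.raises(ValueError, match="term_a"):
            read_score_table(p)


def score_row(a, b, **channels):
    row = {"term_a": a, "term_b": b, **{c: 0.0 for c in CHANNELS}}
    row.update(channels)
    return row


class TestBuildReference:
    def test_threshold_and_vocab_filters(self):
        table = pd.DataFrame(
            [
                score_row("a", "b", database=0.95),  # in
                score_row("a", "c", database=0.69),  # below 0.7 combined
                score_row("a", "z", database=0.95),  # z outside vocab
                score_row("b", "c", cooccurence=0.99),  # excluded channel only
            ]
        )
        ref = build_reference(table, ["a", "b", "c"], prior=0.0)
        assert ref.pairs == frozenset({frozenset(("a", "b"))})

    def test_duplicate_pairs_keep_max_score(self):
        table = pd.DataFrame(
            [
                score_row("a", "b", database=0.75),
                score_row("b", "a", database=0.95),
            ]
        )
        ref = build_reference(table, ["a", "b"], prior=0.0)
        assert ref.scores[frozenset(("a", "b"))] == pytest.approx(0.95)

    def test_matches_brute_force_filter(self, rng):
        vocab = [f"t{i}" for i in range(12)]
        rows = []
        for _ in range(100):
            a, b = rng.choice(14, size=2, replace=False)
            rows.append(
                score_row(
                    f"t{a}",
                    f"t{b}",
                    **{c: float(rng.random()) for c in CHANNELS},
                )
            )
        table = pd.DataFrame(rows)
        prior = 0.063
        ref = build_reference(table, vocab, prior=prior)
        expected = {}
        for row in rows:
            s = combine_channel_scores(
                {c: row[c] for c in CHANNELS}, prior=prior
            )
            if (
                s >= 0.15
                and row["term_a"] in vocab
                and row["term_b"] in vocab
                and s >= 0.7
            ):
                key = frozenset((row["term_a"], row["term_b"]))
                expected[key] = max(expected.get(key, 0.0), s)
        assert ref.pairs == frozenset(expected)

    def test_precomputed_combined_scores_bypass(self):
        table = pd.DataFrame(
            [
                {**score_row("a", "b"), "combined_score": 0.9},
                {**score_row("a", "c"), "combined_score": 0.5},
            ]
        )
        ref = build_reference(table, ["a", "b", "c"], use_precomputed=True)
        assert ref.pairs == frozenset({frozenset(("a", "b"))})

    def test_round_trip_export(self, tmp_path):
        table = pd.DataFrame([score_row("a", "b", database=0.95)])
        ref = build_reference(table, ["a", "b"], prior=0.0)
        write_reference(ref, tmp_path / "ref.tsv")
        back = read_reference(tmp_path / "ref.tsv", ["a", "b"])
        assert back.pairs == ref.pairs


class TestVerification:
    def test_pwf_fraction(self):
        module = make_module(["a", "b", "c", "d"])
        ref = make_ref([("a", "b"), ("c", "d")], "abcd")
        hits, frac = verify_pwf(module, ref)
        assert len(hits) == 2
        assert frac == pytest.approx(2 / 6)

    def test_empty_reference(self):
        module = make_module(["a", "b"])
        hits, frac = verify_pwf(module, make_ref([], "ab"))
        assert hits == frozenset() and frac == 0.0

    def test_trf_triangle_completion(self):
        module = make_module(["a", "b", "c"])
        ref = make_ref([("a", "c"), ("b", "c")], "abc")
        pwf, _ = verify_pwf(module, ref)
        assert verify_trf(module, ref, pwf) == frozenset({frozenset(("a", "b"))})

    def test_trf_never_contains_pwf_pair(self, rng):
        for _ in range(20):
            terms = [f"t{i}" for i in range(8)]
            module = make_module(terms)
            ref_pairs = [
                tuple(rng.choice(terms, size=2, replace=False)) for _ in range(8)
            ]
            ref = make_ref(ref_pairs, terms)
            pwf, _ = verify_pwf(module, ref)
            trf = verify_trf(module, ref, pwf)
            assert not (trf & pwf)
            assert not (trf & ref.pairs)


class TestWorkedExample:
    """An 18-term module matched against a reference network.

    Nine of its 153 pairs are verified edges forming three connected
    components; the largest spans 5 of the 18 terms, so coverage is
    5/18 = 27.8%, and exactly four non-verified pairs are rescued as
    first-order transitive couplings.
    """

    TERMS = [f"og{i:02d}" for i in range(18)]

    # 5-vertex component with one cycle (4 trf), a triangle (0 trf),
    # and an isolated edge (0 trf): 9 edges total.
    EDGES = [
        ("og00", "og01"),
        ("og01", "og02"),
        ("og02", "og03"),
        ("og00", "og03"),
        ("og03", "og04"),
        ("og05", "og06"),
        ("og06", "og07"),
        ("og05", "og07"),
        ("og08", "og09"),
    ]

    def test_nine_verified_pairs_four_transitive(self):
        module = make_module(self.TERMS)
        ref = make_ref(self.EDGES, self.TERMS)
        pwf, frac = verify_pwf(module, ref)
        assert len(pwf) == 9
        assert frac == pytest.approx(9 / 153)
        trf = verify_trf(module, ref, pwf)
        assert trf == frozenset(
            frozenset(p)
            for p in [
                ("og00", "og02"),
                ("og01", "og03"),
                ("og00", "og04"),
                ("og02", "og04"),
            ]
        )

    def test_coverage_and_components(self):
        module = make_module(self.TERMS)
        ref = make_ref(self.EDGES, self.TERMS)
        pwf, _ = verify_pwf(module, ref)
        cov, n_comp = coverage(module, pwf)
        assert cov == pytest.approx(5 / 18)
        assert round(100 * cov, 1) == 27.8
        assert n_comp == 3

    def test_tree_components_five_four_three(self):
        """Alternative layout: three tree components of 5, 4 and 3 vertices."""
        edges = [
            ("og00", "og01"),
            ("og01", "og02"),
            ("og02", "og03"),
            ("og03", "og04"),
            ("og05", "og06"),
            ("og06", "og07"),
            ("og07", "og08"),
            ("og09", "og10"),
            ("og10", "og11"),
        ]
        module = make_module(self.TERMS)
        ref = make_ref(edges, self.TERMS)
        pwf, _ = verify_pwf(module, ref)
        cov, n_comp = coverage(module, pwf)
        assert cov == pytest.approx(5 / 18) and n_comp == 3


class TestCoverage:
    def test_spanning_tree_full_coverage(self):
        terms = [f"t{i}" for i in range(6)]
        module = make_module(terms)
        edges = [(terms[i], terms[i + 1]) for i in range(5)]
        cov, n_comp = coverage(module, [frozenset(e) for e in edges])
        assert cov == 1.0 and n_comp == 1

    def test_no_edges_zero_coverage_zero_components(self):
        module = make_module(["a", "b", "c"])
        assert coverage(module, []) == (0.0, 0)

    def test_monotone_in_edges(self, rng):
        terms = [f"t{i}" for i in range(10)]
        module = make_module(terms)
        all_pairs = [frozenset(p) for p in combinations(terms, 2)]
        order = rng.permutation(len(all_pairs))
        prev = 0.0
        for n in range(0, len(all_pairs), 5):
            cov, _ = coverage(module, [all_pairs[i] for i in order[:n]])
            assert cov >= prev
            prev = cov


def union_find_oracle(terms, edges):
    parent = {t: t for t in terms}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in edges:
        a, b = tuple(p)
        parent[find(a)] = find(b)
    touched = {t for p in edges for t in p}
    comps = {}
    for t in touched:
        comps.setdefault(find(t), set()).add(t)
    if not comps:
        return 0.0, 0
    return max(len(c) for c in comps.values()) / len(terms), len(comps)


def test_coverage_matches_union_find_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(3, 12))
        terms = [f"t{i}" for i in range(n)]
        module = make_module(terms)
        all_pairs = list(combinations(terms, 2))
        n_edges = int(rng.integers(0, len(all_pairs) + 1))
        idx = rng.choice(len(all_pairs), size=n_edges, replace=False)
        edges = [frozenset(all_pairs[i]) for i in idx]
        assert coverage(module, edges) == pytest.approx(
            union_find_oracle(terms, edges)
        )


class TestHypergeomSignificance:
    def test_corpus_scale_arithmetic(self):
        V = 10_431
        D = V * (V - 1) // 2
        U = 60_880
        p_hit, e_h, _ = hypergeom_significance(171, 9, U, D)
        assert round(p_hit, 4) == 0.0011
        assert round(e_h, 2) == 0.19

    def test_zero_hits_tail_is_one(self):
        _, _, p = hypergeom_significance(5, 0, 10, 100)
        assert p == 1.0

    def test_tiny_universe_matches_exhaustive_enumeration(self):
        # |D| = 10 pairs, |U| = 4 of them are "reference", draw m = 3
        D, U, m = 10, 4, 3
        population = [1] * U + [0] * (D - U)
        draws = list(combinations(range(D), m))
        for h in range(m + 1):
            tail = sum(
                1 for d in draws if sum(population[i] for i in d) >= h
            ) / len(draws)
            _, _, p = hypergeom_significance(m, h, U, D)
            assert p == pytest.approx(tail)

    def test_expected_hits_equals_enumerated_mean(self):
        D, U, m = 12, 5, 4
        population = [1] * U + [0] * (D - U)
        draws = list(combinations(range(D), m))
        mean_hits = sum(
            sum(population[i] for i in d) for d in draws
        ) / len(draws)
        _, e_h, _ = hypergeom_significance(m, 0, U, D)
        assert e_h == pytest.approx(mean_hits)

    def test_pmf_sums_to_one_small_universes(self):
        for D, U, m in [(20, 7, 5), (50, 20, 10), (200, 80, 30)]:
            total = 0.0
            for h in range(m + 1):
                total += (
                    math.comb(U, h) * math.comb(D - U, m - h) / math.comb(D, m)
                )
            assert total == pytest.approx(1.0)
            _, _, p_all = hypergeom_significance(m, 0, U, D)
            assert p_all == pytest.approx(1.0)

    def test_h_above_m_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_significance(3, 4, 10, 100)


class TestBaseline:
    def test_threshold_boundary_inclusive(self):
        table = pd.DataFrame(
            [
                score_row("a", "b", cooccurence=0.39),
                score_row("a", "c", cooccurence=0.40),
                score_row("b", "z", cooccurence=0.95),
            ]
        )
        pairs = cooccurrence_baseline(table, ["a", "b", "c"])
        assert pairs == frozenset({frozenset(("a", "c"))})

    def test_matches_brute_force_filter(self, rng):
        vocab = [f"t{i}" for i in range(10)]
        rows = [
            score_row(
                f"t{rng.integers(0, 12)}",
                f"t{rng.integers(0, 12)}",
                cooccurence=float(rng.random()),
            )
            for _ in range(80)
        ]
        table = pd.DataFrame(rows)
        got = cooccurrence_baseline(table, vocab, threshold=0.4)
        expected = {
            frozenset((r["term_a"], r["term_b"]))
            for r in rows
            if r["term_a"] != r["term_b"]
            and r["cooccurence"] >= 0.4
            and r["term_a"] in vocab
            and r["term_b"] in vocab
        }
        assert got == frozenset(expected)


class TestCompareMethods:
    def test_identical_sets_fully_overlap(self):
        module = make_module(["a", "b", "c"])
        baseline = frozenset(module_pairs(module))
        ref = make_ref([("a", "b")], "abc")
        rep = compare_methods([module], baseline, ref)
        assert rep["venn_counts"]["both"] == 3
        assert rep["venn_counts"]["modules_only"] == 0
        assert rep["venn_counts"]["baseline_only"] == 0

    def test_disjoint_sets(self):
        module = make_module(["a", "b"])
        baseline = frozenset({frozenset(("c", "d"))})
        ref = make_ref([], "abcd")
        rep = compare_methods([module], baseline, ref)
        assert rep["venn_counts"]["both"] == 0
        assert rep["venn_counts"]["modules_only"] == 1
        assert rep["venn_counts"]["baseline_only"] == 1

    def test_sections_partition_the_union(self, rng):
        for _ in range(10):
            terms = [f"t{i}" for i in range(9)]
            mods = [
                make_module(rng.choice(terms, size=4, replace=False), topic_id=i)
                for i in range(3)
            ]
            all_pairs = [frozenset(p) for p in combinations(terms, 2)]
            baseline = frozenset(
                all_pairs[i]
                for i in rng.choice(len(all_pairs), size=10, replace=False)
            )
            ref = make_ref(
                [tuple(all_pairs[i]) for i in rng.choice(len(all_pairs), 12, replace=False)],
                terms,
            )
            rep = compare_methods(mods, baseline, ref)
            union = rep["module_pairs"] | rep["baseline_pairs"]
            assert sum(rep["venn_counts"].values()) == len(union)
            # recall accounting against the reference
            assert rep["recall_modules"] == pytest.approx(
                len(rep["module_pairs"] & ref.pairs) / len(ref.pairs)
            )


def test_evaluate_module_bundles_consistent_statistics():
    terms = [f"og{i}" for i in range(6)]
    module = make_module(terms)
    ref = make_ref([("og0", "og1"), ("og1", "og2"), ("og3", "og4")], terms)
    ev = evaluate_module(module, ref)
    assert ev.m == 15
    assert len(ev.pwf) == 3
    assert not (ev.pwf & ev.trf)
    assert len(ev.pwf) + len(ev.trf) <= ev.m
    assert ev.coverage == pytest.approx(3 / 6)
    assert ev.n_components == 2
    assert ev.expected_hits == pytest.approx(15 * 3 / 15)  # |U|=3, |D|=15
    assert 0.0 <= ev.p_mult_hit <= 1.0
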