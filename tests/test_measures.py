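"""Neighborhood measures: counts, distances, network statistics, profiles."""

import itertools
import math
import random

import networkx as nx
import pytest

from helpers import graph_edges, lev_recursive, make_lexicon
from lexneigh import Lexicon, LexiconEntry
from lexneigh.editdist import ORTH, PG, PHON, tokenize_orth
from lexneigh.measures import (
    clustering_coefficient,
    coltheart_n,
    density,
    dimension_profile,
    ldist20,
    neighbor_freq_stats,
    profile,
    resolve_target,
    two_hop_density,
)
from lexneigh.synth import LexiconSpec, generate_lexicon


class TestColtheartN:
    def test_cat_has_five_substitution_neighbors(self, cat_lexicon):
        n, nbrs = coltheart_n("cat", cat_lexicon)
        assert n == 5
        assert set(nbrs) == {"oat", "cot", "vat", "cab", "mat"}

    def test_self_excluded(self):
        lex = make_lexicon(["cat"])
        assert coltheart_n("cat", lex) == (0, [])

    def test_nonword_toosh_single_neighbor(self, nonword_lexicon):
        n, nbrs = coltheart_n("toosh", nonword_lexicon)
        assert n == 1 and nbrs == ["tooth"]


class TestDensity:
    def test_counts_all_three_edit_types(self):
        lex = make_lexicon(["stand", "sad", "band"])
        n, nbrs = density("sand", lex)
        assert n == 3 and set(nbrs) == {"stand", "sad", "band"}

    def test_hermit_has_zero_density(self, cat_lexicon):
        assert density("trek", cat_lexicon)[0] == 0

    def test_nonword_dast(self, nonword_lexicon):
        n, nbrs = density("dast", nonword_lexicon)
        assert n == 4 and set(nbrs) == {"dust", "dash", "dart", "daft"}

    def test_phonographic_requires_both_channels(self, pg_lexicon):
        n, nbrs = density("cat", pg_lexicon, dim=PG)
        assert n == 3 and set(nbrs) == {"bat", "cats", "cap"}
        # 'oat' is one letter away but two phonemes away: not a pg neighbor
        assert "oat" not in nbrs
        assert "oat" in density("cat", pg_lexicon, dim=ORTH)[1]


class TestLdist20:
    def test_constant_distance_one(self):
        lex = make_lexicon(["cat" + c for c in "abcdefghijklmnopqrstuvwxyz"][:25])
        ld, k = ldist20("cata", lex)  # in-lexicon: 24 others, all at distance 1
        assert ld == 1.0 and k == 20

    def test_small_lexicon_reports_k_used(self, nonword_lexicon):
        ld, k = ldist20("dast", nonword_lexicon)
        assert k == 5
        dists = sorted(
            lev_recursive(tuple("dast"), tuple(w)) for w in nonword_lexicon.entries
        )
        assert ld == pytest.approx(sum(dists) / 5)

    def test_matches_full_sort_oracle_on_synthetic_lexicon(self):
        lex = generate_lexicon(LexiconSpec(n_words=100, seed=3))
        for target in list(lex.entries)[:10]:
            expected = sorted(
                lev_recursive(tuple(target), tuple(w))
                for w in lex.entries
                if w != target
            )
            expected = [d for d in expected if d > 0][:20]
            ld, k = ldist20(target, lex)
            assert k == len(expected)
            assert ld == pytest.approx(sum(expected) / len(expected))

    def test_monotone_under_lexicon_growth(self):
        small = make_lexicon(["dust", "dash"])
        large = make_lexicon(["dust", "dash", "dart", "daft"])
        assert ldist20("dast", large)[0] <= ldist20("dast", small)[0]

    def test_empty_comparison_set_rejected(self):
        lex = make_lexicon(["cat"])
        with pytest.raises(ValueError):
            ldist20("cat", lex)


class TestClusteringCoefficient:
    def test_one_edge_among_three_neighbors(self):
        # neighbors of 'cat': bat, rat, cot; only bat-rat are neighbors of each other
        lex = make_lexicon(["bat", "rat", "cot"])
        assert clustering_coefficient("cat", lex) == pytest.approx(1 / 3)

    def test_complete_clique_gives_one(self):
        lex = make_lexicon(["bat", "rat", "sat"])
        assert clustering_coefficient("cat", lex) == 1.0

    def test_undefined_below_two_neighbors(self):
        assert clustering_coefficient("cat", make_lexicon(["bat"])) is None
        assert clustering_coefficient("cat", make_lexicon(["xyz"])) is None

    def test_matches_pair_enumeration_and_networkx(self):
        lex = generate_lexicon(
            LexiconSpec(alphabet=tuple("abcd"), n_words=80, length_range=(2, 4), seed=4)
        )
        edges = graph_edges(lex, ORTH)
        graph = nx.Graph()
        graph.add_nodes_from(lex.entries)
        graph.add_edges_from(tuple(e) for e in edges)
        checked = 0
        for word in lex.entries:
            ours = clustering_coefficient(word, lex)
            nbrs = {v for e in edges if word in e for v in e} - {word}
            if len(nbrs) < 2:
                assert ours is None
                continue
            pairs = sum(
                1 for u, v in itertools.combinations(nbrs, 2) if frozenset((u, v)) in edges
            )
            assert ours == pytest.approx(2 * pairs / (len(nbrs) * (len(nbrs) - 1)))
            assert ours == pytest.approx(nx.clustering(graph, word))
            checked += 1
        assert checked >= 5  # the fixture must actually exercise the formula


class TestTwoHopDensity:
    def test_printed_style_example(self):
        # 1-hop of 'cat': cut, at; 2-hop: cup (via cut), ant (via at)
        lex = make_lexicon(["cut", "at", "cup", "ant"])
        assert two_hop_density("cat", lex) == pytest.approx(0.5)

    def test_complete_bipartite_gives_one(self):
        # 1-hop {aab}; 2-hop {aabb}; the single cross pair is connected
        lex = make_lexicon(["aab", "aabb"])
        assert two_hop_density("aa", lex) == 1.0

    def test_missing_when_no_two_hop_nodes(self, cat_lexicon):
        lex = make_lexicon(["bat"])
        assert two_hop_density("cat", lex) is None
        assert two_hop_density("trek", cat_lexicon) is None

    def test_matches_bruteforce_cross_edge_count(self):
        rng = random.Random(6)
        for seed in range(10):
            lex = generate_lexicon(
                LexiconSpec(alphabet=tuple("abc"), n_words=40, length_range=(2, 4), seed=seed)
            )
            edges = graph_edges(lex, ORTH)
            target = rng.choice(sorted(lex.entries))
            ours = two_hop_density(target, lex)
            one_hop = {v for e in edges if target in e for v in e} - {target}
            two_hop = {
                v for e in edges for v in e
                if any(u in e for u in one_hop)
            } - one_hop - {target}
            if not one_hop or not two_hop:
                assert ours is None
                continue
            cross = sum(
                1 for u in one_hop for v in two_hop if frozenset((u, v)) in edges
            )
            assert ours == pytest.approx(cross / (len(one_hop) * len(two_hop)))
            assert 1 / len(one_hop) - 1e-12 <= ours <= 1.0


class TestNeighborFreqStats:
    def _entries(self, zipfs):
        return [LexiconEntry(word=f"w{i}", zipf=z) for i, z in enumerate(zipfs)]

    def test_mean_sd_and_splits(self):
        stats = neighbor_freq_stats(self._entries([3, 4, 5]), target_freq=4)
        assert stats.mean == 4 and stats.sd == pytest.approx(1.0)
        assert stats.higher_mean == 5 and stats.lower_mean == 3

    def test_single_neighbor_sd_missing(self):
        stats = neighbor_freq_stats(self._entries([3]), target_freq=4)
        assert stats.sd is None

    def test_ties_belong_to_neither_split(self):
        stats = neighbor_freq_stats(self._entries([4, 4]), target_freq=4)
        assert stats.higher_mean is None and stats.lower_mean is None

    def test_nonword_target_has_no_splits(self):
        stats = neighbor_freq_stats(self._entries([3, 5]), target_freq=None)
        assert stats.mean == 4 and stats.higher_mean is None

    def test_matches_independent_recomputation(self):
        rng = random.Random(2)
        for _ in range(20):
            values = [rng.uniform(1, 7) for _ in range(rng.randint(2, 8))]
            target = rng.uniform(1, 7)
            stats = neighbor_freq_stats(self._entries(values), target_freq=target)
            n = len(values)
            mean = sum(values) / n
            sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
            assert stats.mean == pytest.approx(mean)
            assert stats.sd == pytest.approx(sd)
            hi = [v for v in values if v > target]
            lo = [v for v in values if v < target]
            if hi and lo:
                total = len(hi) * stats.higher_mean + len(lo) * stats.lower_mean
                assert total == pytest.approx(n * mean)


class TestProfile:
    def test_word_gets_all_orthographic_fields_and_frequency(self, cat_lexicon):
        row, warnings = profile("oat", cat_lexicon, dims=[ORTH])
        for field in ("orth_N", "orth_density", "OLD20", "orth_C", "orth_2hop_density",
                      "orth_nbr_fpm_m", "orth_nbr_zipf_m", "raw_freq", "zipf"):
            assert field in row
        assert not warnings

    def test_nonword_has_no_frequency_fields(self, nonword_lexicon):
        row, _ = profile("dast", nonword_lexicon, dims=[ORTH])
        assert row["orth_density"] == 4
        assert "raw_freq" not in row and "zipf" not in row

    def test_missing_ipa_warns_and_skips_phon(self, cat_lexicon):
        row, warnings = profile("cat", cat_lexicon, dims=[ORTH, PHON, PG])
        assert warnings and "transcription" in warnings[0]
        assert "phon_density" not in row and "pg_density" not in row
        assert "orth_density" in row

    def test_selected_measures_filtered(self, cat_lexicon):
        row, _ = profile("cat", cat_lexicon, dims=[ORTH], selected={"orth_N", "OLD20"})
        assert set(row) == {"word", "orth_N", "OLD20"}

    def test_invariant_to_lexicon_iteration_order(self, cat_lexicon):
        reversed_entries = dict(reversed(list(cat_lexicon.entries.items())))
        shuffled = Lexicon(reversed_entries, corpus_tokens=cat_lexicon.corpus_tokens)
        row_a, _ = profile("cat", cat_lexicon, dims=[ORTH])
        row_b, _ = profile("cat", shuffled, dims=[ORTH])
        assert row_a == row_b


class TestMeasureRelations:
    def test_invariants_on_synthetic_lexicon(self):
        lex = generate_lexicon(LexiconSpec(n_words=300, seed=8))
        targets = sorted(lex.entries)[:40]
        for word in targets:
            t = resolve_target(lex, word)
            orth = dimension_profile(t, lex, ORTH)
            phon = dimension_profile(t, lex, PHON)
            pg = dimension_profile(t, lex, PG)
            assert orth.n_subst <= orth.density <= len(lex) - 1
            assert pg.density <= min(orth.density, phon.density)
            assert orth.ld20 >= 1 and phon.ld20 >= 1 and pg.ld20 >= 1
            for p in (orth, phon, pg):
                if p.clustering_c is not None:
                    assert 0 <= p.clustering_c <= 1
                if p.two_hop_density is not None:
                    assert 0 < p.two_hop_density <= 1
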