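"""Composite-seed index: entry enumeration, lookup correctness against a
brute-force scan, and the completeness/superset properties."""

import numpy as np
import pytest

import mapalign as ma
from mapalign.seed_index import MERGE12, MERGE23, PLAIN, Q_MERGED, Q_PLAIN, SeedIndex


def entry_set(index):
    return {
        (int(index.map_idx[k]), int(index.r_pos[k]), int(index.variant[k]))
        for k in range(len(index))
    }


class TestBuildIndex:
    def test_three_fragment_enumeration(self, sigma_model):
        ref = ma.ReferenceMap.from_fragments("r", [5000.0, 8000.0, 11000.0], sigma_model)
        index = SeedIndex([ref])
        assert entry_set(index) == {
            (0, 1, PLAIN),
            (0, 2, PLAIN),
            (0, 1, MERGE12),
            (0, 1, MERGE23),
        }

    def test_two_fragment_reference_only_plain(self, sigma_model):
        ref = ma.ReferenceMap.from_fragments("r", [5000.0, 8000.0], sigma_model)
        index = SeedIndex([ref])
        assert entry_set(index) == {(0, 1, PLAIN)}

    def test_entry_count_is_about_3n(self, small_reference):
        index = SeedIndex([small_reference])
        n = small_reference.n
        assert len(index) == (n - 1) + 2 * (n - 2)

    def test_sorted_by_first_element(self, small_index):
        assert np.all(np.diff(small_index.e1) >= 0)

    def test_unsupported_order_rejected(self, small_reference):
        with pytest.raises(ValueError):
            SeedIndex([small_reference], c=3)


def brute_force_hits(o, index, params):
    """Reference implementation of the lookup: test every entry."""
    C = params.C_sigma_seed
    hits = set()
    tuples = [
        (i, Q_PLAIN, o.fragments[i - 1], o.fragments[i]) for i in range(1, o.m)
    ] + [
        (i, Q_MERGED, o.fragments[i - 1] + o.fragments[i], o.fragments[i + 1])
        for i in range(1, o.m - 1)
    ]
    for q_pos, q_var, q1, q2 in tuples:
        for k in range(len(index)):
            if abs(q1 - index.e1[k]) <= C * index.sd1[k] and abs(q2 - index.e2[k]) <= C * index.sd2[k]:
                hits.add(
                    (int(index.map_idx[k]), int(index.r_pos[k]), int(index.variant[k]), q_pos, q_var)
                )
    return hits


class TestQuerySeeds:
    def test_lookup_equals_brute_force(self, small_index, params):
        rng = np.random.default_rng(77)
        for _ in range(5):
            o = ma.ExperimentalMap("q", np.maximum(200.0, rng.exponential(12000.0, 8)))
            got = {
                (int(a), int(b), int(c), int(d), int(e))
                for a, b, c, d, e in zip(*small_index.query_arrays(o, params))
            }
            assert got == brute_force_hits(o, small_index, params)

    def test_error_free_query_hits_true_position_everywhere(self, small_reference, small_index, params):
        o = ma.ExperimentalMap("q", small_reference.fragments[100:110].copy())
        hits = small_index.query_seeds(o, params)
        plain = {
            (h.q_pos, h.r_pos)
            for h in hits
            if h.ref_variant == PLAIN and h.q_variant == Q_PLAIN
        }
        for i in range(1, o.m):
            assert (i, 100 + i) in plain

    def test_out_of_bound_size_is_not_hit(self, sigma_model, params):
        sigma = sigma_model.sigma(10000.0)
        ref = ma.ReferenceMap.from_fragments(
            "r", [10000.0 + 3 * sigma + 1, 20000.0], sigma_model
        )
        index = SeedIndex([ref])
        o = ma.ExperimentalMap("q", [10000.0, 20000.0, 5000.0])
        hits = [h for h in index.query_seeds(o, params) if h.ref_variant == PLAIN]
        assert not any(h.q_pos == 1 and h.r_pos == 1 for h in hits)

    def test_missing_cut_found_via_merge_variant(self, sigma_model, params):
        ref = ma.ReferenceMap.from_fragments(
            "r", [30000.0, 9000.0, 7000.0, 25000.0, 40000.0], sigma_model
        )
        index = SeedIndex([ref])
        # missing cut between r2 and r3: the query sees 16000 as one fragment
        o = ma.ExperimentalMap("q", [30000.0, 16000.0, 25000.0, 40000.0])
        hits = index.query_seeds(o, params)
        assert any(h.ref_variant in (MERGE12, MERGE23) for h in hits)
        assert any(h.r_pos == 2 and h.ref_variant == MERGE12 for h in hits if h.q_pos == 2)

    def test_composite_superset_of_plain(self, small_reference, small_index, params):
        rng = np.random.default_rng(3)
        sc = ma.ScenarioParams.easier()
        maps, _ = ma.simulate_maps(small_reference, sc, 5, 99)
        for o in maps:
            hits = small_index.query_seeds(o, params)
            plain = [h for h in hits if h.ref_variant == PLAIN and h.q_variant == Q_PLAIN]
            assert len(hits) >= len(plain)

    def test_short_query_yields_nothing(self, small_index, params):
        o = ma.ExperimentalMap("q", [10000.0, 20000.0])
        assert small_index.query_seeds(o, params) == []


class TestNarrowSeeds:
    def test_supported_cluster_survives_and_singletons_drop(self, small_reference, small_index, params):
        o = ma.ExperimentalMap("q", small_reference.fragments[20:32].copy())
        hits = small_index.query_seeds(o, params)
        clusters = ma.narrow_seeds(hits, params)
        assert clusters, "true placement must produce an anchor cluster"
        best = max(clusters, key=len)
        assert any(h.r_pos - h.q_pos == 20 for h in best)
        for cl in clusters:
            assert 1 <= len(cl) <= params.max_anchors_per_cluster
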