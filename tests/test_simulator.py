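"""Simulator: the error pipeline, the instrument filter, determinism, and
parameter recovery from truth logs."""

import numpy as np
import pytest

import mapalign as ma
from mapalign.simulator import ScenarioParams, estimate_rates, read_truth, write_truth


@pytest.fixture(scope="module")
def big_reference(sigma_model):
    return ma.synth_reference(4000, 17300, seed=5, sigma_model=sigma_model)


class TestScenarioParams:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ScenarioParams(d=0.0)
        with pytest.raises(ValueError):
            ScenarioParams(f100=-1.0)
        with pytest.raises(ValueError):
            ScenarioParams(missing_fragment_probs=((600.0, 0.5), (350.0, 1.0)))

    def test_drop_prob_table(self):
        sc = ScenarioParams.easier()
        assert sc.drop_prob(300.0) == 1.0
        assert sc.drop_prob(500.0) == 0.75
        assert sc.drop_prob(1000.0) == 0.5
        assert sc.drop_prob(5000.0) == 0.0


class TestSynthReference:
    def test_mean_and_determinism(self):
        ref1 = ma.synth_reference(13920, 17300, seed=9)
        ref2 = ma.synth_reference(13920, 17300, seed=9)
        np.testing.assert_array_equal(ref1.fragments, ref2.fragments)
        assert abs(ref1.fragments.mean() - 17300) / 17300 < 0.02

    def test_single_fragment(self):
        assert ma.synth_reference(1, 17300, seed=0).n == 1


class TestSimulateMap:
    def test_identity_scenario_reproduces_submap(self, big_reference):
        sc = ScenarioParams.identity()
        rng = np.random.default_rng(3)
        out = None
        while out is None:
            out = ma.simulate_map(big_reference, sc, rng, "m")
        m, t = out
        # every fragment maps 1:1 onto one reference fragment, interior
        # fragments exactly
        lo0 = t.source_frag_ranges[0][0]
        for k, (lo, hi) in enumerate(t.source_frag_ranges):
            assert lo == hi == lo0 + k
        interior = m.fragments[1:-1]
        # 1-based reference fragments lo0+1 .. lo0+m-2 are copied verbatim
        ref_interior = big_reference.fragments[lo0 : lo0 + m.m - 2]
        np.testing.assert_allclose(interior, ref_interior)
        assert t.end_bp - t.start_bp == pytest.approx(m.size)

    def test_determinism(self, big_reference):
        sc = ScenarioParams.easier()
        a = ma.simulate_maps(big_reference, sc, 5, seed=11)
        b = ma.simulate_maps(big_reference, sc, 5, seed=11)
        for (m1, m2) in zip(a[0], b[0]):
            np.testing.assert_array_equal(m1.fragments, m2.fragments)

    def test_filter_enforced(self, big_reference):
        sc = ScenarioParams.easier()
        maps, _ = ma.simulate_maps(big_reference, sc, 50, seed=21)
        for m in maps:
            assert m.m >= sc.min_map_fragments
            assert m.size >= sc.min_map_bp

    def test_mean_size_matches_study_conditions(self, big_reference):
        sc = ScenarioParams.easier()
        maps, truths = ma.simulate_maps(big_reference, sc, 300, seed=33)
        mol = np.mean([t.molecule_bp for t in truths])
        # molecules average about 17 fragments of ~17.3 kbp each, i.e.
        # roughly 275 kbp after the >=10-fragment / >=150 kbp filter
        assert 230000 < mol < 330000

    def test_parameter_recovery_quick(self, big_reference):
        sc = ScenarioParams.easier()
        _, truths = ma.simulate_maps(big_reference, sc, 300, seed=13)
        rates = estimate_rates(truths)
        assert abs(rates["d"] - sc.d) < 4 * rates["d_se"]
        assert abs(rates["f100"] - sc.f100) < 4 * rates["f100_se"] + 0.05

    def test_truth_roundtrip(self, big_reference, tmp_path):
        sc = ScenarioParams.harder()
        _, truths = ma.simulate_maps(big_reference, sc, 5, seed=44)
        p = tmp_path / "truth.tsv"
        write_truth(truths, p)
        back = read_truth(p)
        assert len(back) == len(truths)
        for a, b in zip(truths, back):
            assert a.map_id == b.map_id
            assert a.orientation == b.orientation
            assert a.kept_cut_idx == b.kept_cut_idx
            assert a.source_frag_ranges == b.source_frag_ranges
            assert a.start_bp == pytest.approx(b.start_bp, abs=0.05)


class TestSpuriousMap:
    def test_passes_filter_and_is_deterministic(self):
        sc = ScenarioParams.easier()
        m1 = ma.spurious_map(sc, 10800, 7)
        m2 = ma.spurious_map(sc, 10800, 7)
        np.testing.assert_array_equal(m1.fragments, m2.fragments)
        assert m1.m >= sc.min_map_fragments and m1.size >= sc.min_map_bp


class TestSimulateAssembly:
    def test_partition_and_filter(self, big_reference):
        scaffolds, infos = ma.simulate_assembly(big_reference, seed=8, n50_target_bp=2e6)
        # partition conserves total length before filtering
        total = sum(i.end_bp - i.start_bp for i in infos)
        assert total == pytest.approx(big_reference.size, rel=1e-9)
        for s in scaffolds:
            assert s.n - 2 >= 4  # at least 4 non-end fragments

    def test_n50_near_target(self):
        ref = ma.synth_reference(60000, 17300, seed=77)
        target = 2.0e6
        _, infos = ma.simulate_assembly(ref, seed=10, n50_target_bp=target)
        sizes = np.sort([i.end_bp - i.start_bp for i in infos])[::-1]
        csum = np.cumsum(sizes)
        n50 = sizes[np.searchsorted(csum, csum[-1] / 2.0)]
        assert abs(n50 - target) / target < 0.2
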