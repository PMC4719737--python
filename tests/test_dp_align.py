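"""Seed extension: chi^2 arithmetic, the skip rule, and oracle equivalence
of the banded DP against exhaustive partition enumeration."""

import numpy as np
import pytest

import mapalign as ma
from mapalign.dp_align import allow_gap, anchor_matches, extend_seed, match_chi2
from mapalign.seed_index import MERGE23, PLAIN, Q_PLAIN, SeedHit

from conftest import random_instance
from oracle import oracle_extend


class TestMatchChi2:
    @pytest.mark.parametrize(
        "o_sum,r_sum,var,expected",
        [
            (10000.0, 10000.0, 250000.0, 0.0),
            (11000.0, 10000.0, 250000.0, 4.0),
            (12000.0, 10000.0, 250000.0, 16.0),  # doubled deviation -> x4
        ],
    )
    def test_values(self, o_sum, r_sum, var, expected):
        assert match_chi2(o_sum, r_sum, var) == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            match_chi2(1.0, 1.0, 0.0)


class TestAllowGap:
    def test_rescues_infeasible_span(self, params):
        assert allow_gap([500.0], False, np.inf, True, 1.0, params)

    def test_halving_rule(self, params):
        assert allow_gap([500.0], True, 4.0, True, 1.9, params)       # 1.9 <= 2.0
        assert not allow_gap([500.0], True, 4.0, True, 2.1, params)   # 2.1 > 2.0

    def test_large_fragment_never_skippable(self, params):
        assert not allow_gap([3000.0], False, np.inf, True, 0.0, params)

    def test_infeasible_exclusive_rejected(self, params):
        assert not allow_gap([500.0], False, np.inf, False, 0.0, params)


class TestExtendSeed:
    def test_error_free_submap_perfect_score(self, small_reference, params):
        o = ma.ExperimentalMap("sub", small_reference.fragments[50:60].copy())
        hit = SeedHit(small_reference, "forward", 55, 5, PLAIN, Q_PLAIN)
        aln = extend_seed(o, hit, params)
        assert aln is not None
        assert aln.cut_errors == 0
        assert aln.chi2 == pytest.approx(0.0)
        assert aln.score == pytest.approx(0.0)
        assert aln.r_start == 51 and aln.r_end == 60
        assert all(m.q_end - m.q_start == 0 for m in aln.matches)

    def test_missing_cut_resolved_by_merged_seed(self, sigma_model, params):
        # o2 must span r2+r3: only the merged composite anchor allows it
        ref = ma.ReferenceMap.from_fragments("r", [10000.0, 7000.0, 8000.0], sigma_model)
        o = ma.ExperimentalMap("o", [10000.0, 15000.0])
        hit = SeedHit(ref, "forward", 1, 1, MERGE23, Q_PLAIN)
        aln = extend_seed(o, hit, params)
        assert aln is not None
        assert aln.missing_cuts == 1 and aln.cut_errors == 1
        assert [(m.r_start, m.r_end) for m in aln.matches] == [(1, 1), (2, 3)]

    def test_infeasible_extension_returns_none(self, sigma_model, params):
        # remaining query mass cannot fit into the remaining reference
        # (a truncated end may be smaller than the reference, never larger)
        ref = ma.ReferenceMap.from_fragments("r", [10000.0, 10000.0, 4000.0], sigma_model)
        o = ma.ExperimentalMap("o", [10000.0, 10000.0, 500000.0])
        hit = SeedHit(ref, "forward", 1, 1, PLAIN, Q_PLAIN)
        assert extend_seed(o, hit, params) is None

    def test_truncated_end_matches_are_one_sided(self, small_reference, params):
        o = ma.ExperimentalMap("sub", small_reference.fragments[30:40].copy())
        # shorten the terminal fragments as molecule-end truncation would
        frags = o.fragments.copy()
        frags[0] *= 0.4
        frags[-1] *= 0.3
        o = ma.ExperimentalMap("trunc", frags)
        hit = SeedHit(small_reference, "forward", 35, 5, PLAIN, Q_PLAIN)
        aln = extend_seed(o, hit, params)
        assert aln is not None
        assert aln.matches[0].truncated == "left"
        assert aln.matches[-1].truncated == "right"
        assert aln.cut_errors == 0


class TestOracleEquivalence:
    """The DP must agree with exhaustive enumeration on score, cut errors
    and chi^2, and the score must realize the two-stage (cut errors first,
    then chi^2) lexicographic optimum."""

    N_INSTANCES = 500

    def _run(self, seed):
        rng = np.random.default_rng(seed)
        params = ma.AlignParams()
        sigma_model = ma.SigmaModel()
        checked = agreed = 0
        for k in range(self.N_INSTANCES):
            o, ref, hit, anchor = random_instance(rng, params, sigma_model)
            if anchor is None:
                continue
            got = extend_seed(o, hit, params)
            want = oracle_extend(o, ref, anchor, params)
            checked += 1
            if want is None:
                assert got is None, f"instance {k}: DP found alignment, oracle none"
                agreed += 1
                continue
            assert got is not None, f"instance {k}: oracle found alignment, DP none"
            score, ce, chi2 = want["by_score"]
            assert got.score == pytest.approx(score, abs=1e-9), f"instance {k}"
            assert got.cut_errors == ce, f"instance {k}"
            assert got.chi2 == pytest.approx(chi2, abs=1e-9), f"instance {k}"
            # lexicographic dominance of the weighted score
            ts_ce, ts_chi2 = want["two_stage"]
            assert got.cut_errors == ts_ce, f"instance {k}: score is not ce-first"
            assert got.chi2 == pytest.approx(ts_chi2, abs=1e-9), f"instance {k}"
            agreed += 1
        assert checked >= self.N_INSTANCES * 0.9
        assert agreed == checked

    def test_dp_equals_bruteforce(self):
        self._run(915001)


class TestAnchorConstruction:
    def test_variant_shapes(self, small_reference):
        o = ma.ExperimentalMap("o", small_reference.fragments[10:20].copy())
        plain = anchor_matches(o, SeedHit(small_reference, "forward", 11, 1, PLAIN, Q_PLAIN))
        assert [(m.q_start, m.q_end, m.r_start, m.r_end) for m in plain] == [
            (1, 1, 11, 11),
            (2, 2, 12, 12),
        ]
        merged = anchor_matches(o, SeedHit(small_reference, "forward", 11, 1, MERGE23, Q_PLAIN))
        assert [(m.q_start, m.q_end, m.r_start, m.r_end) for m in merged] == [
            (1, 1, 11, 11),
            (2, 2, 12, 13),
        ]

    def test_out_of_bounds_anchor_is_rejected(self, small_reference):
        o = ma.ExperimentalMap("o", small_reference.fragments[10:12].copy())
        n = small_reference.n
        hit = SeedHit(small_reference, "forward", n, 1, PLAIN, Q_PLAIN)
        assert anchor_matches(o, hit) is None
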