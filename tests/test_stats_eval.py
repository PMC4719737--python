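"""Z-score machinery: the Wilson–Hilferty transform, feature
standardization, the combined score, q-values and the uniqueness test."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import mapalign as ma
from mapalign import stats_eval
from mapalign.stats_eval import (
    InsufficientCandidatesError,
    bh_qvalues,
    build_strata,
    combine,
    feature_zscores,
    selection_adjusted_p,
    storey_qvalues,
    wht,
)


class TestWHT:
    def test_hand_computed_values(self):
        assert wht(2.0, 2) == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert wht(0.0, 2) == pytest.approx(-8.0 / 3.0, abs=1e-12)

    def test_zero_by_construction(self):
        for n in (1, 3, 10):
            chi2 = n * (1.0 - 2.0 / (9.0 * n)) ** 3
            assert wht(chi2, n) == pytest.approx(0.0, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            wht(1.0, 0)
        with pytest.raises(ValueError):
            wht(-1.0, 2)

    def test_approximates_standard_normal(self):
        # chi^2 samples mapped through WHT should look standard normal
        rng = np.random.default_rng(4)
        n = 20
        z = np.array([wht(x, n) for x in rng.chisquare(n, 4000) ])
        assert abs(z.mean()) < 0.05
        assert abs(z.std() - 1.0) < 0.05


class TestFeatureZscores:
    def test_two_point_population(self):
        z = feature_zscores(np.array([[0.0], [2.0]]))
        assert z[:, 0] == pytest.approx([-1.0, 1.0])

    def test_zero_spread_convention(self):
        z = feature_zscores(np.array([[5.0, 1.0], [5.0, 2.0]]))
        assert np.all(z[:, 0] == 0.0)

    def test_insufficient_population(self):
        with pytest.raises(InsufficientCandidatesError):
            feature_zscores(np.array([[1.0, 2.0, 3.0]]))

    @settings(max_examples=50, derandomize=True)
    @given(
        vals=st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30),
        a=st.floats(0.1, 100.0),
        b=st.floats(-1e3, 1e3),
    )
    def test_affine_invariance(self, vals, a, b):
        x = np.array(vals)[:, None]
        assume(np.ptp(x) > 1e-6 * (1.0 + np.abs(x).max()))  # avoid cancellation
        z1 = feature_zscores(x)
        z2 = feature_zscores(a * x + b)
        assert np.allclose(z1, z2, atol=1e-5)


class TestCombine:
    def test_strictly_best_candidate_has_lowest_p(self):
        # candidate 0: more matches, fewer errors, lower WHT
        feats = np.array([[12, 1, -2.0], [8, 6, 0.5], [7, 7, 1.0], [9, 5, 0.2]])
        vt, p = combine(feature_zscores(feats))
        assert np.argmin(p) == 0
        assert np.argmin(vt) == 0

    def test_identical_population_is_degenerate(self):
        feats = np.array([[5, 2, 0.1]] * 4)
        vt, p = combine(feature_zscores(feats))
        assert np.all(vt == 0.0)
        assert p == pytest.approx([0.5] * 4)

    def test_vartheta_standardized(self):
        rng = np.random.default_rng(11)
        feats = rng.normal(size=(200, 3))
        vt, _ = combine(feature_zscores(feats))
        assert vt.mean() == pytest.approx(0.0, abs=1e-9)
        assert vt.std() == pytest.approx(1.0, abs=1e-9)


class TestQvalues:
    def test_bh_matches_direct_computation(self):
        p = np.array([0.001, 0.01, 0.03, 0.5])
        q = bh_qvalues(p)
        assert q == pytest.approx([0.004, 0.02, 0.04, 0.5])

    def test_storey_never_exceeds_bh_scaled(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        assert np.all(storey_qvalues(p) <= bh_qvalues(p) + 1e-12)

    def test_selection_adjustment(self):
        assert selection_adjusted_p(1e-6, 1) == pytest.approx(1e-6)
        assert selection_adjusted_p(1e-6, 1000) == pytest.approx(1e-3, rel=1e-2)
        assert selection_adjusted_p(0.5, 1000) == pytest.approx(1.0, abs=1e-6)


class TestStrata:
    def test_merging_to_minimum_size(self):
        m_values = [10] * 30 + [12] * 30 + [14] * 60
        strata = build_strata(m_values, min_per_stratum=50)
        sizes = sorted(len(s) for s in strata)
        assert sum(sizes) == 120
        assert all(s >= 50 for s in sizes)

    def test_single_map(self):
        strata = build_strata([17])
        assert len(strata) == 1 and list(strata[0]) == [0]


class TestUniqueness:
    def _cand(self, ref, r_start, r_end, orientation="forward"):
        from mapalign.dp_align import CandidateAlignment
        from mapalign.map_model import Match

        return CandidateAlignment(
            ref=ref,
            orientation=orientation,
            matches=[Match(1, 10, r_start, r_end)],
            chi2=1.0,
            score=1.0,
            q_len=10,
        )

    def test_separated_best_and_next_best_is_unique(self):
        ref = ma.ReferenceMap.from_fragments("r", [10000.0] * 100)
        best = self._cand(ref, 5, 14)
        other = self._cand(ref, 60, 69)
        ratio = stats_eval.uniqueness_ratio(best, [best, other], np.array([1e-9, 7e-6]))
        assert ratio == pytest.approx(7000.0)
        assert ratio >= 5.0

    def test_equal_pvalues_at_different_loci_not_unique(self):
        ref = ma.ReferenceMap.from_fragments("r", [10000.0] * 100)
        best = self._cand(ref, 5, 14)
        other = self._cand(ref, 60, 69)
        ratio = stats_eval.uniqueness_ratio(best, [best, other], np.array([1e-4, 1e-4]))
        assert ratio == pytest.approx(1.0)
        assert ratio < 5.0

    def test_duplicates_of_best_placement_excluded(self):
        ref = ma.ReferenceMap.from_fragments("r", [10000.0] * 100)
        best = self._cand(ref, 5, 14)
        shifted = self._cand(ref, 6, 15)  # same locus, slightly shifted
        ratio = stats_eval.uniqueness_ratio(
            best, [best, shifted], np.array([1e-9, 2e-9])
        )
        assert ratio == np.inf  # no genuine second locus


class TestFeatureIndependence:
    def test_features_nearly_independent_for_random_alignments(self):
        """For random (false) candidates the pairwise covariances of the
        three feature Z-scores stay near zero."""
        rng = np.random.default_rng(2024)
        n = 2000
        nm = rng.integers(6, 18, n)
        ce = rng.poisson(6.0, n)
        chi2 = np.array([rng.chisquare(k) for k in nm])
        feats = np.column_stack([nm, ce, [wht(c, k) for c, k in zip(chi2, nm)]])
        z = feature_zscores(feats)
        cov = np.cov(z.T)
        off_diag = cov[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off_diag) < 0.1)
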