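"""Statistical significance and uniqueness of candidate alignments.

The population of feasible candidate alignments found for one experimental
map approximates a sample from a conservative null model (at most one of them
can be the true placement).  Each candidate is summarized by three features —
number of matches, total cut errors, and the Wilson–Hilferty transform of its
chi^2 — which are approximately independent for false alignments.  Each
feature is Z-standardized over the candidate population, the signed sum
(more matches good, fewer errors good) is Z-standardized again to give a
combined score, and its standard-normal tail probability is the candidate's
p-value.  The best candidate per map is then subjected to a false discovery
rate (q-value) analysis across comparable maps (same fragment-count stratum)
and a best/next-best p-value ratio test for uniqueness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .dp_align import CandidateAlignment
from .map_model import AlignParams

__all__ = [
    "InsufficientCandidatesError",
    "FeatureVector",
    "CandidateEvaluation",
    "wht",
    "feature_zscores",
    "combine",
    "evaluate_population",
    "bh_qvalues",
    "storey_qvalues",
    "build_strata",
    "uniqueness_ratio",
    "assess",
    "SIGNIFICANT_UNIQUE",
    "NON_SIGNIFICANT",
    "NON_UNIQUE",
]

SIGNIFICANT_UNIQUE = "significant_unique"
NON_SIGNIFICANT = "non_significant"
NON_UNIQUE = "non_unique"

_P_FLOOR = 1e-300


class InsufficientCandidatesError(ValueError):
    """Raised when a candidate population is too small to standardize."""


@dataclass(frozen=True)
class FeatureVector:
    n_matches: int
    cut_errors: int
    wht: float

    @classmethod
    def from_alignment(cls, aln: CandidateAlignment) -> "FeatureVector":
        return cls(aln.n_matches, aln.cut_errors, wht(aln.chi2, aln.n_matches))


@dataclass
class CandidateEvaluation:
    vartheta: float
    p_value: float
    q_value: float | None = None
    status: str | None = None
    low_population: bool = False
    n_candidates: int = 0


def wht(chi2: float, n_matches: int) -> float:
    """Wilson–Hilferty cube-root transform of a chi^2 with ``n_matches``
    degrees of freedom; approximately standard normal for moderate n."""
    if n_matches < 1:
        raise ValueError("n_matches must be >= 1")
    if chi2 < 0:
        raise ValueError("chi2 must be >= 0")
    n = float(n_matches)
    a = (2.0 / n) / 9.0
    return ((chi2 / n) ** (1.0 / 3.0) - (1.0 - a)) / np.sqrt(a)


def _zscores_1d(x: np.ndarray) -> np.ndarray:
    # population SD; a feature with zero spread is non-informative -> all 0
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def feature_zscores(features: np.ndarray) -> np.ndarray:
    """Column-wise Z-scores over the candidate population (rows).

    ``features`` is an (n_candidates, n_features) array; requires at least
    two candidates.  A zero-spread feature yields all-zero Z-scores.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 2:
        raise InsufficientCandidatesError(
            "need at least 2 candidates to standardize features"
        )
    return np.column_stack([_zscores_1d(features[:, j]) for j in range(features.shape[1])])


def combine(z: np.ndarray, signs=( -1.0, 1.0, 1.0 )) -> tuple[np.ndarray, np.ndarray]:
    """Combined score and p-value per candidate.

    The inner signed sum uses sign -1 for features where higher is better
    (#matches) and +1 where lower is better (#cut errors, WHT); the sum is
    Z-standardized over the population and mapped through the standard-normal
    CDF.  Lower p is better; the best candidate is the argmin of p.
    """
    z = np.asarray(z, dtype=float)
    inner = z @ np.asarray(signs, dtype=float)
    vartheta = _zscores_1d(inner)
    p = norm.cdf(vartheta)
    return vartheta, np.clip(p, _P_FLOOR, 1.0 - 1e-16)


def evaluate_population(cands: list[CandidateAlignment]):
    """(vartheta, p) arrays for a map's deduplicated candidate population."""
    feats = np.array(
        [[c.n_matches, c.cut_errors, wht(c.chi2, c.n_matches)] for c in cands]
    )
    return combine(feature_zscores(feats))


def selection_adjusted_p(p_best: float, n_candidates: int) -> float:
    """Best-of-population p-value corrected for selection.

    The best candidate's p is the minimum over the map's ``n_candidates``
    approximately-exchangeable scores; under the null its distribution is
    Beta(1, N)-like, so the Šidák-corrected ``1 - (1 - p)^N`` restores a
    uniform null before the cross-map FDR step.  Candidate correlation
    (overlapping placements) makes the correction conservative.
    """
    if n_candidates <= 1:
        return float(p_best)
    return float(-np.expm1(n_candidates * np.log1p(-min(p_best, 1.0 - 1e-16))))


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg FDR-adjusted q-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    return multipletests(pvals, method="fdr_bh")[1]


def storey_qvalues(pvals: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a fixed-lambda pi0 estimate (optional alternative
    to Benjamini–Hochberg)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    pi0 = min(1.0, (pvals > lam).mean() / (1.0 - lam))
    pi0 = max(pi0, 1.0 / pvals.size)
    return np.minimum(1.0, pi0 * bh_qvalues(pvals))


def build_strata(m_values, bin_width: int = 2, min_per_stratum: int = 50):
    """Group map indices into fragment-count strata.

    Maps are binned by fragment count (width ``bin_width``); adjacent bins
    are merged until each stratum holds at least ``min_per_stratum`` maps
    (small strata make the FDR estimate unstable).  Returns a list of index
    arrays.
    """
    m_values = np.asarray(m_values)
    if m_values.size == 0:
        return []
    bins = (m_values // bin_width).astype(int)
    order = np.argsort(bins, kind="stable")
    strata: list[list[int]] = []
    current: list[int] = []
    current_bin = None
    for idx in order:
        b = bins[idx]
        if current_bin is not None and b != current_bin and len(current) >= min_per_stratum:
            strata.append(current)
            current = []
        current.append(int(idx))
        current_bin = b
    if current:
        if strata and len(current) < min_per_stratum:
            strata[-1].extend(current)
        else:
            strata.append(current)
    return [np.asarray(s) for s in strata]


def uniqueness_ratio(best: CandidateAlignment, cands, pvals) -> float:
    """Ratio p_nextbest / p_best, excluding candidates that duplicate the
    best placement (same map, orientation and >= 50 % reciprocal fragment
    overlap)."""
    order = np.argsort(pvals, kind="stable")
    p_best = None
    for k in order:
        c = cands[k]
        if p_best is None:
            if c is best:
                p_best = pvals[k]
            continue
        if not _same_locus(best, c):
            return float(pvals[k] / max(p_best, _P_FLOOR))
    return np.inf


def _same_locus(a: CandidateAlignment, b: CandidateAlignment) -> bool:
    if a.ref_id != b.ref_id or a.orientation != b.orientation:
        return False
    lo = max(a.r_start, b.r_start)
    hi = min(a.r_end, b.r_end)
    inter = max(0, hi - lo + 1)
    return (
        inter >= 0.5 * (a.r_end - a.r_start + 1)
        and inter >= 0.5 * (b.r_end - b.r_start + 1)
    )


def assess(
    best: CandidateAlignment,
    cands: list[CandidateAlignment],
    pvals: np.ndarray,
    varthetas: np.ndarray,
    q_value: float,
    params: AlignParams,
) -> CandidateEvaluation:
    """Final status of a map's best candidate given its population and a
    q-value computed across comparable maps."""
    k = cands.index(best)
    ev = CandidateEvaluation(
        vartheta=float(varthetas[k]),
        p_value=float(pvals[k]),
        q_value=float(q_value),
        n_candidates=len(cands),
        low_population=len(cands) < 60,
    )
    if q_value > params.q_threshold:
        ev.status = NON_SIGNIFICANT
    elif uniqueness_ratio(best, cands, pvals) < params.uniqueness_ratio:
        ev.status = NON_UNIQUE
    else:
        ev.status = SIGNIFICANT_UNIQUE
    return ev
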