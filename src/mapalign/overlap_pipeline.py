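"""Overlap alignment via sliding-window sub-map alignment and extension.

Each experimental map is divided into sub-maps of ``window_l`` fragments
with a step-1 sliding window; each sub-map is glocally aligned and
statistically evaluated exactly like a full map (truncated ends allowed).
Window solutions are ranked by p-value and iterated best-first under
significance/uniqueness/conflict rules; each surviving window's seed is then
re-extended over the full map until an end of either the experimental or the
in-silico map is reached on both sides, which is what makes the result an
overlap alignment usable for scaffold extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import stats_eval
from .dp_align import CandidateAlignment, extend_overlap
from .glocal_pipeline import align_map
from .map_model import AlignParams, ExperimentalMap
from .seed_index import SeedHit, SeedIndex

__all__ = [
    "WindowSolution",
    "OverlapAlignment",
    "window_align",
    "conflicts",
    "select_and_extend",
    "overlap_run",
]

OVERLAP_COLUMNS = [
    "map_id",
    "ref_id",
    "orientation",
    "r_start",
    "r_end",
    "q_start",
    "q_end",
    "n_matches",
    "chi2",
    "p_value",
    "q_value",
    "overlap_type",
    "extension_fragments",
]


@dataclass
class WindowSolution:
    """Glocal solution of one sliding-window sub-map."""

    map: ExperimentalMap          # the full experimental map
    w_start: int                  # 1-based first fragment of the window
    length: int
    candidates: list = field(default_factory=list)
    pvals: np.ndarray | None = None
    varthetas: np.ndarray | None = None
    best: CandidateAlignment | None = None
    evaluation: stats_eval.CandidateEvaluation | None = None

    @property
    def w_end(self) -> int:
        return self.w_start + self.length - 1

    @property
    def category(self) -> str:
        """(i) significant+unique, (ii) false alignment, (iii) nothing found."""
        if self.best is None:
            return "iii"
        if (
            self.evaluation is not None
            and self.evaluation.status == stats_eval.SIGNIFICANT_UNIQUE
        ):
            return "i"
        return "ii"

    @property
    def p_best(self) -> float:
        if self.pvals is None:
            return float("inf")
        return float(self.pvals.min())

    def diagonal(self) -> float:
        """Expected reference offset of the full map's first fragment, used
        to decide whether two windows continue the same placement."""
        b = self.best
        if b.orientation == "forward":
            return b.r_start - self.w_start
        # reverse: window start counts from the other end of the map
        return b.r_end + (self.map.m - self.w_end + 1)


@dataclass
class OverlapAlignment:
    """A reported overlap alignment (extension of a surviving window)."""

    map: ExperimentalMap
    window: WindowSolution
    alignment: CandidateAlignment
    p_value: float
    q_value: float

    @property
    def left_overhang(self) -> int:
        return self.alignment.q_start - 1

    @property
    def right_overhang(self) -> int:
        return self.alignment.q_len - self.alignment.q_end

    @property
    def extension_fragments(self) -> int:
        return self.left_overhang + self.right_overhang

    @property
    def overlap_type(self) -> str:
        l, r = self.left_overhang > 0, self.right_overhang > 0
        if l and r:
            return "spanning"
        if l:
            return "left"
        if r:
            return "right"
        return "contained"

    def key(self) -> tuple:
        a = self.alignment
        return (a.ref_id, a.orientation, a.r_start, a.r_end, a.q_start, a.q_end)

    def row(self) -> dict:
        a = self.alignment
        return {
            "map_id": self.map.id,
            "ref_id": a.ref_id,
            "orientation": a.orientation,
            "r_start": a.r_start,
            "r_end": a.r_end,
            "q_start": a.q_start,
            "q_end": a.q_end,
            "n_matches": a.n_matches,
            "chi2": a.chi2,
            "p_value": self.p_value,
            "q_value": self.q_value,
            "overlap_type": self.overlap_type,
            "extension_fragments": self.extension_fragments,
        }


def window_align(
    o: ExperimentalMap, index: SeedIndex, params: AlignParams
) -> list[WindowSolution]:
    """One glocal sub-problem per sliding-window position (step 1)."""
    l = params.window_l
    if o.m < l:
        return []
    sols = []
    for w in range(1, o.m - l + 2):
        sub = ExperimentalMap(f"{o.id}:w{w}", o.fragments[w - 1 : w + l - 1].copy())
        res = align_map(sub, index, params)
        sols.append(
            WindowSolution(
                map=o,
                w_start=w,
                length=l,
                candidates=res.candidates,
                pvals=res.pvals,
                varthetas=res.varthetas,
                best=res.best,
            )
        )
    return sols


def conflicts(s1: WindowSolution, s2: WindowSolution, params: AlignParams) -> bool:
    """Conflicting sub-map alignments: overlapping windows, or placement on
    the same in-silico map at a different location or strand.

    Two non-overlapping windows on the same reference are considered the same
    location when they lie on the same orientation-consistent diagonal
    (within a window length), i.e. when one alignment continues the other.
    """
    if s1.best is None or s2.best is None:
        return False
    if not (s1.w_end < s2.w_start or s2.w_end < s1.w_start):
        return True  # sub-maps overlap
    b1, b2 = s1.best, s2.best
    if b1.ref_id != b2.ref_id:
        return False
    if b1.orientation != b2.orientation:
        return True
    return abs(s1.diagonal() - s2.diagonal()) > params.window_l


def _shift_hit(hit: SeedHit, offset: int) -> SeedHit:
    return hit._replace(q_pos=hit.q_pos + offset)


def _extend_window(
    sol: WindowSolution, params: AlignParams
) -> CandidateAlignment | None:
    """Re-extend the winning window seed over the full map, stopping at an
    end of either map on both sides."""
    o = sol.map
    best = sol.best
    if best is None or best.seed is None:
        return None
    if best.orientation == "forward":
        query = o
        offset = sol.w_start - 1
    else:
        query = o.reverse()
        offset = o.m - sol.w_end
    hit = _shift_hit(best.seed, offset)
    return extend_overlap(query, hit, params, orientation=best.orientation)


def select_and_extend(
    solutions: list[WindowSolution], params: AlignParams
) -> list[OverlapAlignment]:
    """Iterate ranked window solutions best-first and extend the survivors.

    Stops at the first false-labeled solution; skips duplicates of already
    reported overlaps, solutions conflicting with better-ranked picks, and
    solutions that are not unique with respect to worse-ranked conflicting
    solutions.  Survivors are extended to an end of either map on both sides
    and reported when their q-value passes the FDR threshold.
    """
    ranked = sorted(
        (s for s in solutions if s.best is not None),
        key=lambda s: (s.p_best, s.w_start),
    )
    picked: list[WindowSolution] = []
    reported: list[OverlapAlignment] = []
    seen_keys: set = set()
    for i, sol in enumerate(ranked):
        if sol.category != "i":
            break  # false alignment: stop iterating
        if any(conflicts(sol, better, params) for better in picked):
            continue
        non_unique = False
        for other in ranked[i + 1 :]:
            if conflicts(sol, other, params):
                ratio = other.p_best / max(sol.p_best, 1e-300)
                if ratio < params.uniqueness_ratio:
                    non_unique = True
                    break
        if non_unique:
            continue
        aln = _extend_window(sol, params)
        if aln is None:
            continue
        ov = OverlapAlignment(
            map=sol.map,
            window=sol,
            alignment=aln,
            p_value=sol.p_best,
            q_value=sol.evaluation.q_value if sol.evaluation else float("nan"),
        )
        if ov.key() in seen_keys:
            continue
        if sol.evaluation is not None and sol.evaluation.q_value is not None:
            if sol.evaluation.q_value > params.q_threshold:
                continue
        seen_keys.add(ov.key())
        picked.append(sol)
        reported.append(ov)
    return reported


def overlap_run(maps, index: SeedIndex, params: AlignParams):
    """Sliding-window overlap alignment of a collection of maps.

    Returns ``(overlaps_per_map, window_solutions_per_map)``.  q-values are
    learned from the pooled population of window solutions across the whole
    run (all windows share the same sub-map length, hence one stratum).
    """
    per_map_sols = [window_align(o, index, params) for o in maps]
    flat = [s for sols in per_map_sols for s in sols if s.pvals is not None]
    if flat:
        q = stats_eval.bh_qvalues(
            np.array(
                [
                    stats_eval.selection_adjusted_p(s.p_best, len(s.candidates))
                    for s in flat
                ]
            )
        )
        for s, qv in zip(flat, q):
            s.evaluation = stats_eval.assess(
                s.best, s.candidates, s.pvals, s.varthetas, float(qv), params
            )
    for sols in per_map_sols:
        for s in sols:
            if s.best is not None and s.evaluation is None:
                # single-candidate windows cannot be standardized
                s.evaluation = stats_eval.CandidateEvaluation(
                    vartheta=float("nan"),
                    p_value=float("nan"),
                    q_value=float("nan"),
                    status=stats_eval.NON_SIGNIFICANT,
                    n_candidates=len(s.candidates),
                    low_population=True,
                )
    overlaps = [select_and_extend(sols, params) for sols in per_map_sols]
    return overlaps, per_map_sols
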