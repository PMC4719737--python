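"""Banded dynamic-programming extension of seeds into glocal/overlap alignments.

A candidate alignment is an ordered sequence of feasible matches that
partitions the experimental fragments (all of them for glocal alignment).
The score being minimized is

    Score = C_ce * (#cut errors) + sum(chi^2 per match),

where ``#cut errors = missing cuts + false cuts + missing fragments`` and
``C_ce`` exceeds any achievable total chi^2, so minimizing the score is
exactly the lexicographic minimization of (cut errors, chi^2).  Each match is
banded to at most 5 consecutive false cuts and 8 consecutive missing cuts.

Small in-silico fragments (<= 2 kbp, below the experimental detection limit)
may be skipped inside a match, in runs of at most three, when doing so either
rescues feasibility or at least halves the chi^2 of the same match span.
Skipping a fragment trades one missing cut for one missing fragment, so the
cut-error count of a match block depends only on its extent — gap variants
compete purely on chi^2.

End matches of an alignment are one-sided tested: the terminal experimental
fragment may be truncated, so only the positive excess of the experimental
sum is capped ("upper" mode); matches pinned at an in-silico map end (overlap
alignment) cap only the deficit ("lower" mode).  One-sided matches carry no
chi^2 term.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import sqrt

from .map_model import AlignParams, ExperimentalMap, Match, ReferenceMap
from .seed_index import MERGE12, MERGE23, PLAIN, Q_MERGED, SeedHit

__all__ = [
    "CandidateAlignment",
    "match_chi2",
    "allow_gap",
    "extend_seed",
    "extend_overlap",
    "anchor_matches",
]


def match_chi2(o_sum: float, r_sum: float, r_var: float) -> float:
    """chi^2 contribution of one match: ``(sum(o) - sum(r))^2 / sum(sigma^2)``."""
    if r_var <= 0:
        raise ValueError("reference variance must be > 0")
    return (o_sum - r_sum) ** 2 / r_var


def allow_gap(
    gap_sizes,
    incl_feasible: bool,
    incl_chi2: float,
    excl_feasible: bool,
    excl_chi2: float,
    params: AlignParams,
) -> bool:
    """Whether skipping small in-silico fragments is allowed for a match span.

    The gapped (exclusive) variant of a match is allowed when every skipped
    fragment is below the detection limit and it either rescues an infeasible
    span or improves the chi^2 of the same span by at least half.
    """
    if any(g > params.small_fragment_bp for g in gap_sizes):
        return False
    if not excl_feasible:
        return False
    if not incl_feasible:
        return True
    return excl_chi2 <= 0.5 * incl_chi2


@dataclass
class CandidateAlignment:
    """A feasible alignment: ordered matches plus error counts and score.

    Query indices refer to the query in its aligned orientation (the pipeline
    reverses the experimental map to search the reverse strand); reference
    indices always refer to the forward in-silico map.
    """

    ref: ReferenceMap
    orientation: str
    matches: list[Match]
    chi2: float
    score: float
    seed: SeedHit | None = None
    q_len: int = 0  # fragments in the aligned query (m for glocal)

    @property
    def ref_id(self) -> str:
        return self.ref.id

    @property
    def n_matches(self) -> int:
        return len(self.matches)

    @property
    def false_cuts(self) -> int:
        return sum(m.false_cuts for m in self.matches)

    @property
    def missing_cuts(self) -> int:
        return sum(m.missing_cuts for m in self.matches)

    @property
    def missing_fragments(self) -> int:
        return sum(m.missing_fragments for m in self.matches)

    @property
    def cut_errors(self) -> int:
        return self.false_cuts + self.missing_cuts + self.missing_fragments

    @property
    def r_start(self) -> int:
        return self.matches[0].r_start

    @property
    def r_end(self) -> int:
        return self.matches[-1].r_end

    @property
    def q_start(self) -> int:
        return self.matches[0].q_start

    @property
    def q_end(self) -> int:
        return self.matches[-1].q_end

    def interval_bp(self) -> tuple[float, float]:
        return self.ref.interval_bp(self.r_start, self.r_end)

    def key(self) -> tuple:
        """Dedup key: placement plus full match structure."""
        structure = tuple(
            (m.q_start, m.q_end, m.r_start, m.r_end, m.gap_fragments) for m in self.matches
        )
        return (self.ref.id, self.orientation, structure)


# ---------------------------------------------------------------------------
# one-sided DP extension
# ---------------------------------------------------------------------------

_DEAD_SPAN = 6  # a match block consumes at most 6 query fragments


@dataclass
class _Terminal:
    score: float
    nm: int
    ce: int
    chi2: float
    s: int          # query fragments consumed on this side
    t: int          # reference fragments consumed on this side
    at_ref_end: bool
    blocks: list    # [(dq, dr, gaps_rel, mode), ...] in extension order


def _best_block_variant(
    o_sum: float,
    t0: int,
    dr: int,
    RP: list,
    RV: list,
    sizes: list,
    smalls: tuple,
    scount: list,
    mode: str,
    C: float,
):
    """Best admissible variant (by chi^2) of one match block.

    The block covers segment fragments ``t0+1 .. t0+dr``; candidate gap
    positions are small (sub-detection-limit) fragments in
    ``t0+1 .. t0+dr-1`` — gaps attach toward the preceding match, never to
    the block's far edge.  ``smalls`` lists the small positions of the
    segment and ``scount`` is their prefix count.  Returns
    ``(scored_chi2, gaps)`` or None; one-sided blocks score no chi^2.
    """
    t = t0 + dr
    r_sum = RP[t] - RP[t0]
    r_var = RV[t] - RV[t0]
    dev = o_sum - r_sum
    bound = C * sqrt(r_var)
    if mode == "two_sided":
        incl_feas = -bound <= dev <= bound
    elif mode == "upper":
        incl_feas = dev <= bound
    else:  # lower
        incl_feas = dev >= -bound
    # Fast paths.  Skipping a reference fragment raises the deviation
    # (d = dev + skipped mass) and shrinks the variance, so gaps can only
    # rescue or improve a block whose experimental sum falls short (dev < 0):
    # with dev >= 0 the gapped chi^2 strictly exceeds the inclusive one and
    # can never reach the halving threshold, and an upper-mode violation
    # (dev > bound) can never be rescued.
    if (
        dr == 1
        or scount[t - 1] == scount[t0]  # no skippable fragment inside
        or mode == "upper"
        or dev >= 0.0
        or (mode == "lower" and incl_feas)
    ):
        if not incl_feas:
            return None
        return (dev * dev / r_var if mode == "two_sided" else 0.0, ())

    incl_chi2 = dev * dev / r_var
    eligible = [g for g in smalls if t0 < g < t]
    if incl_feas and min(sizes[g - 1] for g in eligible) > -2.0 * dev:
        # every candidate gap overshoots: |dev + g_sum| > |dev|, chi^2 grows
        return (incl_chi2, ())
    best = (incl_chi2, ()) if incl_feas else None
    half = 0.5 * incl_chi2
    for size_g in range(1, min(len(eligible), dr - 1) + 1):
        for G in combinations(eligible, size_g):
            # runs of consecutive skipped fragments limited to 3
            run = 1
            ok = True
            for a, b in zip(G, G[1:]):
                run = run + 1 if b == a + 1 else 1
                if run > 3:
                    ok = False
                    break
            if not ok:
                continue
            g_sum = 0.0
            g_var = 0.0
            for g in G:
                g_sum += sizes[g - 1]
                g_var += RV[g] - RV[g - 1]
            v = r_var - g_var
            if v <= 0:
                continue
            d = dev + g_sum
            b_g = C * sqrt(v)
            if mode == "two_sided":
                if not (-b_g <= d <= b_g):
                    continue
            elif mode == "upper":
                if d > b_g:
                    continue
            elif d < -b_g:
                continue
            chi2_g = d * d / v
            # skipping is allowed when it rescues feasibility or halves chi^2
            if incl_feas and chi2_g > half:
                continue
            if best is None or chi2_g < best[0]:
                best = (chi2_g, G)
    if best is None:
        return None
    chi2, gaps = best
    return (chi2 if mode == "two_sided" else 0.0, gaps)


def _extend_side(
    o_sizes,
    ref_sizes,
    ref_vars,
    params: AlignParams,
    Cce: float,
    ref_end_reachable: bool = False,
    query_end_truncated: bool = True,
    stop_at_ref_end: bool = False,
):
    """Extend from an anchor boundary over one side, in extension order.

    ``o_sizes``/``ref_sizes`` run outward from the anchor.  The DP state
    ``(s, t)`` aligns the end of the s-th query segment fragment with the end
    of the t-th reference segment fragment.  Terminal states consume all
    query fragments (the outermost match one-sided "upper" when the map end
    may be truncated) or, when ``stop_at_ref_end``, reach the reference end
    with a one-sided "lower" match.  Returns the list of terminal records.
    """
    Q = len(o_sizes)
    W = len(ref_sizes)
    if Q == 0:
        return [_Terminal(0.0, 0, 0, 0.0, 0, 0, False, [])]
    OP = [0.0]
    for x in o_sizes:
        OP.append(OP[-1] + x)
    RP = [0.0]
    RV = [0.0]
    for x, v in zip(ref_sizes, ref_vars):
        RP.append(RP[-1] + x)
        RV.append(RV[-1] + v)
    smalls = tuple(
        g for g in range(1, W + 1) if ref_sizes[g - 1] <= params.small_fragment_bp
    )
    scount = [0] * (W + 1)
    for g in smalls:
        for j in range(g, W + 1):
            scount[j] += 1
    C = params.C_sigma
    max_fc = params.max_false_cuts_per_match
    max_mc = params.max_missing_cuts_per_match

    # states[s] maps t -> (score, nm, ce, chi2, back); back = (s0, t0, gaps, mode)
    states: list[dict] = [dict() for _ in range(Q + 1)]
    states[0][0] = (0.0, 0, 0, 0.0, None)
    terminals: list[_Terminal] = []

    for s in range(1, Q + 1):
        st_s = states[s]
        is_q_end = s == Q
        mode = "upper" if (is_q_end and query_end_truncated) else "two_sided"
        for dq in range(1, min(max_fc + 1, s) + 1):
            s0 = s - dq
            prev = states[s0]
            if not prev:
                continue
            o_sum = OP[s] - OP[s0]
            ce_q = dq - 1
            for t0, (sc0, nm0, ce0, chi0, _) in prev.items():
                for dr in range(1, min(max_mc + 1, W - t0) + 1):
                    t = t0 + dr
                    ce_blk = ce_q + dr - 1
                    res = _best_block_variant(
                        o_sum, t0, dr, RP, RV, ref_sizes, smalls, scount, mode, C
                    )
                    if res is not None:
                        chi2_blk, gaps = res
                        sc = sc0 + Cce * ce_blk + chi2_blk
                        cur = st_s.get(t)
                        if cur is None or (sc, nm0 + 1) < (cur[0], cur[1]):
                            st_s[t] = (sc, nm0 + 1, ce0 + ce_blk, chi0 + chi2_blk, (s0, t0, gaps, mode))
                    if (
                        stop_at_ref_end
                        and ref_end_reachable
                        and t == W
                        and not is_q_end
                    ):
                        res2 = _best_block_variant(
                            o_sum, t0, dr, RP, RV, ref_sizes, smalls, scount, "lower", C
                        )
                        if res2 is not None:
                            _, gaps2 = res2
                            sc = sc0 + Cce * ce_blk
                            blocks = _backtrace(states, (s0, t0, gaps2, "lower"), s, t)
                            terminals.append(
                                _Terminal(sc, nm0 + 1, ce0 + ce_blk, chi0, s, t, True, blocks)
                            )
        # exact death: no state can seed any future block
        if s >= _DEAD_SPAN and all(
            not states[x] for x in range(s - _DEAD_SPAN + 1, s + 1)
        ):
            return terminals

    for t, (sc, nm, ce, chi2, back) in states[Q].items():
        blocks = _backtrace(states, back, Q, t)
        terminals.append(_Terminal(sc, nm, ce, chi2, Q, t, ref_end_reachable and t == W, blocks))
    return terminals


def _backtrace(states, head_back, s, t):
    blocks = []
    back = head_back
    while back is not None:
        s0, t0, gaps, mode = back
        blocks.append((s - s0, t - t0, tuple(g - t0 for g in gaps), mode))
        s, t = s0, t0
        back = states[s][t][4]
    blocks.reverse()
    return blocks


# ---------------------------------------------------------------------------
# anchor construction and full extension
# ---------------------------------------------------------------------------

def anchor_matches(o: ExperimentalMap, hit: SeedHit) -> list[Match] | None:
    """Fixed matches implied by a seed hit's composition (Definition-4 cases
    on the reference side, optional merged pair on the query side)."""
    i, j = hit.q_pos, hit.r_pos
    n = hit.ref.n
    q_span = 3 if hit.q_variant == Q_MERGED else 2
    r_span = 3 if hit.ref_variant != PLAIN else 2
    if i + q_span - 1 > o.m or j + r_span - 1 > n:
        return None
    if hit.q_variant == Q_MERGED:
        first_q = (i, i + 1)
        second_q = (i + 2, i + 2)
    else:
        first_q = (i, i)
        second_q = (i + 1, i + 1)
    if hit.ref_variant == MERGE12:
        first_r = (j, j + 1)
        second_r = (j + 2, j + 2)
    elif hit.ref_variant == MERGE23:
        first_r = (j, j)
        second_r = (j + 1, j + 2)
    else:
        first_r = (j, j)
        second_r = (j + 1, j + 1)
    return [
        Match(first_q[0], first_q[1], first_r[0], first_r[1]),
        Match(second_q[0], second_q[1], second_r[0], second_r[1]),
    ]


def _side_inputs(
    o: ExperimentalMap, ref: ReferenceMap, qa: int, qb: int, ra: int, rb: int,
    params: AlignParams,
):
    """Per-side query/reference segments in extension order.

    Left side runs from the anchor outward to o_1 / r_1; right side to
    o_m / r_n.  The reference window is capped at the maximum reach of the
    band (at most ``max_missing + 1`` reference fragments per query fragment).
    """
    per_q = params.max_missing_cuts_per_match + 1
    var = ref.sigmas**2
    q_left = o.fragments[: qa - 1][::-1]
    reach_l = min(ra - 1, per_q * len(q_left) + 1)
    r_left = ref.fragments[ra - 1 - reach_l : ra - 1][::-1]
    v_left = var[ra - 1 - reach_l : ra - 1][::-1]
    left_hits_ref_end = reach_l == ra - 1

    q_right = o.fragments[qb:]
    reach_r = min(ref.n - rb, per_q * len(q_right) + 1)
    r_right = ref.fragments[rb : rb + reach_r]
    v_right = var[rb : rb + reach_r]
    right_hits_ref_end = reach_r == ref.n - rb
    return (
        (q_left.tolist(), r_left.tolist(), v_left.tolist(), left_hits_ref_end),
        (q_right.tolist(), r_right.tolist(), v_right.tolist(), right_hits_ref_end),
    )


def _blocks_to_matches(blocks, qa: int, ra: int, side: str) -> list[Match]:
    """Convert extension-order blocks to Match objects in map coordinates.

    ``qa``/``ra`` are the anchor boundary fragments (first fragment beyond
    the anchor is qa±1).  ``side`` is "left" or "right".
    """
    matches = []
    s = t = 0
    for dq, dr, gaps_rel, mode in blocks:
        if side == "right":
            q_lo, q_hi = qa + s + 1, qa + s + dq
            r_lo, r_hi = ra + t + 1, ra + t + dr
            gaps = tuple(ra + t + g for g in gaps_rel)
        else:
            q_hi, q_lo = qa - s - 1, qa - s - dq
            r_hi, r_lo = ra - t - 1, ra - t - dr
            gaps = tuple(sorted(ra - t - g for g in gaps_rel))
        trunc = None
        if mode == "upper":
            trunc = "right" if side == "right" else "left"
        elif mode == "lower":
            trunc = "right" if side == "right" else "left"
        matches.append(Match(q_lo, q_hi, r_lo, r_hi, gaps, trunc))
        s += dq
        t += dr
    if side == "left":
        matches.reverse()
    return matches


def _anchor_stats(o: ExperimentalMap, ref: ReferenceMap, anchor: list[Match]):
    """(cut_errors, chi2) of the fixed anchor matches; anchor matches that
    touch a query end are one-sided by convention and contribute no chi^2."""
    from .map_model import range_stats

    ce = 0
    chi2 = 0.0
    for mt in anchor:
        ce += mt.false_cuts + mt.missing_cuts + mt.missing_fragments
        terminal = mt.q_start == 1 or mt.q_end == o.m
        r_sum, r_var = range_stats(ref, mt.r_start, mt.r_end, mt.gap_fragments)
        o_sum = float(o.fragments[mt.q_start - 1 : mt.q_end].sum())
        if not terminal:
            chi2 += match_chi2(o_sum, r_sum, r_var)
    return ce, chi2


def _mark_anchor_truncation(o: ExperimentalMap, anchor: list[Match]) -> list[Match]:
    out = []
    for mt in anchor:
        trunc = None
        if mt.q_start == 1:
            trunc = "left"
        elif mt.q_end == o.m:
            trunc = "right"
        if trunc:
            mt = Match(mt.q_start, mt.q_end, mt.r_start, mt.r_end, mt.gap_fragments, trunc)
        out.append(mt)
    return out


def extend_seed(
    o: ExperimentalMap,
    hit: SeedHit,
    params: AlignParams,
    orientation: str | None = None,
) -> CandidateAlignment | None:
    """Extend a seed into the optimal glocal alignment containing it.

    Returns the alignment covering all experimental fragments that minimizes
    (cut errors, chi^2) lexicographically, with ties broken by fewer matches
    and then leftmost reference start, or None when no feasible full
    extension exists.
    """
    anchor = anchor_matches(o, hit)
    if anchor is None:
        return None
    ref = hit.ref
    qa, qb = anchor[0].q_start, anchor[-1].q_end
    ra, rb = anchor[0].r_start, anchor[-1].r_end
    Cce = params.cut_error_weight(o.m)

    (lq, lr, lv, _), (rq, rr, rv, _) = _side_inputs(o, ref, qa, qb, ra, rb, params)
    left = _extend_side(lq, lr, lv, params, Cce)
    if not left:
        return None
    right = _extend_side(rq, rr, rv, params, Cce)
    if not right:
        return None
    # leftmost reference start on ties: larger t on the left side
    best_l = min(left, key=lambda T: (T.score, T.nm, -T.t))
    best_r = min(right, key=lambda T: (T.score, T.nm, T.t))

    anchor_ce, anchor_chi2 = _anchor_stats(o, ref, anchor)
    matches = (
        _blocks_to_matches(best_l.blocks, qa, ra, "left")
        + _mark_anchor_truncation(o, anchor)
        + _blocks_to_matches(best_r.blocks, qb, rb, "right")
    )
    chi2 = best_l.chi2 + anchor_chi2 + best_r.chi2
    ce = best_l.ce + anchor_ce + best_r.ce
    score = Cce * ce + chi2
    return CandidateAlignment(
        ref=ref,
        orientation=orientation or hit.orientation,
        matches=matches,
        chi2=chi2,
        score=score,
        seed=hit,
        q_len=o.m,
    )


def extend_overlap(
    o: ExperimentalMap,
    hit: SeedHit,
    params: AlignParams,
    orientation: str | None = None,
) -> CandidateAlignment | None:
    """Extend a seed until an end of either map is reached on both sides.

    Like :func:`extend_seed` but each side may terminate at the in-silico map
    end (one-sided "lower" match, leaving unaligned query overhang); among
    feasible terminals, lower score wins and ties go to longer alignments.
    """
    anchor = anchor_matches(o, hit)
    if anchor is None:
        return None
    ref = hit.ref
    qa, qb = anchor[0].q_start, anchor[-1].q_end
    ra, rb = anchor[0].r_start, anchor[-1].r_end
    Cce = params.cut_error_weight(o.m)

    (lq, lr, lv, l_end), (rq, rr, rv, r_end) = _side_inputs(o, ref, qa, qb, ra, rb, params)
    left = _extend_side(lq, lr, lv, params, Cce, ref_end_reachable=l_end, stop_at_ref_end=True)
    if not left:
        return None
    right = _extend_side(rq, rr, rv, params, Cce, ref_end_reachable=r_end, stop_at_ref_end=True)
    if not right:
        return None
    best_l = min(left, key=lambda T: (T.score, -T.s, T.nm, -T.t))
    best_r = min(right, key=lambda T: (T.score, -T.s, T.nm, T.t))

    anchor_ce, anchor_chi2 = _anchor_stats(o, ref, anchor)
    matches = (
        _blocks_to_matches(best_l.blocks, qa, ra, "left")
        + _mark_anchor_truncation(o, anchor)
        + _blocks_to_matches(best_r.blocks, qb, rb, "right")
    )
    chi2 = best_l.chi2 + anchor_chi2 + best_r.chi2
    ce = best_l.ce + anchor_ce + best_r.ce
    return CandidateAlignment(
        ref=ref,
        orientation=orientation or hit.orientation,
        matches=matches,
        chi2=chi2,
        score=Cce * ce + chi2,
        seed=hit,
        q_len=o.m,
    )
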