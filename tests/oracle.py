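"""Independent brute-force oracle for seed extension.

Enumerates every valid glocal alignment that contains a fixed anchor, by
recursively listing all ordered partitions of the remaining query fragments
into match blocks (within the per-match band limits), including every
admissible skipped-fragment variant, and reports the optimum.  Written
naively (explicit sums, no prefix arrays, no dynamic programming) so it can
serve as an oracle for the DP engine on small instances.

Conventions mirrored from the aligner's match model:

* a block pairs ``dq`` query fragments (dq <= max false cuts + 1) with
  ``dr`` reference fragments (dr <= max missing cuts + 1);
* skipped reference fragments sit strictly inside a block except at the edge
  facing the anchor, are each at most 2 kbp, in runs of at most 3, and are
  admissible only when the unskipped span is infeasible or the skip at least
  halves its chi^2;
* a block containing the outermost query fragment is one-sided tested
  (upper) and scores no chi^2;
* block cut errors are ``dq - 1 + dr - 1`` regardless of skips.
"""

from __future__ import annotations

import math


def _feasible(dev: float, bound: float, mode: str) -> bool:
    if mode == "two_sided":
        return -bound <= dev <= bound
    if mode == "upper":
        return dev <= bound
    return dev >= -bound


def _runs_ok(gaps: tuple) -> bool:
    run = 1
    for a, b in zip(gaps, gaps[1:]):
        run = run + 1 if b == a + 1 else 1
        if run > 3:
            return False
    return True


def _subsets(positions: list) -> list:
    out = [()]
    for p in positions:
        out += [s + (p,) for s in out]
    return out


def _block_variants(o_sum, r_sizes, r_vars, t0, dr, mode, params):
    """All admissible (scored_chi2,) values for the block t0+1..t0+dr."""
    t = t0 + dr
    span = list(range(t0 + 1, t + 1))
    r_sum = sum(r_sizes[g - 1] for g in span)
    r_var = sum(r_vars[g - 1] for g in span)
    dev = o_sum - r_sum
    incl_feas = _feasible(dev, params.C_sigma * math.sqrt(r_var), mode)
    incl_chi2 = dev * dev / r_var
    variants = []
    if incl_feas:
        variants.append(incl_chi2 if mode == "two_sided" else 0.0)
    candidates = [
        g for g in span[:-1] if r_sizes[g - 1] <= params.small_fragment_bp
    ]
    for G in _subsets(candidates):
        if not G or len(G) > dr - 1 or not _runs_ok(G):
            continue
        v = r_var - sum(r_vars[g - 1] for g in G)
        if v <= 0:
            continue
        d = o_sum - (r_sum - sum(r_sizes[g - 1] for g in G))
        if not _feasible(d, params.C_sigma * math.sqrt(v), mode):
            continue
        chi2_g = d * d / v
        if incl_feas and chi2_g > 0.5 * incl_chi2:
            continue
        variants.append(chi2_g if mode == "two_sided" else 0.0)
    return variants


def side_values(o_seg, r_sizes, r_vars, params):
    """All achievable (cut_errors, chi2, n_matches) triples for one
    extension side, enumerated recursively in extension order."""
    Q = len(o_seg)
    W = len(r_sizes)
    results = []

    def recurse(s, t, ce, chi2, nm):
        if s == Q:
            results.append((ce, chi2, nm))
            return
        for dq in range(1, min(params.max_false_cuts_per_match + 1, Q - s) + 1):
            o_sum = sum(o_seg[s : s + dq])
            mode = "upper" if s + dq == Q else "two_sided"
            for dr in range(1, min(params.max_missing_cuts_per_match + 1, W - t) + 1):
                for chi2_blk in _block_variants(o_sum, r_sizes, r_vars, t, dr, mode, params):
                    recurse(
                        s + dq,
                        t + dr,
                        ce + dq - 1 + dr - 1,
                        chi2 + chi2_blk,
                        nm + 1,
                    )

    recurse(0, 0, 0, 0.0, 0)
    return results


def oracle_extend(o, ref, anchor, params):
    """Optimal (score, cut_errors, chi2) over all glocal alignments that
    contain the fixed anchor matches, or None when none is feasible.

    Also returns the two-stage optimum (min cut errors first, then chi^2)
    for checking the lexicographic-dominance property of the score.
    """
    m = o.m
    Cce = params.cut_error_weight(m)
    qa, qb = anchor[0].q_start, anchor[-1].q_end
    ra, rb = anchor[0].r_start, anchor[-1].r_end

    anchor_ce = 0
    anchor_chi2 = 0.0
    for mt in anchor:
        anchor_ce += (mt.q_end - mt.q_start) + (mt.r_end - mt.r_start)
        o_sum = float(o.fragments[mt.q_start - 1 : mt.q_end].sum())
        r_sum = float(ref.fragments[mt.r_start - 1 : mt.r_end].sum())
        r_var = float((ref.sigmas[mt.r_start - 1 : mt.r_end] ** 2).sum())
        if not (mt.q_start == 1 or mt.q_end == m):
            anchor_chi2 += (o_sum - r_sum) ** 2 / r_var

    o_left = list(o.fragments[: qa - 1][::-1])
    r_left = list(ref.fragments[: ra - 1][::-1])
    v_left = list((ref.sigmas[: ra - 1] ** 2)[::-1])
    o_right = list(o.fragments[qb:])
    r_right = list(ref.fragments[rb:])
    v_right = list((ref.sigmas[rb:] ** 2))

    lefts = side_values(o_left, r_left, v_left, params)
    rights = side_values(o_right, r_right, v_right, params)
    if not lefts or not rights:
        return None

    combos = [
        (
            Cce * (anchor_ce + lc + rc) + anchor_chi2 + lx + rx,
            anchor_ce + lc + rc,
            anchor_chi2 + lx + rx,
        )
        for lc, lx, _ in lefts
        for rc, rx, _ in rights
    ]
    by_score = min(combos, key=lambda v: v[0])
    min_ce = min(v[1] for v in combos)
    two_stage = min((v for v in combos if v[1] == min_ce), key=lambda v: v[2])
    return {"by_score": by_score, "two_stage": (two_stage[1], two_stage[2])}
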