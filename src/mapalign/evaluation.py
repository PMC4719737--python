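"""Scoring of alignment output against simulator truth logs.

An alignment is *correct* when it names the right reference and orientation
and its reference bp interval reciprocally overlaps the true source interval
by at least 50 % (a standard criterion that is insensitive to end
truncation).  Sensitivity is the fraction of simulated maps that are both
reported (significant and unique) and correct; precision is the fraction of
reported alignments that are correct.
"""

from __future__ import annotations

import math

import numpy as np

from .map_model import AlignParams
from .seed_index import PLAIN, Q_PLAIN, SeedIndex
from .simulator import TruthRecord

__all__ = [
    "interval_reciprocal_overlap",
    "alignment_correct",
    "score_glocal",
    "seed_sensitivity",
    "score_overlap",
]


def interval_reciprocal_overlap(a: tuple, b: tuple) -> float:
    """Smaller of the two mutual overlap fractions of two bp intervals."""
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    inter = max(0.0, hi - lo)
    la, lb = a[1] - a[0], b[1] - b[0]
    if la <= 0 or lb <= 0:
        return 0.0
    return min(inter / la, inter / lb)


def alignment_correct(aln, truth: TruthRecord, min_overlap: float = 0.5) -> bool:
    if truth is None:
        return False
    if aln.ref_id != truth.ref_id or aln.orientation != truth.orientation:
        return False
    return (
        interval_reciprocal_overlap(aln.interval_bp(), (truth.start_bp, truth.end_bp))
        >= min_overlap
    )


def score_glocal(results, truths: dict) -> tuple[float, float]:
    """(sensitivity, precision) of a glocal run against truth logs.

    ``truths`` maps map_id to a TruthRecord, or to None for maps that are
    known to be spurious (no true placement exists).  A missing entry is an
    error.  Sensitivity counts correct reported alignments over all maps
    with a true placement; precision counts them over all reported
    alignments (NaN when nothing was reported).
    """
    n_genuine = n_reported = n_correct = 0
    for r in results:
        if r.map.id not in truths:
            raise KeyError(f"no truth record for map {r.map.id!r}")
        t = truths[r.map.id]
        if t is not None:
            n_genuine += 1
        if r.reported:
            n_reported += 1
            if alignment_correct(r.best, t):
                n_correct += 1
    sensitivity = n_correct / n_genuine if n_genuine else math.nan
    precision = n_correct / n_reported if n_reported else math.nan
    return sensitivity, precision


def seed_sensitivity(
    maps,
    truths,
    index: SeedIndex,
    params: AlignParams,
    min_fragments: int = 10,
    variants: str = "composite",
) -> float:
    """Fraction of maps (with >= ``min_fragments`` fragments) for which the
    index lookup finds at least one correct seed.

    A seed is correct when it lies on the truth orientation, names the truth
    reference, and its reference position falls within one fragment of the
    true counterpart of its query position.  With ``variants="plain"`` only
    plain/plain 2-mer hits count, which quantifies the sensitivity gain of
    composite seeding.
    """
    n_eval = n_hit = 0
    for o, t in zip(maps, truths):
        if o.m < min_fragments:
            continue
        n_eval += 1
        query = o if t.orientation == "forward" else o.reverse()
        mi, pos, var, qpos, qvar = index.query_arrays(query, params)
        if mi.size == 0:
            continue
        if variants == "plain":
            keep = (var == PLAIN) & (qvar == Q_PLAIN)
            mi, pos, qpos = mi[keep], pos[keep], qpos[keep]
            if mi.size == 0:
                continue
        lo = np.array([r[0] for r in t.source_frag_ranges])
        hi = np.array([r[1] for r in t.source_frag_ranges])
        ok_ref = np.array([index.refs[k].id == t.ref_id for k in mi])
        correct = (
            ok_ref
            & (pos >= lo[qpos - 1] - 1)
            & (pos <= hi[qpos - 1] + 1)
        )
        if correct.any():
            n_hit += 1
    return n_hit / n_eval if n_eval else math.nan


def score_overlap(
    overlaps_per_map,
    truths: dict,
    scaffold_infos,
    min_overlap: float = 0.5,
) -> tuple[int, float]:
    """(number of correct extensions, precision) of an overlap run.

    An extension is correct when the overlap names a scaffold that truly
    intersects the map's source interval, on the right orientation, the
    reported alignment falls on the true region, and the map's source
    interval genuinely continues past the scaffold end on the reported
    overhang side.  Contained alignments never count as extensions.
    """
    info_by_id = {info.scaffold_id: info for info in scaffold_infos}
    n_reported = n_correct_aln = n_ext = 0
    for ovs in overlaps_per_map:
        for ov in ovs:
            n_reported += 1
            t = truths.get(ov.map.id)
            if t is None:
                continue
            info = info_by_id.get(ov.alignment.ref_id)
            if info is None or t.ref_id != info.ref_id:
                continue
            if ov.alignment.orientation != t.orientation:
                continue
            # reported interval in genome coordinates
            lo_bp, hi_bp = ov.alignment.interval_bp()
            genome_iv = (info.start_bp + lo_bp, info.start_bp + hi_bp)
            true_iv = (
                max(t.start_bp, info.start_bp),
                min(t.end_bp, info.end_bp),
            )
            if interval_reciprocal_overlap(genome_iv, true_iv) < min_overlap:
                continue
            n_correct_aln += 1
            if ov.left_overhang > 0 and t.start_bp < info.start_bp:
                n_ext += 1
            if ov.right_overhang > 0 and t.end_bp > info.end_bp:
                n_ext += 1
    precision = n_correct_aln / n_reported if n_reported else math.nan
    return n_ext, precision
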