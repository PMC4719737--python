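"""Sorted index of continuous-valued composite seeds over reference maps.

For seed order ``c = 2``, every reference position ``j`` with enough
following fragments contributes three 2-tuples to the index:

* ``(r_j, r_j+1)`` — the plain 2-mer (no cut errors absorbed);
* ``(r_j + r_j+1, r_j+2)`` — a merged first element, absorbing one missing
  cut in the experimental map at the first position;
* ``(r_j, r_j+1 + r_j+2)`` — the symmetric merge at the second position.

Entries are sorted by their first element, so a lookup is a binary search
over a conservative size window followed by per-entry verification of both
elements against the seed bound ``C_sigma_seed`` (using the reference-side
standard deviation of each constituent; merged constituents use the root of
the sigma^2 sum).  Query tuples are formed both plain, ``(o_i, o_i+1)``, and
with a merged first element, ``(o_i + o_i+1, o_i+2)``, which absorbs one
false cut in the experimental map.

The index holds forward reference maps only; the pipeline searches the
reverse orientation by querying with the reversed experimental map.
"""

from __future__ import annotations

from collections import defaultdict
from typing import NamedTuple, Sequence

import numpy as np

from .map_model import AlignParams, ExperimentalMap, ReferenceMap

__all__ = ["SeedHit", "SeedIndex", "build_index", "query_seeds", "narrow_seeds"]

PLAIN, MERGE12, MERGE23 = 0, 1, 2
_VARIANT_NAMES = {PLAIN: "plain", MERGE12: "merge12", MERGE23: "merge23"}
Q_PLAIN, Q_MERGED = 0, 1


class SeedHit(NamedTuple):
    """A candidate anchor linking a query position to a reference position."""

    ref: ReferenceMap
    orientation: str  # orientation of the *query* that produced the hit
    r_pos: int        # 1-based reference index of the tuple's first constituent
    q_pos: int        # 1-based query index of the tuple's first constituent
    ref_variant: int  # PLAIN | MERGE12 | MERGE23
    q_variant: int    # Q_PLAIN | Q_MERGED

    @property
    def cut_errors(self) -> int:
        """Cut errors implied by the seed composition itself."""
        return (self.ref_variant != PLAIN) + (self.q_variant != Q_PLAIN)

    @property
    def variant_name(self) -> str:
        q = "plain" if self.q_variant == Q_PLAIN else "merged"
        return f"{_VARIANT_NAMES[self.ref_variant]}/{q}"


class SeedIndex:
    """Composite-seed index over a collection of forward reference maps."""

    def __init__(self, refs: Sequence[ReferenceMap], c: int = 2):
        if c != 2:
            raise ValueError(f"only composite seeds of order c=2 are supported, got c={c}")
        if not refs:
            raise ValueError("cannot index an empty reference collection")
        self.c = c
        self.refs = list(refs)

        e1_parts, e2_parts, s1_parts, s2_parts = [], [], [], []
        mi_parts, pos_parts, var_parts = [], [], []
        for mi, ref in enumerate(self.refs):
            r = ref.fragments
            s2 = ref.sigmas**2
            n = ref.n
            if n < 2:
                continue
            # plain: positions 1..n-1
            e1_parts.append(r[:-1]); e2_parts.append(r[1:])
            s1_parts.append(s2[:-1]); s2_parts.append(s2[1:])
            k = n - 1
            mi_parts.append(np.full(k, mi)); pos_parts.append(np.arange(1, n))
            var_parts.append(np.full(k, PLAIN))
            if n >= 3:
                k = n - 2
                # merge12: (r_j + r_j+1, r_j+2)
                e1_parts.append(r[:-2] + r[1:-1]); e2_parts.append(r[2:])
                s1_parts.append(s2[:-2] + s2[1:-1]); s2_parts.append(s2[2:])
                mi_parts.append(np.full(k, mi)); pos_parts.append(np.arange(1, n - 1))
                var_parts.append(np.full(k, MERGE12))
                # merge23: (r_j, r_j+1 + r_j+2)
                e1_parts.append(r[:-2]); e2_parts.append(r[1:-1] + r[2:])
                s1_parts.append(s2[:-2]); s2_parts.append(s2[1:-1] + s2[2:])
                mi_parts.append(np.full(k, mi)); pos_parts.append(np.arange(1, n - 1))
                var_parts.append(np.full(k, MERGE23))

        e1 = np.concatenate(e1_parts)
        order = np.argsort(e1, kind="stable")
        self.e1 = e1[order]
        self.e2 = np.concatenate(e2_parts)[order]
        self.sd1 = np.sqrt(np.concatenate(s1_parts))[order]
        self.sd2 = np.sqrt(np.concatenate(s2_parts))[order]
        self.map_idx = np.concatenate(mi_parts)[order].astype(np.int32)
        self.r_pos = np.concatenate(pos_parts)[order].astype(np.int32)
        self.variant = np.concatenate(var_parts)[order].astype(np.int8)
        # Affine envelope sd1 <= A + B*e1 over all entries, used for a
        # conservative binary-search window (entries below the median size
        # bound the additive term, entries above bound the relative term).
        split = float(np.median(self.e1))
        below = self.e1 <= split
        self._env_a = float(self.sd1[below].max()) if below.any() else 0.0
        above = ~below
        self._env_b = float((self.sd1[above] / self.e1[above]).max()) if above.any() else 0.0

    def __len__(self) -> int:
        return int(self.e1.size)

    # -- lookup ------------------------------------------------------------

    def _window(self, q1: float, C: float) -> tuple[int, int]:
        """Conservative superset window on the first element.

        Solves ``|q1 - e| <= C * (A + B*e)`` for ``e`` using the index-wide
        envelope ``sd1 <= A + B*e1``; every candidate is then verified with
        its own sigma, so the window only needs to be a superset.
        """
        ca, cb = C * self._env_a, C * self._env_b
        lo = (q1 - ca) / (1.0 + cb)
        hi = (q1 + ca) / (1.0 - cb) if cb < 1.0 else np.inf
        a = int(np.searchsorted(self.e1, lo, side="left"))
        b = int(np.searchsorted(self.e1, hi, side="right"))
        return a, b

    def _query_tuples(self, o: ExperimentalMap):
        f = o.fragments
        tuples = []
        for i in range(1, o.m):  # plain (o_i, o_i+1)
            tuples.append((i, Q_PLAIN, float(f[i - 1]), float(f[i])))
        for i in range(1, o.m - 1):  # merged (o_i + o_i+1, o_i+2)
            tuples.append((i, Q_MERGED, float(f[i - 1] + f[i]), float(f[i + 1])))
        return tuples

    def query_arrays(self, o: ExperimentalMap, params: AlignParams):
        """Vectorized lookup.

        Returns parallel arrays ``(map_idx, r_pos, ref_variant, q_pos,
        q_variant)`` of every entry whose two elements both pass the
        per-element ``C_sigma_seed`` bound for some query tuple.
        """
        C = params.C_sigma_seed
        out = []
        for q_pos, q_var, q1, q2 in self._query_tuples(o):
            a, b = self._window(q1, C)
            if a >= b:
                continue
            ok = np.abs(q1 - self.e1[a:b]) <= C * self.sd1[a:b]
            ok &= np.abs(q2 - self.e2[a:b]) <= C * self.sd2[a:b]
            idx = np.nonzero(ok)[0] + a
            if idx.size:
                out.append(
                    (
                        self.map_idx[idx],
                        self.r_pos[idx],
                        self.variant[idx],
                        np.full(idx.size, q_pos, dtype=np.int32),
                        np.full(idx.size, q_var, dtype=np.int8),
                    )
                )
        if not out:
            empty = np.empty(0, dtype=np.int32)
            return empty, empty, empty.astype(np.int8), empty, empty.astype(np.int8)
        return tuple(np.concatenate(cols) for cols in zip(*out))

    def query_seeds(
        self, o: ExperimentalMap, params: AlignParams, orientation: str = "forward"
    ) -> list[SeedHit]:
        """All seed hits for ``o`` (which must have at least c+1 fragments)."""
        if o.m < self.c + 1:
            return []
        mi, pos, var, qpos, qvar = self.query_arrays(o, params)
        return [
            SeedHit(self.refs[mi[k]], orientation, int(pos[k]), int(qpos[k]), int(var[k]), int(qvar[k]))
            for k in range(mi.size)
        ]


def build_index(refs: Sequence[ReferenceMap], c: int = 2) -> SeedIndex:
    """Build the sorted composite-seed index (only ``c = 2`` is supported)."""
    return SeedIndex(refs, c=c)


def query_seeds(
    o: ExperimentalMap, index: SeedIndex, params: AlignParams, orientation: str = "forward"
) -> list[SeedHit]:
    return index.query_seeds(o, params, orientation)


def narrow_seeds(hits: Sequence[SeedHit], params: AlignParams) -> list[list[SeedHit]]:
    """Narrow raw seed hits to the anchor clusters that will be extended.

    Hits are grouped per reference map and clustered along diagonals
    ``r_pos - q_pos`` (sorted diagonals within ``seed_diag_tol`` of their
    neighbour chain into one cluster, so that missing/false cuts shifting the
    diagonal by a few units stay together).  A cluster is kept when it has
    hits at ``min_seed_support`` distinct query positions — isolated spurious
    hits are dropped, while a true placement is supported by many seeds along
    its diagonal.  Each surviving cluster yields up to
    ``max_anchors_per_cluster`` representative anchors (preferring plain
    seeds near the cluster centre); the extension stage tries them in order
    and keeps the first that extends.
    """
    if not hits:
        return []
    by_ref: dict[int, list[SeedHit]] = defaultdict(list)
    for h in hits:
        by_ref[id(h.ref)].append(h)
    out: list[list[SeedHit]] = []
    for group in by_ref.values():
        group.sort(key=lambda h: (h.r_pos - h.q_pos, h.r_pos, h.q_pos))
        clusters: list[list[SeedHit]] = []
        for h in group:
            d = h.r_pos - h.q_pos
            if clusters and d - (clusters[-1][-1].r_pos - clusters[-1][-1].q_pos) <= params.seed_diag_tol:
                clusters[-1].append(h)
            else:
                clusters.append([h])
        for cl in clusters:
            if len({h.q_pos for h in cl}) < params.min_seed_support:
                continue
            med = sorted(h.q_pos for h in cl)[len(cl) // 2]
            cl.sort(key=lambda h: (h.cut_errors, abs(h.q_pos - med), h.q_pos, h.r_pos))
            reps: list[SeedHit] = []
            seen_q: set[int] = set()
            for h in cl:
                if h.q_pos in seen_q:
                    continue
                reps.append(h)
                seen_q.add(h.q_pos)
                if len(reps) >= params.max_anchors_per_cluster:
                    break
            out.append(reps)
    return out
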