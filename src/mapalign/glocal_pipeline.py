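"""End-to-end glocal alignment: seeds -> extensions -> candidate population
-> statistical call, per experimental map.

Both strands of the in-silico maps are searched by querying the index with
the experimental map and with its reversal (equivalent to indexing both
strands, at half the index size).  All successful seed extensions form the
candidate population used by the statistical evaluation; q-values are
assigned across maps within fragment-count strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import stats_eval
from .dp_align import CandidateAlignment, extend_seed
from .map_model import AlignParams, ExperimentalMap
from .seed_index import SeedIndex, narrow_seeds
from .stats_eval import NON_SIGNIFICANT, CandidateEvaluation

__all__ = ["GlocalResult", "find_candidates", "align_map", "align_run", "align_glocal"]

REPORT_COLUMNS = [
    "map_id",
    "ref_id",
    "orientation",
    "r_start",
    "r_end",
    "n_matches",
    "missing_cuts",
    "false_cuts",
    "missing_fragments",
    "chi2",
    "wht",
    "vartheta",
    "p_value",
    "q_value",
    "n_candidates",
    "status",
]


@dataclass
class GlocalResult:
    """Per-map alignment outcome: the candidate population and the best call."""

    map: ExperimentalMap
    candidates: list[CandidateAlignment] = field(default_factory=list)
    pvals: np.ndarray | None = None
    varthetas: np.ndarray | None = None
    best: CandidateAlignment | None = None
    evaluation: CandidateEvaluation | None = None
    reason: str | None = None  # set when no call could be made

    @property
    def reported(self) -> bool:
        return (
            self.evaluation is not None
            and self.evaluation.status == stats_eval.SIGNIFICANT_UNIQUE
        )

    def row(self) -> dict:
        """Report row (column order of REPORT_COLUMNS)."""
        if self.best is None:
            return {
                "map_id": self.map.id,
                "ref_id": "NA",
                "orientation": "NA",
                "r_start": 0,
                "r_end": 0,
                "n_matches": 0,
                "missing_cuts": 0,
                "false_cuts": 0,
                "missing_fragments": 0,
                "chi2": float("nan"),
                "wht": float("nan"),
                "vartheta": float("nan"),
                "p_value": float("nan"),
                "q_value": float("nan"),
                "n_candidates": len(self.candidates),
                "status": self.reason or "no_feasible_alignment",
            }
        b = self.best
        ev = self.evaluation
        return {
            "map_id": self.map.id,
            "ref_id": b.ref_id,
            "orientation": b.orientation,
            "r_start": b.r_start,
            "r_end": b.r_end,
            "n_matches": b.n_matches,
            "missing_cuts": b.missing_cuts,
            "false_cuts": b.false_cuts,
            "missing_fragments": b.missing_fragments,
            "chi2": b.chi2,
            "wht": stats_eval.wht(b.chi2, b.n_matches),
            "vartheta": ev.vartheta if ev else float("nan"),
            "p_value": ev.p_value if ev else float("nan"),
            "q_value": ev.q_value if ev is not None and ev.q_value is not None else float("nan"),
            "n_candidates": len(self.candidates),
            "status": ev.status if ev else "unevaluated",
        }


def find_candidates(
    o: ExperimentalMap, index: SeedIndex, params: AlignParams
) -> list[CandidateAlignment]:
    """Deduplicated successful extensions of all narrowed seed hits, over
    both query orientations."""
    cands: dict = {}
    for orientation, query in (("forward", o), ("reverse", o.reverse())):
        hits = index.query_seeds(query, params, orientation)
        for cluster in narrow_seeds(hits, params):
            for anchor in cluster:
                aln = extend_seed(query, anchor, params, orientation=orientation)
                if aln is not None:
                    cands.setdefault(aln.key(), aln)
                    break  # one extension per anchor cluster
    return list(cands.values())


def align_map(o: ExperimentalMap, index: SeedIndex, params: AlignParams) -> GlocalResult:
    """Candidate population and per-map p-values (q-values are assigned at
    run level by :func:`align_run`)."""
    if o.m < index.c + 1:
        return GlocalResult(map=o, reason="too_few_fragments")
    cands = find_candidates(o, index, params)
    if not cands:
        return GlocalResult(map=o, reason="no_feasible_alignment")
    if len(cands) < 2:
        # a single candidate cannot be standardized against a population
        ev = CandidateEvaluation(
            vartheta=float("nan"),
            p_value=float("nan"),
            q_value=float("nan"),
            status=NON_SIGNIFICANT,
            n_candidates=1,
            low_population=True,
        )
        return GlocalResult(map=o, candidates=cands, best=cands[0], evaluation=ev)
    varthetas, pvals = stats_eval.evaluate_population(cands)
    k = int(np.argmin(pvals))
    return GlocalResult(
        map=o, candidates=cands, pvals=pvals, varthetas=varthetas, best=cands[k]
    )


def align_run(
    maps, index: SeedIndex, params: AlignParams, qvalue_method: str = "bh"
) -> list[GlocalResult]:
    """Align a collection of maps and assign q-values within fragment-count
    strata (bins of two fragments, merged to at least 50 maps)."""
    results = [align_map(o, index, params) for o in maps]
    callable_idx = [i for i, r in enumerate(results) if r.pvals is not None]
    if callable_idx:
        m_values = [results[i].map.m for i in callable_idx]
        # selection-corrected best p per map: the raw best p is a minimum
        # over the map's candidate population
        best_p = np.array(
            [
                stats_eval.selection_adjusted_p(
                    results[i].pvals.min(), len(results[i].candidates)
                )
                for i in callable_idx
            ]
        )
        qfun = stats_eval.storey_qvalues if qvalue_method == "storey" else stats_eval.bh_qvalues
        for stratum in stats_eval.build_strata(m_values):
            q = qfun(best_p[stratum])
            for pos, qv in zip(stratum, q):
                i = callable_idx[int(pos)]
                r = results[i]
                r.evaluation = stats_eval.assess(
                    r.best, r.candidates, r.pvals, r.varthetas, float(qv), params
                )
    return results


def align_glocal(o: ExperimentalMap, index: SeedIndex, params: AlignParams) -> GlocalResult:
    """Align a single map.

    With no comparable maps available the q-value falls back to the map's own
    best p-value (a single-element global population); run-level alignment
    via :func:`align_run` is preferred whenever several maps are available.
    """
    result = align_run([o], index, params)[0]
    return result
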