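"""Benchmark map simulation with the optical-mapping error process.

Experimental maps are generated from a reference map by sampling a molecule
at a uniformly random start (with truncated end fragments), then applying the
error pipeline in order:

1. each true internal cut is dropped independently with probability ``1 - d``
   (Binomial missing cuts; ``d`` is the enzyme digestion rate);
2. false cuts are added as a Poisson process with rate ``f100`` per 100 kbp,
   rejecting placements that would create fragments below 1.2 kbp;
3. small fragments are removed with size-dependent probabilities (the
   fragment disappears and its two flanking cuts collapse into one — the
   neighbouring fragments stay separate);
4. per-fragment sizing error is drawn from a size-range-dependent Gaussian
   relative-error model truncated at +-3 SD;
5. maps smaller than 150 kbp or with fewer than ten fragments are discarded,
   mimicking instrument pre-processing.

Two standard scenarios bracket the observed quality range of optical mapping
runs: the easier scenario (d=0.78, f100=0.97) and the harder scenario
(d=0.61, f100=1.38), with their respective missing-fragment probability
tables.  Every map comes with a truth record (source interval, orientation,
per-cut and per-fragment provenance) so that error rates can be re-estimated
and alignments scored against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .map_model import ExperimentalMap, ReferenceMap, SigmaModel

__all__ = [
    "ScenarioParams",
    "TruthRecord",
    "synth_reference",
    "simulate_map",
    "simulate_maps",
    "spurious_map",
    "simulate_assembly",
    "estimate_rates",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class ScenarioParams:
    """Error-model parameters for one simulation scenario.

    ``missing_fragment_probs`` is an ascending (threshold_bp, probability)
    table: a fragment of size s is dropped with the probability of the first
    threshold with s < threshold.  ``sizing_sd`` maps reference size ranges
    to the relative SD of the Gaussian sizing error.
    """

    d: float = 0.78
    f100: float = 0.97
    missing_fragment_probs: tuple = ((350.0, 1.0), (600.0, 0.75), (1200.0, 0.5))
    sizing_sd: tuple = ((2000.0, 0.15), (10000.0, 0.08), (math.inf, 0.05))
    sizing_trunc_sd: float = 3.0
    false_cut_min_bp: float = 1200.0
    min_map_bp: float = 150000.0
    min_map_fragments: int = 10
    mean_fragments: float = 17.0
    nb_r: float = 8.0
    flip_prob: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.d <= 1.0):
            raise ValueError("digestion rate d must be in (0, 1]")
        if self.f100 < 0:
            raise ValueError("false-cut rate f100 must be >= 0")
        thresholds = [t for t, _ in self.missing_fragment_probs]
        if thresholds != sorted(thresholds):
            raise ValueError("missing-fragment thresholds must be ascending")
        if any(not (0.0 <= p <= 1.0) for _, p in self.missing_fragment_probs):
            raise ValueError("missing-fragment probabilities must be in [0, 1]")

    @classmethod
    def easier(cls) -> "ScenarioParams":
        """High-quality run: d=0.78, f100=0.97, drop <1.2 kbp @0.5 /
        <600 bp @0.75 / <350 bp @1."""
        return cls()

    # scenario aliases matching common usage
    scenario_a = easier

    @classmethod
    def harder(cls) -> "ScenarioParams":
        """Typical-quality run: d=0.61, f100=1.38, drop <2 kbp @0.5 /
        <800 bp @0.75 / <350 bp @1."""
        return cls(
            d=0.61,
            f100=1.38,
            missing_fragment_probs=((350.0, 1.0), (800.0, 0.75), (2000.0, 0.5)),
        )

    scenario_b = harder

    @classmethod
    def identity(cls) -> "ScenarioParams":
        """Error-free scenario (useful for tests): the output equals the
        extracted sub-map exactly, up to the end-truncation of the molecule."""
        return cls(
            d=1.0,
            f100=0.0,
            missing_fragment_probs=(),
            sizing_sd=((math.inf, 0.0),),
            flip_prob=0.0,
        )

    def drop_prob(self, size: float) -> float:
        for threshold, p in self.missing_fragment_probs:
            if size < threshold:
                return p
        return 0.0

    def sizing_sd_for(self, size: float) -> float:
        for threshold, sd in self.sizing_sd:
            if size < threshold:
                return sd
        return self.sizing_sd[-1][1]


@dataclass
class TruthRecord:
    """Ground truth for one simulated map.

    ``source_frag_ranges`` gives, for each emitted fragment *in source order*
    (i.e. before the optional orientation flip), the 1-based inclusive range
    of forward reference fragments it overlaps.
    """

    map_id: str
    ref_id: str
    orientation: str
    start_bp: float
    end_bp: float
    n_true_internal_cuts: int
    kept_cut_idx: tuple
    false_cut_positions: tuple
    dropped_fragment_sizes: tuple
    source_frag_ranges: tuple  # ((lo, hi), ...) per emitted fragment

    @property
    def molecule_bp(self) -> float:
        return self.end_bp - self.start_bp


def synth_reference(
    n_fragments: int,
    mean_bp: float,
    seed,
    sigma_model: SigmaModel | None = None,
    min_fragment_bp: float = 100.0,
    id: str = "synthref",
) -> ReferenceMap:
    """Synthetic reference map with i.i.d. exponential fragment sizes.

    An exponential size distribution is the standard stand-in for the
    spacing of a fixed recognition pattern along a genome; sizes are floored
    at ``min_fragment_bp``.
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    rng = np.random.default_rng(seed)
    frags = np.maximum(min_fragment_bp, rng.exponential(mean_bp, size=n_fragments))
    return ReferenceMap.from_fragments(id, frags, sigma_model)


def _sample_fragment_count(scenario: ScenarioParams, rng) -> int:
    # shifted negative binomial with the scenario's mean fragment count
    mean_nb = scenario.mean_fragments - 1.0
    r = scenario.nb_r
    p = r / (r + mean_nb)
    return 1 + int(rng.negative_binomial(r, p))


def simulate_map(
    ref: ReferenceMap,
    scenario: ScenarioParams,
    rng,
    map_id: str = "sim",
) -> tuple[ExperimentalMap, TruthRecord] | None:
    """Simulate one experimental map from ``ref``; None when the result is
    discarded by the size/fragment-count filter (or no placement fits)."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    cum = ref.prefix_sums
    n = ref.n
    L = float(cum[-1])
    k = max(2, _sample_fragment_count(scenario, rng))

    j0 = None
    for _ in range(50):
        s0 = float(rng.uniform(0.0, L))
        j = int(np.searchsorted(cum, s0, side="right")) - 1
        if j + k <= n:
            j0 = j
            break
    if j0 is None:
        return None
    # molecule = truncated fragment j0, full fragments, truncated fragment j0+k-1
    u = float(rng.uniform(0.02, 1.0))
    e0 = float(cum[j0 + k - 1] + u * (cum[j0 + k] - cum[j0 + k - 1]))

    # 1. missing cuts: internal true cuts are the k-1 boundaries cum[j0+1..j0+k-1]
    keep = rng.random(k - 1) < scenario.d
    kept_idx = tuple(int(j0 + 1 + i) for i in np.nonzero(keep)[0])
    cut_positions = [float(cum[i]) for i in kept_idx]

    # 2. false cuts (Poisson per 100 kbp, avoiding small fragments)
    mol_len = e0 - s0
    n_fc = int(rng.poisson(scenario.f100 * mol_len / 1e5))
    false_positions = []
    boundaries = sorted([s0, e0] + cut_positions)
    for _ in range(n_fc):
        for _ in range(100):
            pos = float(rng.uniform(s0, e0))
            i = int(np.searchsorted(boundaries, pos))
            if i == 0 or i == len(boundaries):
                continue
            if (
                pos - boundaries[i - 1] >= scenario.false_cut_min_bp
                and boundaries[i] - pos >= scenario.false_cut_min_bp
            ):
                false_positions.append(pos)
                boundaries.insert(i, pos)
                break

    # fragments between consecutive boundaries, each with its ref interval
    frags = [
        (boundaries[i], boundaries[i + 1]) for i in range(len(boundaries) - 1)
    ]

    # 3. missing small fragments (fragment disappears; flanking cuts collapse)
    kept_frags = []
    dropped_sizes = []
    for lo, hi in frags:
        size = hi - lo
        p = scenario.drop_prob(size)
        if p > 0 and rng.random() < p:
            dropped_sizes.append(size)
        else:
            kept_frags.append((lo, hi))
    if not kept_frags:
        return None

    # 4. sizing errors (truncated Gaussian relative error by true size range)
    sizes = []
    ranges = []
    for lo, hi in kept_frags:
        size = hi - lo
        sd = scenario.sizing_sd_for(size)
        if sd > 0:
            t = scenario.sizing_trunc_sd
            eps = float(np.clip(rng.normal(0.0, sd), -t * sd, t * sd))
        else:
            eps = 0.0
        sizes.append(max(1.0, size * (1.0 + eps)))
        lo_idx = int(np.searchsorted(cum, lo, side="right"))      # 1-based
        hi_idx = int(np.searchsorted(cum, hi, side="left"))       # 1-based
        ranges.append((lo_idx, min(hi_idx, n)))

    # 5. instrument filter
    if len(sizes) < scenario.min_map_fragments or sum(sizes) < scenario.min_map_bp:
        return None

    orientation = "reverse" if rng.random() < scenario.flip_prob else "forward"
    emitted = sizes[::-1] if orientation == "reverse" else sizes
    exp_map = ExperimentalMap(map_id, np.asarray(emitted))
    truth = TruthRecord(
        map_id=map_id,
        ref_id=ref.id,
        orientation=orientation,
        start_bp=s0,
        end_bp=e0,
        n_true_internal_cuts=k - 1,
        kept_cut_idx=kept_idx,
        false_cut_positions=tuple(false_positions),
        dropped_fragment_sizes=tuple(dropped_sizes),
        source_frag_ranges=tuple(ranges),
    )
    return exp_map, truth


def simulate_maps(
    ref: ReferenceMap,
    scenario: ScenarioParams,
    n: int,
    seed,
    id_prefix: str = "sim",
):
    """Simulate ``n`` maps passing the filter; returns (maps, truths)."""
    rng = np.random.default_rng(seed)
    maps, truths = [], []
    attempts = 0
    max_attempts = 200 * n + 1000
    while len(maps) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not simulate {n} maps passing the filter in {max_attempts} attempts"
            )
        out = simulate_map(ref, scenario, rng, map_id=f"{id_prefix}_{len(maps)}")
        if out is not None:
            maps.append(out[0])
            truths.append(out[1])
    return maps, truths


def spurious_map(
    scenario: ScenarioParams,
    mean_fragment_bp: float,
    rng,
    map_id: str = "rand",
) -> ExperimentalMap:
    """A random map unrelated to any reference (i.i.d. exponential fragment
    sizes, same length distribution and instrument filter as simulated maps)."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    for _ in range(1000):
        k = max(2, _sample_fragment_count(scenario, rng))
        sizes = np.maximum(100.0, rng.exponential(mean_fragment_bp, size=k))
        if k >= scenario.min_map_fragments and sizes.sum() >= scenario.min_map_bp:
            return ExperimentalMap(map_id, sizes)
    raise RuntimeError("could not draw a spurious map passing the filter")


@dataclass(frozen=True)
class ScaffoldInfo:
    scaffold_id: str
    ref_id: str
    start_bp: float
    end_bp: float


def simulate_assembly(
    ref: ReferenceMap,
    seed,
    n50_target_bp: float = 500000.0,
    log_sigma: float = 0.8,
    min_non_end_fragments: int = 4,
    sigma_model: SigmaModel | None = None,
):
    """Partition a reference into scaffold-sized in-silico maps.

    Scaffold sizes are log-normal with the length-weighted median (the N50 of
    a large sample) at ``n50_target_bp``; boundaries fall at arbitrary bp so
    scaffold end fragments are truncated.  Scaffolds with fewer than
    ``min_non_end_fragments`` non-end fragments are dropped, since such maps
    cannot be confidently aligned.  Returns (scaffold maps, ScaffoldInfo
    list); the info list covers the whole partition before filtering.
    """
    rng = np.random.default_rng(seed)
    mu = math.log(n50_target_bp) - log_sigma**2
    cum = ref.prefix_sums
    L = float(cum[-1])
    bounds = [0.0]
    while bounds[-1] < L:
        bounds.append(bounds[-1] + float(rng.lognormal(mu, log_sigma)))
    bounds[-1] = L
    scaffolds, infos = [], []
    for si in range(len(bounds) - 1):
        a, b = bounds[si], bounds[si + 1]
        lo = int(np.searchsorted(cum, a, side="right"))  # 1-based first fragment
        hi = int(np.searchsorted(cum, b, side="left"))   # 1-based last fragment
        hi = min(hi, ref.n)
        if hi < lo:
            continue
        sizes = ref.fragments[lo - 1 : hi].copy()
        sizes[0] = float(cum[lo]) - a
        sizes[-1] = b - float(cum[hi - 1])
        if sizes[0] <= 0 or sizes[-1] <= 0:
            sizes = sizes[sizes > 0]
        info = ScaffoldInfo(f"{ref.id}_scf{si}", ref.id, a, b)
        infos.append(info)
        if len(sizes) - 2 < min_non_end_fragments:
            continue
        scaffolds.append(
            ReferenceMap.from_fragments(info.scaffold_id, sizes, sigma_model)
        )
    return scaffolds, infos


def estimate_rates(truths) -> dict:
    """Re-estimate error-model parameters from truth logs.

    Returns digestion rate ``d`` (fraction of true internal cuts retained,
    with its binomial standard error) and false-cut rate ``f100`` (placed
    false cuts per 100 kbp of molecule, with a Poisson standard error).
    """
    kept = sum(len(t.kept_cut_idx) for t in truths)
    total = sum(t.n_true_internal_cuts for t in truths)
    fc = sum(len(t.false_cut_positions) for t in truths)
    mol = sum(t.molecule_bp for t in truths)
    d_hat = kept / total if total else math.nan
    d_se = math.sqrt(d_hat * (1 - d_hat) / total) if total else math.nan
    f100_hat = fc / (mol / 1e5) if mol else math.nan
    f100_se = math.sqrt(fc) / (mol / 1e5) if mol and fc else math.nan
    return {
        "d": d_hat,
        "d_se": d_se,
        "f100": f100_hat,
        "f100_se": f100_se,
        "n_true_cuts": total,
        "n_false_cuts": fc,
        "molecule_bp": mol,
    }


# ---------------------------------------------------------------------------
# truth-log TSV
# ---------------------------------------------------------------------------

_TRUTH_HEADER = (
    "map_id\tref_id\torientation\tstart_bp\tend_bp\tn_true_internal_cuts\t"
    "kept_cut_idx\tfalse_cut_positions\tdropped_fragment_sizes\tsource_frag_ranges\n"
)


def write_truth(truths, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_TRUTH_HEADER)
        for t in truths:
            ranges = ";".join(f"{lo}-{hi}" for lo, hi in t.source_frag_ranges)
            fh.write(
                f"{t.map_id}\t{t.ref_id}\t{t.orientation}\t{t.start_bp:.1f}\t"
                f"{t.end_bp:.1f}\t{t.n_true_internal_cuts}\t"
                f"{','.join(str(i) for i in t.kept_cut_idx)}\t"
                f"{','.join(f'{p:.1f}' for p in t.false_cut_positions)}\t"
                f"{','.join(f'{s:.1f}' for s in t.dropped_fragment_sizes)}\t"
                f"{ranges}\n"
            )


def read_truth(path: str | Path) -> list[TruthRecord]:
    truths = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("map_id"):
            raise ValueError(f"{path}: not a truth log")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            truths.append(
                TruthRecord(
                    map_id=f[0],
                    ref_id=f[1],
                    orientation=f[2],
                    start_bp=float(f[3]),
                    end_bp=float(f[4]),
                    n_true_internal_cuts=int(f[5]),
                    kept_cut_idx=tuple(int(x) for x in f[6].split(",") if x),
                    false_cut_positions=tuple(float(x) for x in f[7].split(",") if x),
                    dropped_fragment_sizes=tuple(float(x) for x in f[8].split(",") if x),
                    source_frag_ranges=tuple(
                        tuple(int(v) for v in pair.split("-"))
                        for pair in f[9].split(";")
                        if pair
                    ),
                )
            )
    return truths
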