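"""Core data types for genomic (optical) maps and in-silico reference maps.

A genomic map (Rmap) is an ordered list of fragment sizes, in base pairs,
between consecutive recognition-site cuts on a single DNA molecule.  An
in-silico map is the same representation derived from sequence, and carries a
per-fragment sizing standard deviation ``sigma_j`` used by all feasibility
tests.  This module also implements the feasibility test at the heart of the
aligner: a block of experimental fragments matches a block of reference
fragments when their size sums agree within ``C_sigma`` reference standard
deviations,

    | sum(o_i) - sum(r_j) | <= C_sigma * sqrt(sum(sigma_j^2)),

with one-sided relaxations for truncated map ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MapFormatError",
    "DegenerateVarianceError",
    "SigmaModel",
    "ExperimentalMap",
    "ReferenceMap",
    "Match",
    "AlignParams",
    "read_maps",
    "write_maps",
    "read_reference_maps",
    "range_stats",
    "feasible",
    "reverse_map",
]


class MapFormatError(ValueError):
    """Raised for malformed or invalid map files."""


class DegenerateVarianceError(ValueError):
    """Raised when a feasibility test is attempted with zero variance."""


@dataclass(frozen=True)
class SigmaModel:
    """Sizing-error model for in-silico fragments.

    The standard deviation assigned to a reference fragment of size ``r`` is
    ``max(sigma_min, rho * r)``: a relative error with a floor, reproducing
    the size-dependent error structure of optical mapping data (small
    fragments are dominated by a fixed measurement floor, large fragments by
    a relative sizing error).
    """

    rho: float = 0.05
    sigma_min: float = 300.0

    def sigma(self, sizes: np.ndarray | float) -> np.ndarray | float:
        return np.maximum(self.sigma_min, self.rho * np.asarray(sizes, dtype=float))


def _as_fragment_array(fragments: Sequence[float], what: str) -> np.ndarray:
    arr = np.asarray(fragments, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise MapFormatError(f"{what}: fragment list must be a non-empty 1-d sequence")
    if not np.all(arr > 0):
        raise MapFormatError(f"{what}: all fragment sizes must be > 0")
    return arr


@dataclass
class ExperimentalMap:
    """An experimental map: ordered positive fragment sizes in bp."""

    id: str
    fragments: np.ndarray

    def __post_init__(self) -> None:
        self.fragments = _as_fragment_array(self.fragments, f"map {self.id!r}")

    @property
    def m(self) -> int:
        return int(self.fragments.size)

    @property
    def size(self) -> float:
        return float(self.fragments.sum())

    def reverse(self) -> "ExperimentalMap":
        return ExperimentalMap(self.id, self.fragments[::-1].copy())


@dataclass
class ReferenceMap:
    """An in-silico map with per-fragment standard deviations and prefix sums.

    ``prefix_sums[j]`` holds the cumulative size of fragments ``1..j`` (with a
    leading zero), and ``prefix_var[j]`` the cumulative ``sigma^2``; both make
    block sums for the feasibility test O(1).
    """

    id: str
    fragments: np.ndarray
    sigmas: np.ndarray
    orientation: str = "forward"
    prefix_sums: np.ndarray = field(init=False, repr=False)
    prefix_var: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.fragments = _as_fragment_array(self.fragments, f"reference {self.id!r}")
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if self.sigmas.shape != self.fragments.shape:
            raise MapFormatError(f"reference {self.id!r}: sigmas must align 1:1 with fragments")
        if not np.all(self.sigmas >= 0):
            raise MapFormatError(f"reference {self.id!r}: sigmas must be >= 0")
        if self.orientation not in ("forward", "reverse"):
            raise MapFormatError(f"reference {self.id!r}: bad orientation {self.orientation!r}")
        self.prefix_sums = np.concatenate(([0.0], np.cumsum(self.fragments)))
        self.prefix_var = np.concatenate(([0.0], np.cumsum(self.sigmas**2)))

    @classmethod
    def from_fragments(
        cls,
        id: str,
        fragments: Sequence[float],
        sigma_model: SigmaModel | None = None,
        orientation: str = "forward",
    ) -> "ReferenceMap":
        sigma_model = sigma_model or SigmaModel()
        frags = _as_fragment_array(fragments, f"reference {id!r}")
        return cls(id, frags, sigma_model.sigma(frags), orientation)

    @property
    def n(self) -> int:
        return int(self.fragments.size)

    @property
    def size(self) -> float:
        return float(self.prefix_sums[-1])

    def reverse(self) -> "ReferenceMap":
        flipped = "reverse" if self.orientation == "forward" else "forward"
        return ReferenceMap(self.id, self.fragments[::-1].copy(), self.sigmas[::-1].copy(), flipped)

    def interval_bp(self, r_start: int, r_end: int) -> tuple[float, float]:
        """bp interval (0-based, half open) spanned by fragments r_start..r_end (1-based)."""
        return float(self.prefix_sums[r_start - 1]), float(self.prefix_sums[r_end])


@dataclass(frozen=True)
class Match:
    """One feasible match: a block of query fragments against a block of
    reference fragments, with optional skipped (missing) reference fragments.

    Indices are 1-based and inclusive.  ``gap_fragments`` are reference
    indices inside ``[r_start, r_end]`` treated as missing small fragments.
    A ``truncated`` match is one-sided tested and may only sit at an
    alignment end ("left"/"right"); interior matches are two-sided.
    """

    q_start: int
    q_end: int
    r_start: int
    r_end: int
    gap_fragments: tuple[int, ...] = ()
    truncated: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.q_start <= self.q_end):
            raise ValueError("invalid query range")
        if not (1 <= self.r_start <= self.r_end):
            raise ValueError("invalid reference range")
        if any(g < self.r_start or g > self.r_end for g in self.gap_fragments):
            raise ValueError("gap fragments must lie inside the reference range")
        if self.truncated not in (None, "left", "right"):
            raise ValueError("truncated must be None, 'left' or 'right'")

    @property
    def false_cuts(self) -> int:
        return self.q_end - self.q_start

    @property
    def missing_cuts(self) -> int:
        return self.r_end - self.r_start - len(self.gap_fragments)

    @property
    def missing_fragments(self) -> int:
        return len(self.gap_fragments)


@dataclass
class AlignParams:
    """Alignment parameters.

    Defaults reproduce the method's standard settings: feasibility bound
    ``C_sigma = 3`` (appropriate when sizing errors are roughly normal), a
    stricter seed bound ``C_sigma_seed = 2``, composite seeds of order
    ``c = 2``, per-match band limits of 5 consecutive false cuts and 8
    consecutive missing cuts, early-stop count ``f_min_feasible = 5``, a
    2 kbp detection limit for skippable in-silico fragments, FDR level
    ``q_threshold = 0.01``, best/next-best uniqueness ratio 5, and a
    12-fragment sliding window for overlap alignment.
    """

    C_sigma: float = 3.0
    C_sigma_seed: float = 2.0
    c: int = 2
    max_missing_cuts_per_match: int = 8
    max_false_cuts_per_match: int = 5
    f_min_feasible: int = 5
    small_fragment_bp: float = 2000.0
    q_threshold: float = 0.01
    uniqueness_ratio: float = 5.0
    window_l: int = 12
    # seed narrowing (anchor selection before extension)
    min_seed_support: int = 2
    seed_diag_tol: int = 2
    max_anchors_per_cluster: int = 3

    def __post_init__(self) -> None:
        numeric = (
            self.C_sigma,
            self.C_sigma_seed,
            self.c,
            self.max_missing_cuts_per_match,
            self.max_false_cuts_per_match,
            self.f_min_feasible,
            self.small_fragment_bp,
            self.q_threshold,
            self.uniqueness_ratio,
            self.window_l,
        )
        if not all(v > 0 for v in numeric):
            raise ValueError("all alignment parameters must be positive")
        if self.C_sigma_seed > self.C_sigma:
            raise ValueError("C_sigma_seed must not exceed C_sigma")

    def cut_error_weight(self, m: int) -> float:
        """Cut-error weight dominating any achievable total chi^2.

        Each feasible match contributes chi^2 <= C_sigma^2 and an alignment of
        an m-fragment map has at most m matches, so ``C_sigma^2 * m + 1``
        makes score minimization exactly lexicographic in
        (cut errors, chi^2).
        """
        return self.C_sigma**2 * m + 1.0


def range_stats(
    ref: ReferenceMap, l: int, t: int, gaps: Iterable[int] = ()
) -> tuple[float, float]:
    """Sum of fragment sizes and of sigma^2 over reference fragments l..t
    (1-based inclusive), excluding ``gaps``."""
    if not (1 <= l <= t <= ref.n):
        raise IndexError(f"fragment range [{l}, {t}] out of bounds for n={ref.n}")
    total = float(ref.prefix_sums[t] - ref.prefix_sums[l - 1])
    var = float(ref.prefix_var[t] - ref.prefix_var[l - 1])
    for g in gaps:
        if g < l or g > t:
            raise IndexError(f"gap index {g} outside range [{l}, {t}]")
        total -= float(ref.fragments[g - 1])
        var -= float(ref.sigmas[g - 1] ** 2)
    return total, var


def feasible(o_sum: float, r_sum: float, r_var: float, C: float, mode: str = "two_sided") -> bool:
    """Size-sum feasibility test between an experimental block and a
    reference block.

    ``two_sided`` is the standard test; ``upper`` caps only the positive
    excess of the experimental sum (truncated experimental end fragment, which
    can only make the observed sum smaller); ``lower`` caps only the deficit
    (truncated in-silico end, where the reference block understates the true
    genomic fragment).
    """
    if r_var <= 0:
        raise DegenerateVarianceError("reference variance must be > 0 for feasibility test")
    bound = C * np.sqrt(r_var)
    dev = o_sum - r_sum
    if mode == "two_sided":
        return bool(abs(dev) <= bound)
    if mode == "upper":
        return bool(dev <= bound)
    if mode == "lower":
        return bool(dev >= -bound)
    raise ValueError(f"unknown feasibility mode {mode!r}")


def reverse_map(m):
    """Reversed copy of an experimental or reference map (involution)."""
    return m.reverse()


# ---------------------------------------------------------------------------
# om-tsv I/O: one map per line, `map_id<TAB>num_fragments<TAB>size,size,...`
# ---------------------------------------------------------------------------

def _parse_line(line: str, lineno: int) -> ExperimentalMap:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 3:
        raise MapFormatError(f"line {lineno}: expected 3 tab-separated fields, got {len(parts)}")
    map_id, count_s, frag_s = parts
    try:
        count = int(count_s)
    except ValueError as exc:
        raise MapFormatError(f"line {lineno}: fragment count {count_s!r} is not an integer") from exc
    try:
        frags = [float(x) for x in frag_s.split(",")] if frag_s else []
    except ValueError as exc:
        raise MapFormatError(f"line {lineno}: unparseable fragment size") from exc
    if len(frags) != count:
        raise MapFormatError(
            f"line {lineno}: declared {count} fragments but found {len(frags)}"
        )
    if any(f <= 0 for f in frags):
        raise MapFormatError(f"line {lineno}: non-positive fragment size")
    return ExperimentalMap(map_id, np.asarray(frags, dtype=float))


def read_maps(path: str | Path) -> list[ExperimentalMap]:
    """Read experimental maps from an om-tsv file."""
    maps = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            maps.append(_parse_line(line, lineno))
    return maps


def _format_size(x: float) -> str:
    s = f"{x:.1f}"
    return s[:-2] if s.endswith(".0") else s


def write_maps(maps: Iterable[ExperimentalMap | ReferenceMap], path: str | Path) -> None:
    """Write maps in om-tsv (fragment sizes with at most one decimal place)."""
    with open(path, "w", encoding="utf-8") as fh:
        for m in maps:
            frags = ",".join(_format_size(f) for f in m.fragments)
            fh.write(f"{m.id}\t{m.fragments.size}\t{frags}\n")


def read_reference_maps(
    path: str | Path, sigma_model: SigmaModel | None = None
) -> list[ReferenceMap]:
    """Read reference maps from om-tsv, deriving sigmas from ``sigma_model``."""
    sigma_model = sigma_model or SigmaModel()
    return [
        ReferenceMap.from_fragments(m.id, m.fragments, sigma_model)
        for m in read_maps(path)
    ]
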