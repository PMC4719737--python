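"""In-silico restriction digestion of FASTA sequences into reference maps.

A recognition site such as KpnI ``GGTAC^C`` (the caret marks the cut
position) is located on the forward strand of each sequence; successive cut
positions define the in-silico fragment sizes.  For palindromic sites both
strands yield the same cut positions, so a single forward scan suffices.
Ambiguous bases in the sequence (N and friends) never match the pattern,
which avoids phantom cuts inside assembly gaps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .map_model import ReferenceMap, SigmaModel

__all__ = ["RecognitionSite", "DigestError", "digest", "digest_collection", "KPNI"]

# IUPAC nucleotide codes -> the set of concrete bases a *pattern* character
# matches.  Sequence characters outside the expanded set (including N) do not
# match, so ambiguity in the sequence never produces a cut.
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_SEQ_ALPHABET = set("ACGTURYSWKMBDHVN")


class DigestError(ValueError):
    """Raised for invalid sequences or recognition sites."""


@dataclass(frozen=True)
class RecognitionSite:
    """A restriction recognition pattern with the cut offset inside it."""

    pattern: str
    cut_offset: int

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        if len(pat) < 4:
            raise DigestError("recognition pattern must be at least 4 bases long")
        if any(ch not in _IUPAC for ch in pat):
            raise DigestError(f"pattern {pat!r} contains non-IUPAC characters")
        if not (0 <= self.cut_offset <= len(pat)):
            raise DigestError("cut offset must lie within the pattern")

    @classmethod
    def parse(cls, spec: str) -> "RecognitionSite":
        """Parse e.g. ``GGTAC^C`` (or ``GGTAC'C``) where the mark is the cut."""
        for mark in ("^", "'"):
            if mark in spec:
                offset = spec.index(mark)
                return cls(spec.replace(mark, ""), offset)
        raise DigestError(f"site spec {spec!r} lacks a cut mark (^)")

    @property
    def regex(self) -> re.Pattern:
        # lookahead so overlapping occurrences are all cut
        body = "".join(f"[{_IUPAC[ch]}]" for ch in self.pattern)
        return re.compile(f"(?={body})")


KPNI = RecognitionSite("GGTACC", 5)


def digest(
    sequence: str,
    site: RecognitionSite,
    sigma_model: SigmaModel | None = None,
    id: str = "seq",
) -> ReferenceMap:
    """Digest one nucleotide sequence into an in-silico reference map.

    Cut positions are ``occurrence_start + cut_offset`` for every forward
    strand occurrence of the pattern; fragments are the successive
    differences of ``0, cuts..., len(sequence)``.  Zero-length end fragments
    (cuts at position 0 or L) are dropped.
    """
    seq = sequence.upper()
    if not seq:
        raise DigestError(f"sequence {id!r} is empty")
    bad = set(seq) - _SEQ_ALPHABET
    if bad:
        raise DigestError(f"sequence {id!r} has non-IUPAC characters: {sorted(bad)}")
    length = len(seq)
    cuts = [m.start() + site.cut_offset for m in site.regex.finditer(seq)]
    bounds = [0] + [c for c in cuts if 0 < c < length] + [length]
    frags = np.diff(np.asarray(bounds, dtype=float))
    frags = frags[frags > 0]
    if frags.size == 0:
        raise DigestError(f"sequence {id!r} produced no positive fragments")
    return ReferenceMap.from_fragments(id, frags, sigma_model)


def digest_collection(
    fasta: str | Path,
    site: RecognitionSite,
    sigma_model: SigmaModel | None = None,
    both_orientations: bool = False,
) -> list[ReferenceMap]:
    """Digest every record of a FASTA file.

    With ``both_orientations`` the reversed map of each sequence is appended
    as well, so total fragment counts follow the convention of counting both
    strands.
    """
    records = list(SeqIO.parse(str(fasta), "fasta"))
    if not records:
        raise DigestError(f"no FASTA records found in {fasta}")
    maps = [digest(str(rec.seq), site, sigma_model, id=rec.id) for rec in records]
    if both_orientations:
        maps = maps + [m.reverse() for m in maps]
    return maps
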