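"""In-silico tryptic digestion and peptide terminus classification.

Trypsin cleaves C-terminal to lysine (K) and arginine (R) unless the next
residue is proline; search engines encode the same rule, so identified
peptides can be classified as fully tryptic, semi-tryptic (one conforming
terminus) or non-tryptic by looking at their termini in protein context.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import InvalidArgumentError

__all__ = [
    "AMINO_ACIDS",
    "CleavageRule",
    "PeptideRecord",
    "in_silico_digest",
    "cleavage_sites",
    "classify_termini",
    "internal_sites",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_RE = re.compile(rf"^[{AMINO_ACIDS}]+$")
TERMINUS = "-"


@dataclass(frozen=True)
class CleavageRule:
    """Protease cleavage specificity.

    Defaults encode trypsin with proline suppression and two allowed missed
    cleavages, the settings used for typical database searches of FFPE data.
    """

    residues: frozenset[str] = frozenset({"K", "R"})
    suppress_before: frozenset[str] = frozenset({"P"})
    max_missed: int = 2

    def __post_init__(self):
        if not self.residues:
            raise InvalidArgumentError("cleavage rule needs >=1 residue")
        if self.max_missed < 0:
            raise InvalidArgumentError("max_missed must be >= 0")
        object.__setattr__(self, "residues", frozenset(self.residues))
        object.__setattr__(self, "suppress_before", frozenset(self.suppress_before))

    def cleaves_between(self, left: str, right: str) -> bool:
        """True if the bond left-right is a cleavage site (right may be '-')."""
        return left in self.residues and (right == TERMINUS or right not in self.suppress_before)


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide with its protein context and modifications.

    ``modifications`` holds ``(position, mass_shift)`` events with 1-based
    positions inside the peptide, the shape of open-search (PTM-Shepherd
    style) output.
    """

    sequence: str
    prev_aa: str = TERMINUS
    next_aa: str = TERMINUS
    protein: str = ""
    voxel: int | str = 0
    spectral_count: int = 1
    modifications: tuple[tuple[int, float], ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.sequence or not _AA_RE.match(self.sequence):
            raise InvalidArgumentError(f"invalid peptide sequence {self.sequence!r}")
        if self.spectral_count < 1:
            raise InvalidArgumentError("spectral_count must be >= 1")
        mods = tuple((int(p), float(s)) for p, s in self.modifications)
        for pos, _ in mods:
            if not 1 <= pos <= len(self.sequence):
                raise InvalidArgumentError(
                    f"modification position {pos} outside 1..{len(self.sequence)}"
                )
        object.__setattr__(self, "modifications", mods)

    @property
    def mod_key(self) -> tuple[tuple[int, float], ...]:
        """Canonical (sorted) modification set, the peptidoform identity."""
        return tuple(sorted(self.modifications))


def cleavage_sites(sequence: str, rule: CleavageRule) -> list[int]:
    """0-based indices i such that the bond between i and i+1 is cleaved."""
    return [
        i
        for i in range(len(sequence) - 1)
        if rule.cleaves_between(sequence[i], sequence[i + 1])
    ]


def in_silico_digest(
    sequence: str, rule: CleavageRule = CleavageRule()
) -> list[tuple[str, str, str, int]]:
    """Digest a protein, emitting all products with up to ``rule.max_missed``
    retained internal sites.

    Returns
    -------
    list of ``(peptide, prev_aa, next_aa, n_missed)`` ordered by start
    position then peptide length; prev/next are ``"-"`` at protein termini.
    """
    if not _AA_RE.match(sequence or ""):
        raise InvalidArgumentError("sequence must be non-empty uppercase amino acids")
    sites = cleavage_sites(sequence, rule)
    # fragment boundaries: starts/ends of 0-missed products
    starts = [0] + [i + 1 for i in sites]
    ends = [i + 1 for i in sites] + [len(sequence)]  # exclusive
    n_frag = len(starts)
    out = []
    for i in range(n_frag):
        for missed in range(rule.max_missed + 1):
            j = i + missed
            if j >= n_frag:
                break
            start, end = starts[i], ends[j]
            prev_aa = sequence[start - 1] if start > 0 else TERMINUS
            next_aa = sequence[end] if end < len(sequence) else TERMINUS
            out.append((start, end - start, sequence[start:end], prev_aa, next_aa, missed))
    out.sort(key=lambda t: (t[0], t[1]))
    return [(pep, prev, nxt, missed) for _, _, pep, prev, nxt, missed in out]


def classify_termini(record: PeptideRecord, rule: CleavageRule = CleavageRule()) -> str:
    """Classify a peptide as ``fully_tryptic``, ``semi_tryptic`` or ``non_tryptic``.

    A C-terminus conforms when the peptide's last residue is a cleavage
    residue not followed by a suppressing residue, or the peptide ends the
    protein. An N-terminus conforms when the preceding residue is a cleavage
    residue (with the peptide's first residue not suppressing), or the
    peptide starts the protein.
    """
    seq = record.sequence
    c_ok = record.next_aa == TERMINUS or rule.cleaves_between(seq[-1], record.next_aa)
    n_ok = record.prev_aa == TERMINUS or rule.cleaves_between(record.prev_aa, seq[0])
    if c_ok and n_ok:
        return "fully_tryptic"
    if c_ok or n_ok:
        return "semi_tryptic"
    return "non_tryptic"


def internal_sites(sequence: str, rule: CleavageRule = CleavageRule()) -> int:
    """Number of retained (missed) cleavage sites inside a peptide."""
    return len(cleavage_sites(sequence, rule))
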