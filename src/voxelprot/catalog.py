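"""Modification catalog: named monoisotopic mass shifts and residue preferences.

The bundled catalog covers the mass shifts that dominate open searches of
formalin-fixed tissue — methylation (+14 Da, CH2), oxidation/hydroxylation
(+16 Da, O), formylation (+28 Da, CO), dihydroxy (+32 Da, O2) — plus the
common search-engine modifications (carbamidomethyl, acetylation) that such
reports conventionally exclude. Shift values are frozen at full monoisotopic
precision computed from standard atomic masses (C 12 exactly, H 1.00782503,
O 15.99491462, N 14.00307401).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidArgumentError

__all__ = [
    "CatalogEntry",
    "ModificationCatalog",
    "DEFAULT_CATALOG",
    "DEFAULT_EXCLUSIONS",
    "annotate_mass_shift",
    "METHYL_SHIFT",
]

# monoisotopic elemental masses (Da)
_M_C = 12.0
_M_H = 1.0078250319
_M_O = 15.9949146221
_M_N = 14.0030740052

METHYL_SHIFT = _M_C + 2 * _M_H  # CH2 = 14.01565...


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    mass_shift: float
    residues: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "residues", frozenset(self.residues))


@dataclass(frozen=True)
class ModificationCatalog:
    """A list of candidate modifications with a shift-matching tolerance."""

    entries: tuple[CatalogEntry, ...]
    match_tolerance: float = 0.01

    def __post_init__(self):
        if self.match_tolerance <= 0:
            raise InvalidArgumentError("match_tolerance must be > 0")
        object.__setattr__(self, "entries", tuple(self.entries))

    def match(self, delta: float) -> list[CatalogEntry]:
        """Entries within ``match_tolerance`` of ``delta``, nearest first.

        Ties in distance break by catalog-independent (name) order, so the
        result does not depend on how the catalog was assembled.
        """
        hits = [e for e in self.entries if abs(e.mass_shift - delta) <= self.match_tolerance]
        hits.sort(key=lambda e: (abs(e.mass_shift - delta), e.name))
        return hits

    def bin_shift(self, delta: float) -> float:
        """Canonical shift value: the nearest catalog shift within tolerance,
        else the raw value rounded to 4 decimals."""
        hits = self.match(delta)
        return hits[0].mass_shift if hits else round(delta, 4)

    def name_for(self, shift: float) -> str:
        hits = self.match(shift)
        return hits[0].name if hits else f"{shift:+.4f}"


DEFAULT_CATALOG = ModificationCatalog(
    entries=(
        CatalogEntry("methylation", METHYL_SHIFT, frozenset("K")),
        CatalogEntry("oxidation/hydroxylation", _M_O, frozenset("PM")),
        CatalogEntry("formylation", _M_C + _M_O, frozenset("K")),
        CatalogEntry("dihydroxy", 2 * _M_O, frozenset("P")),
        CatalogEntry("deamidation", _M_O - _M_N - _M_H, frozenset("NQ")),
        CatalogEntry("carbamidomethyl", 2 * _M_C + 3 * _M_H + _M_N + _M_O, frozenset("C")),
        CatalogEntry("acetylation", 2 * _M_C + 2 * _M_H + _M_O, frozenset("K")),
    )
)

#: shifts conventionally excluded from open-search landscape reports
#: (fixed carbamidomethylation and acetylation)
DEFAULT_EXCLUSIONS = frozenset(
    e.mass_shift for e in DEFAULT_CATALOG.entries if e.name in ("carbamidomethyl", "acetylation")
)


def annotate_mass_shift(delta: float, catalog: ModificationCatalog = DEFAULT_CATALOG) -> list[str]:
    """Candidate modification names for an observed mass shift, nearest first.

    An empty list means the shift is unannotated at the catalog's tolerance.
    """
    if not catalog.entries:
        raise InvalidArgumentError("catalog is empty")
    return [e.name for e in catalog.match(delta)]
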