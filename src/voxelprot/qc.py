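"""Peptide-level QC and modification-landscape statistics.

All estimators work on lists of :class:`~voxelprot.digest.PeptideRecord` and
count *unique peptides*: distinct (sequence, modification-set) pairs, per
voxel where the statistic is spatial, matching "percentage of total
peptides" semantics rather than spectrum counts.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .catalog import DEFAULT_CATALOG, DEFAULT_EXCLUSIONS, METHYL_SHIFT, ModificationCatalog
from .digest import CleavageRule, PeptideRecord, classify_termini, internal_sites
from .errors import InvalidArgumentError, UndefinedRatioError

__all__ = [
    "QCReport",
    "unique_peptides",
    "semi_tryptic_fraction",
    "miscleavage_fraction",
    "kr_cleavage_ratio",
    "mass_shift_table",
    "residue_distribution",
    "miscleavage_modification_stratification",
    "identification_overlap",
    "subcellular_distribution",
    "STRATA",
]

STRATA = (
    "tryptic_unmodified",
    "tryptic_modified",
    "miscleaved_unmodified",
    "miscleaved_methylK",
    "miscleaved_other_modified",
)


@dataclass
class QCReport:
    """Container for the full digest-QC summary of one peptide table."""

    semi_tryptic: pd.Series  # per-voxel fraction
    miscleavage: pd.Series  # per-voxel fraction
    kr_c_term: float
    kr_upstream: float
    mass_shifts: pd.DataFrame  # columns: shift, name, percent
    stratification: pd.Series  # fraction of total per stratum
    conditional: pd.Series  # among miscleaved & modified


def unique_peptides(
    records: list[PeptideRecord],
) -> dict[int | str, list[PeptideRecord]]:
    """Deduplicate records to distinct (sequence, modification-set) pairs per voxel.

    Returns a mapping voxel -> representative records; the first record of
    each peptidoform in a voxel represents it.
    """
    seen: dict[tuple, PeptideRecord] = {}
    for rec in records:
        key = (rec.voxel, rec.sequence, rec.mod_key)
        if key not in seen:
            seen[key] = rec
    groups: dict = defaultdict(list)
    for (voxel, _, _), rec in seen.items():
        groups[voxel].append(rec)
    return dict(groups)


def _unique_flat(records: list[PeptideRecord]) -> list[PeptideRecord]:
    """All per-voxel unique representatives, pooled over voxels."""
    return [rec for recs in unique_peptides(records).values() for rec in recs]


def _per_voxel_fraction(records, rule, predicate, per_voxel):
    groups = unique_peptides(records)
    if not per_voxel:
        flat = [r for recs in groups.values() for r in recs]
        return sum(1 for r in flat if predicate(r, rule)) / len(flat)
    out = {}
    for voxel, recs in groups.items():
        out[voxel] = sum(1 for r in recs if predicate(r, rule)) / len(recs)
    return pd.Series(out).sort_index()


def semi_tryptic_fraction(
    records: list[PeptideRecord], rule: CleavageRule = CleavageRule(), per_voxel: bool = True
):
    """Fraction of unique peptides conforming to the protease rule at exactly
    one terminus, per voxel (or pooled with ``per_voxel=False``)."""
    if not records:
        raise InvalidArgumentError("no records")
    return _per_voxel_fraction(
        records, rule, lambda r, ru: classify_termini(r, ru) == "semi_tryptic", per_voxel
    )


def miscleavage_fraction(
    records: list[PeptideRecord], rule: CleavageRule = CleavageRule(), per_voxel: bool = True
):
    """Fraction of unique peptides retaining >=1 internal cleavage site."""
    if not records:
        raise InvalidArgumentError("no records")
    return _per_voxel_fraction(
        records, rule, lambda r, ru: internal_sites(r.sequence, ru) >= 1, per_voxel
    )


def kr_cleavage_ratio(
    records: list[PeptideRecord], rule: CleavageRule = CleavageRule()
) -> tuple[float, float]:
    """Lysine:arginine cleavage preference at two contexts.

    C-term context counts unique peptides ending in K vs R (protein
    C-terminal peptides excluded, their terminus is not a cleavage); upstream
    context counts ``prev_aa`` K vs R (protein N-terminal peptides excluded).
    A ratio below 1 means arginine cleavage is preferred.
    """
    recs = _unique_flat(records) if records else []
    ck = cr = uk = ur = 0
    for r in recs:
        if r.next_aa != "-":
            last = r.sequence[-1]
            ck += last == "K"
            cr += last == "R"
        if r.prev_aa != "-":
            uk += r.prev_aa == "K"
            ur += r.prev_aa == "R"
    if cr == 0:
        raise UndefinedRatioError("c_term")
    if ur == 0:
        raise UndefinedRatioError("upstream")
    return ck / cr, uk / ur


def mass_shift_table(
    records: list[PeptideRecord],
    exclusions: frozenset[float] = DEFAULT_EXCLUSIONS,
    top_n: int = 8,
    catalog: ModificationCatalog = DEFAULT_CATALOG,
) -> pd.DataFrame:
    """Frequency of the most abundant mass shifts, as % of total unique peptides.

    Shifts are binned to catalog entries within the catalog's match
    tolerance; a peptide counts once per distinct shift it carries; shifts in
    ``exclusions`` (matched at the same tolerance) are dropped. Rows are the
    ``top_n`` most frequent, ties broken by ascending shift.
    """
    recs = _unique_flat(records)
    total = len(recs)
    if total == 0:
        return pd.DataFrame(columns=["shift", "name", "percent"])
    excl = sorted(exclusions)
    tol = catalog.match_tolerance

    def excluded(shift: float) -> bool:
        return any(abs(shift - e) <= tol for e in excl)

    counts: dict[float, int] = defaultdict(int)
    for rec in recs:
        shifts = {catalog.bin_shift(s) for _, s in rec.modifications}
        for s in shifts:
            if not excluded(s):
                counts[s] += 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return pd.DataFrame(
        {
            "shift": [s for s, _ in rows],
            "name": [catalog.name_for(s) for s, _ in rows],
            "percent": [100.0 * c / total for _, c in rows],
        }
    )


def residue_distribution(
    records: list[PeptideRecord],
    shift: float,
    catalog: ModificationCatalog = DEFAULT_CATALOG,
) -> pd.Series:
    """Residue distribution of one mass shift, as % of shift-carrying peptides.

    Each carrying peptide contributes total weight 1, split evenly over its
    events of that shift, so the distribution sums to 100%.
    """
    recs = _unique_flat(records)
    target = catalog.bin_shift(shift)
    weights: dict[str, float] = defaultdict(float)
    n_carrying = 0
    for rec in recs:
        events = [(p, s) for p, s in rec.modifications if catalog.bin_shift(s) == target]
        if not events:
            continue
        n_carrying += 1
        w = 1.0 / len(events)
        for pos, _ in events:
            weights[rec.sequence[pos - 1]] += w
    if n_carrying == 0:
        warnings.warn(f"mass shift {shift:+.4f} absent from records")
        return pd.Series(dtype=float)
    return (pd.Series(weights) * 100.0 / n_carrying).sort_index()


def _has_methyl_k(rec: PeptideRecord, catalog: ModificationCatalog) -> bool:
    return any(
        rec.sequence[pos - 1] == "K" and abs(shift - METHYL_SHIFT) <= catalog.match_tolerance
        for pos, shift in rec.modifications
    )


def miscleavage_modification_stratification(
    records: list[PeptideRecord],
    rule: CleavageRule = CleavageRule(),
    methyl_shift: float = METHYL_SHIFT,
    catalog: ModificationCatalog = DEFAULT_CATALOG,
) -> tuple[pd.Series, pd.Series]:
    """Assign each unique peptide to one of five exclusive strata.

    Strata: tryptic (no internal site) unmodified/modified; miscleaved
    unmodified; miscleaved carrying lysine methylation; miscleaved with other
    modifications only. Returns (fractions of total, conditional fractions
    among miscleaved & modified).
    """
    recs = _unique_flat(records)
    counts = dict.fromkeys(STRATA, 0)
    for rec in recs:
        miscleaved = internal_sites(rec.sequence, rule) >= 1
        modified = bool(rec.modifications)
        if not miscleaved:
            counts["tryptic_modified" if modified else "tryptic_unmodified"] += 1
        elif not modified:
            counts["miscleaved_unmodified"] += 1
        elif _has_methyl_k(rec, catalog):
            counts["miscleaved_methylK"] += 1
        else:
            counts["miscleaved_other_modified"] += 1
    total = len(recs)
    fractions = pd.Series(
        {k: (v / total if total else 0.0) for k, v in counts.items()}, index=list(STRATA)
    )
    n_mm = counts["miscleaved_methylK"] + counts["miscleaved_other_modified"]
    if n_mm:
        conditional = pd.Series(
            {
                "miscleaved_methylK": counts["miscleaved_methylK"] / n_mm,
                "miscleaved_other_modified": counts["miscleaved_other_modified"] / n_mm,
            }
        )
    else:
        conditional = pd.Series(dtype=float)
    return fractions, conditional


def identification_overlap(labelled_sets: dict[str, set]) -> dict[frozenset[str], int]:
    """Counts for every membership pattern across >=2 labelled id sets.

    The key is the frozenset of labels an element belongs to; counts over all
    non-empty patterns sum to the size of the union.
    """
    if len(labelled_sets) < 2:
        raise InvalidArgumentError("need >= 2 sets")
    labels = sorted(labelled_sets)
    out: dict[frozenset[str], int] = {}
    for k in range(1, len(labels) + 1):
        for combo in combinations(labels, k):
            out[frozenset(combo)] = 0
    membership: dict = defaultdict(set)
    for label, ids in labelled_sets.items():
        for i in ids:
            membership[i].add(label)
    for pattern in membership.values():
        out[frozenset(pattern)] += 1
    return out


def subcellular_distribution(
    proteins: set[str],
    annotation: dict[str, set[str]],
    locations: list[str],
) -> pd.Series:
    """Percent of proteins annotated to each listed location, plus not-annotated.

    Multi-location proteins count in every listed location they carry, so the
    listed percentages may sum above 100; "not_annotated" covers proteins
    with none of the listed locations.
    """
    if not locations:
        raise InvalidArgumentError("locations must be non-empty")
    total = len(proteins)
    if total == 0:
        raise InvalidArgumentError("empty protein set")
    counts = {loc: 0 for loc in locations}
    not_annotated = 0
    for p in proteins:
        locs = annotation.get(p, set()) & set(locations)
        if not locs:
            not_annotated += 1
        for loc in locs:
            counts[loc] += 1
    out = {loc: 100.0 * c / total for loc, c in counts.items()}
    out["not_annotated"] = 100.0 * not_annotated / total
    return pd.Series(out, index=list(locations) + ["not_annotated"])
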