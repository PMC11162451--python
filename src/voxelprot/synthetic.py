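"""Synthetic spatial-proteomics data with exported ground truth.

Three generators emulate the inputs of the downstream pipeline so every
estimator can be tested against known truth:

* a protein x voxel log2-intensity matrix with planted spatially
  co-regulated modules: x_pv = mu + lambda_p * s_m(v) + eps_pv, where s_m is
  the module's spatial profile over retained voxels, lambda_p the member's
  (possibly negated) loading and eps ~ Normal(0, sigma^2) i.i.d.;
* a peptide identification table with controlled semi-tryptic, miscleavage
  and modification rates, including the coupling of lysine methylation to
  trypsin miscleavage;
* per-protein spectral-count tables with an optional resampled replicate.

Each generator call consumes one dedicated random stream derived from
``(config.seed, stream_id)`` in a documented field order, so identical
configs give bit-identical outputs.

The companion proteome generator emits composition-controlled tryptic
blocks (every block carries at least one proline and one methionine, block
interiors are free of K/R/P, terminal K:R odds are 1:2), so that every
tryptic product has modification-eligible residues and the terminus class
of a trimmed peptide is unambiguous. Real proteomes are messier; the point
is exact parameter recovery, not sequence realism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import METHYL_SHIFT
from .digest import (
    CleavageRule,
    PeptideRecord,
    classify_termini,
    cleavage_sites,
    internal_sites,
)
from .errors import InvalidArgumentError
from .layout import VoxelLayout, generate_layout, grid_position

__all__ = [
    "ModChannel",
    "SimulationConfig",
    "GroundTruth",
    "generate_layout",
    "generate_proteome",
    "generate_intensity",
    "generate_peptide_table",
    "generate_spectral_counts",
]

_INTERIOR_ALPHABET = "ACDEFGHILMNQSTVWY"  # no K/R (cleavage), no P (suppression control)


@dataclass(frozen=True)
class ModChannel:
    """One modification channel of the generator.

    ``prob`` is the per-peptide probability of carrying the shift; the
    modified site is drawn among residue *types* present in the peptide with
    the given weights (uniform position within the chosen type), falling
    back to a uniform unmodified position when no preferred type is present.
    """

    shift: float
    prob: float
    residue_weights: tuple[tuple[str, float], ...]

    def __post_init__(self):
        if not 0 <= self.prob <= 1:
            raise InvalidArgumentError("channel prob must be in [0,1]")


DEFAULT_MOD_CHANNELS = (
    ModChannel(15.9949146221, 0.065, (("P", 3.0), ("M", 1.0))),  # oxidation/hydroxylation
    ModChannel(31.9898292442, 0.030, (("P", 1.0),)),  # dihydroxy
    ModChannel(27.9949146221, 0.020, (("K", 1.0),)),  # formylation
    ModChannel(0.9840155850, 0.030, (("N", 1.0), ("Q", 1.0))),  # deamidation
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, defaulting to the emulated design:
    a 4x5 slide grid with voxels 2, 5 and 8 excluded (17 analysis voxels),
    1368 quantified proteins with a 453-protein fully quantified core, and
    digest statistics in the ranges reported for FFPE voxel data (~2%
    semi-tryptic, ~12% miscleaved, ~3% lysine-methylated peptides with
    methylation strongly coupled to miscleavage, R preferred 2:1 over K)."""

    n_rows: int = 4
    n_cols: int = 5
    excluded_voxels: frozenset[int] = frozenset({2, 5, 8})
    n_modules: int = 2
    proteins_per_module: int = 24
    n_background_proteins: int = 1320
    n_core_background: int = 405
    module_profiles: tuple[str, ...] = ("hotspot", "gradient")
    loading_mean: float = 4.0
    anti_fraction: float = 0.15
    baseline_mean: float = 20.0
    noise_sd: float = 0.25
    missing_rate: float = 0.3
    n_peptides: int = 5000
    p_semi: float = 0.022
    p_misclv: float = 0.12
    mod_channels: tuple[ModChannel, ...] = DEFAULT_MOD_CHANNELS
    p_methyl_K: float = 0.08
    methyl_misclv_coupling: float = 0.9
    seed: int = 0

    def __post_init__(self):
        for name in ("anti_fraction", "missing_rate", "p_semi", "p_misclv",
                     "p_methyl_K", "methyl_misclv_coupling"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidArgumentError(f"{name} must be in [0,1], got {v}")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        total = self.n_rows * self.n_cols
        if total < len(self.excluded_voxels) + 1:
            raise InvalidArgumentError("grid must keep at least one voxel")
        for p in self.module_profiles:
            if p not in ("gradient", "hotspot", "uniform"):
                raise InvalidArgumentError(f"unknown spatial profile {p!r}")
        object.__setattr__(self, "excluded_voxels", frozenset(self.excluded_voxels))
        object.__setattr__(self, "module_profiles", tuple(self.module_profiles))
        object.__setattr__(self, "mod_channels", tuple(self.mod_channels))

    def layout(self) -> VoxelLayout:
        return generate_layout(self.n_rows, self.n_cols, self.excluded_voxels)


@dataclass
class GroundTruth:
    """What the generators actually planted, for recovery tests.

    Intensity part: protein -> module id (0 = background), protein ->
    loading sign, module -> spatial profile per retained voxel, the fully
    quantified core. Peptide part: one row of construction truth per emitted
    record plus aggregate category counts.
    """

    protein_module: dict[str, int] = field(default_factory=dict)
    protein_sign: dict[str, int] = field(default_factory=dict)
    module_profiles: dict[int, pd.Series] = field(default_factory=dict)
    core_proteins: list[str] = field(default_factory=list)
    peptide_truth: pd.DataFrame | None = None
    category_counts: dict[str, int] = field(default_factory=dict)

    def module_members(self, module: int) -> list[str]:
        return sorted(p for p, m in self.protein_module.items() if m == module)

    def to_json(self, path) -> None:
        payload = {
            "protein_module": self.protein_module,
            "protein_sign": self.protein_sign,
            "module_profiles": {
                str(m): {str(v): float(x) for v, x in s.items()}
                for m, s in self.module_profiles.items()
            },
            "core_proteins": self.core_proteins,
            "category_counts": self.category_counts,
        }
        if self.peptide_truth is not None:
            payload["peptide_truth"] = self.peptide_truth.to_dict(orient="list")
        with open(path, "w") as fh:
            json.dump(payload, fh)
            fh.write("\n")


# ---------------------------------------------------------------------------
# proteome


def generate_proteome(
    n_proteins: int = 300,
    seed: int = 0,
    n_blocks: tuple[int, int] = (15, 30),
    block_len: tuple[int, int] = (7, 14),
    k_fraction: float = 1 / 3,
) -> list[SeqRecord]:
    """Synthetic protein sequences built from tryptic blocks.

    Each block ends in K (probability ``k_fraction``) or R, has an interior
    free of K/R/P apart from exactly one forced proline and at least one
    methionine (neither at the block start), and is 7-14 residues long.
    Digesting a protein with zero missed cleavages returns exactly its
    blocks.
    """
    if n_proteins < 1:
        raise InvalidArgumentError("n_proteins must be >= 1")
    rng = np.random.default_rng((int(seed), 0))
    interior = np.array(list(_INTERIOR_ALPHABET))
    records = []
    for i in range(n_proteins):
        nb = int(rng.integers(n_blocks[0], n_blocks[1] + 1))
        blocks = []
        for _ in range(nb):
            length = int(rng.integers(block_len[0], block_len[1] + 1))
            letters = list(rng.choice(interior, size=length - 1))
            # force one P and one M at distinct non-initial interior positions
            pos = rng.choice(np.arange(1, length - 1), size=2, replace=False)
            letters[int(pos[0])] = "P"
            letters[int(pos[1])] = "M"
            terminal = "K" if rng.random() < k_fraction else "R"
            blocks.append("".join(letters) + terminal)
        seq = "".join(blocks)
        records.append(
            SeqRecord(Seq(seq), id=f"SYN{i + 1:04d}", description=f"synthetic protein {i + 1}")
        )
    return records


# ---------------------------------------------------------------------------
# intensity matrix


def _profile(name: str, layout: VoxelLayout, n_cols: int, rng) -> pd.Series:
    retained = layout.retained
    n = len(retained)
    if name == "gradient":
        values = [i / (n - 1) if n > 1 else 0.0 for i in range(n)]
    elif name == "uniform":
        values = [1.0] * n
    else:  # hotspot: 1 at a random retained voxel, exp(-distance) decay
        center = retained[int(rng.integers(n))]
        cr, cc = grid_position(n_cols, center)
        values = []
        for v in retained:
            r, c = grid_position(n_cols, v)
            values.append(math.exp(-math.hypot(r - cr, c - cc)))
    return pd.Series(values, index=retained, dtype=float)


def generate_intensity(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Protein x voxel log2-intensity matrix with planted spatial modules.

    Stream order (one rng per call): hotspot centers per module, then the
    noise matrix, then the missingness mask. Module members are named
    ``M{m}P{i}``; within each module the last ``round(anti_fraction * size)``
    members carry a negated loading. Background rows have zero loading. The
    fully quantified core (all module proteins plus the first
    ``n_core_background`` background proteins) never receives missing
    values; other entries are missing completely at random.
    """
    layout = config.layout()
    retained = layout.retained
    if len(retained) < 2:
        raise InvalidArgumentError("need >= 2 retained voxels")
    rng = np.random.default_rng((int(config.seed), 1))

    gt = GroundTruth()
    profiles = []
    for m in range(1, config.n_modules + 1):
        name = config.module_profiles[(m - 1) % len(config.module_profiles)]
        s = _profile(name, layout, config.n_cols, rng)
        profiles.append(s)
        gt.module_profiles[m] = s

    proteins: list[str] = []
    loadings: list[float] = []
    n_anti = round(config.anti_fraction * config.proteins_per_module)
    for m in range(1, config.n_modules + 1):
        for i in range(1, config.proteins_per_module + 1):
            acc = f"M{m}P{i:03d}"
            sign = -1 if i > config.proteins_per_module - n_anti else 1
            proteins.append(acc)
            loadings.append(sign * config.loading_mean)
            gt.protein_module[acc] = m
            gt.protein_sign[acc] = sign
    for i in range(1, config.n_background_proteins + 1):
        acc = f"BG{i:04d}"
        proteins.append(acc)
        loadings.append(0.0)
        gt.protein_module[acc] = 0
        gt.protein_sign[acc] = 0

    n_p, n_v = len(proteins), len(retained)
    x = np.full((n_p, n_v), config.baseline_mean, dtype=float)
    for idx, acc in enumerate(proteins):
        m = gt.protein_module[acc]
        if m:
            x[idx] += loadings[idx] * profiles[m - 1].to_numpy()
    # standard-normal draw scaled by sigma: the stream is consumed identically
    # for sigma = 0, so the noise-free limit shares all other randomness
    x += config.noise_sd * rng.standard_normal(size=(n_p, n_v))

    core = proteins[: config.n_modules * config.proteins_per_module] + [
        f"BG{i:04d}" for i in range(1, config.n_core_background + 1)
    ]
    gt.core_proteins = [p for p in proteins if p in set(core)]
    mask = rng.random(size=(n_p, n_v)) < config.missing_rate
    core_set = set(gt.core_proteins)
    for idx, acc in enumerate(proteins):
        if acc in core_set:
            mask[idx] = False
    x[mask] = np.nan
    matrix = pd.DataFrame(x, index=proteins, columns=retained)
    return matrix, gt


# ---------------------------------------------------------------------------
# peptide table


def _trim(seq: str, start: int, end: int, protein: str, rng) -> tuple[str, int, int, bool]:
    """Trim 1-3 residues from a uniformly chosen terminus (semi-tryptic)."""
    side = int(rng.integers(2))  # 0 = N-term, 1 = C-term
    trim = int(rng.integers(1, 4))
    if end - start - trim < 4:
        return seq, start, end, False
    if side == 0:
        start += trim
    else:
        end -= trim
    return protein[start:end], start, end, True


def generate_peptide_table(
    config: SimulationConfig, proteins
) -> tuple[list[PeptideRecord], GroundTruth]:
    """Sample an identified-peptide table with controlled digest statistics.

    Per record the stream is consumed in this order: protein, tryptic
    fragment, terminal-lysine methylation (and its miscleavage coupling),
    plain miscleavage, semi-tryptic trimming, modification channels in
    catalog order, voxel, spectral count. Ground truth carries one row per
    record (terminus class, miscleaved flag, modification events) plus
    aggregate counts re-derived from the emitted records themselves.
    """
    seqs: list[tuple[str, str]] = []
    for p in proteins:
        if hasattr(p, "id"):
            seqs.append((str(p.id).split()[0], str(p.seq).upper()))
        else:
            acc, s = p
            seqs.append((str(acc), str(s).upper()))
    if not seqs:
        raise InvalidArgumentError("empty FASTA")

    rule = CleavageRule(max_missed=0)
    digests = []
    for acc, seq in seqs:
        bounds = [0] + [i + 1 for i in cleavage_sites(seq, rule)] + [len(seq)]
        frags = [(bounds[j], bounds[j + 1]) for j in range(len(bounds) - 1)]
        digests.append((acc, seq, frags))

    retained = config.layout().retained
    rng = np.random.default_rng((int(config.seed), 2))
    records: list[PeptideRecord] = []
    truth_rows = []

    for _ in range(config.n_peptides):
        acc, seq, frags = digests[int(rng.integers(len(seqs)))]
        i = int(rng.integers(len(frags)))
        start, end = frags[i]
        methyl_abs: int | None = None

        # terminal-lysine methylation and its coupling to miscleavage
        if seq[end - 1] == "K" and rng.random() < config.p_methyl_K:
            methyl_abs = end - 1
            if i + 1 < len(frags) and rng.random() < config.methyl_misclv_coupling:
                end = frags[i + 1][1]  # site left uncleaved

        # plain miscleavage: retain one internal site
        if rng.random() < config.p_misclv and len(frags) > 1 and end == frags[i][1]:
            if i + 1 < len(frags):
                end = frags[i + 1][1]
            else:
                start = frags[i - 1][0]

        pep = seq[start:end]
        if rng.random() < config.p_semi:
            pep, start, end, _applied = _trim(pep, start, end, seq, rng)
        if methyl_abs is not None and not start <= methyl_abs < end:
            methyl_abs = None  # trimmed away

        occupied = set()
        events: list[tuple[int, float]] = []
        if methyl_abs is not None:
            pos = methyl_abs - start + 1
            events.append((pos, METHYL_SHIFT))
            occupied.add(pos)

        for channel in config.mod_channels:
            if rng.random() >= channel.prob:
                continue
            types = [t for t, _w in channel.residue_weights if t in pep]
            pos = None
            if types:
                weights = np.array(
                    [w for t, w in channel.residue_weights if t in pep], dtype=float
                )
                chosen = types[int(rng.choice(len(types), p=weights / weights.sum()))]
                candidates = [
                    j + 1 for j, aa in enumerate(pep) if aa == chosen and j + 1 not in occupied
                ]
            else:
                candidates = [j + 1 for j in range(len(pep)) if j + 1 not in occupied]
            if candidates:
                pos = candidates[int(rng.integers(len(candidates)))]
                events.append((pos, channel.shift))
                occupied.add(pos)

        voxel = retained[int(rng.integers(len(retained)))]
        count = 1 + int(rng.poisson(1.0))
        rec = PeptideRecord(
            sequence=pep,
            prev_aa=seq[start - 1] if start > 0 else "-",
            next_aa=seq[end] if end < len(seq) else "-",
            protein=acc,
            voxel=voxel,
            spectral_count=count,
            modifications=tuple(sorted(events)),
        )
        records.append(rec)
        truth_rows.append(
            {
                "sequence": pep,
                "protein": acc,
                "voxel": voxel,
                "terminus_class": classify_termini(rec, rule),
                "miscleaved": internal_sites(pep, rule) >= 1,
                "n_events": len(events),
                "has_methyl_K": any(
                    pep[p - 1] == "K" and abs(s - METHYL_SHIFT) < 1e-6 for p, s in events
                ),
            }
        )

    truth = pd.DataFrame(truth_rows)
    gt = GroundTruth(peptide_truth=truth)
    gt.category_counts = {
        "total": len(records),
        "semi_tryptic": int((truth["terminus_class"] == "semi_tryptic").sum()),
        "miscleaved": int(truth["miscleaved"].sum()),
        "modified": int((truth["n_events"] > 0).sum()),
        "methyl_K": int(truth["has_methyl_K"].sum()),
    }
    return records, gt


def generate_spectral_counts(
    config: SimulationConfig, peptides: list[PeptideRecord], resample: bool = False
) -> pd.Series:
    """Per-protein record counts, optionally bootstrap-resampled to mimic an
    independently acquired dataset. Deterministic under the config seed."""
    if not peptides:
        raise InvalidArgumentError("peptide table is empty")
    accessions = [r.protein for r in peptides]
    if resample:
        rng = np.random.default_rng((int(config.seed), 3))
        idx = rng.integers(0, len(accessions), size=len(accessions))
        accessions = [accessions[i] for i in idx]
    counts: dict[str, int] = {}
    for acc in accessions:
        counts[acc] = counts.get(acc, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()
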