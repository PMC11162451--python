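"""Protein co-regulation networks over tissue voxels.

Spatial co-regulation is measured as the Pearson correlation of two
proteins' intensity profiles across voxels, mapped to an adjacency strength
in [0, 1] by a soft-threshold power (the weighted co-expression network
convention: unsigned a = |r|^beta, signed a = ((1+r)/2)^beta). Topological
overlap smooths adjacency by shared-neighbor structure and drives module
detection; seed neighborhoods and inverse-regulation partners answer the
"which proteins track / mirror this one" questions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .errors import InvalidArgumentError, NotFoundError, UndefinedCorrelationError

__all__ = [
    "AdjacencyMatrix",
    "SeedNeighborhood",
    "ModuleAssignment",
    "protein_correlation",
    "soft_adjacency",
    "topological_overlap",
    "seed_neighborhood",
    "inverse_partners",
    "edge_list",
    "detect_modules",
]

DEFAULT_BETA_UNSIGNED = 6.0
DEFAULT_BETA_SIGNED = 12.0
DEFAULT_TOP_K = 23


@dataclass
class AdjacencyMatrix:
    """Soft-threshold adjacency with its companion signed correlations."""

    adjacency: pd.DataFrame  # strengths in [0, 1], unit diagonal
    correlation: pd.DataFrame  # signed Pearson r
    beta: float
    mode: str  # "unsigned" | "signed"

    @property
    def proteins(self) -> list[str]:
        return list(self.adjacency.index)


@dataclass
class SeedNeighborhood:
    seed: str
    neighbors: pd.Series  # adjacency values, ranked descending
    rule: str  # "top_k" | "threshold"
    threshold: float | None = None


@dataclass
class ModuleAssignment:
    labels: pd.Series  # protein -> module label; "0" = unassigned singleton
    cut_height: float


def protein_correlation(m: pd.DataFrame) -> pd.DataFrame:
    """Protein-by-protein signed Pearson correlation across voxels."""
    if m.shape[1] < 3:
        raise InvalidArgumentError("need >= 3 voxels")
    values = m.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise InvalidArgumentError("correlation requires a complete matrix")
    sd = values.std(axis=1)
    for protein, s in zip(m.index, sd):
        if s == 0:
            raise UndefinedCorrelationError(protein, "protein")
    r = np.corrcoef(values)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=m.index, columns=m.index)


def soft_adjacency(
    r: pd.DataFrame, beta: float | None = None, mode: str = "unsigned"
) -> AdjacencyMatrix:
    """Map signed correlations to adjacency strengths in [0, 1].

    unsigned: a = |r|^beta (inverse regulation counts as co-regulation);
    signed:   a = ((1+r)/2)^beta (anti-correlation maps toward 0).
    The diagonal is forced to 1.
    """
    if mode not in ("unsigned", "signed"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    if beta is None:
        beta = DEFAULT_BETA_UNSIGNED if mode == "unsigned" else DEFAULT_BETA_SIGNED
    if beta < 1:
        raise InvalidArgumentError("beta must be >= 1")
    rv = r.to_numpy(dtype=float)
    a = np.abs(rv) ** beta if mode == "unsigned" else ((1.0 + rv) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(
        adjacency=pd.DataFrame(a, index=r.index, columns=r.columns),
        correlation=r.copy(),
        beta=float(beta),
        mode=mode,
    )


def topological_overlap(a: AdjacencyMatrix) -> pd.DataFrame:
    """Topological overlap matrix (TOM) of a soft adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with the
    shared-neighbor sum over u distinct from i and j and k the connectivity
    (row sum minus the diagonal); TOM_ii = 1.
    """
    av = a.adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(av, 1.0)
    k = av.sum(axis=1) - 1.0
    # (A @ A)_ij includes u=i and u=j terms, each contributing a_ij (diag 1)
    shared = av @ av - 2.0 * av
    numer = shared + av
    denom = np.minimum.outer(k, k) + 1.0 - av
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numer / denom
    tom = np.where(denom > 0, tom, 1.0)
    np.fill_diagonal(tom, 1.0)
    np.clip(tom, 0.0, 1.0, out=tom)
    tom = (tom + tom.T) / 2.0
    return pd.DataFrame(tom, index=a.adjacency.index, columns=a.adjacency.columns)


def _ranked_partners(values: pd.Series, seed: str) -> pd.Series:
    others = values.drop(index=seed)
    order = sorted(others.index, key=lambda p: (-others[p], str(p)))
    return others.loc[order]


def seed_neighborhood(
    a: AdjacencyMatrix,
    seed: str,
    k: int | None = DEFAULT_TOP_K,
    threshold: float | None = None,
    threshold_direction: str = "ge",
) -> SeedNeighborhood:
    """Proteins most closely spatially co-regulated with a seed.

    Default rule keeps the top ``k`` partners by adjacency (ties broken by
    ascending accession). Alternatively a ``threshold`` on adjacency can be
    used; its direction is configurable (``"ge"`` keeps a >= t, ``"le"``
    keeps a <= t) because published cutoffs have been stated in both senses.
    """
    if seed not in a.adjacency.index:
        raise NotFoundError(seed)
    ranked = _ranked_partners(a.adjacency[seed], seed)
    if threshold is not None:
        if threshold_direction == "ge":
            kept = ranked[ranked >= threshold]
        elif threshold_direction == "le":
            kept = ranked[ranked <= threshold]
        else:
            raise InvalidArgumentError(f"unknown threshold_direction {threshold_direction!r}")
        return SeedNeighborhood(seed=seed, neighbors=kept, rule="threshold", threshold=threshold)
    if k is None or k < 0:
        raise InvalidArgumentError("need k >= 0 or a threshold")
    return SeedNeighborhood(seed=seed, neighbors=ranked.iloc[:k], rule="top_k")


def inverse_partners(r: pd.DataFrame, seed: str, t: float = 0.6) -> pd.Series:
    """Proteins inversely regulated to the seed: r(seed, p) <= -t.

    Sorted most-negative first; ``t`` must lie in (0, 1].
    """
    if not 0 < t <= 1:
        raise InvalidArgumentError("threshold t must be in (0, 1]")
    if seed not in r.index:
        raise NotFoundError(seed)
    row = r[seed].drop(index=seed)
    hits = row[row <= -t]
    order = sorted(hits.index, key=lambda p: (hits[p], str(p)))
    return hits.loc[order]


def edge_list(
    a: AdjacencyMatrix, nodes: set[str] | None = None, t: float = 0.0
) -> list[tuple[str, str, float]]:
    """Undirected weighted edges (i < j by accession) with adjacency >= t."""
    if nodes is None:
        nodes = set(a.proteins)
    unknown = nodes - set(a.proteins)
    if unknown:
        raise NotFoundError(f"nodes not in matrix: {sorted(unknown)[:5]}")
    ordered = sorted(nodes, key=str)
    adj = a.adjacency
    edges = []
    for i, p in enumerate(ordered):
        for q in ordered[i + 1 :]:
            w = float(adj.at[p, q])
            if w >= t:
                edges.append((p, q, w))
    return edges


def detect_modules(a: AdjacencyMatrix, cut_height: float = 0.5) -> ModuleAssignment:
    """Average-linkage modules on topological-overlap dissimilarity (1 - TOM).

    The dendrogram is cut at ``cut_height``; singleton clusters get the
    unassigned label "0", the rest are labelled "1", "2", ... by decreasing
    size (ties by smallest member accession).
    """
    proteins = a.proteins
    if len(proteins) < 2:
        raise InvalidArgumentError("need >= 2 proteins")
    tom = topological_overlap(a).to_numpy()
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    link = average(squareform(diss, checks=False))
    raw = fcluster(link, t=cut_height, criterion="distance")
    groups: dict[int, list[str]] = {}
    for protein, lab in zip(proteins, raw):
        groups.setdefault(int(lab), []).append(protein)
    keep = [g for g in groups.values() if len(g) > 1]
    keep.sort(key=lambda g: (-len(g), min(map(str, g))))
    labels = {p: "0" for p in proteins}
    for idx, members in enumerate(keep, start=1):
        for p in members:
            labels[p] = str(idx)
    return ModuleAssignment(
        labels=pd.Series(labels, index=proteins), cut_height=float(cut_height)
    )
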