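"""Spectral-count abundance ranks and cross-dataset rank concordance.

Summed spectral counts are a rough abundance proxy; plotting count against
protein rank and checking that a protein family (e.g. keratins) occupies
similar rank positions across independently processed datasets argues that
its signal is biological rather than contamination. The visual "similar
positions" comparison is quantified here as a Spearman rank correlation.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .digest import PeptideRecord
from .errors import InsufficientOverlapError, InvalidArgumentError

__all__ = ["sum_spectral_counts", "rank_proteins", "rank_concordance"]


def sum_spectral_counts(records: list[PeptideRecord]) -> pd.Series:
    """Per-protein sum of spectral counts over all records.

    Returns an integer Series indexed by accession (ascending); empty input
    gives an empty table.
    """
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.protein] = counts.get(rec.protein, 0) + rec.spectral_count
    return pd.Series(counts, dtype=int).sort_index()


def rank_proteins(table: pd.Series) -> pd.DataFrame:
    """Rank proteins by descending count.

    Returns a DataFrame with columns ``rank`` (ordinal position 1..N for
    plotting; ties broken by ascending accession), ``protein``, ``count`` and
    ``mean_rank`` (tied counts share the mean rank, the convention used for
    rank-correlation work).
    """
    if table.empty:
        raise InvalidArgumentError("empty count table")
    df = table.rename_axis("protein").reset_index(name="count")
    df = df.sort_values(["count", "protein"], ascending=[False, True], kind="mergesort")
    df.insert(0, "rank", range(1, len(df) + 1))
    # mean rank on descending counts: rank of -count, ties averaged
    df["mean_rank"] = stats.rankdata(-df["count"].to_numpy(), method="average")
    return df.reset_index(drop=True)


def rank_concordance(t1: pd.Series, t2: pd.Series, subset: set[str]) -> float:
    """Spearman correlation of abundance ranks, restricted to ``subset``.

    Ranks are the mean-ranks of each full table (so the subset keeps its
    global rank context); at least 3 shared accessions are required.
    """
    shared = sorted(set(subset) & set(t1.index) & set(t2.index))
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"subset shares only {len(shared)} accessions with both tables (need >= 3)"
        )
    r1 = rank_proteins(t1).set_index("protein")["mean_rank"].loc[shared]
    r2 = rank_proteins(t2).set_index("protein")["mean_rank"].loc[shared]
    rho = stats.spearmanr(r1.to_numpy(), r2.to_numpy()).statistic
    return float(rho)
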