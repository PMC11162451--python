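"""Plain-text readers and writers for the package's table dialects.

Intensity matrices, peptide tables, count tables and term memberships
travel as TSV; layouts and ground truth as JSON; proteomes as FASTA (via
Bio.SeqIO). The peptide dialect mirrors open-search summary output:
``assigned_modifications`` is a semicolon list of ``pos:shift`` events with
1-based positions.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO

from .digest import PeptideRecord
from .errors import DataError

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_peptides",
    "write_peptides",
    "read_counts",
    "write_counts",
    "read_terms",
    "read_gmt",
    "read_fasta",
    "write_fasta",
]


def write_matrix(m: pd.DataFrame, path) -> None:
    """Matrix TSV: rows = protein accessions, columns = voxel ids, empty cell
    = missing value."""
    m.to_csv(path, sep="\t", index_label="protein", na_rep="")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="protein")
    df.columns = [int(c) if str(c).isdigit() else c for c in df.columns]
    return df.astype(float)


def _format_mods(mods) -> str:
    return ";".join(f"{pos}:{shift:.4f}" for pos, shift in sorted(mods))


def _parse_mods(text) -> tuple[tuple[int, float], ...]:
    if not isinstance(text, str) or not text.strip():
        return ()
    events = []
    for item in text.split(";"):
        try:
            pos, shift = item.split(":")
            events.append((int(pos), float(shift)))
        except ValueError as exc:
            raise DataError(f"bad modification event {item!r}") from exc
    return tuple(events)


PEPTIDE_COLUMNS = [
    "peptide",
    "prev_aa",
    "next_aa",
    "protein",
    "voxel",
    "spectral_count",
    "assigned_modifications",
]


def write_peptides(records: list[PeptideRecord], path) -> None:
    rows = [
        {
            "peptide": r.sequence,
            "prev_aa": r.prev_aa,
            "next_aa": r.next_aa,
            "protein": r.protein,
            "voxel": r.voxel,
            "spectral_count": r.spectral_count,
            "assigned_modifications": _format_mods(r.modifications),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=PEPTIDE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_peptides(path) -> list[PeptideRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    missing = set(PEPTIDE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"peptide table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        voxel = int(row.voxel) if str(row.voxel).isdigit() else row.voxel
        records.append(
            PeptideRecord(
                sequence=row.peptide,
                prev_aa=row.prev_aa,
                next_aa=row.next_aa,
                protein=row.protein,
                voxel=voxel,
                spectral_count=int(row.spectral_count),
                modifications=_parse_mods(row.assigned_modifications),
            )
        )
    return records


def write_counts(table: pd.Series, path, label: str = "count") -> None:
    table.rename(label).rename_axis("protein").to_csv(path, sep="\t")


def read_counts(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="protein")
    return df.iloc[:, 0].astype(int)


def read_terms(path) -> dict[str, set[str]]:
    """Term membership TSV with columns term_id, accession."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"term_id", "accession"} <= set(df.columns):
        raise DataError("term table needs columns term_id, accession")
    out: dict[str, set[str]] = {}
    for term, acc in zip(df["term_id"], df["accession"]):
        out.setdefault(term, set()).add(acc)
    return out


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set format: term <tab> description <tab> member..."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = set(p for p in parts[2:] if p)
    return out


def read_fasta(path) -> list:
    """FASTA records; the accession is the first whitespace token of the header."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path) -> None:
    SeqIO.write(records, str(path), "fasta")
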