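"""Readers and writers for every format the pipeline touches.

FASTA for genomes (Biopython-backed, 80-column wrapping), tab-separated
UTF-8 tables with a header row and "NA" for missing values (profiles,
metadata, distance matrices, partitions, results), Roary-style CSV or plain
binary TSV for gene matrices, JSON for truth records and run manifests, and
Newick for the merge tree.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import Genome
from .clustering import SGB
from .sketching import DistanceMatrix
from .synthetic import GeneMatrix

__all__ = [
    "read_fasta", "write_fasta",
    "read_profile_table", "write_profile_table",
    "read_metadata", "write_metadata",
    "read_distance_matrix", "write_distance_matrix",
    "read_genome_catalogue", "write_genome_catalogue",
    "read_gene_matrix", "write_gene_matrix",
    "read_partition", "write_partition",
    "write_newick", "write_json", "read_json",
]

_NA = "NA"


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse a FASTA file into (id, uppercase sequence) pairs.

    Multi-contig files are supported; a zero-length record is rejected.
    """
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {i} ({rec.id!r}) has an empty sequence")
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path, width: int = 80) -> None:
    """Write (id, sequence) pairs as FASTA wrapped at ``width`` columns."""
    recs = [SeqRecord(Seq(seq), id=str(rid), description="") for rid, seq in records]
    writer_path = Path(path)
    with writer_path.open("w") as fh:
        for rec in recs:
            fh.write(f">{rec.id}\n")
            s = str(rec.seq)
            for start in range(0, len(s), width):
                fh.write(s[start:start + width] + "\n")


def write_genomes_fasta(genomes: list[Genome], directory) -> dict[str, Path]:
    """One FASTA per genome (contigs named <id>_c<N>); returns id -> path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for g in genomes:
        if g.sequences is None:
            raise ValueError(f"genome {g.id!r} has no in-memory sequences")
        path = directory / f"{g.id}.fasta"
        write_fasta([(f"{g.id}_c{i + 1}", seq) for i, seq in enumerate(g.sequences)],
                    path)
        paths[g.id] = path
    return paths


def read_profile_table(path, species_level_only: bool = True) -> pd.DataFrame:
    """Read a MetaPhlAn-style TSV (lineage rows x sample columns, percent).

    With ``species_level_only`` keeps rows whose lineage terminates at the
    s__ level (drops higher ranks and strain-level t__ rows).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index.name = "clade_name"
    if species_level_only:
        keep = [lin for lin in df.index
                if "s__" in str(lin) and not str(lin).split("|")[-1].startswith("t__")]
        df = df.loc[keep]
    return df.astype(float)


def write_profile_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="clade_name", na_rep=_NA)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: metadata must have a sample_id column")
    return df.set_index("sample_id")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id", na_rep=_NA)


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValueError(f"{path}: row and column labels differ")
    return DistanceMatrix(ids=ids, values=df.to_numpy(dtype=float))


def write_distance_matrix(d: DistanceMatrix, path) -> None:
    d.to_dataframe().to_csv(path, sep="\t", index_label="id")


_CATALOGUE_COLS = ["genome_id", "source_category", "origin", "site",
                   "completeness", "contamination", "sequence_path"]


def read_genome_catalogue(path) -> list[Genome]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_CATALOGUE_COLS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: catalogue missing columns {sorted(missing)}")
    genomes = []
    for _, row in df.iterrows():
        genomes.append(Genome(
            id=row["genome_id"],
            source_category=row.get("source_category", _NA) or _NA,
            origin=row.get("origin", "MAG"),
            site=row.get("site", ""),
            completeness=float(row["completeness"]) if row.get("completeness", "") not in ("", _NA) else 100.0,
            contamination=float(row["contamination"]) if row.get("contamination", "") not in ("", _NA) else 0.0,
            sequence_path=(row.get("sequence_path") or None),
        ))
    return genomes


def write_genome_catalogue(genomes: list[Genome], path) -> None:
    rows = [{"genome_id": g.id, "source_category": g.source_category,
             "origin": g.origin, "site": g.site or _NA,
             "completeness": g.completeness, "contamination": g.contamination,
             "sequence_path": g.sequence_path or _NA} for g in genomes]
    pd.DataFrame(rows, columns=_CATALOGUE_COLS).to_csv(path, sep="\t", index=False)


def read_gene_matrix(path, groups: pd.Series | None = None) -> GeneMatrix:
    """Read a gene presence/absence matrix.

    Roary-dialect CSV (a "Gene" column plus annotation columns; non-empty
    cells mark presence) and plain binary TSV (gene rows x genome columns
    of 0/1) are both accepted; gene rows are transposed to genome rows.
    ``groups`` maps genome id -> source label; defaults to NA.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if "Gene" not in df.columns:
            raise ValueError(f"{path}: Roary-style CSV needs a 'Gene' column")
        meta_cols = [c for c in df.columns
                     if c in _ROARY_META_COLS or c == "Gene"]
        genome_cols = [c for c in df.columns if c not in meta_cols]
        presence = (df[genome_cols] != "").T
        presence.columns = df["Gene"]
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        presence = (df.astype(float) > 0).T
    presence.index = pd.Index([str(i) for i in presence.index], name=None)
    presence.columns = pd.Index([str(c) for c in presence.columns], name=None)
    if groups is None:
        groups = pd.Series(_NA, index=presence.index, name="group")
    return GeneMatrix(presence=presence, groups=groups.reindex(presence.index).fillna(_NA))


_ROARY_META_COLS = {
    "Non-unique Gene name", "Annotation", "No. isolates", "No. sequences",
    "Avg sequences per isolate", "Genome Fragment", "Order within Fragment",
    "Accessory Fragment", "Accessory Order with Fragment", "QC",
    "Min group size nuc", "Max group size nuc", "Avg group size nuc",
}


def write_gene_matrix(matrix: GeneMatrix, path) -> None:
    """Write as plain binary TSV: gene rows x genome columns of 0/1."""
    (matrix.presence.astype(int).T).to_csv(path, sep="\t", index_label="gene_id")


def read_partition(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def write_partition(sgbs: list[SGB], path) -> None:
    rows = [{"genome_id": m, "sgb_id": s.sgb_id, "sgb_class": s.sgb_class or _NA}
            for s in sgbs for m in s.members]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick + ("\n" if not newick.endswith("\n") else ""))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return super().default(o)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
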