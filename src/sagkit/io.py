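"""Shared file formats: FASTA, newick, and the pipeline's CSV schemas.

Every file the package emits round-trips through the readers here.  CSV
schemas are validated on read with errors naming the missing column;
FASTA ids must be unique and records non-empty.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .synthdata import GenomeAssembly, KineticsPlate

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_assembly",
    "write_assembly",
    "read_newick",
    "write_newick",
    "read_events_csv",
    "write_events_csv",
    "read_kinetics_csv",
    "write_kinetics_csv",
    "read_annotations_csv",
    "write_annotations_csv",
    "read_distance_csv",
    "write_distance_csv",
]

_FLOAT_FORMAT = "%.10g"  # fixed float formatting keeps runs byte-identical


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    seqs: dict[str, str] = {}
    for i, record in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if record.id in seqs:
            raise ValueError(f"{path}: duplicate FASTA id {record.id!r} (record {i})")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty sequence for id {record.id!r} (record {i})")
        seqs[record.id] = seq
    if not seqs:
        raise ValueError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_assembly(path: str | Path, genome_id: str | None = None) -> GenomeAssembly:
    contigs = read_fasta(path)
    return GenomeAssembly(genome_id=genome_id or Path(path).stem, contigs=contigs)


def write_assembly(assembly: GenomeAssembly, path: str | Path) -> None:
    write_fasta(assembly.contigs, path)


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_newick(tree: TreeNode, path: str | Path) -> None:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    Path(path).write_text(buf.getvalue())


def _require_columns(df: pd.DataFrame, columns: tuple[str, ...], path) -> None:
    for col in columns:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")


EVENT_COLUMNS = ("event_id", "ssc_log10", "fl1_log10")


def read_events_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, EVENT_COLUMNS, path)
    return df


def write_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("event_id", "ssc_log10", "fl1_log10", "ssc", "fl1", "truth_class")
            if c in events.columns]
    events[cols].to_csv(path, index=False, float_format=_FLOAT_FORMAT)


KINETICS_COLUMNS = ("well", "template_cells", "t_hours", "fluorescence")


def read_kinetics_csv(path: str | Path) -> KineticsPlate:
    df = pd.read_csv(path)
    _require_columns(df, KINETICS_COLUMNS, path)
    truth = (
        df[["well", "template_cells"]]
        .drop_duplicates()
        .reset_index(drop=True)
        .assign(true_midpoint_hours=float("nan"))
    )
    return KineticsPlate(curves=df, truth=truth)


def write_kinetics_csv(plate: KineticsPlate, path: str | Path) -> None:
    plate.curves[list(KINETICS_COLUMNS)].to_csv(
        path, index=False, float_format=_FLOAT_FORMAT
    )


ANNOTATION_COLUMNS = ("genome_id", "gene_id", "class", "copies")


def read_annotations_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ANNOTATION_COLUMNS, path)
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    return df


def write_annotations_csv(annot: pd.DataFrame, path: str | Path) -> None:
    annot.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_distance_csv(path: str | Path):
    """Square distance matrix CSV with header row and index column."""
    from skbio import DistanceMatrix

    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return DistanceMatrix(df.to_numpy(), ids=list(df.columns))


def write_distance_csv(dm, path: str | Path) -> None:
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path, float_format=_FLOAT_FORMAT
    )
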