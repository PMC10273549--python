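"""Readers and writers for the plain-text formats the pipeline consumes.

All genomic intervals are 0-based half-open in memory; 1-based inclusive
coordinates appear only at the GFF3/depth-table boundary, per those formats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")
    return path


# ---------------------------------------------------------------------------
# Gene models (GFF3)

@dataclass(frozen=True)
class GeneModel:
    """A gene with optional exon structure.

    ``start``/``end`` and exon intervals are 0-based half-open on ``seqid``.
    """

    gene_id: str
    seqid: str
    start: int
    end: int
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval for gene {self.gene_id}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def region(self) -> tuple[tuple[int, int], ...]:
        """Intervals used for coverage: exon union if annotated, else the span."""
        if self.exons:
            return merge_intervals(self.exons)
        return ((self.start, self.end),)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of half-open intervals, sorted and merged."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene and exon features from a GFF3 file (1-based inclusive on disk)."""
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            seqid, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID", attr.get("Name", ""))
                genes[gid] = {
                    "seqid": seqid,
                    "start": int(start) - 1,
                    "end": int(end),
                    "strand": strand,
                }
            elif ftype == "exon":
                parent = attr.get("Parent", "")
                exons.setdefault(parent, []).append((int(start) - 1, int(end)))
    return [
        GeneModel(
            gene_id=gid,
            exons=tuple(sorted(exons.get(gid, []))),
            **info,
        )
        for gid, info in genes.items()
    ]


def write_gff3(genes: Sequence[GeneModel], path: str | Path, source: str = "pavpan") -> Path:
    path = Path(path)
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for g in genes:
            out.write(
                f"{g.seqid}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                out.write(
                    f"{g.seqid}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
    return path


# ---------------------------------------------------------------------------
# Depth tables

class DepthTable:
    """Per-position read depth, indexed by sequence id.

    Built from a 3-column TSV (seqid, 1-based position, integer depth).
    Positions absent from the table have depth 0.
    """

    def __init__(self, per_seq: Mapping[str, tuple[np.ndarray, np.ndarray]]):
        # per_seq: seqid -> (sorted 0-based positions, depths)
        self._per_seq = dict(per_seq)

    @classmethod
    def from_records(cls, seqids: Sequence[str], positions: Sequence[int], depths: Sequence[int]) -> "DepthTable":
        """Build from parallel arrays; positions are 1-based."""
        df = pd.DataFrame({
            "seqid": seqids,
            "pos": np.asarray(positions, dtype=np.int64) - 1,
            "depth": np.asarray(depths, dtype=np.int64),
        })
        per_seq = {}
        for seqid, sub in df.groupby("seqid", sort=False):
            order = np.argsort(sub["pos"].to_numpy(), kind="stable")
            per_seq[str(seqid)] = (
                sub["pos"].to_numpy()[order],
                sub["depth"].to_numpy()[order],
            )
        return cls(per_seq)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DepthTable":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["seqid", "pos", "depth"],
            dtype={"seqid": str, "pos": np.int64, "depth": np.int64},
            comment="#",
        )
        return cls.from_records(df["seqid"], df["pos"], df["depth"])

    def positions_at_least(self, seqid: str, start: int, end: int, min_depth: int) -> int:
        """Number of positions in [start, end) with depth >= min_depth."""
        if seqid not in self._per_seq:
            return 0
        pos, depth = self._per_seq[seqid]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return int(np.count_nonzero(depth[lo:hi] >= min_depth))


def write_depth_tsv(depth_rows: Iterable[tuple[str, int, int]], path: str | Path) -> Path:
    """Write (seqid, 1-based position, depth) rows as TSV."""
    path = Path(path)
    with open(path, "w") as out:
        for seqid, pos, depth in depth_rows:
            out.write(f"{seqid}\t{pos}\t{depth}\n")
    return path


# ---------------------------------------------------------------------------
# Simple two-column tables

def read_labels(path: str | Path) -> pd.Series:
    """Accession -> group label series from a 2-column TSV with header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return df.set_index(df.columns[0])[df.columns[1]]


def read_phenotype(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    df.iloc[:, 0] = df.iloc[:, 0].astype(str)
    return df.set_index(df.columns[0])[df.columns[1]]


# ---------------------------------------------------------------------------
# Alignment TSV (7 columns)

ALIGNMENT_COLUMNS = ["query", "qstart", "qend", "ref", "rstart", "rend", "identity"]


def read_alignment_tsv(path: str | Path, one_based_inclusive: bool = False) -> pd.DataFrame:
    """Read an external alignment table.

    With ``one_based_inclusive=True`` the coordinate dialect of
    ``show-coords`` (1-based inclusive) is converted to the native 0-based
    half-open convention.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=ALIGNMENT_COLUMNS, comment="#")
    if one_based_inclusive:
        for col in ("qstart", "rstart"):
            df[col] = df[col] - 1
    return df


# ---------------------------------------------------------------------------
# Manifest

def write_manifest(paths: Mapping[str, str | Path | list], path: str | Path) -> Path:
    path = Path(path)
    serializable = {
        k: [str(x) for x in v] if isinstance(v, list) else str(v)
        for k, v in paths.items()
    }
    path.write_text(json.dumps(serializable, indent=2, sort_keys=True) + "\n")
    return path
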