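"""Gene presence/absence calling from read depth, and pan-gene occupancy.

A gene is called *lost* in an accession when the fraction of its region
covered by at least ``minCov`` reads falls below ``lostCutoff`` (the
SGSGeneLoss criterion, minCov=2 / lostCutoff=0.2 by default). The gene region
is the union of exon intervals when exons are annotated, otherwise the gene
span. Pan-genes are then classified by their presence frequency across
accessions into core (all), softcore (>= 99% but not all), shell (1-99%) and
cloud (< 1%) classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DepthTable, GeneModel

OCCUPANCY_CLASSES = ("core", "softcore", "shell", "cloud")


@dataclass(frozen=True)
class PAVParams:
    """Presence/absence and occupancy thresholds.

    ``strict_uncovered`` switches to the alternative reading of the loss rule
    (lost iff the *uncovered* fraction is >= lostCutoff) instead of the
    default SGSGeneLoss semantics (lost iff the covered fraction is below
    lostCutoff). The two differ only at the boundary.
    """

    min_cov: int = 2
    lost_cutoff: float = 0.2
    softcore_min: float = 0.99
    cloud_max: float = 0.01
    strict_uncovered: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.lost_cutoff < 1.0:
            raise ValueError("lost_cutoff must be in (0, 1)")
        if not 0.0 < self.cloud_max < self.softcore_min < 1.0:
            raise ValueError("need 0 < cloud_max < softcore_min < 1")
        if self.min_cov < 1:
            raise ValueError("min_cov must be >= 1")


def gene_covered_fraction(
    depth: DepthTable, gene: GeneModel, min_cov: int = 2
) -> float:
    """Fraction of the gene region with depth >= ``min_cov``.

    Positions missing from the depth table count as depth 0.
    """
    region = gene.region()
    total = sum(e - s for s, e in region)
    if total <= 0:
        raise ValueError(f"empty gene region for {gene.gene_id}")
    covered = sum(
        depth.positions_at_least(gene.seqid, s, e, min_cov) for s, e in region
    )
    return covered / total


def call_pav(fraction: float, params: PAVParams = PAVParams()) -> int:
    """1 (present) or 0 (absent) from a covered fraction.

    Default semantics: absent iff fraction < lost_cutoff, so a gene with a
    covered fraction exactly at the cutoff is called present.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction outside [0, 1]")
    if params.strict_uncovered:
        return 0 if (1.0 - fraction) >= (1.0 - params.lost_cutoff) else 1
    return 0 if fraction < params.lost_cutoff else 1


@dataclass
class PAVMatrix:
    """Binary genes x accessions presence/absence table with group labels."""

    matrix: pd.DataFrame  # index: gene ids; columns: accession ids; values 0/1
    labels: pd.Series  # accession -> group

    def __post_init__(self) -> None:
        if self.matrix.isna().any().any():
            raise ValueError("PAV matrix has missing cells")
        missing = [a for a in self.matrix.columns if a not in self.labels.index]
        if missing:
            raise ValueError(f"accessions missing from labels: {missing[:5]}")
        self.labels = self.labels.loc[self.matrix.columns]

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def accessions(self) -> pd.Index:
        return self.matrix.columns

    def presence_frequency(self) -> pd.Series:
        """Per-gene presence frequency across all accessions."""
        return self.matrix.mean(axis=1)

    def all_absent_genes(self) -> list[str]:
        """Genes absent in every accession — flagged, never silently dropped."""
        return list(self.matrix.index[self.matrix.sum(axis=1) == 0])

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path, labels: pd.Series) -> "PAVMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = df.columns.astype(str)
        return cls(matrix=df, labels=labels)


def build_matrix(
    depth_tables: Mapping[str, DepthTable],
    genes: Sequence[GeneModel],
    labels: pd.Series,
    params: PAVParams = PAVParams(),
) -> PAVMatrix:
    """Call presence/absence for every gene in every accession."""
    missing = [a for a in depth_tables if a not in labels.index]
    if missing:
        raise ValueError(f"accessions missing from labels: {missing[:5]}")
    accessions = list(depth_tables)
    data = np.zeros((len(genes), len(accessions)), dtype=np.int8)
    for j, acc in enumerate(accessions):
        depth = depth_tables[acc]
        for i, gene in enumerate(genes):
            frac = gene_covered_fraction(depth, gene, params.min_cov)
            data[i, j] = call_pav(frac, params)
    matrix = pd.DataFrame(
        data, index=[g.gene_id for g in genes], columns=accessions
    )
    return PAVMatrix(matrix=matrix, labels=labels.loc[accessions])


def classify_occupancy(
    pav: PAVMatrix, params: PAVParams = PAVParams()
) -> pd.DataFrame:
    """Core/softcore/shell/cloud classification by presence frequency.

    Boundaries: core f = 1; softcore softcore_min <= f < 1; shell
    cloud_max <= f < softcore_min; cloud 0 < f < cloud_max. Genes with f = 0
    are classified cloud and also reported by ``PAVMatrix.all_absent_genes``.
    """
    f = pav.presence_frequency()
    cls = pd.Series("shell", index=f.index, dtype=object)
    cls[f >= params.softcore_min] = "softcore"
    cls[f == 1.0] = "core"
    cls[f < params.cloud_max] = "cloud"
    out = pd.DataFrame({"frequency": f, "occupancy": cls})
    out.index.name = "gene"
    return out


def occupancy_counts(occupancy: pd.DataFrame) -> pd.Series:
    """Counts per occupancy class; always sums to the number of genes."""
    counts = occupancy["occupancy"].value_counts()
    return counts.reindex(OCCUPANCY_CLASSES, fill_value=0)
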