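"""Resistance-gene-analog summaries, QTL overlap and variant tallies.

RGA subfamily labels (RGAugury-style) and variant consequences (VEP-style)
are consumed as tables; the computations here are the crosstabs, densities,
interval intersections and per-gene mutation tallies built on top of them.
Occupancy classes collapse to two groups: *variable* (cloud + shell) and
*core-group* (core + softcore).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

RGA_SUBFAMILIES = (
    "CN", "CNL", "NBS", "NL", "RLK", "RLP", "TMCC", "TN", "TNL", "TX", "OTHER",
)
LOCATIONS = ("reference", "additional_contig")
CONSEQUENCE_VOCAB = (
    "start_lost", "stop_gained", "stop_lost", "missense_variant",
    "synonymous_variant", "intron_variant", "splice_region_variant",
    "frameshift_variant", "inframe_deletion", "inframe_insertion",
    "5_prime_UTR_variant", "3_prime_UTR_variant",
)

# subfamilies conventionally pooled as NBS-LRR (everything that is not a
# receptor-like kinase/protein or transmembrane coiled-coil)
NBS_LRR_SUBFAMILIES = ("CN", "CNL", "NBS", "NL", "TN", "TNL", "TX", "OTHER")


@dataclass(frozen=True)
class QTLInterval:
    """A QTL region, 0-based half-open."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty QTL interval {self.name}")

    @property
    def span(self) -> int:
        return self.end - self.start


def read_qtl_bed(path) -> list[QTLInterval]:
    """BED (0-based half-open on disk): chrom, start, end, name."""
    qtls = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, *rest = line.split()
            name = rest[0] if rest else f"{chrom}:{start}-{end}"
            qtls.append(QTLInterval(name=name, chrom=chrom, start=int(start), end=int(end)))
    return qtls


def _occupancy_group(occ_class: str) -> str:
    if occ_class in ("core", "softcore"):
        return "core_group"
    if occ_class in ("shell", "cloud"):
        return "variable"
    raise ValueError(f"unknown occupancy class {occ_class!r}")


def crosstab_rga(annotations: pd.DataFrame, occupancy: pd.DataFrame) -> pd.DataFrame:
    """Subfamily x location crosstab of core-group vs variable RGA counts.

    ``annotations`` columns: gene, subfamily, location (+ optional chrom,
    start, end). Every annotated gene must have an occupancy class. Rows are
    subfamilies plus a ``Total`` row; for each location and for the pangenome
    union there are ``total``, ``variable`` and ``core_group`` columns —
    the additive layout of a pan-genome RGA summary table.
    """
    bad = set(annotations["subfamily"]) - set(RGA_SUBFAMILIES)
    if bad:
        raise ValueError(f"unknown RGA subfamilies: {sorted(bad)}")
    missing = [g for g in annotations["gene"] if g not in occupancy.index]
    if missing:
        raise ValueError(f"genes without occupancy class: {missing[:5]}")

    df = annotations.copy()
    df["group"] = [
        _occupancy_group(occupancy.loc[g, "occupancy"]) for g in df["gene"]
    ]
    out = pd.DataFrame(
        0,
        index=list(RGA_SUBFAMILIES) + ["Total"],
        columns=pd.MultiIndex.from_product(
            [list(LOCATIONS) + ["pangenome"], ["total", "variable", "core_group"]]
        ),
    )
    for (subfam, loc, grp), n in df.groupby(["subfamily", "location", "group"]).size().items():
        for where in (loc, "pangenome"):
            out.loc[subfam, (where, "total")] += n
            out.loc[subfam, (where, grp)] += n
    out.loc["Total"] = out.loc[list(RGA_SUBFAMILIES)].sum(axis=0)
    return out


def variable_fraction(crosstab: pd.DataFrame, subfamilies) -> float:
    """Fraction of variable genes among the pooled subfamilies (pangenome-wide)."""
    rows = list(subfamilies)
    total = int(crosstab.loc[rows, ("pangenome", "total")].sum())
    if total == 0:
        return 0.0
    variable = int(crosstab.loc[rows, ("pangenome", "variable")].sum())
    return variable / total


def annotations_from_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand a published subfamily/location count summary into synthetic
    per-gene annotation and occupancy tables.

    ``counts`` columns: subfamily, location, variable, core. Variable genes
    get occupancy class ``shell`` and core-group genes ``core`` (the crosstab
    only distinguishes the pooled groups). Returns (annotations, occupancy)
    ready for :func:`crosstab_rga`.
    """
    ann_rows, occ_rows = [], []
    i = 0
    for rec in counts.itertuples(index=False):
        for occ_class, n in (("shell", int(rec.variable)), ("core", int(rec.core))):
            for _ in range(n):
                i += 1
                gid = f"rga{i:04d}"
                ann_rows.append({
                    "gene": gid, "subfamily": rec.subfamily, "location": rec.location,
                })
                occ_rows.append({"gene": gid, "occupancy": occ_class})
    annotations = pd.DataFrame(ann_rows, columns=["gene", "subfamily", "location"])
    occupancy = pd.DataFrame(occ_rows).set_index("gene") if occ_rows else (
        pd.DataFrame(columns=["occupancy"]).rename_axis("gene")
    )
    return annotations, occupancy


def rga_density(annotations: pd.DataFrame, chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Genes per Mb, per chromosome per subfamily; unplaced genes separate.

    Returns a table indexed by chromosome with one column per subfamily plus
    ``all``; an ``unplaced`` attribute lists genes without coordinates.
    """
    placed = annotations.dropna(subset=["chrom"]) if "chrom" in annotations else annotations.iloc[0:0]
    out = pd.DataFrame(
        0.0, index=sorted(chrom_lengths), columns=list(RGA_SUBFAMILIES) + ["all"]
    )
    for chrom, length in chrom_lengths.items():
        mb = length / 1e6
        sub = placed[placed["chrom"] == chrom]
        for fam in RGA_SUBFAMILIES:
            out.loc[chrom, fam] = (sub["subfamily"] == fam).sum() / mb
        out.loc[chrom, "all"] = len(sub) / mb
    out.attrs["unplaced"] = (
        [] if "chrom" not in annotations
        else list(annotations.loc[annotations["chrom"].isna(), "gene"])
    )
    return out


def qtl_gene_overlap(genes: pd.DataFrame, qtls: list[QTLInterval]) -> pd.DataFrame:
    """All (gene, QTL) pairs with >= 1 bp intersection under half-open
    arithmetic.

    ``genes`` columns: gene, chrom, start, end (0-based half-open). A sorted
    sweep per chromosome; output is ordered by (gene, qtl).
    """
    rows = []
    by_chrom: dict[str, list[QTLInterval]] = {}
    for q in qtls:
        by_chrom.setdefault(q.chrom, []).append(q)
    for q_list in by_chrom.values():
        q_list.sort(key=lambda q: q.start)
    for rec in genes.sort_values(["chrom", "start"]).itertuples(index=False):
        for q in by_chrom.get(rec.chrom, ()):
            if q.start >= rec.end:
                break
            ov = min(rec.end, q.end) - max(rec.start, q.start)
            if ov >= 1:
                rows.append((rec.gene, q.name, ov))
    out = pd.DataFrame(rows, columns=["gene", "qtl", "overlap_bp"])
    return out.sort_values(["gene", "qtl"]).reset_index(drop=True)


def mean_qtl_span_mb(qtls: list[QTLInterval]) -> float:
    """Mean QTL span in Mb."""
    if not qtls:
        raise ValueError("no QTL intervals")
    return sum(q.span for q in qtls) / len(qtls) / 1e6


def variant_tally(
    consequences: pd.DataFrame, gene_set: list[str], n_accessions: int
) -> pd.DataFrame:
    """Per-gene mutation frequency and consequence composition.

    ``consequences`` columns: gene, accession, consequence. Mutation
    frequency = accessions with >= 1 consequence in the gene / n_accessions.
    Rows are ranked by decreasing frequency with gene-id tie-break; genes in
    ``gene_set`` without records get zeroes.
    """
    if n_accessions < 1:
        raise ValueError("n_accessions must be >= 1")
    bad = set(consequences["consequence"]) - set(CONSEQUENCE_VOCAB)
    if bad:
        raise ValueError(f"consequences outside the declared vocabulary: {sorted(bad)}")
    sub = consequences[consequences["gene"].isin(gene_set)]
    rows = []
    for gene in gene_set:
        g = sub[sub["gene"] == gene]
        comp = {c: int((g["consequence"] == c).sum()) for c in CONSEQUENCE_VOCAB}
        rows.append({
            "gene": gene,
            "n_mutated_accessions": g["accession"].nunique(),
            "mutation_frequency": g["accession"].nunique() / n_accessions,
            **comp,
        })
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["mutation_frequency", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
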