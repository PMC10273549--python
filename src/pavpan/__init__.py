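"""pavpan: pan-genome gene presence/absence variation analysis.

Map-to-pan construction from assembled contigs, depth-based gene PAV calling
and occupancy classification, Fisher-exact selection scans across a
domestication series, gene-PAV GWAS, resistance-gene/QTL summaries and NG86
Ka/Ks — with a synthetic-data generator providing ground-truth datasets.
"""

from importlib import resources

import pandas as pd

from .io import (
    DepthTable, GeneModel, read_fasta, write_fasta, read_gff3, write_gff3,
    read_labels, read_phenotype, read_alignment_tsv,
)
from .panbuild import (
    AlignmentBlock, PanBuildParams, NonRefSegment, align_contigs,
    classify_contigs, filter_short_contigs, remove_redundancy,
    filter_contamination, build_pangenome,
)
from .pav import (
    PAVParams, PAVMatrix, gene_covered_fraction, call_pav, build_matrix,
    classify_occupancy, occupancy_counts,
)
from .selection import (
    SelectionParams, group_frequencies, fisher_pav_test, bh_fdr,
    classify_selected, selection_scan,
)
from .gwas import (
    GwasParams, encode_genotypes, pav_pca, association_scan,
    bonferroni_threshold, group_frequency_summary,
)
from .rga import (
    QTLInterval, crosstab_rga, annotations_from_counts, variable_fraction,
    rga_density, qtl_gene_overlap, mean_qtl_span_mb, variant_tally,
    read_qtl_bed, NBS_LRR_SUBFAMILIES,
)
from .kaks import (
    CodingSequencePair, KaKsResult, apply_snps_to_cds, ng86_kaks, kaks_table,
)
from .synthetic import (
    SimConfig, TruthTable, DatasetBundle, generate_dataset, write_dataset,
    bundle_digest, simulate_pav_matrix,
)

__version__ = "0.1.0"


def load_rga_counts() -> pd.DataFrame:
    """Published watermelon RGA subfamily/location counts shipped with the
    package (variable = cloud + shell, core = core + softcore)."""
    with resources.files("pavpan.data").joinpath("watermelon_rga_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_pan_gene_counts() -> pd.Series:
    """Published watermelon pan-gene headline counts (category -> count)."""
    with resources.files("pavpan.data").joinpath("watermelon_pan_gene_counts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df.set_index("category")["count"]


def load_gsb_qtl() -> list:
    """Synthetic stand-in BED for the three gummy stem blight QTLs."""
    path = resources.files("pavpan.data").joinpath("gsb_qtl_synthetic.bed")
    return read_qtl_bed(str(path))
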