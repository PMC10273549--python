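"""Synthetic population datasets with known PAV ground truth.

Emulates, at desk scale, the inputs of a pan-genome PAV study of a
domestication series: a reference genome with gene models, per-accession
assembled contigs (reference substrings for present genes, plus planted novel
sequences absent from the reference), per-accession read-depth tables around
the presence/absence calling boundary, group labels for a wild relative /
landrace / cultivar series, a binary phenotype driven by one causal shell
gene, and CDS + SNP inputs for Ka/Ks.

Default design (fractions of the reference gene set):
60% core genes (never lost), 15% shell genes lost uniformly across groups,
15% selection-like genes with group-differential loss, 10% cloud-like genes
present in very few accessions; novel genes are shell-like. Per-position
depth is Poisson around ``depth_present`` (10 reads) for present genes and
``depth_absent`` (0) for lost genes, stressing the minCov = 2 boundary from
both sides. Contigs carry 1% substitution noise by default so the 90%
identity rule is exercised without being violated.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .io import DepthTable, GeneModel
from .pav import PAVMatrix
from .kaks import SENSE_CODONS

_GC35 = np.array([0.325, 0.175, 0.175, 0.325])  # A C G T, GC ~ 0.35
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset."""

    seed: int = 0
    n_ref_genes: int = 40
    ref_gene_length: int = 600
    n_novel_genes: int = 10
    groups: tuple[tuple[str, int], ...] = (
        ("CM", 15), ("CL-landrace", 20), ("CL-cultivar", 25),
    )
    # absence frequency per gene per group; None -> default design
    loss_freq_table: pd.DataFrame | None = None
    depth_present: float = 10.0
    depth_absent: float = 0.0
    depth_noise: str = "poisson"  # "poisson" or "constant" (noise off)
    min_cov: int = 2
    novel_seq_length: int = 800
    phenotype_effect_gene: str | None = "auto"
    phenotype_flip_prob: float = 0.0
    contig_noise_rate: float = 0.01
    contig_flank: int = 200
    intergenic_spacer: int = 400
    n_cds_genes: int = 8
    cds_length: int = 300
    snp_rate: float = 0.01

    def __post_init__(self) -> None:
        for name in ("n_ref_genes", "ref_gene_length", "n_novel_genes",
                     "novel_seq_length", "n_cds_genes", "cds_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.groups:
            raise ValueError("at least one group is required")
        for name, n in self.groups:
            if n <= 0:
                raise ValueError(f"group {name!r} has zero accessions")
        for rate in (self.phenotype_flip_prob, self.contig_noise_rate, self.snp_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if not self.depth_absent < self.min_cov <= self.depth_present:
            raise ValueError("need depth_absent < min_cov <= depth_present")
        if self.depth_noise not in ("poisson", "constant"):
            raise ValueError("depth_noise must be 'poisson' or 'constant'")
        if self.loss_freq_table is not None:
            vals = self.loss_freq_table.to_numpy(dtype=float)
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError("loss frequencies must be in [0, 1]")


@dataclass
class TruthTable:
    """Planted ground truth: per-accession presence, causal and selected genes."""

    presence: pd.DataFrame  # genes x accessions, 0/1
    causal_gene: str | None
    selected_gene_ids: set[str]
    loss_design: pd.DataFrame  # genes x groups, planted absence frequency


@dataclass
class DatasetBundle:
    """In-memory synthetic dataset; ``write`` serializes it to plain text."""

    config: SimConfig
    reference: dict[str, str]
    genes: list[GeneModel]  # reference + novel gene models
    novel_sequences: dict[str, str]
    contigs: dict[str, dict[str, str]]  # accession -> {contig id: sequence}
    depths: dict[str, DepthTable]
    labels: pd.Series  # accession -> group
    phenotype: pd.Series  # accession -> 0/1
    cds: dict[str, str]
    snp_table: pd.DataFrame
    truth: TruthTable

    @property
    def accessions(self) -> list[str]:
        return list(self.labels.index)

    def depth_rows(self, accession: str):
        table = self.depths[accession]
        for seqid, (pos, depth) in table._per_seq.items():
            for p, d in zip(pos.tolist(), depth.tolist()):
                yield seqid, p + 1, int(d)

    def truth_matrix(self) -> PAVMatrix:
        return PAVMatrix(matrix=self.truth.presence.copy(), labels=self.labels)


# ---------------------------------------------------------------------------
# helpers

def _random_seq(rng: np.random.Generator, length: int, probs=None) -> str:
    return "".join(_BASES[rng.choice(4, size=length, p=probs)])


def _novel_sequence(rng: np.random.Generator, length: int, ref_kmers: set, k: int = 21) -> str:
    """Random GC~0.35 sequence sharing no k-mer with the reference."""
    seq = list(_random_seq(rng, length, _GC35))
    for _ in range(50):
        shared = [
            i for i in range(length - k + 1)
            if "".join(seq[i : i + k]) in ref_kmers
        ]
        if not shared:
            break
        for i in shared:
            j = i + k // 2
            current = seq[j]
            choices = [b for b in "ACGT" if b != current]
            seq[j] = choices[int(rng.integers(3))]
    return "".join(seq)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def default_loss_design(config: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, set[str], str | None]:
    """Planted per-gene per-group absence frequencies.

    Returns (design, selected gene ids, causal gene id). The derived group is
    the last group in ``config.groups``; selection-like genes are lost in the
    first (wild) group and retained in the derived one.
    """
    ref_ids = [f"gene{i + 1:04d}" for i in range(config.n_ref_genes)]
    novel_ids = [f"novel{i + 1:04d}" for i in range(config.n_novel_genes)]
    group_names = [g for g, _ in config.groups]
    design = pd.DataFrame(0.0, index=ref_ids + novel_ids, columns=group_names)

    n = config.n_ref_genes
    n_core = int(round(0.60 * n))
    n_shell = int(round(0.15 * n))
    n_sel = int(round(0.15 * n))
    shell_ids = ref_ids[n_core : n_core + n_shell]
    sel_ids = ref_ids[n_core + n_shell : n_core + n_shell + n_sel]
    cloud_ids = ref_ids[n_core + n_shell + n_sel :]

    for gid in shell_ids:
        design.loc[gid, :] = 0.5
    for gid in sel_ids:
        # lost in the wild group, retained in the most derived group
        design.loc[gid, group_names[0]] = 0.9
        if len(group_names) > 2:
            design.loc[gid, group_names[1]] = 0.5
        design.loc[gid, group_names[-1]] = 0.05
    for gid in cloud_ids:
        design.loc[gid, :] = 0.97
    for gid in novel_ids:
        design.loc[gid, :] = 0.5

    causal = shell_ids[0] if shell_ids else None
    return design, set(sel_ids), causal


# ---------------------------------------------------------------------------
# generation

def generate_dataset(config: SimConfig = SimConfig()) -> DatasetBundle:
    """Generate the full bundle; the same config (seed included) reproduces it
    byte-for-byte."""
    rng = np.random.default_rng(config.seed)

    # reference chromosome with evenly spaced genes
    spacer = config.intergenic_spacer
    glen = config.ref_gene_length
    unit = glen + 2 * spacer
    chrom_len = config.n_ref_genes * unit
    chrom = "chr1"
    ref_seq = _random_seq(rng, chrom_len)
    reference = {chrom: ref_seq}

    genes: list[GeneModel] = []
    for i in range(config.n_ref_genes):
        start = i * unit + spacer
        genes.append(GeneModel(
            gene_id=f"gene{i + 1:04d}", seqid=chrom, start=start, end=start + glen,
        ))

    # novel sequences sharing no 21-mer with the reference
    k = 21
    ref_kmers = {ref_seq[i : i + k] for i in range(len(ref_seq) - k + 1)}
    novel_sequences: dict[str, str] = {}
    for i in range(config.n_novel_genes):
        nid = f"novel{i + 1:04d}"
        novel_sequences[nid] = _novel_sequence(rng, config.novel_seq_length, ref_kmers)
        genes.append(GeneModel(
            gene_id=nid, seqid=nid, start=0, end=config.novel_seq_length,
        ))

    # planted presence design
    if config.loss_freq_table is not None:
        design = config.loss_freq_table.copy()
        selected_ids: set[str] = set()
        causal = None
    else:
        design, selected_ids, causal = default_loss_design(config, rng)
    if config.phenotype_effect_gene not in (None, "auto"):
        causal = config.phenotype_effect_gene
    elif config.phenotype_effect_gene is None:
        causal = None

    accessions: list[str] = []
    labels_vals: list[str] = []
    for gname, gn in config.groups:
        for j in range(gn):
            accessions.append(f"{gname}_{j + 1:02d}")
            labels_vals.append(gname)
    labels = pd.Series(labels_vals, index=accessions, name="group")

    gene_ids = [g.gene_id for g in genes]
    presence = pd.DataFrame(0, index=gene_ids, columns=accessions, dtype=np.int8)
    for gid in gene_ids:
        for acc, grp in labels.items():
            p_absent = float(design.loc[gid, grp]) if gid in design.index else 0.0
            presence.loc[gid, acc] = 0 if rng.random() < p_absent else 1

    # phenotype from the causal gene, with optional label flips
    if causal is not None:
        base = presence.loc[causal].to_numpy(dtype=int)
        flips = rng.random(len(accessions)) < config.phenotype_flip_prob
        pheno_vals = np.where(flips, 1 - base, base)
    else:
        pheno_vals = rng.integers(0, 2, size=len(accessions))
    phenotype = pd.Series(pheno_vals.astype(int), index=accessions, name="phenotype")

    # per-accession contigs and depth tables
    contigs: dict[str, dict[str, str]] = {}
    depths: dict[str, DepthTable] = {}
    flank = config.contig_flank
    for acc in accessions:
        acc_contigs: dict[str, str] = {}
        per_seq: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        chrom_pos: list[np.ndarray] = []
        chrom_depth: list[np.ndarray] = []
        for g in genes:
            present = bool(presence.loc[g.gene_id, acc])
            mean_depth = config.depth_present if present else config.depth_absent
            if config.depth_noise == "poisson":
                d = rng.poisson(mean_depth, size=g.length).astype(np.int64)
            else:
                d = np.full(g.length, int(round(mean_depth)), dtype=np.int64)
            if g.seqid == chrom:
                chrom_pos.append(np.arange(g.start, g.end, dtype=np.int64))
                chrom_depth.append(d)
            else:
                per_seq[g.seqid] = (np.arange(g.start, g.end, dtype=np.int64), d)
            if not present:
                continue
            if g.seqid == chrom:
                s = max(0, g.start - flank)
                e = min(chrom_len, g.end + flank)
                seq = _mutate(rng, ref_seq[s:e], config.contig_noise_rate)
                acc_contigs[f"ctg_{g.gene_id}"] = seq
            else:
                acc_contigs[f"ctg_{g.gene_id}"] = novel_sequences[g.gene_id]
        if chrom_pos:
            per_seq = {chrom: (np.concatenate(chrom_pos), np.concatenate(chrom_depth)), **per_seq}
        contigs[acc] = acc_contigs
        depths[acc] = DepthTable(per_seq)

    # CDS + SNPs for Ka/Ks
    cds: dict[str, str] = {}
    snp_rows: list[dict] = []
    n_codons = config.cds_length // 3
    for i in range(config.n_cds_genes):
        gid = f"cds{i + 1:03d}"
        codons = [SENSE_CODONS[int(j)] for j in rng.integers(0, len(SENSE_CODONS), size=n_codons)]
        seq = "".join(codons)
        cds[gid] = seq
        for pos in np.flatnonzero(rng.random(len(seq)) < config.snp_rate):
            ref_base = seq[pos]
            alt = [b for b in "ACGT" if b != ref_base][int(rng.integers(3))]
            snp_rows.append({
                "gene_id": gid, "cds_position": int(pos) + 1,
                "ref_base": ref_base, "alt_base": alt,
            })
    snp_table = pd.DataFrame(
        snp_rows, columns=["gene_id", "cds_position", "ref_base", "alt_base"]
    )

    truth = TruthTable(
        presence=presence, causal_gene=causal,
        selected_gene_ids=selected_ids, loss_design=design,
    )
    return DatasetBundle(
        config=config, reference=reference, genes=genes,
        novel_sequences=novel_sequences, contigs=contigs, depths=depths,
        labels=labels, phenotype=phenotype, cds=cds, snp_table=snp_table,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# serialization

def write_dataset(bundle: DatasetBundle, directory: str | Path) -> dict:
    """Write the bundle as plain-text files and a JSON manifest.

    Layout: reference.fasta, genes.gff3, labels.tsv, phenotype.tsv,
    cds.fasta, snps.tsv, truth.json, contigs/<accession>.fasta,
    depth/<accession>.depth.tsv.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "contigs").mkdir(exist_ok=True)
    (directory / "depth").mkdir(exist_ok=True)

    manifest: dict = {}
    manifest["reference"] = pio.write_fasta(bundle.reference, directory / "reference.fasta")
    manifest["genes"] = pio.write_gff3(bundle.genes, directory / "genes.gff3")
    labels_df = bundle.labels.rename_axis("accession").reset_index()
    labels_df.to_csv(directory / "labels.tsv", sep="\t", index=False)
    manifest["labels"] = directory / "labels.tsv"
    pheno_df = bundle.phenotype.rename_axis("accession").reset_index()
    pheno_df.to_csv(directory / "phenotype.tsv", sep="\t", index=False)
    manifest["phenotype"] = directory / "phenotype.tsv"
    manifest["cds"] = pio.write_fasta(bundle.cds, directory / "cds.fasta")
    bundle.snp_table.to_csv(directory / "snps.tsv", sep="\t", index=False)
    manifest["snps"] = directory / "snps.tsv"

    contig_paths, depth_paths = [], []
    for acc in bundle.accessions:
        cpath = directory / "contigs" / f"{acc}.fasta"
        pio.write_fasta(bundle.contigs[acc], cpath)
        contig_paths.append(cpath)
        dpath = directory / "depth" / f"{acc}.depth.tsv"
        pio.write_depth_tsv(bundle.depth_rows(acc), dpath)
        depth_paths.append(dpath)
    manifest["contigs"] = contig_paths
    manifest["depth"] = depth_paths

    truth_path = directory / "truth.json"
    import json

    truth_payload = {
        "causal_gene": bundle.truth.causal_gene,
        "selected_gene_ids": sorted(bundle.truth.selected_gene_ids),
        "presence": {
            gid: {acc: int(v) for acc, v in row.items()}
            for gid, row in bundle.truth.presence.iterrows()
        },
    }
    truth_path.write_text(json.dumps(truth_payload, indent=1, sort_keys=True) + "\n")
    manifest["truth"] = truth_path

    relative = {
        k: [p.relative_to(directory) for p in v] if isinstance(v, list)
        else Path(v).relative_to(directory)
        for k, v in manifest.items()
    }
    manifest_path = pio.write_manifest(relative, directory / "manifest.json")
    manifest["manifest"] = manifest_path
    return manifest


def bundle_digest(directory: str | Path) -> dict[str, str]:
    """SHA-256 of every file in a written bundle (for determinism checks)."""
    directory = Path(directory)
    out = {}
    for path in sorted(directory.rglob("*")):
        if path.is_file():
            out[str(path.relative_to(directory))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    return out


# ---------------------------------------------------------------------------
# matrix-scale simulation (for scan-size power/FDR studies)

def simulate_pav_matrix(
    presence_freq: pd.DataFrame,
    group_sizes: dict[str, int],
    seed: int = 0,
) -> tuple[PAVMatrix, pd.DataFrame]:
    """Draw a PAV matrix directly from per-gene per-group presence
    frequencies (genes x groups), skipping sequence/depth simulation.

    Returns the matrix and the realized per-group presence counts.
    """
    rng = np.random.default_rng(seed)
    accessions, labels_vals = [], []
    for gname, n in group_sizes.items():
        if n <= 0:
            raise ValueError(f"group {gname!r} has zero accessions")
        accessions += [f"{gname}_{j + 1:03d}" for j in range(n)]
        labels_vals += [gname] * n
    labels = pd.Series(labels_vals, index=accessions, name="group")

    cols = []
    for gname, n in group_sizes.items():
        p = presence_freq[gname].to_numpy(dtype=float)[:, None]
        cols.append(rng.random((len(presence_freq), n)) < p)
    data = np.concatenate(cols, axis=1).astype(np.int8)
    matrix = pd.DataFrame(data, index=presence_freq.index, columns=accessions)
    pav = PAVMatrix(matrix=matrix, labels=labels)
    realized = pd.DataFrame({
        g: matrix[labels.index[labels == g]].sum(axis=1) for g in group_sizes
    })
    return pav, realized
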