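"""End-to-end recovery studies on ground-truth synthetic data.

Each function runs one stage of the pipeline against datasets with planted
truth and returns the headline quantities of that stage: published-count
arithmetic, PAV-call accuracy, pan-build novel-sequence recall, selection-scan
recall and empirical false-discovery rate, GWAS detection and family-wise
error, and the NG86 oracle checks. Both the test suite and the reproduction
script are thin layers over these functions.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd

from . import (
    PanBuildParams, SimConfig, align_contigs, bonferroni_threshold,
    build_matrix, classify_contigs, classify_occupancy, filter_short_contigs,
    generate_dataset, load_gsb_qtl, load_pan_gene_counts, load_rga_counts,
    mean_qtl_span_mb, remove_redundancy, selection_scan, simulate_pav_matrix,
    crosstab_rga, annotations_from_counts, variable_fraction,
    NBS_LRR_SUBFAMILIES, pav_pca, association_scan,
)
from .gwas import GwasParams
from .kaks import (
    SENSE_CODONS, CodingSequencePair, codon_differences, codon_sites,
    ng86_kaks, translate_codon,
)


def _subseed(seed: int, offset: int) -> int:
    return (int(seed) * 1000 + offset) % (2**31 - 1)


# ---------------------------------------------------------------------------
# published-count arithmetic

def headline_arithmetic() -> dict[str, float]:
    """Quantities derivable from the published summary tables alone."""
    counts = load_pan_gene_counts()
    pan_total = int(
        counts["reference_protein_coding_genes"] + counts["novel_protein_coding_genes"]
    )
    occupancy_total = int(
        counts["core_and_softcore_genes"] + counts["shell_genes"] + counts["cloud_genes"]
    )
    threshold = bonferroni_threshold(0.05, int(counts["shell_genes_tested_in_gwas"]))

    annotations, occupancy = annotations_from_counts(load_rga_counts())
    table = crosstab_rga(annotations, occupancy)
    subfams = [s for s in table.index if s != "Total"]

    qtls = load_gsb_qtl()
    return {
        "pan_gene_total": pan_total,
        "occupancy_class_sum": occupancy_total,
        "gwas_bonferroni_threshold": threshold,
        "rga_total": int(table.loc["Total", ("pangenome", "total")]),
        "rga_reference_total": int(table.loc["Total", ("reference", "total")]),
        "rga_additional_total": int(table.loc["Total", ("additional_contig", "total")]),
        "rga_variable_pct": 100 * variable_fraction(table, subfams),
        "rga_rlp_variable_pct": 100 * variable_fraction(table, ["RLP"]),
        "rga_rlk_variable_pct": 100 * variable_fraction(table, ["RLK"]),
        "rga_nbs_lrr_variable_pct": 100 * variable_fraction(table, NBS_LRR_SUBFAMILIES),
        "mean_qtl_span_mb": mean_qtl_span_mb(qtls),
    }


# ---------------------------------------------------------------------------
# PAV-call recovery

def pav_recovery(seed: int) -> dict[str, float]:
    """Matrix-vs-truth agreement with Poisson depth and with noise-free depth."""
    out = {}
    for key, noise in (("pav_accuracy_pct", "poisson"),
                       ("pav_accuracy_noisefree_pct", "constant")):
        cfg = SimConfig(seed=_subseed(seed, 1), depth_noise=noise)
        b = generate_dataset(cfg)
        m = build_matrix(b.depths, b.genes, b.labels)
        out[key] = 100 * float(
            (m.matrix.to_numpy() == b.truth.presence.to_numpy()).mean()
        )
        out["pav_n_cells"] = int(m.matrix.size)
    return out


# ---------------------------------------------------------------------------
# pan-build recovery

def panbuild_recovery(seed: int) -> dict[str, float]:
    """Recall of planted novel sequences through align/classify/redundancy,
    and the count of pure reference substrings surviving as segments."""
    b = generate_dataset(SimConfig(seed=_subseed(seed, 2)))
    params = PanBuildParams()
    segments = []
    for acc in b.accessions:
        ctgs = filter_short_contigs(b.contigs[acc], params)
        blocks = align_contigs(ctgs, b.reference)
        segments += classify_contigs(blocks, ctgs, params, accession=acc)["segments"]
    nonred = remove_redundancy(segments, params)
    planted = {
        nid for nid in b.novel_sequences if b.truth.presence.loc[nid].sum() > 0
    }
    recovered = {
        nid for nid in planted
        if any(s.sequence == b.novel_sequences[nid] for s in nonred)
    }
    ref = b.reference["chr1"]
    return {
        "novel_recovery_pct": 100 * len(recovered) / max(1, len(planted)),
        "n_planted_novel": len(planted),
        "n_reference_substrings_kept": sum(s.sequence in ref for s in nonred),
        "n_nonredundant_segments": len(nonred),
    }


# ---------------------------------------------------------------------------
# selection-scan recovery

def selection_recovery(
    seed: int, n_seeds: int = 10, n_genes: int = 1000, n_selected: int = 50,
    n_per_group: int = 40,
) -> dict[str, float]:
    """Recall of planted 8-fold frequency gaps (|log2 FC| = 3) and the rate at
    which equal-frequency null genes pass FDR < 0.001, averaged over seeds."""
    recalls, null_rates = [], []
    for i in range(n_seeds):
        rng = np.random.default_rng(_subseed(seed, 100 + i))
        base = rng.uniform(0.2, 0.8, size=n_genes)
        freq = pd.DataFrame(
            {"wild": base, "derived": base},
            index=[f"g{j}" for j in range(n_genes)],
        )
        sel_ids = [f"g{j}" for j in range(n_selected)]
        freq.loc[sel_ids, "wild"] = 0.1
        freq.loc[sel_ids, "derived"] = 0.8
        pav, _ = simulate_pav_matrix(
            freq, {"wild": n_per_group, "derived": n_per_group},
            seed=_subseed(seed, 200 + i),
        )
        res = selection_scan(pav, "wild", "derived", derived_group="derived")
        res = res.set_index("gene")
        recalls.append(res.loc[sel_ids, "selected"].mean())
        null = res.drop(index=sel_ids)
        null_rates.append((null["fdr"] < 0.001).mean())
    return {
        "selection_recall_pct": 100 * float(np.mean(recalls)),
        "selection_null_fdr_rate": float(np.mean(null_rates)),
        "selection_n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# GWAS detection and family-wise error

def gwas_study(
    seed: int, n_accessions: int = 40, n_genes: int = 200, n_perm: int = 150,
) -> dict[str, float]:
    """Detection of a fully penetrant causal shell gene, and the family-wise
    error rate of the Bonferroni-thresholded scan under permuted phenotypes."""
    rng = np.random.default_rng(_subseed(seed, 3))
    geno = pd.DataFrame(
        (rng.random((n_genes, n_accessions)) < rng.uniform(0.2, 0.8, (n_genes, 1))).astype(int),
        index=[f"g{j}" for j in range(n_genes)],
        columns=[f"a{j}" for j in range(n_accessions)],
    )
    causal = geno.loc["g0"].to_numpy()
    if causal.std() == 0:  # ensure the causal gene is polymorphic
        geno.loc["g0", geno.columns[:n_accessions // 2]] = 1
        geno.loc["g0", geno.columns[n_accessions // 2:]] = 0
        causal = geno.loc["g0"].to_numpy()
    pheno = pd.Series(causal, index=geno.columns, dtype=float)
    covs = pav_pca(geno, n_pcs=10)
    params = GwasParams()
    res = association_scan(geno, pheno, covs, params).set_index("gene")
    n_tested = int(res["n_tested"].iloc[0])
    threshold = bonferroni_threshold(params.alpha, n_tested)

    y = pheno.to_numpy().copy()
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(y)
        perm = association_scan(geno, pd.Series(y, index=pheno.index), covs, params)
        hits += int(perm["significant"].any())
    return {
        "gwas_causal_p": float(res.loc["g0", "p"]),
        "gwas_threshold": threshold,
        "gwas_causal_detected": int(res.loc["g0", "significant"]),
        "gwas_fwer": hits / n_perm,
        "gwas_n_tested": n_tested,
    }


# ---------------------------------------------------------------------------
# NG86 checks

def _oracle_codon(ca: str, cb: str) -> tuple[float, float]:
    """Brute-force pathway enumeration for one codon pair."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur, syn, non, blocked = ca, 0.0, 0.0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if translate_codon(nxt) == "*" or translate_codon(cur) == "*":
                blocked = True
            if translate_codon(nxt) == translate_codon(cur):
                syn += 1
            else:
                non += 1
            cur = nxt
        paths.append((syn, non, blocked))
    ok = [p for p in paths if not p[2]] or paths
    return (sum(p[0] for p in ok) / len(ok), sum(p[1] for p in ok) / len(ok))


def ng86_checks() -> dict[str, float]:
    """Exhaustive codon-pair agreement with the pathway oracle plus the two
    single-substitution worked examples."""
    mismatches = 0
    n_pairs = 0
    for ca in SENSE_CODONS:
        sa = codon_sites(ca)
        for cb in SENSE_CODONS:
            n_pairs += 1
            got = codon_differences(ca, cb)
            exp = _oracle_codon(ca, cb)
            if abs(got[0] - exp[0]) > 1e-9 or abs(got[1] - exp[1]) > 1e-9:
                mismatches += 1
        if abs(sum(sa) - 3.0) > 1e-9:
            mismatches += 1
    syn = ng86_kaks(CodingSequencePair("syn", "GGGGGGGGG", "GGAGGGGGG"))
    non_ref = ng86_kaks(
        CodingSequencePair("non", "GGGGGGGGG", "AGGGGGGGG"), sites="reference"
    )
    non_avg = ng86_kaks(CodingSequencePair("non", "GGGGGGGGG", "AGGGGGGGG"))
    return {
        "ng86_codon_pairs_checked": n_pairs,
        "ng86_oracle_mismatches": mismatches,
        "ng86_example_ds": float(syn.dS),
        "ng86_example_dn_reference_sites": float(non_ref.dN),
        "ng86_example_dn": float(non_avg.dN),
    }
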