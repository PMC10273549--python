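"""PAV-GWAS: genotype encoding, PCA covariates, score test, Bonferroni."""

import numpy as np
import pandas as pd
import pytest

from pavpan import (
    GwasParams, PAVMatrix, encode_genotypes, pav_pca, association_scan,
    bonferroni_threshold, group_frequency_summary, classify_occupancy,
    simulate_pav_matrix,
)
from pavpan.gwas import untestable_genes


def _pav(data, groups=None):
    genes = [f"g{i}" for i in range(data.shape[0])]
    accs = [f"a{j}" for j in range(data.shape[1])]
    labels = pd.Series(groups or ["G"] * data.shape[1], index=accs)
    return PAVMatrix(matrix=pd.DataFrame(data, index=genes, columns=accs),
                     labels=labels)


class TestEncoding:
    def test_only_shell_genes_retained(self):
        rng = np.random.default_rng(0)
        n = 50
        data = np.vstack([
            np.ones((3, n), dtype=int),                       # core
            (rng.random((2, n)) < 0.5).astype(int),           # shell
        ])
        pav = _pav(data)
        occ = classify_occupancy(pav)
        geno = encode_genotypes(pav, occ)
        assert len(geno) == 2
        assert set(geno.index) == set(occ.index[occ["occupancy"] == "shell"])

    def test_constant_gene_flagged_untestable(self):
        geno = pd.DataFrame(
            [[1, 1, 1, 1], [1, 0, 1, 0]], index=["const", "var"],
            columns=list("abcd"),
        )
        flags = untestable_genes(geno)
        assert bool(flags["const"]) and not bool(flags["var"])

    def test_genotype_rows_match_truth_shell_count(self, small_bundle):
        b = small_bundle
        pav = b.truth_matrix()
        occ = classify_occupancy(pav)
        geno = encode_genotypes(pav, occ)
        n = len(b.accessions)
        truth_shell = [
            gid for gid in b.truth.presence.index
            if 0.01 <= b.truth.presence.loc[gid].sum() / n < 0.99
            and b.truth.presence.loc[gid].sum() < n
        ]
        assert len(geno) == len(truth_shell)


class TestPca:
    def test_identical_accessions_have_zero_variance(self):
        geno = pd.DataFrame(np.ones((5, 6), dtype=int),
                            index=[f"g{i}" for i in range(5)],
                            columns=[f"a{j}" for j in range(6)])
        scores = pav_pca(geno, n_pcs=3)
        assert np.allclose(scores.to_numpy(), 0.0)

    def test_two_planted_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(1)
        n_genes, n_per = 80, 20
        freq = pd.DataFrame({
            "A": rng.uniform(0.7, 0.95, size=n_genes),
            "B": rng.uniform(0.05, 0.3, size=n_genes),
        }, index=[f"g{i}" for i in range(n_genes)])
        pav, _ = simulate_pav_matrix(freq, {"A": n_per, "B": n_per}, seed=2)
        scores = pav_pca(pav.matrix, n_pcs=2)
        from sklearn.metrics import silhouette_score
        sil = silhouette_score(scores[["PC1"]], pav.labels.to_numpy())
        assert sil > 0.5

    def test_zero_pcs_accepted_downstream(self):
        rng = np.random.default_rng(3)
        geno = pd.DataFrame((rng.random((10, 30)) < 0.5).astype(int),
                            index=[f"g{i}" for i in range(10)],
                            columns=[f"a{j}" for j in range(30)])
        covs = pav_pca(geno, n_pcs=0)
        assert covs.shape == (30, 0)
        pheno = pd.Series(rng.integers(0, 2, size=30), index=geno.columns)
        res = association_scan(geno, pheno, covs)
        assert len(res) == 10

    def test_components_orthogonal_and_variance_ordered(self):
        rng = np.random.default_rng(4)
        geno = pd.DataFrame((rng.random((40, 50)) < rng.uniform(0.2, 0.8, (40, 1))).astype(int),
                            index=[f"g{i}" for i in range(40)],
                            columns=[f"a{j}" for j in range(50)])
        scores = pav_pca(geno, n_pcs=5)
        X = scores.to_numpy()
        gram = X.T @ X
        off = gram - np.diag(np.diag(gram))
        assert np.allclose(off, 0.0, atol=1e-8)
        variances = X.var(axis=0)
        assert np.all(np.diff(variances) <= 1e-10)


class TestThreshold:
    @pytest.mark.parametrize("alpha,n,expected", [
        (0.05, 6161, 8.1e-6),
        (0.05, 1, 0.05),
        (0.05, 500, 1e-4),
    ])
    def test_values(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected, rel=0.01)

    def test_threshold_decreases_with_n(self):
        ts = [bonferroni_threshold(0.05, n) for n in (1, 10, 100, 1000)]
        assert all(a > b for a, b in zip(ts, ts[1:]))

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestAssociation:
    def _dataset(self, n=40, n_genes=60, seed=5, flip=0.0):
        rng = np.random.default_rng(seed)
        geno = pd.DataFrame((rng.random((n_genes, n)) < 0.5).astype(int),
                            index=[f"g{i}" for i in range(n_genes)],
                            columns=[f"a{j}" for j in range(n)])
        causal = geno.loc["g0"].to_numpy()
        flips = rng.random(n) < flip
        pheno = pd.Series(np.where(flips, 1 - causal, causal), index=geno.columns)
        return geno, pheno

    def test_perfect_causal_gene_is_significant(self):
        geno, pheno = self._dataset()
        covs = pav_pca(geno, n_pcs=5)
        res = association_scan(geno, pheno, covs).set_index("gene")
        n_tested = int(res["n_tested"].iloc[0])
        assert res.loc["g0", "p"] < bonferroni_threshold(0.05, n_tested)
        assert bool(res.loc["g0", "significant"])

    def test_constant_gene_gets_nan_and_is_not_counted(self):
        geno, pheno = self._dataset()
        geno.loc["g1"] = 1
        res = association_scan(geno, pheno).set_index("gene")
        assert np.isnan(res.loc["g1", "p"])
        assert res["n_tested"].iloc[0] == len(geno) - 1

    def test_phenotype_accession_mismatch_rejected(self):
        geno, pheno = self._dataset()
        with pytest.raises(ValueError, match="phenotype missing"):
            association_scan(geno, pheno.drop("a0"))

    def test_quantitative_phenotype_supported(self):
        rng = np.random.default_rng(6)
        geno, _ = self._dataset(seed=6)
        pheno = pd.Series(
            2.0 * geno.loc["g0"].to_numpy() + rng.normal(0, 0.3, size=40),
            index=geno.columns,
        )
        res = association_scan(geno, pheno).set_index("gene")
        assert res.loc["g0", "p"] < bonferroni_threshold(0.05, int(res["n_tested"].iloc[0]))
        assert res.loc["g0", "beta"] > 0

    def test_permuted_phenotype_fwer_near_alpha(self):
        """Bonferroni keeps the family-wise error at or below alpha under the
        null; over permutations the any-hit rate should not exceed alpha by
        more than Monte-Carlo error."""
        geno, pheno = self._dataset(n=40, n_genes=50, seed=7)
        rng = np.random.default_rng(8)
        y = pheno.to_numpy().copy()
        hits = 0
        n_perm = 120
        for _ in range(n_perm):
            rng.shuffle(y)
            res = association_scan(geno, pd.Series(y, index=pheno.index))
            hits += int(res["significant"].any())
        rate = hits / n_perm
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_perm)

    def test_logistic_path_detects_causal_gene(self):
        geno, pheno = self._dataset()
        covs = pav_pca(geno, n_pcs=5)
        params = GwasParams(binary_model="logistic")
        res = association_scan(geno, pheno, covs, params).set_index("gene")
        thr = bonferroni_threshold(0.05, int(res["n_tested"].iloc[0]))
        assert res.loc["g0", "p"] < thr

    def test_logistic_and_linear_agree_on_ranking(self):
        geno, pheno = self._dataset(flip=0.2, seed=9)
        res_lin = association_scan(geno, pheno).set_index("gene")
        res_log = association_scan(
            geno, pheno, params=GwasParams(binary_model="logistic")
        ).set_index("gene")
        # the causal gene tops both scans
        assert res_lin["p"].idxmin() == res_log["p"].idxmin() == "g0"

    def test_power_increases_with_sample_size(self):
        """Detection of a noisy causal gene improves along n = 20, 40, 80."""
        detection = []
        for n in (20, 40, 80):
            hits = 0
            for seed in range(12):
                geno, pheno = self._dataset(n=n, n_genes=40, seed=100 + seed, flip=0.15)
                res = association_scan(geno, pheno).set_index("gene")
                thr = bonferroni_threshold(0.05, int(res["n_tested"].iloc[0]))
                hits += int(res.loc["g0", "p"] < thr)
            detection.append(hits / 12)
        assert detection[0] <= detection[1] <= detection[2]
        assert detection[2] > detection[0]


class TestGroupSummary:
    def test_exact_counting_per_group(self):
        data = np.array([[1, 1, 0, 0, 0, 1]])
        pav = _pav(data, groups=["A", "A", "A", "B", "B", "B"])
        out = group_frequency_summary(pav, ["g0"])
        fa = out[out["group"] == "A"]["frequency"].iloc[0]
        fb = out[out["group"] == "B"]["frequency"].iloc[0]
        assert fa == pytest.approx(2 / 3)
        assert fb == pytest.approx(1 / 3)

    def test_empty_gene_set_rejected(self):
        pav = _pav(np.ones((1, 4), dtype=int))
        with pytest.raises(ValueError):
            group_frequency_summary(pav, [])
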