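"""Gene-PAV genome-wide association scan.

Shell genes become binary genotypes (present = 1); principal components of
the genotype matrix (or externally supplied covariates) adjust for population
structure, and each gene is tested one at a time with a 1-df generalized
linear model score test — Gaussian for quantitative phenotypes, Binomial with
a logit link for binary ones. The score test only requires the null model
(covariates alone), so it remains well defined under perfect separation,
which a fully penetrant gene–phenotype pair produces. Significance is by
Bonferroni: alpha / number of genes actually tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.decomposition import PCA

from .pav import PAVMatrix


@dataclass(frozen=True)
class GwasParams:
    """Scan parameters.

    ``binary_model`` selects how a 0/1 phenotype is scored: ``linear`` (the
    default) treats it numerically, the convention of single-locus GWAS tools,
    and keeps the family-wise error controlled at small sample sizes;
    ``logistic`` uses a Firth-penalised binomial null with saddlepoint tail
    probabilities, which is better-powered for very unbalanced traits but
    mildly anti-conservative below ~100 accessions.
    """

    alpha: float = 0.05
    n_pcs: int = 10
    maf_like_min: float = 0.01  # minimum presence-frequency spread to test
    binary_model: str = "linear"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")
        if self.binary_model not in ("linear", "logistic"):
            raise ValueError("binary_model must be 'linear' or 'logistic'")


def encode_genotypes(pav: PAVMatrix, occupancy: pd.DataFrame) -> pd.DataFrame:
    """Restrict the PAV matrix to shell genes (genes x accessions, 0/1).

    Constant rows are kept in the output but flagged by
    :func:`untestable_genes`; the association scan excludes them from
    ``n_tested``.
    """
    shell = occupancy.index[occupancy["occupancy"] == "shell"]
    return pav.matrix.loc[pav.matrix.index.intersection(shell, sort=False)]


def untestable_genes(genotypes: pd.DataFrame, params: GwasParams = GwasParams()) -> pd.Series:
    """True for genes whose presence-frequency spread is below the MAF-like
    floor (including constant genes)."""
    freq = genotypes.mean(axis=1)
    spread = np.minimum(freq, 1.0 - freq)
    return spread < params.maf_like_min


def pav_pca(genotypes: pd.DataFrame, n_pcs: int = 10) -> pd.DataFrame:
    """Accession-level principal components of the genotype matrix.

    Components are orthogonal and ordered by decreasing explained variance.
    With fewer informative dimensions than requested, the available number is
    returned.
    """
    if genotypes.shape[1] < 2:
        raise ValueError("PCA needs at least 2 accessions")
    if n_pcs == 0:
        return pd.DataFrame(index=genotypes.columns)
    X = genotypes.to_numpy(dtype=float).T  # accessions x genes
    n_comp = min(n_pcs, X.shape[0] - 1, X.shape[1])
    if n_comp == 0 or np.allclose(X.var(axis=0), 0):
        return pd.DataFrame(
            np.zeros((X.shape[0], min(n_pcs, max(1, n_comp) ))),
            index=genotypes.columns,
            columns=[f"PC{i+1}" for i in range(min(n_pcs, max(1, n_comp)))],
        )
    pca = PCA(n_components=n_comp, random_state=0)
    scores = pca.fit_transform(X)
    return pd.DataFrame(
        scores, index=genotypes.columns,
        columns=[f"PC{i+1}" for i in range(scores.shape[1])],
    )


def bonferroni_threshold(alpha: float, n_tested: int) -> float:
    """Family-wise significance threshold alpha / n_tested."""
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")
    return alpha / n_tested


def _null_fit(y: np.ndarray, Z: np.ndarray, binary: bool) -> tuple[np.ndarray, np.ndarray]:
    """Fit the covariate-only null model; return (mu0, working weights).

    The binomial fit uses Firth's penalised likelihood, which keeps fitted
    probabilities away from 0/1 when the covariates (quasi-)separate the
    phenotype — with tens of accessions and ten principal-component
    covariates an unpenalised fit frequently separates, and the score test
    loses calibration.
    """
    if not binary:
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        mu = Z @ beta
        sigma2 = float(np.sum((y - mu) ** 2) / max(1, len(y) - Z.shape[1]))
        w = np.full(len(y), 1.0 / max(sigma2, 1e-12))
        return mu, w
    beta = np.zeros(Z.shape[1])
    for _ in range(100):
        eta = np.clip(Z @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        WZ = Z * w[:, None]
        info_inv = np.linalg.pinv(Z.T @ WZ)
        hat = (WZ @ info_inv * Z).sum(axis=1)
        score = Z.T @ (y - mu + hat * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < 1e-9:
            break
    eta = np.clip(Z @ beta, -30.0, 30.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    return mu, w


def _spa_tail(x: np.ndarray, mu: np.ndarray, q: float) -> float | None:
    """Saddlepoint tail probability of the centered score U = x'(y - mu) for a
    Bernoulli(mu) vector y: P(U >= q) for q > 0, P(U <= q) for q < 0.

    Returns None when no saddlepoint exists (q at or beyond the support) or
    the approximation degenerates.
    """
    from scipy.stats import norm

    xm = x * mu

    def kprime(t):
        e = np.exp(np.clip(x * t, -700, 700))
        pt = mu * e / (1.0 - mu + mu * e)
        return float(np.sum(x * pt) - xm.sum())

    def kval(t):
        xt = np.clip(x * t, -700, 700)
        return float(np.sum(np.log1p(mu * (np.exp(xt) - 1.0))) - t * xm.sum())

    def kpp(t):
        e = np.exp(np.clip(x * t, -700, 700))
        pt = mu * e / (1.0 - mu + mu * e)
        return float(np.sum(x * x * pt * (1.0 - pt)))

    # Newton with bisection safeguard on K'(t) = q
    lo, hi = -500.0, 500.0
    if not (kprime(lo) <= q <= kprime(hi)):
        return None
    t = 0.0
    for _ in range(80):
        f = kprime(t) - q
        if abs(f) < 1e-12:
            break
        if f > 0:
            hi = t
        else:
            lo = t
        d = kpp(t)
        t_new = t - f / d if d > 1e-14 else (lo + hi) / 2.0
        t = t_new if lo < t_new < hi else (lo + hi) / 2.0
    if abs(t) < 1e-10:
        return None
    arg = 2.0 * (t * q - kval(t))
    k2 = kpp(t)
    if arg <= 0 or k2 <= 0:
        return None
    w_stat = np.sign(t) * np.sqrt(arg)
    v_stat = t * np.sqrt(k2)
    if w_stat == 0 or v_stat / w_stat <= 0:
        return None
    z = w_stat + np.log(v_stat / w_stat) / w_stat
    return float(norm.sf(z)) if q > 0 else float(norm.cdf(z))


def _score_test_all(G: np.ndarray, y: np.ndarray, Z: np.ndarray, binary: bool) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised 1-df score test of each genotype row added to the null model.

    Returns (two-sided p values, one-step effect estimates U/V). For binary
    phenotypes the tail probabilities use a saddlepoint approximation of the
    score distribution, which stays calibrated for unbalanced case/control
    splits where the usual chi-squared tail is anti-conservative.
    """
    from scipy.stats import chi2

    mu0, w = _null_fit(y, Z, binary)
    WZ = Z * w[:, None]
    ZtWZ_inv = np.linalg.pinv(Z.T @ WZ)
    GWZ = (G * w[None, :]) @ Z  # n_genes x p
    # covariate-adjusted genotypes: the score must be computed against them
    # because the Firth-penalised null is not the exact MLE, so the raw score
    # does not vanish along the covariate directions
    Gt = G - GWZ @ ZtWZ_inv @ Z.T
    U = Gt @ ((y - mu0) if binary else (y - mu0) * w)
    # V = x'Wx - x'WZ (Z'WZ)^-1 Z'Wx, per gene
    V = (G * G * w[None, :]).sum(axis=1) - np.einsum(
        "ip,pq,iq->i", GWZ, ZtWZ_inv, GWZ
    )
    V = np.clip(V, 1e-12, None)
    p = chi2.sf(U * U / V, df=1)
    if binary:
        for i in range(len(U)):
            q = abs(float(U[i]))
            if q == 0:
                p[i] = 1.0
                continue
            upper = _spa_tail(Gt[i], mu0, q)
            lower = _spa_tail(Gt[i], mu0, -q)
            if upper is not None and lower is not None:
                p[i] = min(1.0, upper + lower)
    return p, U / V


def association_scan(
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
    params: GwasParams = GwasParams(),
) -> pd.DataFrame:
    """Per-gene association of PAV genotype with a phenotype.

    Genes below the MAF-like spread floor get NaN statistics and do not count
    toward ``n_tested`` (recorded in the ``n_tested`` column, identical for
    all rows). ``significant`` applies the Bonferroni threshold
    alpha / n_tested.
    """
    accessions = list(genotypes.columns)
    missing = [a for a in accessions if a not in phenotype.index]
    if missing:
        raise ValueError(f"phenotype missing for accessions: {missing[:5]}")
    y = phenotype.loc[accessions].to_numpy(dtype=float)
    binary = (
        set(np.unique(y)) <= {0.0, 1.0} and params.binary_model == "logistic"
    )

    Z = np.ones((len(accessions), 1))
    if covariates is not None and covariates.shape[1] > 0:
        missing = [a for a in accessions if a not in covariates.index]
        if missing:
            raise ValueError(f"covariates missing for accessions: {missing[:5]}")
        Z = np.column_stack([Z, covariates.loc[accessions].to_numpy(dtype=float)])

    testable = ~untestable_genes(genotypes, params)
    G = genotypes.to_numpy(dtype=float)
    n_tested = int(testable.sum())

    p = np.full(len(genotypes), np.nan)
    beta = np.full(len(genotypes), np.nan)
    if n_tested:
        p_tested, eff = _score_test_all(G[testable.to_numpy()], y, Z, binary)
        p[testable.to_numpy()] = p_tested
        beta[testable.to_numpy()] = eff

    threshold = bonferroni_threshold(params.alpha, max(n_tested, 1))
    out = pd.DataFrame({
        "gene": genotypes.index,
        "beta": beta,
        "p": p,
        "significant": (p < threshold) & ~np.isnan(p),
        "n_tested": n_tested,
    }).reset_index(drop=True)
    return out


def group_frequency_summary(
    pav: PAVMatrix, gene_set: list[str]
) -> pd.DataFrame:
    """Per-group presence frequencies for a gene set (exact counting)."""
    if not gene_set:
        raise ValueError("gene set is empty")
    from .selection import group_frequencies

    sub = PAVMatrix(matrix=pav.matrix.loc[gene_set], labels=pav.labels)
    return group_frequencies(sub)
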