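"""Gene-PAV selection scan between population groups.

For each gene the presence frequency is compared between two groups with
Fisher's exact test (two-sided); Benjamini–Hochberg FDR is applied across
genes, and genes with |log2 frequency fold change| above a threshold at an
FDR below a threshold are called selected. Selected genes with the higher
frequency in the more-derived population are *favorable*; with the lower
frequency, *unfavorable* — mirroring the domestication series
wild relative -> landrace -> cultivar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .pav import PAVMatrix


@dataclass(frozen=True)
class SelectionParams:
    log2fc_threshold: float = 2.0
    fdr_threshold: float = 0.001
    pseudo_freq: float | None = None  # default 1/(2n) on the zero side
    use_raw_p: bool = False  # alternative reading: threshold raw p instead of FDR

    def __post_init__(self) -> None:
        if self.log2fc_threshold <= 0 or self.fdr_threshold <= 0:
            raise ValueError("thresholds must be positive")


def group_frequencies(
    pav: PAVMatrix, groups: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene per-group presence counts and frequencies (exact counting).

    Returns a long table: gene, group, n_present, n_total, frequency.
    """
    labels = pav.labels
    groups = groups if groups is not None else sorted(labels.unique())
    rows = []
    for group in groups:
        members = labels.index[labels == group]
        if len(members) == 0:
            raise ValueError(f"group {group!r} has no accessions")
        sub = pav.matrix[members]
        n_present = sub.sum(axis=1)
        rows.append(
            pd.DataFrame({
                "gene": pav.genes,
                "group": group,
                "n_present": n_present.to_numpy(),
                "n_total": len(members),
            })
        )
    out = pd.concat(rows, ignore_index=True)
    out["frequency"] = out["n_present"] / out["n_total"]
    return out


def fisher_pav_test(n_present_a: int, n_a: int, n_present_b: int, n_b: int) -> float:
    """Two-sided Fisher exact p for a 2x2 presence/absence table.

    The two-sided p sums hypergeometric probabilities of all tables with the
    same margins whose probability does not exceed the observed table's
    (probability-mass criterion).
    """
    if not (0 <= n_present_a <= n_a and 0 <= n_present_b <= n_b):
        raise ValueError("inconsistent counts")
    table = [[n_present_a, n_a - n_present_a], [n_present_b, n_b - n_present_b]]
    return float(fisher_exact(table, alternative="two-sided")[1])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (order-preserving, clipped to 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _log2_fold_change(freq_a: float, freq_b: float, n_a: int, n_b: int,
                      pseudo: float | None) -> float:
    """log2(freq_a / freq_b) with a pseudo-frequency substituted on a zero side.

    The pseudo-frequency defaults to 1/(2n) of the zero side's group, keeping
    the fold change finite and monotone in the observed frequency gap.
    """
    fa = freq_a if freq_a > 0 else (pseudo if pseudo is not None else 1.0 / (2 * n_a))
    fb = freq_b if freq_b > 0 else (pseudo if pseudo is not None else 1.0 / (2 * n_b))
    return float(np.log2(fa / fb))


def classify_selected(
    freq_table: pd.DataFrame,
    group_a: str,
    group_b: str,
    derived_group: str,
    params: SelectionParams = SelectionParams(),
) -> pd.DataFrame:
    """Selection scan between two groups of a frequency table.

    ``derived_group`` names the more-derived population of the comparison
    (must be ``group_a`` or ``group_b``). Genes absent in both groups carry
    no information and are excluded from testing; they are returned with
    ``skipped=True`` and NaN statistics.
    """
    if derived_group not in (group_a, group_b):
        raise ValueError("derived_group must be one of the two compared groups")
    wide = freq_table[freq_table["group"].isin([group_a, group_b])].pivot(
        index="gene", columns="group", values=["n_present", "n_total", "frequency"]
    )
    genes = wide.index
    ka = wide[("n_present", group_a)].to_numpy(dtype=int)
    na = wide[("n_total", group_a)].to_numpy(dtype=int)
    kb = wide[("n_present", group_b)].to_numpy(dtype=int)
    nb = wide[("n_total", group_b)].to_numpy(dtype=int)
    fa = wide[("frequency", group_a)].to_numpy(dtype=float)
    fb = wide[("frequency", group_b)].to_numpy(dtype=float)

    skipped = (ka == 0) & (kb == 0)
    p = np.full(len(genes), np.nan)
    lfc = np.full(len(genes), np.nan)
    for i in range(len(genes)):
        if skipped[i]:
            continue
        p[i] = fisher_pav_test(ka[i], na[i], kb[i], nb[i])
        lfc[i] = _log2_fold_change(fa[i], fb[i], na[i], nb[i], params.pseudo_freq)

    fdr = np.full(len(genes), np.nan)
    tested = ~skipped
    if tested.any():
        fdr[tested] = bh_fdr(p[tested])

    crit = p if params.use_raw_p else fdr
    selected = tested & (np.abs(lfc) > params.log2fc_threshold) & (
        np.nan_to_num(crit, nan=1.0) < params.fdr_threshold
    )
    higher_in_a = lfc > 0
    derived_is_a = derived_group == group_a
    favorable = selected & (higher_in_a == derived_is_a)
    direction = np.where(
        selected, np.where(favorable, "favorable", "unfavorable"), "none"
    )

    return pd.DataFrame({
        "gene": genes,
        "freq_a": fa,
        "freq_b": fb,
        "log2_fc": lfc,
        "p_fisher": p,
        "fdr": fdr,
        "selected": selected,
        "direction": direction,
        "skipped": skipped,
    }).reset_index(drop=True)


def selection_scan(
    pav: PAVMatrix,
    group_a: str,
    group_b: str,
    derived_group: str,
    params: SelectionParams = SelectionParams(),
) -> pd.DataFrame:
    """Convenience wrapper: frequencies + Fisher + FDR + direction calls."""
    freq = group_frequencies(pav, groups=[group_a, group_b])
    return classify_selected(freq, group_a, group_b, derived_group, params)
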