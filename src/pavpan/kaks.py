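"""Nei–Gojobori (1986) Ka/Ks from population SNPs applied to a reference CDS.

The SNPs observed across a population are collapsed onto the reference coding
sequence to form one alternate haplotype; synonymous (S) and nonsynonymous
(N) sites are counted per codon as the fraction of the three possible changes
at each position that preserve the encoded amino acid, averaged over the two
sequences, and observed differences are partitioned by averaging over all
minimal mutational pathways between differing codons. Proportions are
corrected for multiple hits with the Jukes–Cantor formula
d = -3/4 ln(1 - 4p/3), and the ratio dN/dS is reported with explicit flags
when it is undefined (dS = 0, or saturation at p >= 3/4).

Site counting treats changes that create a stop codon as nonsynonymous, so
S + N always equals the coding length; mutational pathways passing through a
stop codon are excluded from difference counting (all pathways are used if
every pathway is blocked). Codons containing a stop in either sequence are
excluded from counting and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from math import log

import pandas as pd

BASES = "ACGT"

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SENSE_CODONS = tuple(c for c, aa in _CODON_TABLE.items() if aa != "*")


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon]


@dataclass(frozen=True)
class CodingSequencePair:
    """Reference CDS and the alternate CDS with population SNPs applied."""

    gene_id: str
    reference: str
    alternate: str

    def __post_init__(self) -> None:
        if len(self.reference) != len(self.alternate):
            raise ValueError(f"{self.gene_id}: sequence lengths differ")
        if len(self.reference) % 3 != 0:
            raise ValueError(f"{self.gene_id}: length not divisible by 3")
        ref_codons = [
            self.reference[i : i + 3] for i in range(0, len(self.reference) - 3, 3)
        ]
        if any(_CODON_TABLE.get(c) == "*" for c in ref_codons):
            raise ValueError(f"{self.gene_id}: internal stop codon in reference")


@dataclass
class KaKsResult:
    gene_id: str
    S: float  # synonymous sites
    N: float  # nonsynonymous sites
    Sd: float  # observed synonymous differences
    Nd: float  # observed nonsynonymous differences
    pS: float
    pN: float
    dS: float | None
    dN: float | None
    ratio: float | None
    flags: list[str] = field(default_factory=list)
    excluded_codons: int = 0


def apply_snps_to_cds(cds: str, snps: pd.DataFrame, gene_id: str = "") -> str:
    """Apply substitution SNPs (1-based CDS positions) to a coding sequence.

    ``snps`` columns: cds_position, ref_base, alt_base. The reference base of
    every SNP must match the CDS; multi-base alleles (indels) are rejected.
    """
    seq = list(cds.upper())
    for row in snps.itertuples(index=False):
        pos = int(row.cds_position)
        ref, alt = str(row.ref_base).upper(), str(row.alt_base).upper()
        if len(ref) != 1 or len(alt) != 1:
            raise ValueError(f"{gene_id}: indel at CDS position {pos} not supported")
        if not 1 <= pos <= len(seq):
            raise ValueError(f"{gene_id}: SNP position {pos} outside CDS")
        if seq[pos - 1] != ref:
            raise ValueError(
                f"{gene_id}: ref base mismatch at CDS position {pos} "
                f"(CDS has {seq[pos - 1]}, SNP table says {ref})"
            )
        seq[pos - 1] = alt
    return "".join(seq)


def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes the fraction of its three possible changes that
    are synonymous; changes creating a stop codon count as nonsynonymous, so
    the two counts always sum to 3.
    """
    aa = translate_codon(codon)
    if aa == "*":
        raise ValueError("stop codon has no site decomposition")
    syn = 0.0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if translate_codon(alt) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two sense codons.

    Multi-hit codons are averaged over all minimal mutational pathways;
    pathways passing through a stop codon are excluded (with a fallback to
    all pathways when every one is blocked).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diff_pos):
        current = codon_a
        syn = nonsyn = 0.0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            aa_from, aa_to = translate_codon(current), translate_codon(nxt)
            if aa_to == "*" or aa_from == "*":
                blocked = True
            if aa_from == aa_to:
                syn += 1.0
            else:
                nonsyn += 1.0
            current = nxt
        pathways.append((syn, nonsyn, blocked))
    allowed = [p for p in pathways if not p[2]] or pathways
    syn = sum(p[0] for p in allowed) / len(allowed)
    nonsyn = sum(p[1] for p in allowed) / len(allowed)
    return syn, nonsyn


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(pair: CodingSequencePair, sites: str = "average") -> KaKsResult:
    """NG86 synonymous/nonsynonymous rates for one reference/alternate pair.

    ``sites="average"`` (the classical method) averages per-codon site counts
    over the two sequences, which makes the result symmetric under swapping
    reference and alternate. ``sites="reference"`` counts sites on the
    reference codons only, the convention of some simple population-SNP
    scripts; it is asymmetric and provided for comparability.
    """
    if sites not in ("average", "reference"):
        raise ValueError("sites must be 'average' or 'reference'")
    flags: list[str] = []
    S = N = Sd = Nd = 0.0
    excluded = 0
    length = len(pair.reference)
    for i in range(0, length, 3):
        ca, cb = pair.reference[i : i + 3], pair.alternate[i : i + 3]
        if translate_codon(ca) == "*" or translate_codon(cb) == "*":
            excluded += 1
            continue
        sa, na = codon_sites(ca)
        if sites == "average":
            sb, nb = codon_sites(cb)
            sa, na = (sa + sb) / 2.0, (na + nb) / 2.0
        S += sa
        N += na
        sd, nd = codon_differences(ca, cb)
        Sd += sd
        Nd += nd
    if excluded:
        flags.append(f"excluded_stop_codons={excluded}")

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    if dS is None:
        flags.append("dS_saturated")
    if dN is None:
        flags.append("dN_saturated")

    ratio: float | None
    if dS is None or dN is None:
        ratio = None
    elif dS == 0.0 and dN == 0.0:
        ratio = None
        flags.append("no_substitutions")
    elif dS == 0.0:
        ratio = None
        flags.append("dS_zero")
    else:
        ratio = dN / dS
    return KaKsResult(
        gene_id=pair.gene_id, S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
        dS=dS, dN=dN, ratio=ratio, flags=flags, excluded_codons=excluded,
    )


def kaks_table(
    cds: dict[str, str], snp_table: pd.DataFrame, sites: str = "average"
) -> pd.DataFrame:
    """NG86 results for every gene in a CDS set, SNPs collapsed per gene.

    ``snp_table`` columns: gene_id, cds_position, ref_base, alt_base.
    """
    rows = []
    for gene_id, ref_seq in cds.items():
        snps = snp_table[snp_table["gene_id"] == gene_id]
        alt_seq = apply_snps_to_cds(ref_seq, snps, gene_id=gene_id)
        res = ng86_kaks(CodingSequencePair(gene_id, ref_seq.upper(), alt_seq), sites=sites)
        rows.append({
            "gene": res.gene_id, "S": res.S, "N": res.N,
            "Sd": res.Sd, "Nd": res.Nd, "pS": res.pS, "pN": res.pN,
            "dS": res.dS, "dN": res.dN, "ratio": res.ratio,
            "flags": ";".join(res.flags), "excluded_codons": res.excluded_codons,
        })
    return pd.DataFrame(rows)
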