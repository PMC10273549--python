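"""Map-to-pan construction.

Per-accession assembled contigs are aligned to the reference; contigs with no
reliable alignment (identity > 90% over > 300 bp) are collected whole as fully
unaligned, while sufficiently long gaps between the reliable blocks of aligned
contigs are extracted as partially unaligned segments. After redundancy
removal the surviving non-reference segments are appended to the reference to
form the pan-genome.

The internal aligner is deliberately simple: exact k-mer anchors chained per
diagonal and extended without gaps under an x-drop rule, with identity =
matches / aligned columns. It is adequate for high-identity contig-to-
reference comparison; precomputed alignment tables from an external aligner
can be supplied instead (see :func:`pavpan.io.read_alignment_tsv`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentBlock:
    """One local contig-to-reference alignment (0-based half-open on both sides)."""

    query_id: str
    query_start: int
    query_end: int
    ref_id: str
    ref_start: int
    ref_end: int
    identity: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.query_end <= self.query_start or self.ref_end <= self.ref_start:
            raise ValueError("alignment block has an empty side")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0, 1]")

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@dataclass(frozen=True)
class PanBuildParams:
    """Thresholds of the map-to-pan procedure.

    Reliability reads as strict "exceeding": a block is reliable iff
    identity > ``reliable_identity`` and aligned length > ``reliable_len``.
    """

    min_contig_len: int = 500
    reliable_identity: float = 0.90
    reliable_len: int = 300
    unaligned_seg_min: int = 500
    redund_cov: float = 0.90
    redund_identity: float = 0.90

    def __post_init__(self) -> None:
        for name in ("min_contig_len", "reliable_len", "unaligned_seg_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("reliable_identity", "redund_cov", "redund_identity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class NonRefSegment:
    """A candidate non-reference sequence extracted from one contig."""

    id: str
    source_accession: str
    source_contig: str
    start: int  # interval on the source contig, half-open
    end: int
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# Internal aligner

def _extend_ungapped(
    query: str, ref: str, qs: int, qe: int, rs: int, re_: int,
    match: int = 1, mismatch: int = -2, xdrop: int = 20,
) -> tuple[int, int, int, int, int]:
    """Extend an exact anchor in both directions on the same diagonal.

    Returns (qstart, qend, rstart, rend, matches). Extension stops when the
    running score falls ``xdrop`` below its maximum; the returned ends are at
    the score maximum (trailing mismatches are trimmed).
    """
    matches = qe - qs  # anchor is exact

    # right extension
    score = best = 0
    best_off = 0
    off = 0
    while qe + off < len(query) and re_ + off < len(ref):
        score += match if query[qe + off] == ref[re_ + off] else mismatch
        off += 1
        if score > best:
            best, best_off = score, off
        if best - score > xdrop:
            break
    add_m = sum(
        1 for i in range(best_off) if query[qe + i] == ref[re_ + i]
    )
    qe += best_off
    re_ += best_off
    matches += add_m

    # left extension
    score = best = 0
    best_off = 0
    off = 0
    while qs - off - 1 >= 0 and rs - off - 1 >= 0:
        score += match if query[qs - off - 1] == ref[rs - off - 1] else mismatch
        off += 1
        if score > best:
            best, best_off = score, off
        if best - score > xdrop:
            break
    add_m = sum(
        1 for i in range(1, best_off + 1) if query[qs - i] == ref[rs - i]
    )
    qs -= best_off
    rs -= best_off
    matches += add_m

    return qs, qe, rs, re_, matches


def _index_kmers(reference: Mapping[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for ref_id, seq in reference.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((ref_id, i))
    return index


def _align_one_strand(
    query_id: str, query: str, reference: Mapping[str, str],
    index: Mapping[str, list[tuple[str, int]]], k: int, strand: str,
    orig_len: int,
) -> list[AlignmentBlock]:
    # collect anchor hits grouped by (ref_id, diagonal)
    diagonals: dict[tuple[str, int], list[int]] = {}
    for qpos in range(len(query) - k + 1):
        for ref_id, rpos in index.get(query[qpos : qpos + k], ()):
            diagonals.setdefault((ref_id, qpos - rpos), []).append(qpos)

    blocks: list[AlignmentBlock] = []
    for (ref_id, diag), qhits in sorted(diagonals.items()):
        ref = reference[ref_id]
        qhits.sort()
        # chain adjacent/overlapping anchors on the same diagonal, then extend
        covered_to = -1
        i = 0
        while i < len(qhits):
            j = i
            while j + 1 < len(qhits) and qhits[j + 1] <= qhits[j] + k:
                j += 1
            qs, qe = qhits[i], qhits[j] + k
            i = j + 1
            if qe <= covered_to:
                continue
            rs, re_ = qs - diag, qe - diag
            qs, qe, rs, re_, matches = _extend_ungapped(query, ref, qs, qe, rs, re_)
            covered_to = qe
            cols = qe - qs
            if strand == "-":
                # report coordinates on the original (forward) contig
                fqs, fqe = orig_len - qe, orig_len - qs
            else:
                fqs, fqe = qs, qe
            blocks.append(
                AlignmentBlock(
                    query_id=query_id, query_start=fqs, query_end=fqe,
                    ref_id=ref_id, ref_start=rs, ref_end=re_,
                    identity=matches / cols, strand=strand,
                )
            )
    return blocks


def _dedupe_blocks(blocks: list[AlignmentBlock]) -> list[AlignmentBlock]:
    """Drop blocks whose query interval is contained in a longer block's."""
    blocks = sorted(blocks, key=lambda b: (-(b.query_span), b.query_start))
    kept: list[AlignmentBlock] = []
    for b in blocks:
        if any(
            o.query_start <= b.query_start and b.query_end <= o.query_end
            and o.identity >= b.identity
            for o in kept
        ):
            continue
        kept.append(b)
    kept.sort(key=lambda b: (b.query_id, b.query_start, b.query_end, b.ref_id, b.ref_start))
    return kept


def align_contigs(
    contigs: Mapping[str, str],
    reference: Mapping[str, str],
    k: int = 21,
) -> list[AlignmentBlock]:
    """Align contigs to the reference with exact k-mer anchors and ungapped
    x-drop extension. Both strands are searched; coordinates are always on the
    forward contig."""
    if not reference or all(len(s) == 0 for s in reference.values()):
        raise ValueError("empty reference")
    if k < 11:
        raise ValueError("anchor length k must be >= 11")
    index = _index_kmers(reference, k)
    blocks: list[AlignmentBlock] = []
    for query_id, seq in contigs.items():
        per_contig = _align_one_strand(query_id, seq, reference, index, k, "+", len(seq))
        per_contig += _align_one_strand(
            query_id, revcomp(seq), reference, index, k, "-", len(seq)
        )
        blocks.extend(_dedupe_blocks(per_contig))
    return blocks


def blocks_from_dataframe(df: pd.DataFrame) -> list[AlignmentBlock]:
    """Build blocks from an external alignment table (native coordinates)."""
    return [
        AlignmentBlock(
            query_id=str(r.query), query_start=int(r.qstart), query_end=int(r.qend),
            ref_id=str(r.ref), ref_start=int(r.rstart), ref_end=int(r.rend),
            identity=float(r.identity),
        )
        for r in df.itertuples(index=False)
    ]


def filter_short_contigs(
    contigs: Mapping[str, str], params: PanBuildParams = PanBuildParams()
) -> dict[str, str]:
    """Drop contigs shorter than ``params.min_contig_len``."""
    return {cid: s for cid, s in contigs.items() if len(s) >= params.min_contig_len}


# ---------------------------------------------------------------------------
# Classification

def is_reliable(block: AlignmentBlock, params: PanBuildParams) -> bool:
    return (
        block.identity > params.reliable_identity
        and block.query_span > params.reliable_len
    )


def classify_contigs(
    blocks: Sequence[AlignmentBlock],
    contigs: Mapping[str, str],
    params: PanBuildParams = PanBuildParams(),
    accession: str = "",
) -> dict:
    """Partition contigs into aligned / fully unaligned and extract the
    partially unaligned segments of aligned contigs.

    A contig with at least one reliable block is *aligned*; the complement of
    the union of its reliable blocks yields candidate segments, kept when
    longer than ``params.unaligned_seg_min``. Contigs without any reliable
    block are emitted whole as *fully unaligned*.
    """
    for b in blocks:
        if b.query_id not in contigs:
            raise ValueError(f"alignment block references unknown contig {b.query_id!r}")

    reliable: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        if is_reliable(b, params):
            reliable.setdefault(b.query_id, []).append((b.query_start, b.query_end))

    aligned: list[str] = []
    fully_unaligned: list[str] = []
    segments: list[NonRefSegment] = []
    prefix = f"{accession}|" if accession else ""

    for contig_id in contigs:
        seq = contigs[contig_id]
        if contig_id not in reliable:
            fully_unaligned.append(contig_id)
            segments.append(
                NonRefSegment(
                    id=f"{prefix}{contig_id}|full",
                    source_accession=accession, source_contig=contig_id,
                    start=0, end=len(seq), sequence=seq,
                )
            )
            continue
        aligned.append(contig_id)
        # complement of the union of reliable blocks
        covered = _merge(reliable[contig_id])
        prev = 0
        gaps: list[tuple[int, int]] = []
        for s, e in covered:
            if s > prev:
                gaps.append((prev, s))
            prev = max(prev, e)
        if prev < len(seq):
            gaps.append((prev, len(seq)))
        for s, e in gaps:
            if e - s > params.unaligned_seg_min:
                segments.append(
                    NonRefSegment(
                        id=f"{prefix}{contig_id}|{s}-{e}",
                        source_accession=accession, source_contig=contig_id,
                        start=s, end=e, sequence=seq[s:e],
                    )
                )
    return {
        "aligned": aligned,
        "fully_unaligned": fully_unaligned,
        "segments": segments,
    }


def _merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


# ---------------------------------------------------------------------------
# Redundancy removal

def remove_redundancy(
    segments: Sequence[NonRefSegment],
    params: PanBuildParams = PanBuildParams(),
    k: int = 21,
) -> list[NonRefSegment]:
    """Greedy longest-first redundancy removal.

    Segments are visited by decreasing length (id ascending on ties). A
    segment is discarded iff at least ``redund_cov`` of its length aligns at
    identity >= ``redund_identity`` to an already-retained segment; otherwise
    it is retained. The pass is idempotent.
    """
    ordered = sorted(segments, key=lambda s: (-len(s), s.id))
    retained: list[NonRefSegment] = []
    retained_seqs: dict[str, str] = {}
    for seg in ordered:
        if retained and _redundant_against(seg, retained_seqs, params, k):
            continue
        retained.append(seg)
        retained_seqs[seg.id] = seg.sequence
    return retained


def _redundant_against(
    seg: NonRefSegment,
    retained: Mapping[str, str],
    params: PanBuildParams,
    k: int,
) -> bool:
    if len(seg.sequence) < k:
        return any(seg.sequence in s for s in retained.values())
    blocks = align_contigs({seg.id: seg.sequence}, retained, k=k)
    good = [
        (b.query_start, b.query_end)
        for b in blocks
        if b.identity >= params.redund_identity
    ]
    if not good:
        return False
    covered = sum(e - s for s, e in _merge(good))
    return covered >= params.redund_cov * len(seg.sequence)


# ---------------------------------------------------------------------------
# Contamination filter and pan-genome assembly

def filter_contamination(
    segments: Sequence[NonRefSegment],
    taxon_labels: Mapping[str, str],
) -> list[NonRefSegment]:
    """Keep segments labelled ``keep``; drop those labelled ``drop``;
    unlabelled segments are retained by default."""
    return [s for s in segments if taxon_labels.get(s.id, "keep") != "drop"]


def build_pangenome(
    reference: Mapping[str, str],
    segments: Sequence[NonRefSegment],
    segment_prefix: str = "panseg",
) -> dict[str, str]:
    """Reference records followed by non-reference segments with stable ids."""
    pan = dict(reference)
    for i, seg in enumerate(segments, 1):
        name = f"{segment_prefix}{i:05d}"
        if name in pan:
            raise ValueError(f"duplicate sequence id {name!r}")
        pan[name] = seg.sequence
    return pan
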