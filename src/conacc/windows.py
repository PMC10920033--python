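"""Annotation-aware segmentation of alignment blocks into scan windows.

Blocks are partitioned at every annotation boundary and each segment is
labelled with a single category by priority (CDS > 5'-UTR > 3'-UTR > intron >
intergenic); ties within the winning category keep all contributing gene IDs.
Segments are then cut into 10-99-base windows: pieces shorter than 10
reference bases are dropped, 10-99-base segments pass unchanged, and longer
segments are cut every 60 bases from the 5' end with a short (<20-base) tail
merged into the preceding window.  Lengths count non-gap reference columns;
gap columns travel with their window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .formats_io import AlignmentBlock, GeneModel
from .intervals import GenomicInterval
from .model import MISSING, encode_sequences

logger = logging.getLogger(__name__)

CATEGORIES = ("CDS", "five_prime_UTR", "three_prime_UTR", "intron", "intergenic")
_PRIORITY = {c: i for i, c in enumerate(CATEGORIES)}

MIN_LEN = 10
MAX_UNSPLIT = 99
SPLIT_EVERY = 60
MIN_TAIL = 20


@dataclass
class Segment:
    """A single-category slice of a block, pre-windowing."""

    block: AlignmentBlock
    ref_interval: GenomicInterval
    category: str
    gene_ids: frozenset[str]


@dataclass
class AnnotationWindow:
    """A 10-99-reference-base alignment slice carrying one annotation category."""

    block: AlignmentBlock
    ref_interval: GenomicInterval
    category: str
    gene_ids: frozenset[str]
    window_id: str

    def __post_init__(self) -> None:
        n = len(self.ref_interval)
        if not (MIN_LEN <= n <= MAX_UNSPLIT):
            raise ValueError(f"window length {n} outside [{MIN_LEN}, {MAX_UNSPLIT}]")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def species(self) -> list[str]:
        return self.block.species

    def columns_for(self, leaf_labels: list[str]) -> np.ndarray:
        """Encoded columns (ncols, n_leaves) in the given taxon order.

        Species absent from the block contribute missing data throughout.
        """
        present = {r.species: r.text for r in self.block.rows}
        cols = np.full((self.block.ncols, len(leaf_labels)), MISSING, dtype=np.int8)
        have = [i for i, t in enumerate(leaf_labels) if t in present]
        if have:
            sub = encode_sequences([present[leaf_labels[i]] for i in have])
            cols[:, have] = sub
        return cols

    @property
    def is_testable(self) -> bool:
        """At least two species carry at least one non-gap base."""
        n = sum(1 for r in self.block.rows if r.size > 0)
        return n >= 2


def _column_anchor_positions(block: AlignmentBlock) -> np.ndarray:
    """Reference position each column belongs to (gap columns attach left)."""
    refpos = block.ref_column_positions()
    anchored = refpos.copy()
    last = block.ref_interval().start
    for i, p in enumerate(refpos):
        if p >= 0:
            last = p
        anchored[i] = last if p < 0 else p
    return anchored


def _slice_by_ref(block: AlignmentBlock, anchored: np.ndarray, s: int, e: int) -> AlignmentBlock:
    mask = (anchored >= s) & (anchored < e)
    first = int(mask.argmax())
    stop = int(len(mask) - mask[::-1].argmax())
    return block.slice_columns(first, stop)


def assign_annotation(
    blocks: list[AlignmentBlock], genes: list[GeneModel]
) -> list[Segment]:
    """Partition blocks at annotation boundaries and label by priority.

    Only protein-coding gene models drive the five-way categorisation;
    intron means inside a gene span but in no exon-level feature.  When two
    genes contribute the same winning category both gene IDs are kept; when
    they contribute different categories the higher-priority one wins.
    """
    coding = [g for g in genes if g.is_coding]
    segments: list[Segment] = []
    for block in blocks:
        iv = block.ref_interval()
        span = len(iv)
        cat = np.full(span, _PRIORITY["intergenic"], dtype=np.int8)
        contributors: list[dict[str, set[str]]] = [dict() for _ in range(span)]

        def paint(lo: int, hi: int, category: str, gene_id: str) -> None:
            lo = max(lo, iv.start) - iv.start
            hi = min(hi, iv.end) - iv.start
            code = _PRIORITY[category]
            for p in range(lo, hi):
                contributors[p].setdefault(category, set()).add(gene_id)
                if code < cat[p]:
                    cat[p] = code

        for g in coding:
            if g.span.chrom != iv.chrom or not g.span.overlaps(iv):
                continue
            covered = np.zeros(span, dtype=bool)
            for fcat, fiv in g.features:
                lo = max(fiv.start, iv.start) - iv.start
                hi = min(fiv.end, iv.end) - iv.start
                if hi > lo:
                    covered[lo:hi] = True
                if fcat != "exon":
                    paint(fiv.start, fiv.end, fcat, g.gene_id)
            lo = max(g.span.start, iv.start) - iv.start
            hi = min(g.span.end, iv.end) - iv.start
            inside = np.zeros(span, dtype=bool)
            inside[lo:hi] = True
            for p in np.flatnonzero(inside & ~covered):
                contributors[p].setdefault("intron", set()).add(g.gene_id)
                if _PRIORITY["intron"] < cat[p]:
                    cat[p] = _PRIORITY["intron"]

        anchored = _column_anchor_positions(block)
        keys = [
            (int(cat[p]), frozenset(contributors[p].get(CATEGORIES[cat[p]], ())))
            for p in range(span)
        ]
        start = 0
        for p in range(1, span + 1):
            if p == span or keys[p] != keys[start]:
                code, gids = keys[start]
                segments.append(
                    Segment(
                        block=_slice_by_ref(
                            block, anchored, iv.start + start, iv.start + p
                        ),
                        ref_interval=GenomicInterval(
                            iv.chrom, iv.start + start, iv.start + p
                        ),
                        category=CATEGORIES[code],
                        gene_ids=gids,
                    )
                )
                start = p
    return segments


def split_lengths(length: int) -> list[int]:
    """Window lengths for a segment of the given reference length.

    <10: dropped; 10-99: kept whole; >=100: cut every 60 from the 5' end,
    with a final fragment of <20 merged into the preceding window.
    """
    if length < MIN_LEN:
        return []
    if length <= MAX_UNSPLIT:
        return [length]
    n_full, rem = divmod(length, SPLIT_EVERY)
    if rem == 0:
        return [SPLIT_EVERY] * n_full
    if rem < MIN_TAIL:
        return [SPLIT_EVERY] * (n_full - 1) + [SPLIT_EVERY + rem]
    return [SPLIT_EVERY] * n_full + [rem]


def split_windows(segments: list[Segment]) -> list[AnnotationWindow]:
    """Cut category segments into 10-99-base annotated windows."""
    windows: list[AnnotationWindow] = []
    dropped = 0
    for seg in segments:
        iv = seg.ref_interval
        pieces = split_lengths(len(iv))
        if not pieces:
            dropped += 1
            continue
        anchored = _column_anchor_positions(seg.block)
        pos = iv.start
        for n in pieces:
            sub_iv = GenomicInterval(iv.chrom, pos, pos + n)
            windows.append(
                AnnotationWindow(
                    block=_slice_by_ref(seg.block, anchored, pos, pos + n),
                    ref_interval=sub_iv,
                    category=seg.category,
                    gene_ids=seg.gene_ids,
                    window_id=f"{iv.chrom}:{pos}-{pos + n}",
                )
            )
            pos += n
    if dropped:
        logger.info("dropped %d segments shorter than %d bases", dropped, MIN_LEN)
    return windows


def window_stats(segments: list[Segment], windows: list[AnnotationWindow]) -> dict:
    """Counts and median lengths before and after splitting."""
    seg_lengths = [len(s.ref_interval) for s in segments]
    win_lengths = [len(w.ref_interval) for w in windows]
    return {
        "n_segments": len(segments),
        "n_windows": len(windows),
        "median_segment_length": float(np.median(seg_lengths)) if seg_lengths else 0.0,
        "median_window_length": float(np.median(win_lengths)) if win_lengths else 0.0,
    }
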