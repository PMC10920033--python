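"""Bespoke curation of pairwise genome alignments.

Three cleaning steps precede the multi-species merge: N-trimming (edge Ns
removed, long internal N runs cut out with a block split), overlap resolution
on the reference (longer alignments win, shorter ones are trimmed to the
uncovered remainder), and a species-count filter on the merged blocks.  The
merge itself is a simplified reference-anchored stacking of the per-species
pairwise alignments: reference positions form the columns and species
insertions relative to the reference are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .formats_io import AlignmentBlock, AlignmentRow
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class CurationConfig:
    """Thresholds for alignment curation.

    ``n_run_fraction_threshold``: an internal N run longer than this fraction
    of its row's ungapped length is excised (default 0.5, i.e. ">50% of the
    length of the sequence").  ``min_species``: blocks with fewer species are
    discarded after merging (default 7 of 8).
    """

    n_run_fraction_threshold: float = 0.5
    min_species: int = 7
    total_species: int = 8

    def __post_init__(self) -> None:
        if not (0 < self.n_run_fraction_threshold <= 1):
            raise ValueError("n_run_fraction_threshold must be in (0, 1]")
        if not (1 <= self.min_species <= self.total_species):
            raise ValueError("need 1 <= min_species <= total_species")


def _n_runs(text: str) -> list[tuple[int, int]]:
    """Maximal runs of 'N' columns, as half-open column ranges."""
    runs, start = [], None
    for i, ch in enumerate(text):
        if ch == "N":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(text)))
    return runs


def trim_and_split_n(
    block: AlignmentBlock, cfg: CurationConfig | None = None
) -> list[AlignmentBlock]:
    """Remove edge Ns and excise over-long internal N runs from a pairwise block.

    Leading/trailing columns in which either row carries an N are trimmed.
    Any remaining maximal N run whose length exceeds
    ``cfg.n_run_fraction_threshold`` times the ungapped length of its row
    splits the block at the run; the run's columns are discarded.  Blocks
    emptied by trimming are dropped.
    """
    cfg = cfg or CurationConfig()
    if len(block.rows) != 2:
        raise ValueError("trim_and_split_n expects a pairwise (2-row) block")
    has_n = [
        any(r.text[i] == "N" for r in block.rows) for i in range(block.ncols)
    ]
    lo = 0
    while lo < block.ncols and has_n[lo]:
        lo += 1
    hi = block.ncols
    while hi > lo and has_n[hi - 1]:
        hi -= 1
    if hi <= lo:
        return []
    trimmed = block.slice_columns(lo, hi)

    cuts: list[tuple[int, int]] = []
    for row in trimmed.rows:
        ungapped = row.size
        if ungapped == 0:
            continue
        for run in _n_runs(row.text):
            if (run[1] - run[0]) > cfg.n_run_fraction_threshold * ungapped:
                cuts.append(run)
    if not cuts:
        return [trimmed]
    cuts.sort()
    merged = [list(cuts[0])]
    for s, e in cuts[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out, pos = [], 0
    for s, e in merged:
        if s > pos:
            out.append(trimmed.slice_columns(pos, s))
        pos = e
    if pos < trimmed.ncols:
        out.append(trimmed.slice_columns(pos, trimmed.ncols))
    return [b for b in out if b.ncols > 0]


def resolve_reference_overlaps(blocks: list[AlignmentBlock]) -> list[AlignmentBlock]:
    """Make reference coverage single-valued, preferring longer alignments.

    Blocks are ranked by descending column count (ties: smaller reference
    start first).  Each accepted block claims its reference interval; later
    blocks keep only columns over unclaimed reference positions (which may
    split them).  Zero-length remnants are dropped.
    """
    ranked = sorted(
        enumerate(blocks),
        key=lambda ib: (-ib[1].ncols, ib[1].ref_interval().start, ib[0]),
    )
    claimed: dict[str, list[tuple[int, int]]] = {}
    out: list[AlignmentBlock] = []
    for _, block in ranked:
        iv = block.ref_interval()
        free = _subtract(iv.start, iv.end, claimed.get(iv.chrom, []))
        refpos = block.ref_column_positions()
        # attach reference-gap columns to the preceding reference position
        last = iv.start
        anchored = refpos.copy()
        for i, p in enumerate(refpos):
            if p >= 0:
                last = p
            anchored[i] = last if p < 0 else p
        for s, e in free:
            colmask = (anchored >= s) & (anchored < e)
            if not colmask.any():
                continue
            first = int(colmask.argmax())
            stop = int(len(colmask) - colmask[::-1].argmax())
            piece = block.slice_columns(first, stop)
            if piece.reference.size > 0:
                out.append(piece)
            claimed.setdefault(iv.chrom, []).append((s, e))
    for chrom in claimed:
        claimed[chrom].sort()
    out.sort(key=lambda b: (b.ref_interval().chrom, b.ref_interval().start))
    return out


def _subtract(start: int, end: int, claimed: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Parts of [start, end) not covered by the claimed intervals."""
    free, pos = [], start
    for s, e in sorted(claimed):
        if e <= pos or s >= end:
            continue
        if s > pos:
            free.append((pos, min(s, end)))
        pos = max(pos, e)
        if pos >= end:
            break
    if pos < end:
        free.append((pos, end))
    return free


def merge_reference_anchored(
    per_species: dict[str, list[AlignmentBlock]], ref_name: str
) -> list[AlignmentBlock]:
    """Stack per-species pairwise alignments into reference-anchored blocks.

    Columns are the reference positions (the reference row is gap-free);
    species insertions relative to the reference are dropped.  One block is
    emitted per maximal reference interval over which the set of contributing
    pairwise blocks is constant; species without an alignment there are
    omitted.  Conflicting reference bases between inputs raise ``ValueError``.

    After insertion removal a non-reference row's ``src_start``/``size``
    describe the first aligned base and the base count; the row may not be a
    contiguous source run.
    """
    # per chrom: ref base per position; per species: pos -> (base, payload)
    ref_bases: dict[str, dict[int, str]] = {}
    ref_size: dict[str, int] = {}
    cover: dict[str, dict[str, dict[int, tuple]]] = {}
    for sp, blocks in per_species.items():
        for bi, block in enumerate(blocks):
            ref = block.reference
            others = [r for r in block.rows if r is not ref]
            if len(block.rows) != 2:
                raise ValueError("merge expects pairwise blocks per species")
            tgt = others[0]
            chrom = ref.chrom
            ref_size.setdefault(chrom, ref.src_size)
            bases = ref_bases.setdefault(chrom, {})
            table = cover.setdefault(chrom, {}).setdefault(sp, {})
            pos = ref.src_start
            tpos = tgt.src_start
            for rc, tc in zip(ref.text, tgt.text):
                if rc == "-":
                    if tc != "-":
                        tpos += 1
                    continue
                prev = bases.get(pos)
                if prev is not None and prev != rc:
                    raise ValueError(
                        f"conflicting reference base at {chrom}:{pos}: {prev} vs {rc}"
                    )
                bases[pos] = rc
                table[pos] = (tc, tpos, tgt.strand, tgt.src, tgt.src_size, (sp, bi))
                if tc != "-":
                    tpos += 1
                pos += 1

    out: list[AlignmentBlock] = []
    for chrom in sorted(ref_bases):
        bases = ref_bases[chrom]
        species = sorted(cover.get(chrom, {}))
        positions = sorted(bases)
        runs: list[tuple[int, int]] = []
        sig_prev, run_start = None, None
        prev_pos = None
        for p in positions:
            sig = tuple(
                cover[chrom][sp][p][5] if p in cover[chrom][sp] else None
                for sp in species
            )
            if run_start is None or sig != sig_prev or p != prev_pos + 1:
                if run_start is not None:
                    runs.append((run_start, prev_pos + 1))
                run_start = p
                sig_prev = sig
            prev_pos = p
        if run_start is not None:
            runs.append((run_start, prev_pos + 1))

        for s, e in runs:
            ref_text = "".join(bases[p] for p in range(s, e))
            rows = [
                AlignmentRow(
                    species=ref_name,
                    src=f"{ref_name}.{chrom}",
                    src_start=s,
                    size=e - s,
                    src_size=ref_size[chrom],
                    strand="+",
                    text=ref_text,
                )
            ]
            for sp in species:
                table = cover[chrom][sp]
                if s not in table:
                    continue
                recs = [table[p] for p in range(s, e)]
                text = "".join(r[0] for r in recs)
                size = len(text) - text.count("-")
                firsts = [r for r in recs if r[0] != "-"]
                src_start = firsts[0][1] if firsts else recs[0][1]
                rows.append(
                    AlignmentRow(
                        species=sp,
                        src=recs[0][3],
                        src_start=src_start,
                        size=size,
                        src_size=recs[0][4],
                        strand=recs[0][2],
                        text=text,
                    )
                )
            out.append(AlignmentBlock(rows))
    return out


def filter_species_count(
    blocks: list[AlignmentBlock], cfg: CurationConfig | None = None
) -> list[AlignmentBlock]:
    """Keep blocks with at least ``cfg.min_species`` species (order preserved)."""
    cfg = cfg or CurationConfig()
    kept = [b for b in blocks if len(b.rows) >= cfg.min_species]
    logger.info("species-count filter kept %d of %d blocks", len(kept), len(blocks))
    return kept


def curate_pairwise(
    per_species: dict[str, list[AlignmentBlock]],
    ref_name: str,
    cfg: CurationConfig | None = None,
) -> list[AlignmentBlock]:
    """Full curation chain: N-clean, overlap-resolve, merge, species filter."""
    cfg = cfg or CurationConfig()
    cleaned = {
        sp: resolve_reference_overlaps(
            [piece for b in blocks for piece in trim_and_split_n(b, cfg)]
        )
        for sp, blocks in per_species.items()
    }
    merged = merge_reference_anchored(cleaned, ref_name)
    return filter_species_count(merged, cfg)
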