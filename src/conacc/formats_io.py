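"""Readers and writers for the standard formats the pipeline touches.

MAF, GFF3, BED6, Newick and FASTA all pass through here and are converted to
a single internal convention: 0-based half-open intervals on the reference
forward strand.  MAF rows keep their raw strand-relative fields so that
write-back is lossless.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import gffutils
import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval
from .phylo import PhyloTree, read_newick, write_newick  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)

_ALPHABET = set("ACGTN-")

NCRNA_BIOTYPES = {"snRNA", "lncRNA", "miRNA", "rRNA", "snoRNA", "scRNA"}
BIOTYPES = {"protein_coding"} | NCRNA_BIOTYPES | {"other"}


class MafFormatError(ValueError):
    """Malformed MAF content (with the offending line number when known)."""


@dataclass
class AlignmentRow:
    """One 's' line of a MAF block.

    ``src_start`` is 0-based and strand-relative exactly as in MAF; ``size``
    counts non-gap bases; ``text`` is the gapped sequence over {A,C,G,T,N,-}.
    """

    species: str
    src: str
    src_start: int
    size: int
    src_size: int
    strand: str
    text: str

    def __post_init__(self) -> None:
        clean = []
        mapped = 0
        for ch in self.text.upper():
            if ch not in _ALPHABET:
                mapped += 1
                ch = "N"
            clean.append(ch)
        if mapped:
            logger.warning(
                "%d non-ACGTN characters mapped to N in row %s", mapped, self.src
            )
        self.text = "".join(clean)
        ungapped = len(self.text) - self.text.count("-")
        if ungapped != self.size:
            raise MafFormatError(
                f"row {self.src}: size {self.size} != non-gap count {ungapped}"
            )
        if self.src_start + self.size > self.src_size:
            raise MafFormatError(
                f"row {self.src}: src_start + size exceeds src_size"
            )

    @property
    def chrom(self) -> str:
        """Sequence name with any 'species.' prefix stripped."""
        return self.src.split(".", 1)[1] if "." in self.src else self.src

    def forward_interval(self) -> GenomicInterval:
        """Interval on the forward strand of the source sequence."""
        if self.strand == "+":
            start = self.src_start
        else:
            start = self.src_size - self.src_start - self.size
        return GenomicInterval(self.chrom, start, start + self.size, "+")


@dataclass
class AlignmentBlock:
    """One MAF block; the reference row is ``rows[0]`` and is forward-strand."""

    rows: list[AlignmentRow]

    def __post_init__(self) -> None:
        if not self.rows:
            raise MafFormatError("block with no rows")
        n = len(self.rows[0].text)
        for r in self.rows:
            if len(r.text) != n:
                raise MafFormatError("rows differ in column count")
        seen = set()
        for r in self.rows:
            if r.species in seen:
                raise MafFormatError(f"duplicate species {r.species} in block")
            seen.add(r.species)

    @property
    def ncols(self) -> int:
        return len(self.rows[0].text)

    @property
    def reference(self) -> AlignmentRow:
        return self.rows[0]

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.rows]

    def ref_interval(self) -> GenomicInterval:
        ref = self.reference
        if ref.strand != "+":
            raise MafFormatError("reference row must be forward strand")
        return GenomicInterval(ref.chrom, ref.src_start, ref.src_start + ref.size)

    def slice_columns(self, start: int, stop: int) -> "AlignmentBlock":
        """Column slice with per-row source coordinates recomputed."""
        rows = []
        for r in self.rows:
            prefix = r.text[:start]
            offset = len(prefix) - prefix.count("-")
            sub = r.text[start:stop]
            rows.append(
                replace(
                    r,
                    src_start=r.src_start + offset,
                    size=len(sub) - sub.count("-"),
                    text=sub,
                )
            )
        return AlignmentBlock(rows)

    def ref_column_positions(self) -> np.ndarray:
        """For each column, the reference coordinate, or -1 on a reference gap."""
        ref = self.reference
        out = np.full(self.ncols, -1, dtype=np.int64)
        pos = ref.src_start
        for i, ch in enumerate(ref.text):
            if ch != "-":
                out[i] = pos
                pos += 1
        return out


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------


def read_maf(path) -> list[AlignmentBlock]:
    """Read a UCSC-dialect MAF file into a list of blocks (file order).

    Row species labels are the text before the first '.' in the MAF ``src``
    field; sequence is uppercased, non-ACGTN characters become N.
    """
    blocks: list[AlignmentBlock] = []
    try:
        with open(path) as fh:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for msa in AlignIO.parse(fh, "maf"):
                    rows = []
                    for rec in msa:
                        ann = rec.annotations
                        rows.append(
                            AlignmentRow(
                                species=rec.id.split(".", 1)[0],
                                src=rec.id,
                                src_start=int(ann["start"]),
                                size=int(ann["size"]),
                                src_size=int(ann["srcSize"]),
                                strand="+" if ann["strand"] in (1, "+") else "-",
                                text=str(rec.seq),
                            )
                        )
                    blocks.append(AlignmentBlock(rows))
    except ValueError as exc:
        if isinstance(exc, MafFormatError):
            raise
        raise MafFormatError(f"{path}: {exc}") from exc
    return blocks


def write_maf(blocks, path) -> None:
    """Write blocks in MAF with single-space-separated 's' fields."""
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for block in blocks:
            fh.write("a\n")
            for r in block.rows:
                fh.write(
                    f"s {r.src} {r.src_start} {r.size} {r.strand} "
                    f"{r.src_size} {r.text}\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

FEATURE_CATEGORIES = ("CDS", "five_prime_UTR", "three_prime_UTR", "exon")


@dataclass
class GeneModel:
    """A gene with its span and exon-level features on one chromosome."""

    gene_id: str
    name: str
    biotype: str
    span: GenomicInterval
    features: list[tuple[str, GenomicInterval]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cat, iv in self.features:
            if cat not in FEATURE_CATEGORIES:
                raise ValueError(f"unknown feature category {cat!r}")
            if (
                iv.chrom != self.span.chrom
                or iv.start < self.span.start
                or iv.end > self.span.end
            ):
                raise ValueError(
                    f"gene {self.gene_id}: feature {cat} {iv} outside gene span"
                )

    @property
    def is_coding(self) -> bool:
        return self.biotype == "protein_coding"

    @property
    def is_ncrna(self) -> bool:
        return self.biotype in NCRNA_BIOTYPES

    def features_of(self, category: str) -> list[GenomicInterval]:
        return [iv for cat, iv in self.features if cat == category]


def _gff_biotype(attrs) -> str:
    for key in ("gene_biotype", "biotype"):
        if key in attrs:
            bt = attrs[key][0]
            return bt if bt in BIOTYPES else "other"
    return "other"


def read_gff3(path) -> list[GeneModel]:
    """Read gene models from GFF3 (1-based closed -> 0-based half-open).

    Features whose Parent chain does not reach a gene are skipped with a
    warning.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    genes: list[GeneModel] = []
    attached = set()
    for g in db.features_of_type(("gene", "ncRNA_gene"), order_by="start"):
        span = GenomicInterval(g.seqid, g.start - 1, g.end)
        features = []
        for ft in FEATURE_CATEGORIES:
            for child in db.children(g, featuretype=ft):
                attached.add(child.id)
                features.append(
                    (ft, GenomicInterval(child.seqid, child.start - 1, child.end))
                )
        for child in db.children(g):
            attached.add(child.id)
        attrs = dict(g.attributes)
        genes.append(
            GeneModel(
                gene_id=g.id,
                name=attrs.get("Name", [g.id])[0],
                biotype=_gff_biotype(attrs),
                span=span,
                features=features,
            )
        )
    orphans = [
        f.id
        for f in db.all_features()
        if "Parent" in f.attributes and f.id not in attached
    ]
    if orphans:
        logger.warning("skipped %d GFF3 features with orphan Parent", len(orphans))
    return genes


def write_gff3(genes: list[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene + mRNA/transcript + features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};Name={g.name};gene_biotype={g.biotype}"
            fh.write(
                f"{g.span.chrom}\tconacc\tgene\t{g.span.start + 1}\t{g.span.end}"
                f"\t.\t{g.span.strand}\t.\t{attrs}\n"
            )
            if not g.features:
                continue
            tid = f"{g.gene_id}.t1"
            ttype = "mRNA" if g.is_coding else "transcript"
            fh.write(
                f"{g.span.chrom}\tconacc\t{ttype}\t{g.span.start + 1}\t{g.span.end}"
                f"\t.\t{g.span.strand}\t.\tID={tid};Parent={g.gene_id}\n"
            )
            for i, (cat, iv) in enumerate(g.features, 1):
                phase = "0" if cat == "CDS" else "."
                fh.write(
                    f"{iv.chrom}\tconacc\t{cat}\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{g.span.strand}\t{phase}\tID={tid}.{cat}.{i};Parent={tid}\n"
                )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_bed(calls, path) -> None:
    """Write ``(GenomicInterval, name, score)`` triples as BED6."""
    with open(path, "w") as fh:
        for iv, name, score in calls:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def read_bed(path) -> list[tuple[GenomicInterval, str, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            score = parts[4] if len(parts) > 4 else "0"
            strand = parts[5] if len(parts) > 5 else "+"
            out.append((GenomicInterval(chrom, start, end, strand), name, score))
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
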