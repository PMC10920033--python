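"""Synthetic desk-scale datasets with known ground truth.

Emulates the study system: an 8-taxon alignment (seven anole species plus an
outgroup) whose regions evolve neutrally, under all-branch conservation
(rate scale < 1), or under acceleration on one named branch (scale > 1);
gene models in the five annotation categories plus standalone ncRNA genes;
per-species coding sequence with controllable codon-usage bias; and optional
curation artefacts (edge/internal N runs, overlapping duplicate blocks,
missing species).  Every generator takes an explicit seed and is
deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .codon_neutral import AA_FAMILIES, CODON_TO_AA
from .formats_io import (
    AlignmentBlock,
    AlignmentRow,
    GeneModel,
    write_gff3,
    write_maf,
)
from .intervals import GenomicInterval
from .model import SubstModel, decode_columns
from .phylo import PhyloTree, ScaledTree, simulate_columns

#: taxa of the emulated system; the first is the reference
DEFAULT_TAXA = (
    "A_carolinensis",
    "A_porcatus",
    "A_allisoni",
    "A_isolepis",
    "A_sagrei",
    "A_homolechis",
    "A_allogus",
    "A_frenatus",
)

DEFAULT_BRANCH_LENGTH = 0.05

#: default target branches for acceleration scans: the seven ingroup
#: terminal branches plus the ancestor of the three hot-open trunk-crown taxa
DEFAULT_TARGET_BRANCHES = (
    "A_carolinensis",
    "A_porcatus",
    "A_allisoni",
    "A_isolepis",
    "A_sagrei",
    "A_homolechis",
    "A_allogus",
    "TC_open",
)


def default_tree(
    branch_length: float = DEFAULT_BRANCH_LENGTH,
    overrides: dict[str, float] | None = None,
) -> PhyloTree:
    """The default 8-taxon tree with the TC_open internal branch labelled.

    Topology: ((((carolinensis,(porcatus,allisoni))TC_open,isolepis),
    (sagrei,(homolechis,allogus))),frenatus).  All branch lengths default to
    ``branch_length``; ``overrides`` adjusts named branches (leaf names or
    'TC_open').
    """
    L = branch_length
    text = (
        f"((((A_carolinensis:{L},(A_porcatus:{L},A_allisoni:{L}):{L})TC_open:{L},"
        f"A_isolepis:{L}):{L},(A_sagrei:{L},(A_homolechis:{L},A_allogus:{L}):{L}):{L})"
        f":{L},A_frenatus:{L});"
    )
    tree = PhyloTree.from_newick(text)
    for name, length in (overrides or {}).items():
        tree.lengths[tree.branch_index(name)] = float(length)
    return tree


def default_model() -> SubstModel:
    """A GTR model with mild GC skew and transition bias, unit mean rate."""
    return SubstModel(
        pi=np.array([0.3, 0.2, 0.2, 0.3]),
        exch=np.array([1.0, 4.0, 1.0, 1.0, 4.0, 1.0]),
    )


# ---------------------------------------------------------------------------
# region plans
# ---------------------------------------------------------------------------


@dataclass
class PlanRegion:
    """One tile of the synthetic reference with its evolutionary class."""

    start: int
    end: int
    cls: str  # neutral | conserved | accelerated
    scale: float = 1.0
    target_branch: str | None = None
    category: str = "intergenic"
    gene_id: str | None = None
    biotype: str | None = None  # ncRNA biotype for standalone ncRNA genes

    def __post_init__(self) -> None:
        if self.cls not in ("neutral", "conserved", "accelerated"):
            raise ValueError(f"unknown region class {self.cls!r}")
        if self.cls == "conserved" and not (0 < self.scale < 1):
            raise ValueError("conserved regions need 0 < scale < 1")
        if self.cls == "accelerated":
            if self.scale <= 1:
                raise ValueError("accelerated regions need scale > 1")
            if not self.target_branch:
                raise ValueError("accelerated regions need a target branch")


@dataclass
class RegionPlan:
    """Regions tiling one synthetic reference chromosome without gaps."""

    regions: list[PlanRegion]
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        pos = None
        for r in self.regions:
            if r.end <= r.start:
                raise ValueError("empty plan region")
            if pos is not None and r.start != pos:
                raise ValueError("plan regions must tile the reference contiguously")
            pos = r.end

    @property
    def length(self) -> int:
        return self.regions[-1].end if self.regions else 0

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "class": [r.cls for r in self.regions],
                "scale": [r.scale for r in self.regions],
                "target_branch": [r.target_branch or "" for r in self.regions],
                "category": [r.category for r in self.regions],
                "gene_id": [r.gene_id or "" for r in self.regions],
            }
        )


def plan_windows(
    n_neutral: int,
    n_conserved: int = 0,
    n_accelerated: int = 0,
    window: int = 60,
    conserved_scale: float = 0.1,
    accelerated_scale: float = 10.0,
    target_branch: str = "A_sagrei",
    seed: int = 0,
) -> RegionPlan:
    """A shuffled tiling of fixed-size intergenic regions of the three classes.

    Default implanted scales are rho = 0.1 (conserved) and lambda = 10
    (accelerated on one branch), strong enough for single-window power at
    60-base windows and 0.05-substitution branch lengths.
    """
    rng = np.random.default_rng(seed)
    classes = (
        ["neutral"] * n_neutral
        + ["conserved"] * n_conserved
        + ["accelerated"] * n_accelerated
    )
    rng.shuffle(classes)
    regions = []
    pos = 0
    for cls in classes:
        scale = {"neutral": 1.0, "conserved": conserved_scale, "accelerated": accelerated_scale}[cls]
        regions.append(
            PlanRegion(
                start=pos,
                end=pos + window,
                cls=cls,
                scale=scale,
                target_branch=target_branch if cls == "accelerated" else None,
            )
        )
        pos += window
    return RegionPlan(regions=regions)


def plan_gene_cassette(
    n_repeats: int = 1,
    part: int = 60,
    seed: int = 0,
    ncrna_every: int = 2,
) -> RegionPlan:
    """Neutral regions arranged as gene cassettes covering every category.

    Each repeat is intergenic / 5'-UTR / CDS / intron / CDS / 3'-UTR /
    intergenic, followed every ``ncrna_every`` repeats by a standalone ncRNA
    gene inside the trailing intergenic stretch.
    """
    regions: list[PlanRegion] = []
    pos = 0

    def add(category: str, gene: str | None, biotype: str | None = None, size: int = part):
        nonlocal pos
        regions.append(
            PlanRegion(
                start=pos, end=pos + size, cls="neutral",
                category=category, gene_id=gene, biotype=biotype,
            )
        )
        pos += size

    for i in range(n_repeats):
        gid = f"gene{i + 1}"
        add("intergenic", None)
        add("five_prime_UTR", gid)
        add("CDS", gid)
        add("intron", gid)
        add("CDS", gid)
        add("three_prime_UTR", gid)
        add("intergenic", None)
        if ncrna_every and (i + 1) % ncrna_every == 0:
            add("intergenic", f"ncrna{i + 1}", biotype="lncRNA")
            add("intergenic", None)
    return RegionPlan(regions=regions)


def genes_from_plan(plan: RegionPlan) -> list[GeneModel]:
    """Gene models whose annotation reproduces the plan's categories."""
    by_gene: dict[str, list[PlanRegion]] = {}
    for r in plan.regions:
        if r.gene_id:
            by_gene.setdefault(r.gene_id, []).append(r)
    genes = []
    for gid, regs in by_gene.items():
        start = min(r.start for r in regs)
        end = max(r.end for r in regs)
        span = GenomicInterval(plan.chrom, start, end)
        biotypes = {r.biotype for r in regs if r.biotype}
        if biotypes:
            (biotype,) = biotypes
            genes.append(GeneModel(gene_id=gid, name=gid, biotype=biotype, span=span))
            continue
        features = []
        for r in regs:
            if r.category in ("CDS", "five_prime_UTR", "three_prime_UTR"):
                features.append(
                    (r.category, GenomicInterval(plan.chrom, r.start, r.end))
                )
            elif r.category == "intron":
                pass  # span minus features is intron by definition
            else:
                raise ValueError(
                    f"gene {gid}: region category {r.category} inconsistent with a gene"
                )
        genes.append(
            GeneModel(
                gene_id=gid, name=gid, biotype="protein_coding",
                span=span, features=features,
            )
        )
    return sorted(genes, key=lambda g: g.span.start)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    blocks: list[AlignmentBlock]
    genes: list[GeneModel]
    truth: pd.DataFrame
    tree: PhyloTree
    model: SubstModel
    plan: RegionPlan

    def write(self, maf_path, gff3_path, truth_path) -> None:
        write_maf(self.blocks, maf_path)
        write_gff3(self.genes, gff3_path)
        self.truth.to_csv(truth_path, sep="\t", index=False)


def _region_scaled_tree(tree: PhyloTree, region: PlanRegion) -> ScaledTree:
    if region.cls == "conserved":
        return ScaledTree(tree, global_scale=region.scale)
    if region.cls == "accelerated":
        return ScaledTree(tree, branch_scales={region.target_branch: region.scale})
    return ScaledTree(tree)


def generate_dataset(
    plan: RegionPlan,
    tree: PhyloTree | None = None,
    model: SubstModel | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate an 8-species alignment (one block per plan region) plus genes.

    Conserved regions scale every branch by their rho; accelerated regions
    scale only their target branch by lambda.  Alignments are gap-free;
    deterministic given the seed.
    """
    tree = tree or default_tree()
    model = model or default_model()
    rng = np.random.default_rng(seed)
    taxa = tree.leaf_labels
    ref = taxa[0]
    blocks = []
    chrom_len = plan.length
    for region in plan.regions:
        n = region.end - region.start
        cols = simulate_columns(_region_scaled_tree(tree, region), model, n, rng)
        seqs = decode_columns(cols)
        rows = []
        for sp, seq in zip(taxa, seqs):
            src = f"{sp}.chr1" if sp == ref else f"{sp}.scaf1"
            rows.append(
                AlignmentRow(
                    species=sp,
                    src=src,
                    src_start=region.start,
                    size=n,
                    src_size=chrom_len,
                    strand="+",
                    text=seq,
                )
            )
        # reference row first, in plan chromosome naming
        rows[0] = replace(rows[0], src=f"{ref}.{plan.chrom}")
        blocks.append(AlignmentBlock(rows))
    genes = genes_from_plan(plan)
    return SyntheticDataset(
        blocks=blocks,
        genes=genes,
        truth=plan.truth_frame(),
        tree=tree,
        model=model,
        plan=plan,
    )


# ---------------------------------------------------------------------------
# curation artefacts
# ---------------------------------------------------------------------------


@dataclass
class ArtifactConfig:
    """Curation artefacts injected into per-species pairwise alignments."""

    edge_n_fraction: float = 0.2       # fraction of blocks given an edge N run
    edge_n_length: int = 4
    internal_n_fraction: float = 0.1   # fraction given an over-threshold N run
    internal_n_length: int = 0         # 0 = just over half the block
    missing_species_fraction: float = 0.05
    duplicate_fraction: float = 0.1    # fraction of blocks duplicated (shorter)


def to_pairwise(
    blocks: list[AlignmentBlock], ref_name: str | None = None
) -> dict[str, list[AlignmentBlock]]:
    """Decompose multi-species blocks into per-species pairwise blocks."""
    out: dict[str, list[AlignmentBlock]] = {}
    for block in blocks:
        ref = block.reference
        if ref_name is not None and ref.species != ref_name:
            raise ValueError(f"reference row is {ref.species}, expected {ref_name}")
        for row in block.rows[1:]:
            out.setdefault(row.species, []).append(AlignmentBlock([ref, row]))
    return out


def _with_n_run(row: AlignmentRow, start: int, length: int) -> AlignmentRow:
    text = list(row.text)
    for i in range(start, min(start + length, len(text))):
        if text[i] != "-":
            text[i] = "N"
    return replace(row, text="".join(text))


def inject_artifacts(
    per_species: dict[str, list[AlignmentBlock]],
    cfg: ArtifactConfig,
    seed: int = 0,
) -> dict[str, list[AlignmentBlock]]:
    """Add edge/internal N runs, duplicate overlapping blocks, drop species.

    Bases outside injected N runs are never altered; duplicates are shortened
    copies so that overlap resolution prefers the original.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[AlignmentBlock]] = {}
    species = sorted(per_species)
    for sp in species:
        new_blocks = []
        for block in per_species[sp]:
            if rng.random() < cfg.missing_species_fraction:
                continue
            rows = list(block.rows)
            if rng.random() < cfg.edge_n_fraction:
                rows[1] = _with_n_run(rows[1], 0, cfg.edge_n_length)
            if rng.random() < cfg.internal_n_fraction and block.ncols >= 8:
                run = cfg.internal_n_length or (block.ncols // 2 + 1)
                start = max(1, (block.ncols - run) // 2)
                rows[1] = _with_n_run(rows[1], start, run)
            fixed = AlignmentBlock(
                [replace(r, text=r.text, size=len(r.text) - r.text.count("-"))
                 for r in rows]
            )
            new_blocks.append(fixed)
            if rng.random() < cfg.duplicate_fraction and fixed.ncols >= 10:
                cut = int(rng.integers(2, fixed.ncols // 2))
                new_blocks.append(fixed.slice_columns(cut, fixed.ncols))
        out[sp] = new_blocks
    return out


# ---------------------------------------------------------------------------
# codon data with controllable usage bias
# ---------------------------------------------------------------------------


def default_bias_spec() -> dict[str, float]:
    """Under-representation of CTA, TCG, CCG, ACG and GCG (target RSCU 0.3)."""
    return {c: 0.3 for c in ("CTA", "TCG", "CCG", "ACG", "GCG")}


def _family_probabilities(bias_spec: dict[str, float]) -> dict[str, float]:
    """Per-codon sampling probabilities within each synonymous family."""
    probs: dict[str, float] = {}
    for aa, family in AA_FAMILIES.items():
        k = len(family)
        fixed = {c: bias_spec[c] for c in family if c in bias_spec}
        spent = sum(fixed.values())
        if spent > k + 1e-9:
            raise ValueError(f"bias spec for {aa} family exceeds the family sum {k}")
        free = [c for c in family if c not in fixed]
        if not free and abs(spent - k) > 1e-9:
            raise ValueError(f"bias spec for {aa} family must sum to {k}")
        share = (k - spent) / len(free) if free else 0.0
        for c in family:
            probs[c] = fixed.get(c, share) / k
    return probs


@dataclass
class CodonDataset:
    cds_by_species: dict[str, dict[str, str]]
    codon_alignments: list[tuple[str, dict[str, str]]] = field(default_factory=list)

    def species_counts(self) -> dict[str, dict[str, int]]:
        from .codon_neutral import codon_counts_from_seqs

        return {
            sp: codon_counts_from_seqs(seqs.values())
            for sp, seqs in self.cds_by_species.items()
        }


def generate_biased_codon_data(
    bias_spec: dict[str, float] | None = None,
    n_genes: int = 200,
    codons_per_gene: int = 300,
    species: tuple[str, ...] = DEFAULT_TAXA,
    per_species_overrides: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
) -> CodonDataset:
    """Per-species CDS with codon usage matching target RSCU values.

    Within each synonymous family the codon counts are allocated
    deterministically in proportion to the target RSCU (largest-remainder
    rounding), so the realised RSCU matches the spec to within rounding;
    only the arrangement into genes is random.  All species share the same
    bias unless per-species overrides are given; codon alignments are
    identical across species (gap-free, in frame).
    """
    bias_spec = default_bias_spec() if bias_spec is None else bias_spec
    rng = np.random.default_rng(seed)
    total_codons = n_genes * codons_per_gene
    aas = sorted(AA_FAMILIES)
    aa_seq = [aas[i % len(aas)] for i in range(total_codons)]
    rng.shuffle(aa_seq)

    def _allocate(weights: np.ndarray, n: int) -> np.ndarray:
        """Largest-remainder allocation of n items proportional to weights."""
        if weights.sum() <= 0:
            weights = np.ones_like(weights)
        raw = weights / weights.sum() * n
        counts = np.floor(raw).astype(int)
        remainder = raw - counts
        for i in np.argsort(-remainder)[: n - counts.sum()]:
            counts[i] += 1
        return counts

    def build_codon_stream(spec: dict[str, float], shuffle_rng) -> list[str]:
        probs = _family_probabilities(spec)
        stream_by_aa: dict[str, list[str]] = {}
        for aa, family in AA_FAMILIES.items():
            n = sum(1 for a in aa_seq if a == aa)
            weights = np.array([probs[c] * len(family) for c in family])
            counts = _allocate(weights, n)
            pool = [c for c, m in zip(family, counts) for _ in range(m)]
            shuffle_rng.shuffle(pool)
            stream_by_aa[aa] = pool
        cursors = {aa: 0 for aa in aas}
        stream = []
        for aa in aa_seq:
            stream.append(stream_by_aa[aa][cursors[aa]])
            cursors[aa] += 1
        return stream

    def rebias_stream(base: list[str], spec: dict[str, float], shuffle_rng) -> list[str]:
        """Reassign third bases within (aa, prefix) groups to match spec.

        Keeps the family-prefix arrangement of the base stream so codon
        alignments stay prefix-consistent across species.
        """
        probs = _family_probabilities(spec)
        groups: dict[tuple[str, str], list[int]] = {}
        for i, codon in enumerate(base):
            groups.setdefault((CODON_TO_AA[codon], codon[:2]), []).append(i)
        out = list(base)
        for (aa, prefix), idx in groups.items():
            members = [c for c in AA_FAMILIES[aa] if c[:2] == prefix]
            if len(members) == 1:
                continue
            weights = np.array([probs[c] for c in members])
            counts = _allocate(weights, len(idx))
            pool = [c for c, m in zip(members, counts) for _ in range(m)]
            shuffle_rng.shuffle(pool)
            for i, codon in zip(idx, pool):
                out[i] = codon
        return out

    base_stream = build_codon_stream(
        bias_spec, np.random.default_rng(rng.integers(2**31))
    )
    cds_by_species: dict[str, dict[str, str]] = {}
    for sp in species:
        spec = (per_species_overrides or {}).get(sp)
        stream = (
            base_stream
            if spec is None
            else rebias_stream(
                base_stream, spec, np.random.default_rng(rng.integers(2**31))
            )
        )
        genes = {}
        for gi in range(n_genes):
            chunk = stream[gi * codons_per_gene : (gi + 1) * codons_per_gene]
            genes[f"gene{gi + 1}"] = "".join(chunk)
        cds_by_species[sp] = genes
    alignments = [
        (f"gene{gi + 1}", {sp: cds_by_species[sp][f"gene{gi + 1}"] for sp in species})
        for gi in range(n_genes)
    ]
    return CodonDataset(cds_by_species=cds_by_species, codon_alignments=alignments)
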