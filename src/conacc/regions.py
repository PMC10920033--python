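"""Interval-level downstream analyses of element calls.

Covers the AR-vs-CE overlap requirement for noncoding ARs, gene association
through annotation categories and 5-kb gene flanks, the >80% ncRNA-overlap
filter, Fisher/chi-square enrichment statistics, detection of genes commonly
accelerated in habitat-matched lineages, and the summary-report arithmetic
(coverage and category percentages recomputed from integer counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree
from scipy.stats import chi2_contingency, fisher_exact

from .formats_io import GeneModel
from .intervals import GenomicInterval
from .scan import ElementCall

ASSOCIATION_CATEGORIES = (
    "CDS",
    "three_prime_UTR",
    "five_prime_UTR",
    "intron",
    "upstream5kb",
    "downstream5kb",
)


@dataclass
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = group, columns = with/without property."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    def as_list(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]

    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return (self.a * self.d) / (self.b * self.c)


@dataclass
class GeneAssociationTable:
    """Genes associated with one lineage's ARs, by annotation category."""

    lineage: str
    by_category: dict[str, set[str]] = field(
        default_factory=lambda: {c: set() for c in ASSOCIATION_CATEGORIES}
    )
    window_genes: dict[str, set[str]] = field(default_factory=dict)
    ce_overlap_required: bool = True

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.by_category.values():
            out |= genes
        return out

    def counts(self) -> dict[str, int]:
        return {c: len(g) for c, g in self.by_category.items()}


def _coverage_tree(features: list[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in features:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    for t in trees.values():
        t.merge_overlaps()
    return trees


def _overlap_bases(trees: dict[str, IntervalTree], iv: GenomicInterval) -> int:
    tree = trees.get(iv.chrom)
    if tree is None:
        return 0
    return sum(
        min(h.end, iv.end) - max(h.begin, iv.start) for h in tree.overlap(iv.start, iv.end)
    )


def overlap_filter(
    windows: list[ElementCall],
    features: list[GenomicInterval],
    min_frac: float,
) -> list[ElementCall]:
    """Keep windows whose overlapped fraction strictly exceeds ``min_frac``."""
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    trees = _coverage_tree(features)
    return [
        w
        for w in windows
        if _overlap_bases(trees, w.ref_interval) > min_frac * len(w.ref_interval)
    ]


def ar_ce_overlap(ars: list[ElementCall], ces: list[ElementCall]) -> list[ElementCall]:
    """Keep intron/intergenic ARs only when they overlap an all-branch CE.

    Overlap means at least one shared base; ARs of other categories pass
    through untouched.
    """
    trees = _coverage_tree([c.ref_interval for c in ces])
    out = []
    for ar in ars:
        if ar.category not in ("intron", "intergenic"):
            out.append(ar)
        elif _overlap_bases(trees, ar.ref_interval) >= 1:
            out.append(ar)
    return out


def gene_flanks(
    gene: GeneModel,
    distance: int = 5000,
    chrom_length: int | None = None,
) -> tuple[GenomicInterval | None, GenomicInterval | None]:
    """Strand-aware 5' (upstream) and 3' (downstream) flanks of a gene span.

    Flanks are clipped at position 0 and at ``chrom_length`` when given;
    a flank clipped to zero length is returned as None.
    """
    span = gene.span
    left_lo = max(0, span.start - distance)
    right_hi = span.end + distance
    if chrom_length is not None:
        right_hi = min(right_hi, chrom_length)
    left = (
        GenomicInterval(span.chrom, left_lo, span.start)
        if left_lo < span.start
        else None
    )
    right = (
        GenomicInterval(span.chrom, span.end, right_hi)
        if span.end < right_hi
        else None
    )
    if span.strand == "+":
        return left, right
    return right, left


def associate_genes(
    ars: list[ElementCall],
    ces: list[ElementCall],
    genes: list[GeneModel],
    ce_overlap_required: bool = True,
    flank_distance: int = 5000,
    chrom_lengths: dict[str, int] | None = None,
    lineage: str = "",
) -> GeneAssociationTable:
    """Map a lineage's ARs to genes they sit in or near.

    CDS/UTR/intron ARs contribute the gene IDs attached at annotation time;
    intergenic ARs contribute genes whose 5-kb flank they overlap by at least
    one base.  When ``ce_overlap_required`` is set, intron/intergenic ARs
    must overlap an all-branch CE first.
    """
    table = GeneAssociationTable(lineage=lineage, ce_overlap_required=ce_overlap_required)
    if ce_overlap_required:
        ars = ar_ce_overlap(ars, ces)
    coding = [g for g in genes if g.is_coding]
    up_trees: dict[str, IntervalTree] = {}
    down_trees: dict[str, IntervalTree] = {}
    for g in coding:
        clen = (chrom_lengths or {}).get(g.span.chrom)
        up, down = gene_flanks(g, flank_distance, clen)
        if up is not None:
            up_trees.setdefault(up.chrom, IntervalTree()).addi(up.start, up.end, g.gene_id)
        if down is not None:
            down_trees.setdefault(down.chrom, IntervalTree()).addi(
                down.start, down.end, g.gene_id
            )
    for ar in ars:
        contributed: set[str] = set()
        if ar.category in ("CDS", "three_prime_UTR", "five_prime_UTR", "intron"):
            table.by_category[ar.category] |= set(ar.gene_ids)
            contributed |= set(ar.gene_ids)
        elif ar.category == "intergenic":
            iv = ar.ref_interval
            for trees, cat in ((up_trees, "upstream5kb"), (down_trees, "downstream5kb")):
                tree = trees.get(iv.chrom)
                if tree is None:
                    continue
                hits = {h.data for h in tree.overlap(iv.start, iv.end)}
                table.by_category[cat] |= hits
                contributed |= hits
        if contributed:
            table.window_genes.setdefault(ar.window_id, set()).update(contributed)
    return table


def fisher_enrichment(
    table: ContingencyTable2x2, sided: str = "greater"
) -> tuple[float, float]:
    """Fisher's exact test; returns (odds ratio ad/bc, p-value)."""
    alternative = {"greater": "greater", "two": "two-sided"}[sided]
    _, p = fisher_exact(table.as_list(), alternative=alternative)
    return table.odds_ratio(), float(p)


def chi_square_2x2(table: ContingencyTable2x2) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction; df = 1."""
    cells = table.as_list()
    rows = [sum(r) for r in cells]
    cols = [cells[0][j] + cells[1][j] for j in range(2)]
    n = sum(rows)
    if min(rows) == 0 or min(cols) == 0:
        raise ValueError("chi-square needs positive margins")
    if any(r * c == 0 for r in rows for c in cols) or n == 0:
        raise ValueError("all expected counts must be positive")
    stat, p, dof, _ = chi2_contingency(cells, correction=False)
    return float(stat), int(dof), float(p)


def ncrna_contingency(
    n_group: int,
    k_group: int,
    n_all: int,
    k_all: int,
    background_mode: str = "exclusive",
) -> ContingencyTable2x2:
    """2x2 table for ncRNA enrichment of a call set against the alignment.

    ``exclusive`` subtracts the group from the all-windows background so the
    cells are disjoint; ``inclusive`` compares against the full alignment as
    printed in the study's tables.
    """
    if background_mode == "exclusive":
        return ContingencyTable2x2(
            k_group, n_group - k_group, k_all - k_group, (n_all - n_group) - (k_all - k_group)
        )
    if background_mode == "inclusive":
        return ContingencyTable2x2(k_group, n_group - k_group, k_all, n_all - k_all)
    raise ValueError("background_mode must be 'exclusive' or 'inclusive'")


def common_accelerated_genes(
    assoc_a: GeneAssociationTable, assoc_b: GeneAssociationTable
) -> list[tuple[str, bool]]:
    """Genes accelerated in both lineages (categories may differ).

    ``same_window`` is True when some window is an AR in both lineages and
    contributes the gene in both.
    """
    shared = assoc_a.all_genes() & assoc_b.all_genes()
    common_windows = set(assoc_a.window_genes) & set(assoc_b.window_genes)
    out = []
    for gene in sorted(shared):
        same = any(
            gene in assoc_a.window_genes[w] and gene in assoc_b.window_genes[w]
            for w in common_windows
        )
        out.append((gene, same))
    return out


# ---------------------------------------------------------------------------
# summary report
# ---------------------------------------------------------------------------


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded to the given decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, decimals)


def summary_report(
    aligned_bases: int,
    reference_length: int,
    windows,
    ces: list[ElementCall],
    ars_by_branch: dict[str, list[ElementCall]],
    ncrna_features: list[GenomicInterval],
    ncrna_min_frac: float = 0.8,
    background_mode: str = "exclusive",
) -> dict:
    """Pipeline-level summary statistics.

    All percentages recompute from their integer numerators/denominators:
    alignment coverage (1 decimal), CE length share of the alignment
    (2 decimals), per-category base fractions, per-lineage AR counts, and
    ncRNA-overlap proportions (2 decimals) with Fisher enrichment p-values.
    """
    report: dict = {
        "aligned_bases": aligned_bases,
        "reference_length": reference_length,
        "coverage_pct": percent(aligned_bases, reference_length, 1),
    }
    window_list = list(windows)
    n_windows = len(window_list)
    total_window_bases = sum(len(w.ref_interval) for w in window_list)
    by_cat: dict[str, int] = {}
    for w in window_list:
        by_cat[w.category] = by_cat.get(w.category, 0) + len(w.ref_interval)
    report["n_windows"] = n_windows
    report["category_base_fraction"] = {
        c: round(b / total_window_bases, 4) if total_window_bases else 0.0
        for c, b in sorted(by_cat.items())
    }
    ce_len = sum(len(c.ref_interval) for c in ces)
    report["ce_total_length"] = ce_len
    report["ce_pct_of_alignment"] = (
        percent(ce_len, aligned_bases, 2) if aligned_bases else 0.0
    )
    report["n_ce_windows"] = len(ces)

    trees = _coverage_tree(ncrna_features)

    def ncrna_count(calls) -> int:
        return sum(
            1
            for c in calls
            if _overlap_bases(trees, c.ref_interval)
            > ncrna_min_frac * len(c.ref_interval)
        )

    k_all = sum(
        1
        for w in window_list
        if _overlap_bases(trees, w.ref_interval) > ncrna_min_frac * len(w.ref_interval)
    )
    report["ncrna_windows_all"] = k_all
    report["ncrna_pct_all"] = percent(k_all, n_windows, 2) if n_windows else 0.0
    groups = {"all_branch_CE": ces, **{f"AR:{b}": a for b, a in ars_by_branch.items()}}
    enrich = {}
    for name, calls in groups.items():
        n_g = len(calls)
        k_g = ncrna_count(calls)
        entry = {
            "n": n_g,
            "ncrna": k_g,
            "pct": percent(k_g, n_g, 2) if n_g else 0.0,
        }
        if n_g and n_windows > n_g:
            tab = ncrna_contingency(n_g, k_g, n_windows, k_all, background_mode)
            orat, p = fisher_enrichment(tab, "greater")
            entry["odds_ratio"] = orat
            entry["fisher_p"] = p
        enrich[name] = entry
    report["ncrna_enrichment"] = enrich
    report["ar_counts"] = {b: len(a) for b, a in ars_by_branch.items()}
    return report
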