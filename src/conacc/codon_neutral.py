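"""Codon-usage screening and neutral-model estimation.

The neutral substitution model is fitted on fourfold-degenerate (4D) third
codon positions, after removing codon families whose usage is biased.
Relative synonymous codon usage (RSCU) is computed per species over
synonymous families of the standard genetic code; codons with RSCU < 0.6 or
> 1.6 are flagged as biased, and any 4D family containing a biased codon is
excluded.  Third positions of the surviving families are extracted from
codon-aware alignments and the GTR(+gamma) model and branch lengths are
fitted by maximum likelihood on a fixed topology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from scipy.optimize import minimize, minimize_scalar

from .model import BASE_CODES, MISSING, SubstModel
from .phylo import PhyloTree, compress_columns, _pattern_log_likelihood

logger = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid (stop codons excluded)
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

#: amino acid -> synonymous codon family
AA_FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_FAMILIES.setdefault(_aa, []).append(_codon)

#: the eight fourfold-degenerate family prefixes (first two codon bases)
FOURFOLD_PREFIXES: tuple[str, ...] = tuple(
    sorted(
        {
            c[:2]
            for c in CODON_TO_AA
            if all(
                c[:2] + b in CODON_TO_AA
                and CODON_TO_AA[c[:2] + b] == CODON_TO_AA[c]
                for b in "ACGT"
            )
        }
    )
)


@dataclass
class CodonUsageTable:
    """Per-species codon counts, RSCU values, and bias flags."""

    counts: dict[str, dict[str, int]]
    rscu: dict[str, dict[str, float]] = field(default_factory=dict)
    biased: dict[str, dict[str, str]] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return list(self.counts)


def count_codons(cds: str) -> dict[str, int]:
    """Count in-frame codons of a CDS, skipping stops and ambiguous codons."""
    counts: dict[str, int] = {}
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3].upper()
        if codon in CODON_TO_AA:
            counts[codon] = counts.get(codon, 0) + 1
    return counts


def codon_counts_from_seqs(seqs) -> dict[str, int]:
    total: dict[str, int] = {}
    for s in seqs:
        for codon, n in count_codons(s).items():
            total[codon] = total.get(codon, 0) + n
    return total


def compute_rscu(cds_by_species: dict[str, dict[str, int]]) -> CodonUsageTable:
    """RSCU(c) = k * n_c / sum of counts over c's synonymous family (size k).

    Families with zero total count yield no RSCU entry (reported missing).
    """
    rscu: dict[str, dict[str, float]] = {}
    for sp, counts in cds_by_species.items():
        if any(v < 0 for v in counts.values()):
            raise ValueError(f"negative codon count for species {sp}")
        vals: dict[str, float] = {}
        for family in AA_FAMILIES.values():
            total = sum(counts.get(c, 0) for c in family)
            if total == 0:
                continue
            k = len(family)
            for c in family:
                vals[c] = k * counts.get(c, 0) / total
        rscu[sp] = vals
    return CodonUsageTable(counts=dict(cds_by_species), rscu=rscu)


def flag_biased_codons(
    table: CodonUsageTable, low: float = 0.6, high: float = 1.6
) -> CodonUsageTable:
    """Flag codons as 'under' (RSCU < low) or 'over' (RSCU > high), strictly."""
    biased: dict[str, dict[str, str]] = {}
    for sp, vals in table.rscu.items():
        flags = {}
        for codon, v in vals.items():
            flags[codon] = "under" if v < low else ("over" if v > high else "none")
        biased[sp] = flags
    table.biased = biased
    return table


def select_unbiased_4d_families(
    table: CodonUsageTable, require: str = "any"
) -> set[str]:
    """Fourfold families retained after dropping those with biased codons.

    ``require='any'`` drops a family when any of its four codons is flagged in
    any species; ``'all'`` only when flagged in every species.
    """
    if not table.biased:
        raise ValueError("bias flags not computed; call flag_biased_codons first")
    if require not in ("any", "all"):
        raise ValueError("require must be 'any' or 'all'")
    kept: set[str] = set()
    species = table.species
    for prefix in FOURFOLD_PREFIXES:
        dropped = False
        for b in "ACGT":
            codon = prefix + b
            flags = [
                table.biased.get(sp, {}).get(codon, "none") != "none"
                for sp in species
            ]
            if (require == "any" and any(flags)) or (
                require == "all" and flags and all(flags)
            ):
                dropped = True
                break
        if not dropped:
            kept.add(prefix)
    if not kept:
        raise ValueError(
            "no unbiased fourfold families remain; review the RSCU thresholds"
        )
    return kept


@dataclass
class FourfoldSiteSet:
    """Third-position columns of retained 4D codon families.

    ``columns`` is an int8 matrix (n_sites, n_taxa) of base codes in ``taxa``
    order; missing species carry code 4.  ``source`` records the originating
    (gene_id, codon index) per column.
    """

    taxa: list[str]
    columns: np.ndarray
    source: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return self.columns.shape[0]

    def base_frequencies(self) -> np.ndarray:
        """Empirical frequencies of A,C,G,T over non-missing entries."""
        flat = self.columns[self.columns != MISSING]
        counts = np.bincount(flat, minlength=4)[:4].astype(float)
        counts += 1e-6
        return counts / counts.sum()

    def reorder(self, taxa: list[str]) -> "FourfoldSiteSet":
        idx = [self.taxa.index(t) for t in taxa]
        return FourfoldSiteSet(list(taxa), self.columns[:, idx], self.source)


def extract_4d_sites(
    codon_alignments: list[tuple[str, dict[str, str]]],
    families: set[str],
    taxa: list[str] | None = None,
) -> FourfoldSiteSet:
    """Extract unbiased 4D third-position columns from codon alignments.

    A codon column is used iff every species with a non-missing codon has a
    codon in a retained family and all share the same family prefix; species
    with gaps or N contribute missing.  Alignments must be in frame (length
    divisible by 3).
    """
    if taxa is None:
        taxa = sorted({sp for _, seqs in codon_alignments for sp in seqs})
    cols: list[list[int]] = []
    source: list[tuple[str, int]] = []
    for gene_id, seqs in codon_alignments:
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise ValueError(f"{gene_id}: aligned sequences differ in length")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"{gene_id}: alignment length {length} not in frame")
        for ci in range(length // 3):
            prefix = None
            column = []
            ok = True
            for sp in taxa:
                seq = seqs.get(sp)
                codon = seq[3 * ci : 3 * ci + 3].upper() if seq else None
                if codon is None or any(ch not in "ACGT" for ch in codon):
                    column.append(MISSING)
                    continue
                if codon[:2] not in families:
                    ok = False
                    break
                if prefix is None:
                    prefix = codon[:2]
                elif codon[:2] != prefix:
                    ok = False
                    break
                column.append(BASE_CODES[codon[2]])
            if ok and prefix is not None:
                cols.append(column)
                source.append((gene_id, ci))
    columns = (
        np.asarray(cols, dtype=np.int8)
        if cols
        else np.empty((0, len(taxa)), dtype=np.int8)
    )
    return FourfoldSiteSet(taxa=list(taxa), columns=columns, source=source)


# ---------------------------------------------------------------------------
# neutral model fitting
# ---------------------------------------------------------------------------


@dataclass
class NeutralFitResult:
    tree: PhyloTree
    model: SubstModel
    log_likelihood: float
    n_sites: int


BRANCH_BOUNDS = (1e-8, 10.0)


def fit_neutral_model(
    sites: FourfoldSiteSet,
    topology: PhyloTree,
    use_gamma: bool = False,
    tol: float = 1e-6,
    max_sweeps: int = 30,
) -> NeutralFitResult:
    """Fit GTR branch lengths and exchangeabilities on a fixed topology.

    Stationary frequencies are fixed to the empirical base frequencies of the
    site set.  Optimisation alternates bounded per-branch length fits with a
    simplex update of the exchangeabilities (and gamma shape when requested)
    until the log-likelihood improves by less than ``tol`` per sweep.
    Deterministic start: all branch lengths 0.1, exchangeabilities 1, shape 1.
    """
    if sites.n_sites < 1:
        raise ValueError("need at least one 4D site")
    missing = set(topology.leaf_labels) - set(sites.taxa)
    if missing:
        raise ValueError(f"site set lacks taxa {sorted(missing)}")
    ordered = sites.reorder(topology.leaf_labels)
    patterns, counts = compress_columns(ordered.columns)
    if all((len(set(p[p != MISSING])) <= 1) for p in patterns):
        logger.warning(
            "all 4D columns are constant; branch lengths will sit at the lower bound"
        )
    pi = ordered.base_frequencies()
    tree = topology.with_lengths(np.full(topology.n_nodes, 0.1))
    tree.lengths[tree.root] = 0.0
    exch = np.ones(6)
    alpha = 1.0

    def make_model(e: np.ndarray, a: float) -> SubstModel:
        return SubstModel(
            pi=pi,
            exch=e,
            gamma_shape=a if use_gamma else None,
            n_rate_categories=4 if use_gamma else 1,
        )

    def lnl(lengths: np.ndarray, model: SubstModel) -> float:
        vals = _pattern_log_likelihood(tree, model, lengths, patterns)
        return float(np.dot(counts, vals))

    model = make_model(exch, alpha)
    best = lnl(tree.lengths, model)
    free_nodes = [n for n in range(tree.n_nodes) if n != tree.root]
    for _ in range(max_sweeps):
        start = best
        # branch lengths, one at a time
        for node in free_nodes:
            def neg(x: float, node=node) -> float:
                lengths = tree.lengths.copy()
                lengths[node] = x
                return -lnl(lengths, model)

            res = minimize_scalar(
                neg, bounds=BRANCH_BOUNDS, method="bounded",
                options={"xatol": 1e-8},
            )
            if -res.fun >= best:
                tree.lengths[node] = float(res.x)
                best = -float(res.fun)
        # exchangeabilities (+ gamma shape), GT fixed to 1
        theta0 = np.log(exch[:5])
        if use_gamma:
            theta0 = np.concatenate([theta0, [np.log(alpha)]])

        def neg_model(theta: np.ndarray) -> float:
            e = np.concatenate([np.exp(theta[:5]), [1.0]])
            a = float(np.exp(theta[5])) if use_gamma else 1.0
            return -lnl(tree.lengths, make_model(e, a))

        res = minimize(
            neg_model, theta0, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
        )
        if -res.fun > best:
            best = -float(res.fun)
            exch = np.concatenate([np.exp(res.x[:5]), [1.0]])
            if use_gamma:
                alpha = float(np.exp(res.x[5]))
            model = make_model(exch, alpha)
        if best - start < tol:
            break
    if not np.isfinite(best):
        raise FloatingPointError("non-finite likelihood during neutral fit")
    return NeutralFitResult(
        tree=tree, model=model, log_likelihood=best, n_sites=ordered.n_sites
    )
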