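# Methods

This note records the statistical model, the procedure each module
implements, the defaults and why they were chosen, and what the synthetic
data does and does not emulate.

## Substitution model and likelihood engine

The engine (`model.py`, `phylo.py`) implements a reversible nucleotide
model: stationary frequencies π (A, C, G, T), six symmetric
exchangeabilities in the order AC, AG, AT, CG, CT, GT with GT ≡ 1 for
identifiability, and optional discrete-gamma rate variation with four
equal-probability categories whose rates are the category means (so the
expected rate is exactly 1 regardless of the shape α). The rate matrix is
normalised to one expected substitution per site per unit branch length, so
branch lengths are in substitutions/site.

Likelihoods use Felsenstein pruning over an array-based rooted tree.
Transition matrices come from the eigendecomposition of the symmetrised
rate matrix (D^1/2 Q D^−1/2 with D = diag π), computed once per model and
re-used for every branch length; identical effective branch lengths within
an evaluation share one matrix. Identical alignment columns are collapsed
to patterns with counts before any likelihood work. Partial likelihoods are
rescaled per column at each internal node with the log of the scaling
accumulated, so long trees or many categories cannot underflow. Missing
data: `N` and the gap character are equivalent and marginalised (a partial
vector of ones), matching the standard treatment of gapped windows.

Scale fitting is bounded scalar maximisation (Brent, tolerance 1e−6) of the
likelihood over ρ ∈ [1e−6, 100] applied to all branches, or λ over the
named target branch(es) only. Scaling a branch multiplies only that branch,
not the subtree below it; for the `TC_open` test this means the single
ancestral branch of the three hot-open trunk–crown taxa. This reading
follows the contrast between "the target branch" and the background; it is
configurable in the sense that any branch set may be passed.

Simulation draws the root state from π and each child state from the
branch transition matrix, with an independent gamma category per site, and
is deterministic given a seed (explicit `numpy` generators throughout, no
global state).

## Neutral model from fourfold-degenerate sites

`codon_neutral.py` computes RSCU per species over synonymous families of
the standard genetic code (Leu, Ser, Arg are 6-codon families: RSCU is
relative to the whole synonym set, while 4D site extraction uses the
two-base family prefixes). Codons with RSCU < 0.6 or > 1.6 — strict
inequalities — are biased; a fourfold family is excluded when any of its
four codons is biased in **any** species (the `all`-species rule is
available; `any` is the stricter, safer default since the motivating
scenario had the same five codons biased in every species, leaving the
choice unconstrained). A third-position column is extracted only when every
species with data carries a retained-family codon and all share the same
family prefix; gapped species contribute `N`.

Fitting fixes π at the empirical base frequencies of the site set
(phyloFit-like; halves the optimiser dimensionality) and alternates bounded
per-branch length optimisation (bounds [1e−8, 10]) with a Nelder–Mead
update of the five free exchangeabilities (and log α when gamma is on),
from a deterministic start (lengths 0.1, exchangeabilities 1, α 1), until a
sweep improves lnL by less than 1e−6. Gamma is off by default: the window
tests are calibrated against the same model family used for fitting, and
the single-rate model keeps the scan null exact under the generator.

Identifiability: for a reversible model the two branches meeting at the
root are identifiable only through their sum. Recovery checks therefore
compare every other branch individually and the root pair as a sum.

## Curation rules

Edge columns containing `N` in either row of a pairwise block are trimmed.
An internal maximal N run longer than half the ungapped length of its row
(threshold configurable) is excised and the block split at the run —
deletion of the ambiguous bases, not of the whole alignment. Overlap
resolution ranks blocks by descending column count (ties: smaller reference
start, then input order — deterministic and order-free) and trims later
blocks to unclaimed reference positions. The merge stacks per-species
pairwise rows on reference-position columns, dropping species insertions;
after insertion removal a non-reference row's source fields describe its
first aligned base and base count rather than a contiguous run (downstream
analysis only uses reference coordinates). The species filter keeps blocks
with ≥ 7 of 8 species: "more than seven of eight" is read as ≥ 7 because a
literal > 7 (= 8) would contradict tolerating one missing draft genome.

## Windows and annotation

Categories are assigned per reference base from protein-coding gene models
with priority CDS > 5′-UTR > 3′-UTR > intron > intergenic; intron means
inside a gene span but in no exon-level feature. When two genes tie on the
winning category, both gene IDs are kept. ncRNA genes deliberately do not
drive the five-way categorisation — they enter only through the >80 %
ncRNA-overlap filter — because how ncRNA exons map onto the five categories
is not otherwise defined; their windows are categorised by the surrounding
coding annotation (usually intergenic).

Lengths are counted in reference bases; gap columns travel with their
window. Segments shorter than 10 bases are dropped, 10–99-base segments
pass unchanged, and longer segments are cut every 60 bases from the 5′
(reference-forward) end, merging a would-be tail of < 20 bases into the
preceding window (so 130 → 60 + 70 and 315 → 60·4 + 75, and every split
piece is 20–79 bases). Splitting from the left end is a convention choice;
the alternative right-end reading only relabels window boundaries.

## Tests, scores, correction

The per-window statistic is T = 2(lnL₁ − lnL₀), clipped at 0. Because the
null (scale = 1) lies on the boundary of each one-sided alternative, the
reference distribution is the ½χ²₀ + ½χ²₁ mixture: p = ½·P(χ²₁ ≥ T) for
the observed direction and the complement for the other, so T = 0 gives
p = 0.5 and the two directional p-values always sum to 1. The LRT mode was
chosen over score/SPH-style alternatives as the best-documented and
oracle-checkable option. CONACC is signed −log₁₀p (positive = conserved),
matching the continuous conservation/acceleration convention; 0 iff p = 1.

BH correction (via `statsmodels.multipletests`) runs within families: one
family of conservation p-values over all windows, one acceleration family
per target branch. Calls require q strictly below α = 0.05 **and** the
fitted scale on the called side of 1. Windows with fewer than two species
carrying data are excluded from scanning and logged.

## Downstream interval analyses

Overlap for gene flanks and the AR∩CE requirement means ≥ 1 shared base;
the strict > 80 % fraction applies only to the ncRNA filter. Flanks are
strand-aware 5-kb intervals clipped at chromosome edges. Fisher enrichment
tables are built either excluding the call set from the background
(`exclusive`, default — keeps the cells disjoint) or against the full
alignment as printed in the motivating study's tables (`inclusive`); the
acceptance checks pass under both. χ² is Pearson without continuity
correction (the counts involved are large enough that Yates would be
immaterial). Genes "commonly accelerated" in two lineages are those
appearing in any category of both lineages' association tables, with a
flag for sharing an identical accelerated window.

## Synthetic data: what it emulates, what it does not

The generator tiles one reference chromosome with fixed-size regions of
three classes — neutral, conserved (all-branch scale ρ < 1), accelerated
(λ > 1 on a named branch) — simulated under the default 8-taxon tree
(all branch lengths 0.05 substitutions/site, the `TC_open` internal branch
labelled) and a GTR model with mild GC skew and transition bias. Default
implanted scales are ρ = 0.1 and λ = 10: strong, single-window-detectable
effects at 60-base windows and 0.05 branch lengths, chosen so recovery
tests measure the machinery rather than borderline power. Gene cassettes
cover all five annotation categories plus standalone lncRNA genes; artefact
injection adds edge/internal N runs, overlapping duplicate blocks and
missing species without touching any base outside the injected runs.

Not emulated: indel evolution (alignments are gap-free except injected
artefacts), repeat content, GC isochores, alignment error, and rate
variation along the genome beyond the implanted classes. Passing tests
therefore demonstrate correctness of the statistical machinery and
calibration under the model, not robustness to misalignment or
model misspecification in real genomes.

Problem sizes used by the test suite and the acceptance script — 1,000
neutral windows for calibration, 200 + 200 implanted windows among 1,000
neutral for recovery, 20,000 sites for neutral-model recovery, 1,000
random 3–5-taxon instances for the brute-force likelihood comparison — are
desk-scale choices that keep a full run around a minute while leaving the
binomial error on the measured rates small relative to the thresholds.

## Known limitations

- The reference-anchored merge is a deliberate simplification of a true
  multiple-alignment merge: columns are reference positions, so lineage
  insertions are invisible to the scan.
- One scale parameter per window cannot represent a window that is both
  conserved in the background and accelerated on the target branch; such
  windows surface through the branch test only.
- Neutral-model uncertainty is ignored downstream (the fitted model is
  treated as known), as is standard for phyloP-style scans.
- The asymptotic χ² mixture is slightly conservative for very short
  windows (10–20 bases) with few informative columns.
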