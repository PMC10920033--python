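"""Per-window conservation/acceleration likelihood-ratio tests.

Each 10-99-base window is compared against the neutral model by a
likelihood-ratio test with a single free rate multiplier: a global scale rho
over all branches (conservation when rho < 1) or a scale lambda on one named
target branch (acceleration when lambda > 1).  Because the null value 1 is
interior but the test is directional, one-sided p-values use the boundary
chi-square mixture (1/2 chi2_0 + 1/2 chi2_1): p = 0.5 * P(chi2_1 >= T) for
the observed direction, 1 minus that for the opposite direction.  CONACC
scores are signed -log10(p) (positive = conserved); p-values are
Benjamini-Hochberg corrected within families (one conservation family over
all windows; one acceleration family per target branch) and elements are
called at FDR < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval
from .model import SubstModel
from .phylo import (
    PhyloTree,
    UninformativeWindowError,
    fit_branch_scale,
    fit_global_scale,
    log_likelihood,
)
from .windows import AnnotationWindow

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class ScanResult:
    """Outcome of one likelihood-ratio test on one window."""

    window_id: str
    mode: str  # "all_branch" or "branch:<name>"
    ref_interval: GenomicInterval
    category: str
    gene_ids: frozenset[str]
    lnl0: float
    lnl1: float
    scale_hat: float
    stat: float
    direction: str  # "conservation" or "acceleration"
    p: float
    p_conservation: float
    p_acceleration: float
    conacc: float
    q: float | None = None


@dataclass
class ElementCall:
    """A window called as an all-branch CE or a branch AR at FDR < alpha."""

    ref_interval: GenomicInterval
    window_id: str
    kind: str  # "all_branch_CE" or "AR"
    branch: str | None
    q: float
    category: str
    gene_ids: frozenset[str] = field(default_factory=frozenset)


def _directional_pvalues(stat: float, scale_hat: float) -> tuple[str, float, float, float]:
    """One-sided p-values from the 1/2 chi2_0 + 1/2 chi2_1 boundary mixture."""
    tail = 0.5 * float(chi2.sf(stat, df=1))
    if scale_hat < 1.0:
        direction = "conservation"
        p_cons, p_acc = tail, 1.0 - tail
    else:
        direction = "acceleration"
        p_acc, p_cons = tail, 1.0 - tail
    p_obs = tail
    return direction, p_obs, p_cons, p_acc


def conacc_score(direction: str, p: float) -> float:
    """Signed -log10(p): positive for conservation, negative for acceleration."""
    if p <= 0 or p > 1:
        raise ValueError("p must be in (0, 1]")
    mag = -np.log10(p)
    return float(mag if direction == "conservation" else -mag)


def _result(
    window: AnnotationWindow,
    mode: str,
    lnl0: float,
    lnl1: float,
    scale_hat: float,
) -> ScanResult:
    stat = max(0.0, 2.0 * (lnl1 - lnl0))
    direction, p_obs, p_cons, p_acc = _directional_pvalues(stat, scale_hat)
    return ScanResult(
        window_id=window.window_id,
        mode=mode,
        ref_interval=window.ref_interval,
        category=window.category,
        gene_ids=window.gene_ids,
        lnl0=lnl0,
        lnl1=lnl1,
        scale_hat=scale_hat,
        stat=stat,
        direction=direction,
        p=p_obs,
        p_conservation=p_cons,
        p_acceleration=p_acc,
        conacc=conacc_score(direction, p_obs),
    )


def test_window_all_branch(
    window: AnnotationWindow, tree: PhyloTree, model: SubstModel
) -> ScanResult | None:
    """All-branch conservation/acceleration LRT; None for untestable windows."""
    cols = window.columns_for(tree.leaf_labels)
    try:
        rho, lnl1 = fit_global_scale(tree, model, cols)
    except UninformativeWindowError as exc:
        logger.info("window %s skipped: %s", window.window_id, exc)
        return None
    lnl0 = log_likelihood(tree, model, cols)
    return _result(window, "all_branch", lnl0, lnl1, rho)


def test_window_branch(
    window: AnnotationWindow, tree: PhyloTree, model: SubstModel, branch: str
) -> ScanResult | None:
    """Branch-specific acceleration LRT; None for untestable windows."""
    cols = window.columns_for(tree.leaf_labels)
    try:
        lam, lnl1 = fit_branch_scale(tree, model, cols, branch)
    except UninformativeWindowError as exc:
        logger.info("window %s skipped for %s: %s", window.window_id, branch, exc)
        return None
    lnl0 = log_likelihood(tree, model, cols)
    return _result(window, f"branch:{branch}", lnl0, lnl1, lam)


def scan_windows(
    windows: list[AnnotationWindow],
    tree: PhyloTree,
    model: SubstModel,
    target_branches: list[str] | None = None,
) -> list[ScanResult]:
    """Run the all-branch test and per-branch acceleration tests on windows."""
    results: list[ScanResult] = []
    for w in windows:
        if not w.is_testable:
            logger.info("window %s untestable (fewer than 2 species)", w.window_id)
            continue
        res = test_window_all_branch(w, tree, model)
        if res is not None:
            results.append(res)
        for branch in target_branches or []:
            res = test_window_branch(w, tree, model, branch)
            if res is not None:
                results.append(res)
    return results


def correct_fdr(results: list[ScanResult]) -> list[ScanResult]:
    """Benjamini-Hochberg correction within test families.

    Conservation p-values of all all-branch results form one family;
    acceleration p-values form one family per target branch.  The q value
    stored on each result is the one its call decision uses.
    """
    families: dict[str, list[ScanResult]] = {}
    for r in results:
        families.setdefault(r.mode, []).append(r)
    for mode, members in families.items():
        pvals = [
            r.p_conservation if mode == "all_branch" else r.p_acceleration
            for r in members
        ]
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(members, qvals):
            r.q = float(q)
    return results


def call_elements(results: list[ScanResult], alpha: float = ALPHA) -> list[ElementCall]:
    """Call all-branch CEs and branch ARs at FDR strictly below alpha."""
    calls: list[ElementCall] = []
    for r in results:
        if r.q is None:
            raise ValueError("run correct_fdr before calling elements")
        if r.q >= alpha:
            continue
        if r.mode == "all_branch":
            if r.scale_hat >= 1.0:
                continue
            kind, branch = "all_branch_CE", None
        else:
            if r.scale_hat <= 1.0:
                continue
            kind, branch = "AR", r.mode.split(":", 1)[1]
        calls.append(
            ElementCall(
                ref_interval=r.ref_interval,
                window_id=r.window_id,
                kind=kind,
                branch=branch,
                q=r.q,
                category=r.category,
                gene_ids=r.gene_ids,
            )
        )
    return calls


def results_to_frame(results: list[ScanResult]) -> pd.DataFrame:
    """Tabular scan output (one row per window x test)."""
    return pd.DataFrame(
        {
            "window_id": [r.window_id for r in results],
            "mode": [r.mode for r in results],
            "chrom": [r.ref_interval.chrom for r in results],
            "start": [r.ref_interval.start for r in results],
            "end": [r.ref_interval.end for r in results],
            "category": [r.category for r in results],
            "gene_ids": [",".join(sorted(r.gene_ids)) for r in results],
            "lnL0": [r.lnl0 for r in results],
            "lnL1": [r.lnl1 for r in results],
            "scale": [r.scale_hat for r in results],
            "T": [r.stat for r in results],
            "direction": [r.direction for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "conacc": [r.conacc for r in results],
        }
    )
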