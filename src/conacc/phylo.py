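"""Phylogenetic likelihood engine.

Implements the pruning (post-order dynamic programming) log-likelihood for a
rooted tree under a reversible substitution model, maximum-likelihood fitting
of a global rate multiplier (conservation/acceleration scale) or of a
multiplier restricted to named branches, and simulation of alignment columns
under a scaled tree.  Missing data (``N`` or gap) is marginalised: a missing
leaf contributes a partial-likelihood vector of ones.

Alignment columns are represented as an int8 matrix of shape
``(n_columns, n_taxa)`` with base codes from :mod:`conacc.model`; taxon order
matches ``PhyloTree.leaf_labels``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .model import MISSING, SubstModel


class UninformativeWindowError(ValueError):
    """Raised when a window carries no data usable for a likelihood fit."""


class PhyloTree:
    """A rooted tree stored as flat arrays for fast likelihood work.

    Nodes are indexed ``0 .. n_nodes-1`` with leaves first (in a stable taxon
    order).  Every non-root node has a branch above it whose length is
    ``lengths[node]``; branches are addressed by the label of their child node
    (a leaf name, or an internal-node label such as an ancestor name).
    """

    def __init__(
        self,
        parent: np.ndarray,
        lengths: np.ndarray,
        leaf_labels: list[str],
        internal_labels: dict[int, str] | None = None,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float)
        self.leaf_labels = list(leaf_labels)
        self.internal_labels = dict(internal_labels or {})
        self.n_nodes = len(self.parent)
        self.n_leaves = len(self.leaf_labels)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        if len(set(self.leaf_labels)) != self.n_leaves:
            raise ValueError("leaf labels must be unique")
        if np.any(self.lengths[np.arange(self.n_nodes) != self.root] < 0):
            raise ValueError("branch lengths must be non-negative")
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for node, par in enumerate(self.parent):
            if par >= 0:
                self.children[par].append(node)
        # post-order: children before parents
        self.postorder = self._postorder()

    def _postorder(self) -> np.ndarray:
        order, stack = [], [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        return np.asarray(order, dtype=np.int64)

    # -- construction ---------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=False
            )
        except Exception as exc:  # dendropy raises several error types
            raise ValueError(f"newick parse error: {exc}") from exc
        leaves = [nd for nd in dtree.leaf_node_iter()]
        internals = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
        index = {}
        leaf_labels = []
        for i, nd in enumerate(leaves):
            index[id(nd)] = i
            leaf_labels.append(nd.taxon.label.replace(" ", "_") if nd.taxon else f"leaf{i}")
        internal_labels = {}
        for j, nd in enumerate(internals):
            k = len(leaves) + j
            index[id(nd)] = k
            label = None
            if nd.taxon is not None and nd.taxon.label:
                label = nd.taxon.label
            elif nd.label:
                label = nd.label
            if label:
                internal_labels[k] = label.replace(" ", "_")
        n = len(leaves) + len(internals)
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n)
        for nd in dtree.preorder_node_iter():
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is not None:
                lengths[i] = float(nd.edge.length)
        return cls(parent, lengths, leaf_labels, internal_labels)

    def to_newick(self) -> str:
        def render(node: int) -> str:
            label = (
                self.leaf_labels[node]
                if node < self.n_leaves
                else self.internal_labels.get(node, "")
            )
            if self.children[node]:
                inner = ",".join(render(c) for c in self.children[node])
                core = f"({inner}){label}"
            else:
                core = label
            if node == self.root:
                return core
            return f"{core}:{self.lengths[node]:.10g}"

        return render(self.root) + ";"

    # -- queries --------------------------------------------------------------

    def branch_index(self, name: str) -> int:
        """Node index of the branch (edge above the node) with this label."""
        if name in self.leaf_labels:
            return self.leaf_labels.index(name)
        for node, label in self.internal_labels.items():
            if label == name:
                return node
        raise KeyError(f"no branch named {name!r}")

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def total_length(self) -> float:
        mask = np.arange(self.n_nodes) != self.root
        return float(self.lengths[mask].sum())

    def leaf_side_taxa(self, branch: int) -> set[str]:
        """Leaf labels in the subtree below the given branch."""
        out, stack = set(), [branch]
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                out.add(self.leaf_labels[node])
            stack.extend(self.children[node])
        return out

    def with_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        return PhyloTree(self.parent, lengths, self.leaf_labels, self.internal_labels)

    def copy(self) -> "PhyloTree":
        return self.with_lengths(self.lengths.copy())


@dataclass
class ScaledTree:
    """A tree with a global rate multiplier and optional per-branch multipliers.

    ``global_scale`` models average conservation (< 1) or acceleration (> 1)
    over all branches; ``branch_scales`` maps branch names (child-node labels)
    to multipliers applied to those branches only.
    """

    tree: PhyloTree
    global_scale: float = 1.0
    branch_scales: dict[str, float] = field(default_factory=dict)

    def effective_lengths(self) -> np.ndarray:
        if self.global_scale <= 0:
            raise ValueError("global scale must be positive")
        eff = self.tree.lengths * self.global_scale
        for name, lam in self.branch_scales.items():
            if lam < 0:
                raise ValueError("branch scale must be non-negative")
            eff[self.tree.branch_index(name)] *= lam
        return eff


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------


def compress_columns(columns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical columns; returns (patterns, counts)."""
    cols = np.ascontiguousarray(np.asarray(columns, dtype=np.int8))
    patterns, counts = np.unique(cols, axis=0, return_counts=True)
    return patterns, counts


def _pattern_log_likelihood(
    tree: PhyloTree,
    model: SubstModel,
    eff_lengths: np.ndarray,
    patterns: np.ndarray,
) -> np.ndarray:
    """Per-pattern log-likelihood via pruning with per-column rescaling."""
    npat = patterns.shape[0]
    rates = model.rate_category_multipliers()
    per_cat = np.empty((len(rates), npat))
    leaf_partials = np.concatenate([np.eye(4), np.ones((1, 4))])  # code -> partial
    for ci, rate in enumerate(rates):
        scaled = eff_lengths * rate
        uniq, inv = np.unique(scaled, return_inverse=True)
        pmats = model.transition_matrices(uniq)[inv]  # (n_nodes, 4, 4)
        partial = np.empty((tree.n_nodes, npat, 4))
        logscale = np.zeros(npat)
        for node in tree.postorder:
            kids = tree.children[node]
            if not kids:
                partial[node] = leaf_partials[patterns[:, node]]
                continue
            acc = np.ones((npat, 4))
            for c in kids:
                acc *= partial[c] @ pmats[c].T
            if node != tree.root:
                m = acc.max(axis=1)
                bad = m <= 0
                if np.any(bad):
                    m = np.where(bad, 1.0, m)
                acc /= m[:, None]
                logscale += np.log(m)
            partial[node] = acc
        site_l = partial[tree.root] @ model.pi
        with np.errstate(divide="ignore"):
            per_cat[ci] = np.log(site_l) + logscale
    if len(rates) == 1:
        return per_cat[0]
    # equal-weight mixture over categories, in log space
    mx = per_cat.max(axis=0)
    return mx + np.log(np.exp(per_cat - mx).mean(axis=0))


def log_likelihood(
    tree: PhyloTree | ScaledTree,
    model: SubstModel,
    columns: np.ndarray,
) -> float:
    """Total pruning log-likelihood (nats) of alignment columns.

    ``columns`` has one row per alignment column and one entry per taxon in
    ``tree.leaf_labels`` order; code 4 (N or gap) is marginalised.
    """
    scaled = tree if isinstance(tree, ScaledTree) else ScaledTree(tree)
    cols = np.asarray(columns, dtype=np.int8)
    if cols.ndim != 2 or cols.shape[0] == 0:
        raise ValueError("need at least one column")
    if cols.shape[1] != scaled.tree.n_leaves:
        raise ValueError("column width does not match leaf count")
    patterns, counts = compress_columns(cols)
    lnl = _pattern_log_likelihood(
        scaled.tree, model, scaled.effective_lengths(), patterns
    )
    total = float(np.dot(counts, lnl))
    if not np.isfinite(total):
        raise FloatingPointError("non-finite log-likelihood")
    return total


# ---------------------------------------------------------------------------
# scale fitting
# ---------------------------------------------------------------------------

SCALE_BOUNDS = (1e-6, 100.0)


def _check_informative(columns: np.ndarray) -> None:
    cols = np.asarray(columns)
    present = (cols != MISSING).sum(axis=0)
    if np.count_nonzero(present) < 2:
        raise UninformativeWindowError(
            "window has data for fewer than two taxa"
        )


def fit_global_scale(
    tree: PhyloTree,
    model: SubstModel,
    columns: np.ndarray,
    bounds: tuple[float, float] = SCALE_BOUNDS,
) -> tuple[float, float]:
    """ML estimate of the all-branch rate multiplier rho.

    Returns ``(rho_hat, lnL at rho_hat)``; rho < 1 indicates conservation and
    rho > 1 acceleration relative to the neutral branch lengths.
    """
    _check_informative(columns)
    patterns, counts = compress_columns(np.asarray(columns, dtype=np.int8))
    base = tree.lengths

    def neg(rho: float) -> float:
        lnl = _pattern_log_likelihood(tree, model, base * rho, patterns)
        return -float(np.dot(counts, lnl))

    res = minimize_scalar(
        neg, bounds=bounds, method="bounded", options={"xatol": 1e-6}
    )
    return float(res.x), -float(res.fun)


def fit_branch_scale(
    tree: PhyloTree,
    model: SubstModel,
    columns: np.ndarray,
    target_branches: str | set[str],
    bounds: tuple[float, float] = SCALE_BOUNDS,
) -> tuple[float, float]:
    """ML estimate of the rate multiplier lambda on the named branch(es) only.

    Background branches keep their neutral lengths.  Raises
    :class:`UninformativeWindowError` when all taxa on either side of the
    (single) target branch are missing throughout the window.
    """
    if isinstance(target_branches, str):
        target_branches = {target_branches}
    idx = np.asarray(sorted(tree.branch_index(b) for b in target_branches))
    cols = np.asarray(columns, dtype=np.int8)
    _check_informative(cols)
    if len(idx) == 1:
        below = {
            tree.leaf_labels.index(t) for t in tree.leaf_side_taxa(int(idx[0]))
        }
        present = {
            int(i) for i in np.flatnonzero((cols != MISSING).any(axis=0))
        }
        if not (present & below) or not (present - below):
            raise UninformativeWindowError(
                "no data on one side of the target branch"
            )
    patterns, counts = compress_columns(cols)
    base = tree.lengths

    def neg(lam: float) -> float:
        eff = base.copy()
        eff[idx] *= lam
        lnl = _pattern_log_likelihood(tree, model, eff, patterns)
        return -float(np.dot(counts, lnl))

    res = minimize_scalar(
        neg, bounds=bounds, method="bounded", options={"xatol": 1e-6}
    )
    return float(res.x), -float(res.fun)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_columns(
    tree: PhyloTree | ScaledTree,
    model: SubstModel,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Simulate ``n`` alignment columns under the (scaled) tree and model.

    Root states are drawn from the stationary distribution; each branch
    evolves by the model's transition matrix over its effective length.  With
    gamma rate variation a category is drawn independently per site.  Returns
    an int8 matrix ``(n, n_taxa)`` in leaf order; deterministic given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    scaled = tree if isinstance(tree, ScaledTree) else ScaledTree(tree)
    t = scaled.tree
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eff = scaled.effective_lengths()
    rates = model.rate_category_multipliers()
    cat = rng.integers(0, len(rates), size=n) if len(rates) > 1 else np.zeros(n, dtype=int)
    site_rate = rates[cat]
    states = np.empty((t.n_nodes, n), dtype=np.int8)
    states[t.root] = rng.choice(4, size=n, p=model.pi)
    # pre-order: parents before children
    for node in t.postorder[::-1]:
        if node == t.root:
            continue
        if len(rates) == 1:
            pmat = model.transition_matrices([eff[node]])[0]
            cum = pmat.cumsum(axis=1)
            u = rng.random(n)
            states[node] = (u[:, None] > cum[states[t.parent[node]]]).sum(axis=1)
        else:
            parent_states = states[t.parent[node]]
            out = np.empty(n, dtype=np.int8)
            for ci, rate in enumerate(rates):
                mask = cat == ci
                if not mask.any():
                    continue
                pmat = model.transition_matrices([eff[node] * rate])[0]
                cum = pmat.cumsum(axis=1)
                u = rng.random(mask.sum())
                out[mask] = (u[:, None] > cum[parent_states[mask]]).sum(axis=1)
            states[node] = out
    del site_rate
    return states[: t.n_leaves].T.copy()
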