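import itertools

import numpy as np
import pytest

import conacc as cc
from conacc.model import SubstModel


@pytest.fixture(scope="session")
def tree8():
    return cc.default_tree()


@pytest.fixture(scope="session")
def model():
    return cc.default_model()


def brute_force_log_likelihood(tree, model, columns, eff_lengths=None):
    """Independent oracle: enumerate all ancestral-state assignments."""
    eff = tree.lengths if eff_lengths is None else eff_lengths
    pmats = {
        n: model.transition_matrices([eff[n]])[0]
        for n in range(tree.n_nodes)
        if n != tree.root
    }
    internals = [n for n in range(tree.n_nodes) if tree.children[n]]
    rates = model.rate_category_multipliers()
    total = 0.0
    for col in np.asarray(columns):
        cat_likes = []
        for rate in rates:
            pr_cat = {
                n: model.transition_matrices([eff[n] * rate])[0]
                for n in pmats
            }
            like = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                amap = dict(zip(internals, assign))
                pr = model.pi[amap[tree.root]]
                for n in range(tree.n_nodes):
                    if n == tree.root:
                        continue
                    parent_state = amap[tree.parent[n]]
                    if n < tree.n_leaves:
                        b = int(col[n])
                        if b == 4:
                            continue
                        pr *= pr_cat[n][parent_state, b]
                    else:
                        pr *= pr_cat[n][parent_state, amap[n]]
                like += pr
            cat_likes.append(like)
        total += np.log(np.mean(cat_likes))
    return total


def random_model(rng, gamma=False):
    pi = rng.dirichlet(np.ones(4) * 5)
    exch = np.concatenate([rng.uniform(0.2, 3.0, 5), [1.0]])
    if gamma:
        return SubstModel(pi=pi, exch=exch, gamma_shape=rng.uniform(0.3, 2.0),
                          n_rate_categories=4)
    return SubstModel(pi=pi, exch=exch)


def random_small_tree(rng, n_taxa):
    """Random rooted binary tree with n_taxa leaves and random lengths."""
    nodes = [f"T{i}:{rng.uniform(0.02, 0.5):.4f}" for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.02, 0.5):.4f}")
    text = nodes[0].rsplit(":", 1)[0] + ";"
    return cc.PhyloTree.from_newick(text)
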