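"""Shared fixtures: deterministic RNGs, small trees, random alignments."""

import numpy as np
import pytest

from armroot.io import read_newick
from armroot.phylo import AA_ORDER
from armroot.simulate import simulate_species_tree

AA = list(AA_ORDER)


@pytest.fixture
def rng():
    return np.random.default_rng(20240131)


def scale_tree(tree, target_height):
    """Rescale all branch lengths so the root-to-leaf height equals target."""
    h = max(tree.calc_node_root_distances(return_leaf_distances_only=True))
    f = target_height / h
    for e in tree.preorder_edge_iter():
        if e.length:
            e.length *= f
    return tree


@pytest.fixture
def quartet_tree():
    return read_newick("((A:0.3,B:0.5):0.2,(C:0.1,D:0.7):0.4);", rooted=True)


@pytest.fixture
def balanced_tree():
    return read_newick("((A:1,B:1):1,(C:1,D:1):1);", rooted=True)


def random_msa(rng, n_rows, n_cols, prefix="r", gap_p=0.2, no_allgap_columns=True):
    """Random aligned block; optionally guarantees no all-gap column."""
    while True:
        rows = {
            f"{prefix}{i}": "".join(
                rng.choice(AA) if rng.random() > gap_p else "-"
                for _ in range(n_cols)
            )
            for i in range(n_rows)
        }
        if not no_allgap_columns:
            return rows
        arr = np.array([list(s) for s in rows.values()])
        if not (arr == "-").all(axis=0).any():
            return rows


def random_tree(rng, n, height=None):
    t = simulate_species_tree(n_species=n, seed=int(rng.integers(2**31)))
    if height is not None:
        scale_tree(t, height)
    return t


def simulate_on_tree(tree, model, n_sites, seed):
    """Direct CTMC simulation of one alignment on an arbitrary tree."""
    r = np.random.default_rng(seed)
    classes = r.choice(len(model.rates), size=n_sites, p=model.rate_weights)
    states = {
        tree.seed_node: r.choice(20, size=n_sites, p=model.frequencies)
    }
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = states[node.parent_node]
        child = np.empty(n_sites, dtype=int)
        for ci, rate in enumerate(model.rates):
            mask = classes == ci
            if not mask.any():
                continue
            pm = model.transition_matrix(node.edge.length or 0.0, rate)
            cum = pm.cumsum(axis=1)
            cum[:, -1] = 1.0
            u = r.random(mask.sum())
            child[mask] = (u[:, None] > cum[parent[mask]]).sum(axis=1)
        states[node] = child
    return {
        l.taxon.label: "".join(AA_ORDER[i] for i in states[l])
        for l in tree.leaf_node_iter()
    }
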