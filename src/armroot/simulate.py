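"""Synthetic data with the statistical structure the analysis assumes.

Four generators cover every downstream stage without any external data:

* a birth–death species tree (ultrametric, extant taxa only);
* coupled Dollo presence/absence histories for two analogous complexes,
  both present at the root, lost at most once per lineage, with a coupling
  knob that suppresses (negative) or promotes (positive) losing the second
  complex where the first is already gone — negative coupling produces the
  anti-correlated extant pattern the real complexes show;
* subunit sequences descending from a single pre-root ancestor through two
  duplication waves (arm split, then within-arm splits), evolved by exact
  CTMC sampling along the gene tree — the species-tree copy under each
  subunit terminal, pruned by the complex's loss edges;
* per-species scaffold layouts (clustered with exponential spacing, or
  scaffolds assigned uniformly at random) for co-localization tests.

Truth objects (loss-edge sets, the gene tree, scaffold assignments) are
always returned alongside observations so parameter-recovery tests can
compare against them.  Identical seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .io import ArmrootError
from .phylo import AA_ORDER, PhyloModel
from .profiles import DAM1_SUBUNITS, SKA_SUBUNITS, PresenceMatrix
from .supermatrix import DEFAULT_PARALOG_MAP, ParalogMap


# ---------------------------------------------------------------------------
# Species trees


def simulate_species_tree(
    n_species=None, birth_rate=1.0, death_rate=0.0, seed=0, max_time=None
):
    """Rooted ultrametric birth–death tree.

    Either condition on ``n_species`` extant tips (>= 3) or run the
    unconditioned process for ``max_time``.  Leaves are relabelled
    S1..Sn deterministically; tiny floating-point drift in leaf depths is
    snapped so the tree is ultrametric to < 1e-9.
    """
    if death_rate >= birth_rate:
        raise ArmrootError("death_rate >= birth_rate: process need not terminate")
    if (n_species is None) == (max_time is None):
        raise ArmrootError("specify exactly one of n_species or max_time")
    if n_species is not None and n_species < 3:
        raise ArmrootError("n_species must be >= 3")
    import random as _random

    rng = _random.Random(seed)
    kwargs = dict(birth_rate=birth_rate, death_rate=death_rate, rng=rng)
    if n_species is not None:
        tree = treesim.birth_death_tree(num_extant_tips=n_species, **kwargs)
    else:
        tree = treesim.birth_death_tree(
            max_time=max_time, is_add_extinct_attr=False, **kwargs
        )
    tree.is_rooted = True
    leaves = list(tree.leaf_node_iter())
    for i, leaf in enumerate(leaves, start=1):
        leaf.taxon.label = f"S{i}"
    # snap leaf depths to the maximum root-to-leaf depth
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    target = max(depths)
    for leaf in tree.leaf_node_iter():
        drift = target - leaf.root_distance
        if abs(drift) > 0:
            leaf.edge.length = max((leaf.edge.length or 0.0) + drift, 0.0)
    return tree


# ---------------------------------------------------------------------------
# Coupled Dollo presence/absence


@dataclass
class DolloSimParams:
    """Loss-process parameters for two complexes present at the root.

    ``loss_rate_*`` are expected losses per unit branch length while the
    complex is still held; ``coupling`` multiplies the loss rate of the
    remaining complex by max(0, 1 + coupling) once the other is gone
    (−1 = full protection, the anti-correlation regime; +1 = doubled);
    ``dropout_rate`` is the per-subunit observation-failure probability
    applied only to the observed matrix (transcriptome incompleteness).
    """

    loss_rate_a: float = 0.6
    loss_rate_b: float = 0.45
    coupling: float = -0.9
    dropout_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.loss_rate_a < 0 or self.loss_rate_b < 0:
            raise ArmrootError("loss rates must be >= 0")
        if not (-1.0 <= self.coupling <= 1.0):
            raise ArmrootError("coupling must be in [-1, 1]")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ArmrootError("dropout_rate must be in [0, 1)")


@dataclass
class DolloTruth:
    """Un-dropped simulation truth: loss clades and extant presence."""

    loss_edges: dict  # complex name -> frozenset of leaf-set frozensets
    presence: pd.DataFrame  # species x complex booleans (pre-dropout)


def _branch_losses(rng, t, state_a, state_b, rate_a, rate_b, coupling):
    """First-arrival losses along one branch; returns the end state and
    which complexes were lost on this branch."""
    lost_here = []
    time = 0.0
    while state_a or state_b:
        ra = rate_a * (max(0.0, 1.0 + coupling) if not state_b else 1.0) if state_a else 0.0
        rb = rate_b * (max(0.0, 1.0 + coupling) if not state_a else 1.0) if state_b else 0.0
        total = ra + rb
        if total <= 0.0:
            break
        wait = rng.exponential(1.0 / total)
        if time + wait > t:
            break
        time += wait
        if rng.random() < ra / total:
            state_a, name = False, "A"
        else:
            state_b, name = False, "B"
        lost_here.append(name)
    return state_a, state_b, lost_here


def simulate_coupled_dollo(tree, params, complexes=None, conditioning_gene="Ndc80"):
    """Simulate presence/absence of two complexes on a species tree.

    Both complexes are present at the root; each lineage loses a complex at
    most once (Dollo).  Returns (observed PresenceMatrix, DolloTruth).
    ``complexes`` maps the two complex names to their subunit tuples
    (defaults to the ten- and three-subunit study complexes).
    """
    if complexes is None:
        complexes = {"Dam1-C": list(DAM1_SUBUNITS), "Ska-C": list(SKA_SUBUNITS)}
    if len(complexes) != 2:
        raise ArmrootError("coupled simulation needs exactly two complexes")
    name_a, name_b = list(complexes)
    rng = np.random.default_rng(params.seed)

    loss_edges = {name_a: set(), name_b: set()}
    leaf_state = {}

    def leafset(node):
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def walk(node, state_a, state_b):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            a2, b2, lost = _branch_losses(
                rng, t, state_a, state_b,
                params.loss_rate_a, params.loss_rate_b, params.coupling,
            )
            for name in lost:
                loss_edges[name_a if name == "A" else name_b].add(leafset(child))
            if child.is_leaf():
                leaf_state[child.taxon.label] = (a2, b2)
            else:
                walk(child, a2, b2)

    walk(tree.seed_node, True, True)
    species = [l.taxon.label for l in tree.leaf_node_iter()]
    truth = pd.DataFrame(
        {
            name_a: [leaf_state[s][0] for s in species],
            name_b: [leaf_state[s][1] for s in species],
        },
        index=species,
    )

    columns = [conditioning_gene] + list(complexes[name_a]) + list(complexes[name_b])
    data = pd.DataFrame(0, index=species, columns=columns, dtype="int8")
    data[conditioning_gene] = 1
    for cname, subunits in complexes.items():
        for sp in species:
            if truth.at[sp, cname]:
                observed = rng.random(len(subunits)) >= params.dropout_rate
                data.loc[sp, list(subunits)] = observed.astype("int8")
    matrix = PresenceMatrix(
        data=data,
        complexes={k: list(v) for k, v in complexes.items()},
        conditioning_gene=conditioning_gene,
    )
    return matrix, DolloTruth(
        loss_edges={k: frozenset(v) for k, v in loss_edges.items()},
        presence=truth,
    )


# ---------------------------------------------------------------------------
# Duplication-structured sequences


@dataclass
class DuplicationHistory:
    """Pre-root duplication scenario: a proto-subunit splits into two arm
    ancestors, which split stepwise into the terminal subunits of each arm.

    ``arm_divergence`` is the branch length from the complex root to each
    arm ancestor (the depth of the rooting signal); ``within_arm_divergence``
    the length of each within-arm duplication branch.  Arms must have equal
    subunit counts (taken from ``paralog_map``).
    """

    paralog_map: ParalogMap = field(default_factory=lambda: DEFAULT_PARALOG_MAP)
    arm_divergence: float = 1.0
    within_arm_divergence: float = 0.3

    def __post_init__(self):
        if self.arm_divergence < 0 or self.within_arm_divergence < 0:
            raise ArmrootError("divergence branch lengths must be >= 0")
        if len(self.paralog_map.arm1) != len(self.paralog_map.arm2):
            raise ArmrootError("arms must contain equal subunit counts")

    @property
    def subunits(self):
        return self.paralog_map.arm1 + self.paralog_map.arm2

    def duplication_tree(self):
        """Newick-less skeleton: nested tuples (name or (left, right), length)."""

        def balanced(members):
            if len(members) == 1:
                return members[0]
            half = len(members) // 2
            return (balanced(members[:half]), balanced(members[half:]))

        return (
            (balanced(self.paralog_map.arm1), balanced(self.paralog_map.arm2)),
            self.arm_divergence,
            self.within_arm_divergence,
        )


def _sample_children(rng, parent_states, pmat):
    """Sample one child state per site from the categorical rows of pmat."""
    cum = pmat.cumsum(axis=1)
    cum[:, -1] = 1.0
    u = rng.random(len(parent_states))
    return (u[:, None] > cum[parent_states]).sum(axis=1).astype(np.int64)


def simulate_complex_sequences(
    tree, history, model=None, seq_length=300, loss_edges=frozenset(), seed=0
):
    """Evolve subunit sequences along the duplication-grafted gene tree.

    The gene tree is the duplication tree with a copy of the species tree
    attached below each terminal subunit, pruned by ``loss_edges`` (a set
    of species-leaf-set frozensets: every species inside a loss clade lacks
    the whole complex).  Sequences evolve by exact per-branch CTMC
    transition sampling under ``model`` (Poisson by default); with a gamma
    rate model, each site keeps one rate class across the whole tree.

    Returns (alignments, gene_tree): ``alignments[subunit][species]`` is an
    ungapped sequence of length ``seq_length`` for every surviving species;
    gene-tree leaves are labelled ``subunit::species``.
    """
    if seq_length < 50:
        raise ArmrootError("seq_length must be >= 50")
    if model is None:
        model = PhyloModel("POISSON")
    rng = np.random.default_rng(seed)
    lost_species = set().union(*loss_edges) if loss_edges else set()
    taxon_ns = dendropy.TaxonNamespace()

    def copy_species_subtree(sp_node, subunit):
        """Copy of the species subtree with lost species pruned; returns
        None when every descendant species is lost."""
        if sp_node.is_leaf():
            name = sp_node.taxon.label
            if name in lost_species:
                return None
            n = dendropy.Node()
            n.edge.length = sp_node.edge.length or 0.0
            n.taxon = taxon_ns.new_taxon(f"{subunit}::{name}")
            return n
        kids = [copy_species_subtree(c, subunit) for c in sp_node.child_nodes()]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:  # collapse the pruned unifurcation
            kids[0].edge.length += sp_node.edge.length or 0.0
            return kids[0]
        n = dendropy.Node()
        n.edge.length = sp_node.edge.length or 0.0
        for k in kids:
            n.add_child(k)
        return n

    struct, arm_len, within_len = history.duplication_tree()

    def expand(spec, length):
        if isinstance(spec, str):
            node = copy_species_subtree(tree.seed_node, spec)
            if node is None:
                return None
            node.edge.length = (node.edge.length or 0.0) + length
            return node
        node = dendropy.Node()
        node.edge.length = length
        for part in spec:
            child = expand(part, within_len)
            if child is not None:
                node.add_child(child)
        if not node.child_nodes():
            return None
        return node

    gene = dendropy.Tree(taxon_namespace=taxon_ns)
    gene.is_rooted = True
    for arm_spec in struct:
        child = expand(arm_spec, arm_len)
        if child is not None:
            gene.seed_node.add_child(child)
    if not gene.seed_node.child_nodes():
        raise ArmrootError(
            "loss edges remove the complex from every species; "
            "no sequences to simulate"
        )

    # Per-site rate classes are fixed across the tree.
    classes = rng.choice(len(model.rates), size=seq_length, p=model.rate_weights)
    states = {
        gene.seed_node: rng.choice(
            len(model.frequencies), size=seq_length, p=model.frequencies
        )
    }
    for node in gene.preorder_node_iter():
        if node is gene.seed_node:
            continue
        t = node.edge.length or 0.0
        parent = states[node.parent_node]
        child = np.empty(seq_length, dtype=np.int64)
        for ci, rate in enumerate(model.rates):
            mask = classes == ci
            if not mask.any():
                continue
            pmat = model.transition_matrix(t, rate)
            child[mask] = _sample_children(rng, parent[mask], pmat)
        states[node] = child

    alignments = {subunit: {} for subunit in history.subunits}
    for leaf in gene.leaf_node_iter():
        subunit, species = leaf.taxon.label.split("::", 1)
        seq = "".join(AA_ORDER[i] for i in states[leaf])
        alignments[subunit][species] = seq
    return alignments, gene


def simulate_loci(
    species,
    subunits,
    n_scaffolds,
    clustered=False,
    mean_spacing_bp=10_000,
    seed=0,
    gene_length_bp=1_500,
):
    """Per-species gene locus table.

    ``clustered=True`` places every subunit on one scaffold with
    independent exponential intergenic spacing (mean ``mean_spacing_bp``);
    otherwise each subunit lands on a scaffold chosen uniformly at random
    with a uniform start position.  Coordinates are 0-based half-open.
    """
    if n_scaffolds < 1:
        raise ArmrootError("n_scaffolds must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for sp in species:
        if clustered:
            pos = 0
            for su in subunits:
                gap = int(rng.exponential(mean_spacing_bp))
                start = pos + gap
                end = start + gene_length_bp
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append((sp, su, "scaffold_1", start, end, strand))
                pos = end
        else:
            for su in subunits:
                scaf = f"scaffold_{rng.integers(1, n_scaffolds + 1)}"
                start = int(rng.integers(0, 10_000_000))
                end = start + gene_length_bp
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append((sp, su, scaf, start, end, strand))
    return pd.DataFrame(
        rows, columns=["species", "subunit", "scaffold", "start", "end", "strand"]
    )
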