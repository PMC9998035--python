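"""Desk-scale likelihood phylogenetics and topology testing.

Implements per-site log-likelihoods by Felsenstein pruning under Poisson or
LG exchangeabilities (model or empirical ``+F`` frequencies; uniform or
discrete-gamma rates), coordinate-wise branch-length optimisation, NJ
starting trees with NNI hill climbing (optionally constrained to display a
given set of bipartitions), and the RELL machinery: bootstrap of per-site
log-likelihoods, the Kishino–Hasegawa test against the best competitor,
and the approximately unbiased (AU) test via weighted least-squares fitting
of inverse-normal-transformed multiscale bootstrap proportions.

Trees are dendropy objects; alignments are ``{taxon: sequence}`` mappings
over the 20-letter amino-acid alphabet with ``-``/``.`` gaps and ambiguity
codes (B, Z, X) treated as missing data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize, special, stats

from ._lg import AA_ORDER, LG_EXCHANGEABILITIES, LG_FREQUENCIES
from .io import ArmrootError, read_newick
from .supermatrix import ARM_SUFFIXES

AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
N_STATES = 20
_MISSING = set("-.?*XBZJUO")


# ---------------------------------------------------------------------------
# Substitution model


def _lg_matrix():
    r = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            r[i, j] = r[j, i] = LG_EXCHANGEABILITIES[k]
            k += 1
    return r


def discrete_gamma_rates(alpha, k):
    """Mean rates of k equal-probability classes of a Gamma(alpha, alpha)
    distribution (mean 1), the standard discretisation."""
    if alpha <= 0 or k < 1:
        raise ArmrootError("gamma rate model needs alpha > 0 and k >= 1")
    bounds = stats.gamma.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([bounds, [np.inf]])
    lower = np.concatenate([[0.0], bounds])
    probs = special.gammainc(alpha + 1, alpha * upper) - special.gammainc(
        alpha + 1, alpha * lower
    )
    rates = probs * k  # mean of each class, normalised to overall mean 1
    return rates


class PhyloModel:
    """Reversible amino-acid substitution model.

    Parameters
    ----------
    exchangeability : "POISSON" (all equal) or "LG".
    frequencies : None for the model's own frequencies (uniform for
        Poisson), or a length-20 vector (the empirical ``+F`` mode).
    rate_model : "UNIFORM" or "GAMMA" with ``gamma_classes``/``gamma_alpha``.

    The rate matrix is normalised to one expected substitution per unit
    branch length at equilibrium.
    """

    def __init__(
        self,
        exchangeability="POISSON",
        frequencies=None,
        rate_model="UNIFORM",
        gamma_classes=4,
        gamma_alpha=1.0,
    ):
        if exchangeability == "POISSON":
            r = np.ones((N_STATES, N_STATES))
            np.fill_diagonal(r, 0.0)
            default_freqs = np.full(N_STATES, 1.0 / N_STATES)
        elif exchangeability == "LG":
            r = _lg_matrix()
            default_freqs = np.array(LG_FREQUENCIES)
        else:
            raise ArmrootError(f"unknown exchangeability {exchangeability!r}")
        self.exchangeability = exchangeability
        pi = default_freqs if frequencies is None else np.asarray(frequencies, float)
        if pi.shape != (N_STATES,) or abs(pi.sum() - 1.0) > 1e-12 or (pi <= 0).any():
            raise ArmrootError("frequencies must be 20 positive values summing to 1")
        self.frequencies = pi

        q = r * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        q /= mu
        self.rate_matrix = q

        if rate_model == "UNIFORM":
            self.rates = np.array([1.0])
        elif rate_model == "GAMMA":
            self.rates = discrete_gamma_rates(gamma_alpha, gamma_classes)
        else:
            raise ArmrootError(f"unknown rate model {rate_model!r}")
        self.rate_weights = np.full(len(self.rates), 1.0 / len(self.rates))
        self.rate_model = rate_model
        self.gamma_alpha = gamma_alpha

        # Symmetrised eigendecomposition for fast transition matrices.
        sq = np.sqrt(pi)
        b = (q * sq[:, None]) / sq[None, :]
        evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
        self._evals = evals
        self._left = evecs / sq[:, None]
        self._right = evecs * sq[:, None]

    def transition_matrix(self, t, rate=1.0):
        """P(t) = exp(Q t · rate); rows sum to 1."""
        if t < 0:
            raise ArmrootError("negative branch length")
        p = (self._left * np.exp(self._evals * t * rate)) @ self._right.T
        return np.clip(p, 0.0, None)

    def describe(self):
        freq = "model" if self.exchangeability == "POISSON" else "+F-capable"
        return (
            f"{self.exchangeability} frequencies={freq} rates={self.rate_model}"
            f"(k={len(self.rates)}, alpha={self.gamma_alpha})"
        )


def model_from_config(config, alignment=None):
    """Build a PhyloModel from an AnalysisConfig (empirical frequencies are
    estimated from the supplied alignment in EMPIRICAL mode)."""
    freqs = None
    if config.frequency_mode == "EMPIRICAL":
        if alignment is None:
            raise ArmrootError("EMPIRICAL frequency mode needs an alignment")
        freqs = empirical_frequencies(alignment)
    return PhyloModel(
        exchangeability=config.substitution_model,
        frequencies=freqs,
        rate_model="GAMMA" if config.rate_model == "GAMMA" else "UNIFORM",
        gamma_classes=config.gamma_classes,
        gamma_alpha=config.gamma_alpha,
    )


def empirical_frequencies(alignment, pseudocount=0.5):
    """Amino-acid frequencies observed in an alignment (+F)."""
    counts = np.full(N_STATES, pseudocount)
    for seq in alignment.values():
        for c in seq.upper():
            i = AA_INDEX.get(c)
            if i is not None:
                counts[i] += 1
    return counts / counts.sum()


def encode_alignment(alignment):
    """Map sequences to int codes (0..19; -1 = gap/ambiguous/missing)."""
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ArmrootError("alignment rows differ in length")
    coded = {}
    for name, seq in alignment.items():
        row = np.empty(len(seq), dtype=np.int8)
        for j, c in enumerate(seq.upper()):
            if c in AA_INDEX:
                row[j] = AA_INDEX[c]
            elif c in _MISSING:
                row[j] = -1
            else:
                raise ArmrootError(f"unknown residue {c!r} in sequence {name!r}")
        coded[name] = row
    return coded


# ---------------------------------------------------------------------------
# Pruning likelihood


def _leaf_partial(codes, n_sites):
    p = np.ones((n_sites, N_STATES))
    known = codes >= 0
    p[known] = 0.0
    p[np.nonzero(known)[0], codes[known]] = 1.0
    return p


def site_loglik(tree, alignment, model):
    """Per-site log-likelihood (nats) of an alignment on a tree.

    Post-order pruning with per-branch transition matrices; discrete-gamma
    mixtures are averaged per site; gaps and ambiguity codes contribute a
    partial likelihood of 1 in every state.  Root-edge lengths are ignored.
    """
    coded = encode_alignment(alignment)
    taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if taxa != set(coded):
        only_tree = sorted(taxa - set(coded))
        only_aln = sorted(set(coded) - taxa)
        raise ArmrootError(
            f"tree/alignment taxa mismatch; tree-only: {only_tree}, "
            f"alignment-only: {only_aln}"
        )
    n_sites = len(next(iter(coded.values())))
    per_class = np.empty((len(model.rates), n_sites))
    for ci, rate in enumerate(model.rates):
        scale_log = np.zeros(n_sites)
        partial = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                partial[node] = _leaf_partial(coded[node.taxon.label], n_sites)
                continue
            p = np.ones((n_sites, N_STATES))
            for child in node.child_nodes():
                t = child.edge.length or 0.0
                pm = model.transition_matrix(t, rate)
                p *= partial.pop(child) @ pm.T
            mx = p.max(axis=1)
            mx[mx == 0] = 1.0
            scale_log += np.log(mx)
            partial[node] = p / mx[:, None]
        root_p = partial[tree.seed_node]
        lik = root_p @ model.frequencies
        per_class[ci] = np.log(np.clip(lik, 1e-300, None)) + scale_log
    if len(model.rates) == 1:
        return per_class[0]
    return special.logsumexp(per_class, axis=0, b=model.rate_weights[:, None])


@dataclass
class SiteLogLikTable:
    """Per-site log-likelihoods for a set of candidate topologies."""

    topologies: list
    site_ll: np.ndarray  # n_topologies x n_sites

    def __post_init__(self):
        self.site_ll = np.asarray(self.site_ll, float)
        if self.site_ll.ndim != 2 or self.site_ll.shape[0] != len(self.topologies):
            raise ArmrootError("site table shape does not match topology list")
        if not np.all(np.isfinite(self.site_ll)):
            raise ArmrootError("non-finite site log-likelihoods")

    @property
    def totals(self):
        return self.site_ll.sum(axis=1)

    @property
    def n_sites(self):
        return self.site_ll.shape[1]


def site_loglik_table(trees, alignment, model):
    """Evaluate several topologies on one alignment -> SiteLogLikTable."""
    names = list(trees)
    rows = [site_loglik(trees[n], alignment, model) for n in names]
    return SiteLogLikTable(topologies=names, site_ll=np.vstack(rows))


# ---------------------------------------------------------------------------
# Branch-length optimisation


def optimize_branch_lengths(
    tree, alignment, model, tol=1e-4, max_rounds=20, max_length=20.0
):
    """Coordinate-wise ML branch lengths (Brent per edge, sweeps until the
    total log-likelihood improves by less than ``tol``).  Returns the final
    log-likelihood; the tree is modified in place and its log-likelihood
    never decreases across sweeps."""
    edges = [
        e for e in tree.preorder_edge_iter() if e.tail_node is not None
    ]
    for e in edges:
        if e.length is None or e.length < 0:
            e.length = max(e.length or 0.0, 0.0)

    def total():
        return float(site_loglik(tree, alignment, model).sum())

    current = total()
    for _ in range(max_rounds):
        previous = current
        for edge in edges:
            old = edge.length

            def neg(t, edge=edge):
                edge.length = t
                return -float(site_loglik(tree, alignment, model).sum())

            res = optimize.minimize_scalar(
                neg, bounds=(1e-9, max_length), method="bounded",
                options={"xatol": 1e-7},
            )
            if -res.fun > current:
                edge.length = float(res.x)
                current = -res.fun
            else:
                edge.length = old
        if current - previous < tol:
            break
    return current


# ---------------------------------------------------------------------------
# Distance trees and NNI search


def _p_distance(a, b):
    both = (a >= 0) & (b >= 0)
    n = int(both.sum())
    if n == 0:
        return 0.75, 0  # uninformative pair
    return float((a[both] != b[both]).sum()) / n, n


def poisson_distance(p):
    """ML distance under the Poisson (equal-rates) model for mismatch
    fraction p: d = -(19/20) ln(1 - 20 p / 19)."""
    cap = 0.95 * (N_STATES - 1) / N_STATES
    p = min(p, cap)
    return -(N_STATES - 1) / N_STATES * math.log(1.0 - p * N_STATES / (N_STATES - 1))


def _ml_pair_distance(a, b, model):
    both = (a >= 0) & (b >= 0)
    if not both.any():
        return 3.0
    xa, xb = a[both], b[both]
    pi = model.frequencies

    def neg(t):
        pm = model.transition_matrix(t)
        vals = pi[xa] * pm[xa, xb]
        return -np.log(np.clip(vals, 1e-300, None)).sum()

    res = optimize.minimize_scalar(neg, bounds=(1e-6, 10.0), method="bounded")
    return float(res.x)


def nj_tree(alignment, model):
    """Neighbor-joining starting topology from model-corrected pairwise
    distances (closed-form Poisson correction, or per-pair 1-D ML distances
    for LG).  Negative NJ branch lengths are clamped to zero."""
    import skbio

    coded = encode_alignment(alignment)
    names = sorted(coded)
    if len(names) < 3:
        raise ArmrootError("NJ needs >= 3 taxa")
    n = len(names)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if model.exchangeability == "POISSON":
                p, _ = _p_distance(coded[names[i]], coded[names[j]])
                d = poisson_distance(p)
            else:
                d = _ml_pair_distance(coded[names[i]], coded[names[j]], model)
            dm[i, j] = dm[j, i] = d
    newick = str(skbio.tree.nj(skbio.DistanceMatrix(dm, ids=names)))
    tree = read_newick(newick)
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length <= 0:
            e.length = 0.0
    return tree


def tree_bipartitions(tree, restrict_to=None):
    """Non-trivial bipartitions as frozensets of leaf labels, each
    normalised to the side not containing the alphabetically first taxon."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    if restrict_to is not None:
        leaves = [l for l in leaves if l in restrict_to]
    if not leaves:
        return set()
    universe = set(leaves)
    anchor = leaves[0]
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(
            l.taxon.label for l in node.leaf_iter() if l.taxon.label in universe
        )
        if anchor in below:
            below = frozenset(universe - below)
        if 1 < len(below) < len(universe) - 1:
            splits.add(below)
    return splits


def displays_constraint(tree, constraint_tree):
    """True iff the tree, pruned to the constraint's taxa, contains every
    non-trivial constraint bipartition."""
    taxa = {l.taxon.label for l in constraint_tree.leaf_node_iter()}
    tree_taxa = {l.taxon.label for l in tree.leaf_node_iter()}
    if not taxa <= tree_taxa:
        raise ArmrootError(
            f"constraint taxa missing from tree: {sorted(taxa - tree_taxa)}"
        )
    want = tree_bipartitions(constraint_tree)
    have = tree_bipartitions(tree, restrict_to=taxa)
    return want <= have


def _rooted_at_leaf(tree):
    """Clone, rerooted on the pendant edge of the alphabetically first leaf,
    giving every internal node exactly two children (canonical NNI form)."""
    t = tree.clone(depth=1)
    leaf = min(t.leaf_node_iter(), key=lambda l: l.taxon.label)
    half = (leaf.edge.length or 0.0) / 2.0
    t.reroot_at_edge(leaf.edge, length1=half, length2=half,
                     update_bipartitions=False)
    t.suppress_unifurcations()
    # reroot_at_edge splits the pendant edge; resolve any multifurcation left.
    for node in t.preorder_node_iter():
        while len(node.child_nodes()) > 2:
            c1, c2 = node.child_nodes()[:2]
            node.remove_child(c1)
            node.remove_child(c2)
            joint = dendropy.Node()
            joint.edge.length = 0.0
            joint.add_child(c1)
            joint.add_child(c2)
            node.add_child(joint)
    return t


def _nni_neighbors(tree):
    """Yield (edge index, variant) cloned trees one NNI move away."""
    base = tree
    internal = []
    for idx, node in enumerate(base.preorder_node_iter()):
        node._nni_idx = idx
        parent = node.parent_node
        if (
            parent is not None
            and parent.parent_node is not None
            and not node.is_leaf()
        ):
            internal.append(idx)
    for idx in internal:
        for variant in (0, 1):
            t = base.clone(depth=1)
            nodes = list(t.preorder_node_iter())
            v = nodes[idx]
            u = v.parent_node
            sib = [c for c in u.child_nodes() if c is not v][0]
            child = v.child_nodes()[variant]
            u.remove_child(sib)
            v.remove_child(child)
            u.add_child(child)
            v.add_child(sib)
            yield t


def nni_search(
    start,
    alignment,
    model,
    constraint=None,
    tol=1e-3,
    opt_rounds=2,
    max_moves=50,
):
    """Hill-climbing NNI search from a starting topology.

    Each candidate's branch lengths are re-optimised (``opt_rounds``
    sweeps) before comparison and only strict log-likelihood improvements
    are accepted (best move per sweep; deterministic given input order).
    With a ``constraint`` tree, moves producing a topology that does not
    display every constraint bipartition are rejected.  Returns
    (tree, logL).
    """
    tree = _rooted_at_leaf(start)
    if constraint is not None and not displays_constraint(tree, constraint):
        raise ArmrootError("starting tree violates the constraint")
    current = optimize_branch_lengths(tree, alignment, model, tol=tol,
                                      max_rounds=opt_rounds)
    for _ in range(max_moves):
        best_ll, best_tree = current, None
        for cand in _nni_neighbors(tree):
            if constraint is not None and not displays_constraint(cand, constraint):
                continue
            ll = optimize_branch_lengths(cand, alignment, model, tol=tol,
                                         max_rounds=opt_rounds)
            if ll > best_ll + 1e-9:
                best_ll, best_tree = ll, cand
        if best_tree is None:
            break
        tree, current = best_tree, best_ll
    return tree, current


# ---------------------------------------------------------------------------
# RELL bootstrap, KH and AU tests


def rell_bootstrap(site_table, n_reps, seed, scale=1.0):
    """Resample site log-likelihoods with replacement (RELL).

    At scale r, each replicate draws ceil(r * n_sites) sites; returns an
    (n_topologies, n_reps) array of replicate total log-likelihoods.
    """
    if len(site_table.topologies) < 2:
        raise ArmrootError("RELL needs >= 2 topologies")
    rng = np.random.default_rng(seed)
    n = site_table.n_sites
    m = int(math.ceil(scale * n))
    counts = rng.multinomial(m, np.full(n, 1.0 / n), size=n_reps)
    return (counts @ site_table.site_ll.T).T


def kh_test(site_table, n_reps=1000, seed=0):
    """Kishino–Hasegawa test of each topology against its best competitor,
    using centred RELL replicate differences at scale 1.

    For topology i the statistic is d_i = max_{j != i} logL_j − logL_i and
    p_i = P*(centred replicate d >= d_i); the ML topology therefore gets a
    large p."""
    totals = site_table.totals
    reps = rell_bootstrap(site_table, n_reps, seed, scale=1.0)
    k = len(totals)
    p = np.empty(k)
    for i in range(k):
        others = [j for j in range(k) if j != i]
        d_obs = totals[others].max() - totals[i]
        d_rep = reps[others].max(axis=0) - reps[i]
        d_centered = d_rep - d_rep.mean()
        p[i] = float((d_centered >= d_obs).mean())
    return p


@dataclass
class AuResult:
    p_values: np.ndarray
    bootstrap_proportions: np.ndarray  # n_topologies x n_scales
    scales: tuple
    n_reps: int
    seed: int
    degenerate: np.ndarray = field(default=None)


def au_test(site_table, scales=(0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4),
            n_reps=1000, seed=0):
    """Approximately unbiased test from multiscale RELL bootstrap.

    For each scale r the bootstrap proportion BP_r of a topology is the
    fraction of replicates in which it attains the maximum total.  The
    signed distance d and curvature c are fit by weighted least squares to
    Phi^-1(1 − BP_r) ≈ d·sqrt(r) + c/sqrt(r), and p_AU = 1 − Phi(d − c).
    A topology that never wins a replicate at any scale is flagged
    degenerate with p = 0.
    """
    scales = tuple(float(s) for s in scales)
    k = len(site_table.topologies)
    bp = np.zeros((k, len(scales)))
    for si, r in enumerate(scales):
        reps = rell_bootstrap(site_table, n_reps, seed + si, scale=r)
        # exact ties split their replicate's win equally between topologies
        top = reps.max(axis=0)
        wins = reps == top
        bp[:, si] = (wins / wins.sum(axis=0)).mean(axis=1)
    eps = 1.0 / (2.0 * n_reps)
    p = np.empty(k)
    degenerate = np.zeros(k, dtype=bool)
    sq = np.sqrt(np.asarray(scales))
    design = np.column_stack([sq, 1.0 / sq])
    for i in range(k):
        if np.all(bp[i] == 0.0):
            p[i] = 0.0
            degenerate[i] = True
            continue
        if np.all(bp[i] == 1.0):  # never loses a replicate at any scale
            p[i] = 1.0
            continue
        bpc = np.clip(bp[i], eps, 1.0 - eps)
        z = stats.norm.ppf(1.0 - bpc)
        w = n_reps * stats.norm.pdf(z) ** 2 / (bpc * (1.0 - bpc))
        wd = design * w[:, None]
        coef, *_ = np.linalg.lstsq(wd.T @ design, wd.T @ z, rcond=None)
        d, c = coef
        p[i] = float(np.clip(1.0 - stats.norm.cdf(d - c), 0.0, 1.0))
    return AuResult(p_values=p, bootstrap_proportions=bp, scales=scales,
                    n_reps=n_reps, seed=seed, degenerate=degenerate)


@dataclass
class TopologyTestResult:
    """Per-topology log-likelihoods and test p-values.

    A topology is rejected at the conventional threshold when p_AU < 0.05.
    """

    table: object  # pandas DataFrame
    n_reps: int
    scales: tuple
    seed: int


def topology_test(site_table, scales=(0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2,
                                      1.3, 1.4), n_reps=1000, seed=0):
    """Run KH and AU tests on a site log-likelihood table."""
    import pandas as pd

    totals = site_table.totals
    au = au_test(site_table, scales=scales, n_reps=n_reps, seed=seed)
    kh = kh_test(site_table, n_reps=n_reps, seed=seed)
    best = totals.max()
    df = pd.DataFrame(
        {
            "topology": site_table.topologies,
            "logL": totals,
            "deltaL": best - totals,
            "p_KH": kh,
            "p_AU": au.p_values,
            "au_degenerate": au.degenerate,
        }
    )
    return TopologyTestResult(table=df, n_reps=n_reps, scales=tuple(scales),
                              seed=seed)


# ---------------------------------------------------------------------------
# Arm-root evaluation


@dataclass
class RootSplitReport:
    bipartition_present: bool
    support: float  # RELL support of the arm split; NaN when not assessed
    rooted_tree: object  # dendropy Tree rooted on the arm branch, or None
    arm_monophyly: dict


def root_split_report(tree, alignment=None, model=None, suffixes=ARM_SUFFIXES,
                      groups=None, n_reps=1000, seed=0):
    """Check for the arm1/arm2 bipartition in a pseudo-taxon tree.

    If the bipartition separating all "<species>__arm1" leaves from all
    "<species>__arm2" leaves exists in the unrooted topology, the returned
    tree is rooted on that branch.  When an alignment and model are given,
    RELL support for the split is the proportion of scale-1 replicates in
    which the tree beats its two NNI rearrangements across that branch.
    ``groups`` (species -> label) adds per-arm monophyly checks per label.
    """
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    arm1 = {l for l in labels if l.endswith(suffixes[0])}
    arm2 = {l for l in labels if l.endswith(suffixes[1])}
    if not arm1 or not arm2 or arm1 | arm2 != set(labels):
        raise ArmrootError("leaves are not consistently arm-suffixed")

    split_edge = None
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {l.taxon.label for l in node.leaf_iter()}
        if below == arm1 or below == arm2:
            split_edge = node.edge
            break

    monophyly = {}
    if groups is not None and split_edge is not None:
        for arm_set, suffix in ((arm1, suffixes[0]), (arm2, suffixes[1])):
            for g in sorted(set(groups.values())):
                members = {
                    sp + suffix for sp, grp in groups.items() if grp == g
                } & arm_set
                if len(members) < 2:
                    continue
                mrca = tree.mrca(taxon_labels=sorted(members))
                clade = {l.taxon.label for l in mrca.leaf_iter()}
                monophyly[f"{g}{suffix}"] = clade == members

    if split_edge is None:
        return RootSplitReport(False, float("nan"), None, monophyly)

    support = float("nan")
    if alignment is not None and model is not None:
        support = _rell_split_support(tree, split_edge, alignment, model,
                                      n_reps, seed)

    rooted = tree.clone(depth=1)
    for node in rooted.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {l.taxon.label for l in node.leaf_iter()}
        if below == arm1 or below == arm2:
            half = (node.edge.length or 0.0) / 2.0
            rooted.reroot_at_edge(node.edge, length1=half, length2=half,
                                  update_bipartitions=False)
            break
    rooted.is_rooted = True
    return RootSplitReport(True, support, rooted, monophyly)


def _rell_split_support(tree, split_edge, alignment, model, n_reps, seed):
    """RELL proportion for the focal split against its two NNI neighbours."""
    canon = _rooted_at_leaf(tree)
    below_target = {l.taxon.label for l in split_edge.head_node.leaf_iter()}
    candidates = {"observed": canon}
    found = 0
    idx = 0
    for node in canon.preorder_node_iter():
        node._nni_idx = idx
        idx += 1
    target_idx = None
    for node in canon.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = {l.taxon.label for l in node.leaf_iter()}
        if below == below_target or below == (
            {l.taxon.label for l in canon.leaf_node_iter()} - below_target
        ):
            target_idx = node._nni_idx
            break
    if target_idx is None:
        return float("nan")
    nodes = list(canon.preorder_node_iter())
    target = nodes[target_idx]
    if target.parent_node.parent_node is None:
        return float("nan")
    for variant in (0, 1):
        t = canon.clone(depth=1)
        tn = list(t.preorder_node_iter())[target_idx]
        u = tn.parent_node
        sib = [c for c in u.child_nodes() if c is not tn][0]
        child = tn.child_nodes()[variant]
        u.remove_child(sib)
        tn.remove_child(child)
        u.add_child(child)
        tn.add_child(sib)
        candidates[f"nni{variant}"] = t
        found += 1
    if found < 2:
        return float("nan")
    table = site_loglik_table(candidates, alignment, model)
    reps = rell_bootstrap(table, n_reps, seed, scale=1.0)
    winners = np.argmax(reps, axis=0)
    return float((winners == 0).mean())
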