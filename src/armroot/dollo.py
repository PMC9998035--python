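"""Dollo parsimony: minimal loss histories under a single-gain model.

A character (here: possession of a protein complex) is gained exactly once
on a rooted species tree and may only be lost thereafter.  The minimal
reconstruction places one loss on each maximal subtree below the gain node
that contains no present leaf.  Clades and edges are identified by the
frozenset of leaf labels they subtend, which is stable across topologically
equal trees regardless of node order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .io import ArmrootError

_STATES = {"present", "absent", "unknown"}


@dataclass
class DolloReconstruction:
    """Gain node, minimal loss-edge set, and ancestral presence states.

    ``gain_clade`` and each entry of ``loss_edges`` are frozensets of leaf
    labels (the clade below the gain node / below the lost edge).
    ``node_states`` maps every clade's leaf set to its reconstructed
    presence state.
    """

    gain_clade: frozenset
    loss_edges: frozenset
    node_states: dict
    unknown_leaves: frozenset = field(default_factory=frozenset)

    @property
    def n_losses(self):
        return len(self.loss_edges)


def _leafset(node):
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def _normalize_states(presence_vector, leaves):
    missing = set(leaves) - set(presence_vector)
    if missing:
        raise ArmrootError(f"presence vector missing leaves: {sorted(missing)}")
    states = {}
    for leaf in leaves:
        v = presence_vector[leaf]
        if isinstance(v, bool):
            v = "present" if v else "absent"
        if v not in _STATES:
            raise ArmrootError(f"bad presence state {v!r} for leaf {leaf!r}")
        states[leaf] = v
    return states


def dollo_reconstruct(
    tree, presence_vector, gain_policy="fixed_root", unknown_policy="absent"
):
    """Minimal single-gain loss reconstruction on a rooted tree.

    Parameters
    ----------
    presence_vector : mapping leaf label -> "present" | "absent" | "unknown"
        (booleans accepted).
    gain_policy : "fixed_root" places the gain at the root (ancestral-origin
        hypothesis); "mrca_of_present" places it at the MRCA of present
        leaves (errors when none are present).
    unknown_policy : "absent" treats unknown leaves as absent (they can pull
        in loss edges); "free" lets each unknown take whichever state avoids
        a loss, so all-unknown clades never cost one.
    """
    if gain_policy not in {"fixed_root", "mrca_of_present"}:
        raise ArmrootError(f"unknown gain policy {gain_policy!r}")
    if unknown_policy not in {"absent", "free"}:
        raise ArmrootError(f"unknown unknown_policy {unknown_policy!r}")
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    states = _normalize_states(presence_vector, leaves)
    unknown = frozenset(l for l, s in states.items() if s == "unknown")

    # Per-node tallies of strict presences and loss-forcing absences below.
    has_present, has_absent = {}, {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states[node.taxon.label]
            has_present[node] = s == "present"
            has_absent[node] = (
                s == "absent" or (s == "unknown" and unknown_policy == "absent")
            )
        else:
            has_present[node] = any(has_present[c] for c in node.child_nodes())
            has_absent[node] = any(has_absent[c] for c in node.child_nodes())

    root = tree.seed_node
    if gain_policy == "fixed_root":
        gain = root
    else:
        if not has_present[root]:
            raise ArmrootError("mrca_of_present gain policy with zero present leaves")
        gain = root
        while True:
            kids = [c for c in gain.child_nodes() if has_present[c]]
            if len(kids) == 1 and not kids[0].is_leaf():
                gain = kids[0]
            elif len(kids) == 1 and kids[0].is_leaf():
                gain = kids[0]
                break
            else:
                break

    loss_edges = set()
    node_states = {}

    def walk(node, present):
        node_states[_leafset(node)] = present
        for child in node.child_nodes():
            if not present:
                walk(child, False)
            elif has_present[child]:
                walk(child, True)
            elif has_absent[child]:
                loss_edges.add(_leafset(child))
                walk(child, False)
            else:  # all-unknown subtree under the "free" policy: stays present
                walk(child, True)

    # Everything outside the gain clade predates the gain.
    for node in tree.preorder_node_iter():
        ls = _leafset(node)
        node_states.setdefault(ls, False)
    walk(gain, True)

    return DolloReconstruction(
        gain_clade=_leafset(gain),
        loss_edges=frozenset(loss_edges),
        node_states=node_states,
        unknown_leaves=unknown,
    )


def count_independent_losses(
    tree, matrix, complex_name, min_subunits=1, gain_policy="fixed_root",
    unknown_policy="absent",
):
    """Number of independent losses of a complex on a rooted species tree.

    Applies the complex presence call (>= ``min_subunits`` subunits) to the
    matrix, prunes tree leaves without matrix rows (with a warning), and
    runs :func:`dollo_reconstruct` with the gain fixed at the root.
    A species with no present subunit but at least one unknown cell gets the
    "unknown" leaf state.
    """
    from .profiles import call_complex_presence

    calls = call_complex_presence(matrix, complex_name, min_subunits)
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    keep = [t for t in taxa if t in calls.index]
    if len(keep) < len(taxa):
        dropped = sorted(set(taxa) - set(keep))
        warnings.warn(
            f"pruning {len(dropped)} tree leaves absent from the matrix: "
            + ", ".join(dropped[:5])
            + ("..." if len(dropped) > 5 else ""),
            stacklevel=2,
        )
        tree = tree.extract_tree_with_taxa_labels(keep)
    vec = {}
    for sp in keep:
        row = calls.loc[sp]
        if row["present"]:
            vec[sp] = "present"
        elif row["n_present"] == 0 and row["n_unknown"] > 0:
            vec[sp] = "unknown"
        else:
            vec[sp] = "absent"
    rec = dollo_reconstruct(tree, vec, gain_policy=gain_policy,
                            unknown_policy=unknown_policy)
    return rec.n_losses


def map_losses_to_taxa(reconstruction, species_table=None):
    """Label each loss edge by the lineage it subtends.

    A loss clade is named by its single species, by its major group when a
    species table is given and all members share one, or otherwise by the
    sorted member list.  Returned in a deterministic order (clade size,
    then name).
    """
    labels = []
    for clade in reconstruction.loss_edges:
        members = sorted(clade)
        if species_table is not None:
            groups = {species_table.group_of(sp) for sp in members}
            if len(groups) == 1:
                labels.append((len(members), groups.pop()))
                continue
        if len(members) == 1:
            labels.append((1, members[0]))
        else:
            labels.append((len(members), "+".join(members)))
    return [name for _, name in sorted(labels)]
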