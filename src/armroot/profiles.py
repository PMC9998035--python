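"""Phylogenetic presence/absence profiles and complex co-occurrence.

The central object is a species × subunit :class:`PresenceMatrix` with
three-valued cells (present / absent / unknown) plus named complex
definitions and a conditioning gene.  Counting is always conditioned on
species that possess the conditioning gene (by default Ndc80, the
kinetochore hub both microtubule-coupling complexes attach to), so that
species without any kinetochore signal do not dilute the denominators.

"Unknown" cells model transcriptome incompleteness: absence of a subunit
from a transcriptome is not evidence of genomic absence, so unknowns are
excluded from denominators and never drive exclusivity calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ArmrootError

PRESENT, ABSENT, UNKNOWN = 1, 0, -1

#: The ten subunits of the two-armed microtubule-coupling complex (Dam1-C).
DAM1_SUBUNITS = (
    "Dam1", "Duo1", "Ask1", "Hsk3", "Spc19", "Spc34",
    "Dad1", "Dad2", "Dad3", "Dad4",
)

#: The three subunits of its non-homologous functional counterpart (Ska-C).
SKA_SUBUNITS = ("Ska1", "Ska2", "Ska3")


def default_complexes(available_columns):
    """Default complex definitions restricted to subunits actually present
    as matrix columns (a complex is dropped if no subunit column exists)."""
    out = {}
    for name, subunits in (("Dam1-C", DAM1_SUBUNITS), ("Ska-C", SKA_SUBUNITS)):
        have = [s for s in subunits if s in available_columns]
        if have:
            out[name] = have
    return out


@dataclass
class PresenceMatrix:
    """Species × subunit presence matrix with complex definitions.

    ``data`` holds int8 cells coded 1 (present), 0 (absent), -1 (unknown).
    """

    data: pd.DataFrame
    complexes: dict
    conditioning_gene: str = "Ndc80"

    def __post_init__(self):
        if self.data.index.duplicated().any():
            raise ArmrootError("duplicate species in presence matrix")
        bad = set(self.data.values.ravel()) - {PRESENT, ABSENT, UNKNOWN}
        if bad:
            raise ArmrootError(f"invalid presence codes: {sorted(bad)}")
        for name, subunits in self.complexes.items():
            missing = set(subunits) - set(self.data.columns)
            if missing:
                raise ArmrootError(
                    f"complex {name!r} subunits missing from matrix: {sorted(missing)}"
                )

    @property
    def species(self):
        return list(self.data.index)

    def subunits_of(self, complex_name):
        try:
            return list(self.complexes[complex_name])
        except KeyError:
            raise ArmrootError(
                f"unknown complex {complex_name!r} (have: {sorted(self.complexes)})"
            ) from None

    def conditioning_positive(self):
        """Boolean Series: species with the conditioning gene present."""
        if self.conditioning_gene not in self.data.columns:
            raise ArmrootError(
                f"conditioning gene {self.conditioning_gene!r} not a matrix column"
            )
        return self.data[self.conditioning_gene] == PRESENT


@dataclass
class CooccurrenceSummary:
    """Counts of complex co-occurrence among conditioning-gene-positive
    species, plus the derived fractions (3 decimals).

    ``frac_either_inclusive`` counts species with A or B (or both);
    ``frac_either_exclusive`` counts species with exactly one.  Both are
    reported because a headline "either" percentage is ambiguous between
    the two readings.
    """

    complex_a: str
    complex_b: str
    n_conditioning: int
    n_a: int
    n_b: int
    n_both: int
    n_neither: int
    frac_a: float = field(init=False)
    frac_b: float = field(init=False)
    frac_both: float = field(init=False)
    frac_either_inclusive: float = field(init=False)
    frac_either_exclusive: float = field(init=False)

    def __post_init__(self):
        n = self.n_conditioning
        if n <= 0:
            raise ArmrootError("no conditioning-gene-positive species")
        if self.n_a + self.n_b - self.n_both + self.n_neither != n:
            raise ArmrootError("inconsistent co-occurrence counts")
        self.frac_a = round(self.n_a / n, 3)
        self.frac_b = round(self.n_b / n, 3)
        self.frac_both = round(self.n_both / n, 3)
        either = self.n_a + self.n_b - self.n_both
        self.frac_either_inclusive = round(either / n, 3)
        self.frac_either_exclusive = round((either - self.n_both) / n, 3)


def call_complex_presence(matrix, complex_name, min_subunits=1):
    """Call a complex present in each species.

    A species is flagged present iff at least ``min_subunits`` of the
    complex's subunit cells are *present*.  Unknown cells count toward
    neither side but are tallied separately.

    Returns a DataFrame indexed by species with columns ``n_present``,
    ``n_unknown`` and boolean ``present``.
    """
    if min_subunits < 1:
        raise ArmrootError("min_subunits must be >= 1")
    sub = matrix.data[matrix.subunits_of(complex_name)]
    n_present = (sub == PRESENT).sum(axis=1)
    n_unknown = (sub == UNKNOWN).sum(axis=1)
    return pd.DataFrame(
        {
            "n_present": n_present,
            "n_unknown": n_unknown,
            "present": n_present >= min_subunits,
        }
    )


def cooccurrence_summary(matrix, complex_a, complex_b, min_subunits=1):
    """Summarise co-occurrence of two complexes among conditioning-positive
    species (see :class:`CooccurrenceSummary`)."""
    cond = matrix.conditioning_positive()
    if int(cond.sum()) == 0:
        raise ArmrootError(
            f"no species has the conditioning gene {matrix.conditioning_gene!r}"
        )
    a = call_complex_presence(matrix, complex_a, min_subunits)["present"][cond]
    b = call_complex_presence(matrix, complex_b, min_subunits)["present"][cond]
    return CooccurrenceSummary(
        complex_a=complex_a,
        complex_b=complex_b,
        n_conditioning=int(cond.sum()),
        n_a=int(a.sum()),
        n_b=int(b.sum()),
        n_both=int((a & b).sum()),
        n_neither=int((~a & ~b).sum()),
    )


@dataclass
class ExclusivityResult:
    observed_both: int
    p_value: float
    n_permutations: int
    null_kind: str
    degenerate: bool = False


def mutual_exclusivity_test(
    matrix, complex_a, complex_b, n_permutations=1000, seed=0, tree=None,
    min_subunits=1,
):
    """One-sided permutation test for mutual exclusivity of two complexes.

    Null without a tree: complex-A presence labels are permuted among
    conditioning-gene-positive species while complex B stays fixed; the
    statistic is the number of species carrying both, and
    ``p = (1 + #{perm: n_both <= observed}) / (1 + n_permutations)``
    (small observed overlap = exclusive).

    With a rooted species ``tree`` the null instead re-simulates single-gain
    Dollo loss histories for both complexes, conditioned on the observed
    minimal loss counts: loss-edge sets of the observed cardinality are
    drawn uniformly among antichains of tree edges (no edge ancestral to
    another), which keeps the phylogenetic dependence structure of species
    that permutation ignores.
    """
    if n_permutations < 100:
        raise ArmrootError("n_permutations must be >= 100")
    cond = matrix.conditioning_positive()
    a = call_complex_presence(matrix, complex_a, min_subunits)["present"][cond].to_numpy()
    b = call_complex_presence(matrix, complex_b, min_subunits)["present"][cond].to_numpy()
    observed = int((a & b).sum())
    rng = np.random.default_rng(seed)
    if a.sum() == 0 or a.sum() == len(a):
        return ExclusivityResult(observed, 1.0, n_permutations, "degenerate", True)
    if tree is None:
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(a)
            if int((perm & b).sum()) <= observed:
                hits += 1
        p = (1 + hits) / (1 + n_permutations)
        return ExclusivityResult(observed, p, n_permutations, "label_permutation")
    return _tree_null_test(
        matrix, complex_a, complex_b, observed, n_permutations, rng, tree, min_subunits
    )


def _tree_null_test(
    matrix, complex_a, complex_b, observed, n_permutations, rng, tree, min_subunits
):
    from .dollo import dollo_reconstruct

    cond = matrix.conditioning_positive()
    cond_species = set(matrix.data.index[cond])
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    keep = [t for t in taxa if t in cond_species]
    work = tree.extract_tree_with_taxa_labels(keep) if set(keep) != set(taxa) else tree

    def loss_count(cname):
        calls = call_complex_presence(matrix, cname, min_subunits)["present"]
        vec = {sp: ("present" if calls.get(sp, False) else "absent") for sp in keep}
        return dollo_reconstruct(work, vec).n_losses

    k_a, k_b = loss_count(complex_a), loss_count(complex_b)

    # Edge bookkeeping: leaves below each non-root edge, as index bitsets.
    leaves = [leaf.taxon.label for leaf in work.leaf_node_iter()]
    idx = {name: i for i, name in enumerate(leaves)}
    edges = []
    for node in work.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(idx[l.taxon.label] for l in node.leaf_iter())
        edges.append(below)

    def sample_losses(k):
        """Uniform-ish antichain of k loss edges via rejection sampling."""
        for _ in range(1000):
            pick = rng.choice(len(edges), size=k, replace=False) if k else []
            sets = [edges[i] for i in pick]
            ok = all(
                s1.isdisjoint(s2) for i, s1 in enumerate(sets) for s2 in sets[i + 1 :]
            )
            if ok:
                lost = set().union(*sets) if sets else set()
                return np.array([i in lost for i in range(len(leaves))])
        raise ArmrootError(f"could not sample an antichain of {k} loss edges")

    hits = 0
    for _ in range(n_permutations):
        a_null = ~sample_losses(k_a)
        b_null = ~sample_losses(k_b)
        if int((a_null & b_null).sum()) <= observed:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return ExclusivityResult(observed, p, n_permutations, "dollo_resimulation")


def taxon_completeness(matrix, species_table, group_by="group"):
    """Per-group presence fractions for every gene column.

    Returns a DataFrame indexed by group with one column per gene, each cell
    the fraction of the group's species (unknowns excluded from the
    denominator) with the gene present; plus an ``n_species`` column.
    Groups with zero species are omitted.
    """
    ann = species_table.data.set_index("species")[group_by]
    missing = set(matrix.data.index) - set(ann.index)
    if missing:
        raise ArmrootError(f"species without group labels: {sorted(missing)}")
    groups = ann.loc[matrix.data.index]
    rows = {}
    for group, block in matrix.data.groupby(groups):
        known = (block != UNKNOWN).sum(axis=0)
        present = (block == PRESENT).sum(axis=0)
        frac = (present / known.replace(0, np.nan)).astype(float)
        frac["n_species"] = len(block)
        rows[group] = frac
    return pd.DataFrame(rows).T


def complexes_per_group(matrix, species_table, complex_name, min_subunits=1):
    """Number of major groups in which a complex is present in >= 1 species."""
    calls = call_complex_presence(matrix, complex_name, min_subunits)["present"]
    ann = species_table.data.set_index("species")["group"]
    groups = ann.loc[matrix.data.index]
    per_group = calls.groupby(groups).any()
    return int(per_group.sum()), int(len(per_group))
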