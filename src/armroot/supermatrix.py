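"""Duplication-rooted supermatrix construction.

Each subunit of the two-armed complex has a structural paralog in the other
arm.  Merging the ortholog alignment of a subunit with that of its partner
(profile–profile, sub-MSA preserving), trimming sparse columns, and
concatenating the merged pair blocks yields a supermatrix in which every
species contributes one pseudo-taxon per arm ("<species>__arm1" /
"<species>__arm2").  A tree inferred from it can be rooted on the branch
separating the arms, because the arm-generating duplication predates the
species radiation.

The merge never splits, reorders or edits input columns: every output
column is a column of A, a column of B, or both, so deleting the partner's
rows and the resulting all-gap columns recovers each input exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .io import ArmrootError

ARM_SUFFIXES = ("__arm1", "__arm2")


@dataclass(frozen=True)
class ParalogPair:
    name: str
    arm1_member: str
    arm2_member: str


@dataclass
class ParalogMap:
    """Cross-arm subunit pairing plus subunits excluded from concatenation."""

    pairs: list
    excluded: tuple = ()

    def __post_init__(self):
        seen = set()
        for p in self.pairs:
            for s in (p.arm1_member, p.arm2_member):
                if s in seen:
                    raise ArmrootError(f"subunit {s!r} appears in more than one pair")
                seen.add(s)
        bad = set(self.excluded) & seen
        if bad:
            raise ArmrootError(f"excluded subunits appear in pairs: {sorted(bad)}")

    @property
    def arm1(self):
        return [p.arm1_member for p in self.pairs]

    @property
    def arm2(self):
        return [p.arm2_member for p in self.pairs]

    def arm_of(self, subunit):
        if subunit in self.arm1:
            return "arm1"
        if subunit in self.arm2:
            return "arm2"
        raise ArmrootError(f"subunit {subunit!r} not in paralog map")


#: The four validated paralog pairs of the complex; the fifth candidate pair
#: (Spc19–Spc34) showed no reproducible homology signal and is excluded.
DEFAULT_PARALOG_MAP = ParalogMap(
    pairs=[
        ParalogPair("Ask1-Dad3", "Ask1", "Dad3"),
        ParalogPair("Dad2-Duo1", "Dad2", "Duo1"),
        ParalogPair("Dad4-Dad1", "Dad4", "Dad1"),
        ParalogPair("Hsk3-Dam1", "Hsk3", "Dam1"),
    ],
    excluded=("Spc19", "Spc34"),
)


# ---------------------------------------------------------------------------
# Profile–profile merge alignment


def _check_msa(msa, what):
    if not msa:
        raise ArmrootError(f"{what} alignment is empty")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ArmrootError(f"{what} alignment rows differ in length")
    return lengths.pop()


def _column_scores(msa_a, la, msa_b, lb, submat, alphabet):
    """Mean pairwise substitution score between every column pair; column
    pairs with no jointly non-gap residues score 0."""
    k = len(alphabet)
    index = {c: i for i, c in enumerate(alphabet)}

    def counts(msa, length):
        m = np.zeros((length, k))
        for row in msa.values():
            for j, c in enumerate(row):
                i = index.get(c)
                if i is not None:
                    m[j, i] += 1
        return m

    ca, cb = counts(msa_a, la), counts(msa_b, lb)
    na, nb = ca.sum(axis=1), cb.sum(axis=1)
    raw = ca @ submat @ cb.T
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, raw / np.maximum(denom, 1), 0.0)
    return s


def profile_merge_align(msa_a, msa_b, gap_open=-11.0, gap_extend=-1.0):
    """Globally align two alignments column-against-column (affine gaps).

    Inputs are ``{row_id: aligned_sequence}`` mappings with disjoint row
    ids.  Column scores are mean pairwise BLOSUM62 values over jointly
    non-gap residues.  Ties in the traceback resolve match > gap-in-B >
    gap-in-A, which makes the output deterministic.
    """
    la, lb = _check_msa(msa_a, "first"), _check_msa(msa_b, "second")
    overlap = set(msa_a) & set(msa_b)
    if overlap:
        raise ArmrootError(f"row ids present in both alignments: {sorted(overlap)}")

    b62 = substitution_matrices.load("BLOSUM62")
    alphabet = "ARNDCQEGHILKMFPSTWYV"
    sub = np.array([[b62[x][y] for y in alphabet] for x in alphabet], float)
    s = _column_scores(msa_a, la, msa_b, lb, sub, alphabet)

    neg = -np.inf
    m = np.full((la + 1, lb + 1), neg)
    gx = np.full((la + 1, lb + 1), neg)  # gap in B (consume A column)
    gy = np.full((la + 1, lb + 1), neg)  # gap in A (consume B column)
    m[0, 0] = 0.0
    for i in range(1, la + 1):
        gx[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, lb + 1):
        gy[0, j] = gap_open + gap_extend * (j - 1)
    ptr_m = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptr_x = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptr_y = np.zeros((la + 1, lb + 1), dtype=np.int8)
    M, X, Y = 0, 1, 2
    for i in range(1, la + 1):
        srow = s[i - 1]
        for j in range(1, lb + 1):
            best, arg = m[i - 1, j - 1], M
            if gx[i - 1, j - 1] > best:
                best, arg = gx[i - 1, j - 1], X
            if gy[i - 1, j - 1] > best:
                best, arg = gy[i - 1, j - 1], Y
            m[i, j] = best + srow[j - 1]
            ptr_m[i, j] = arg

            best, arg = m[i - 1, j] + gap_open, M
            cand = gx[i - 1, j] + gap_extend
            if cand > best:
                best, arg = cand, X
            cand = gy[i - 1, j] + gap_open
            if cand > best:
                best, arg = cand, Y
            gx[i, j] = best
            ptr_x[i, j] = arg

            best, arg = m[i, j - 1] + gap_open, M
            cand = gx[i, j - 1] + gap_open
            if cand > best:
                best, arg = cand, X
            cand = gy[i, j - 1] + gap_extend
            if cand > best:
                best, arg = cand, Y
            gy[i, j] = best
            ptr_y[i, j] = arg

    # Traceback from the best terminal state (M > X > Y on ties).
    i, j = la, lb
    state = max((M, X, Y), key=lambda st: (m, gx, gy)[st][la, lb] - st * 1e-12)
    ops = []
    while i > 0 or j > 0:
        if i == 0:
            state = Y
        elif j == 0:
            state = X
        if state == M:
            prev = ptr_m[i, j]
            ops.append(("M", i - 1, j - 1))
            i, j = i - 1, j - 1
        elif state == X:
            prev = ptr_x[i, j]
            ops.append(("X", i - 1, None))
            i -= 1
        else:
            prev = ptr_y[i, j]
            ops.append(("Y", None, j - 1))
            j -= 1
        state = prev
    ops.reverse()

    merged = {}
    for name, row in msa_a.items():
        merged[name] = "".join(
            row[ia] if op in ("M", "X") else "-" for op, ia, _ in ops
        )
    for name, row in msa_b.items():
        merged[name] = "".join(
            row[jb] if op in ("M", "Y") else "-" for op, _, jb in ops
        )
    return merged


# ---------------------------------------------------------------------------
# Gap-threshold trimming


def trim_columns(msa, keep_fraction):
    """Drop sparse columns: keep a column iff its non-gap fraction is
    >= ``keep_fraction``.  Returns (trimmed msa, kept original indices)."""
    if not (0 < keep_fraction <= 1):
        raise ArmrootError("keep_fraction must be in (0, 1]")
    length = _check_msa(msa, "input")
    rows = list(msa.values())
    n = len(rows)
    kept = [
        j
        for j in range(length)
        if sum(1 for r in rows if r[j] != "-") / n >= keep_fraction
    ]
    if not kept:
        raise ArmrootError(
            f"trimming at keep_fraction={keep_fraction} removed all "
            f"{length} columns ({n} rows)"
        )
    trimmed = {name: "".join(row[j] for j in kept) for name, row in msa.items()}
    return trimmed, kept


# ---------------------------------------------------------------------------
# Species filter and supermatrix assembly


def select_species_by_arm_coverage(matrix, paralog_map, min_per_arm=2):
    """Species with >= ``min_per_arm`` present subunits in *both* arms
    (excluded subunits never count)."""
    if min_per_arm < 1:
        raise ArmrootError("min_per_arm must be >= 1")
    from .profiles import PRESENT

    included = []
    for sp in matrix.data.index:
        row = matrix.data.loc[sp]
        counts = {}
        for arm, members in (("arm1", paralog_map.arm1), ("arm2", paralog_map.arm2)):
            have = [s for s in members if s in matrix.data.columns]
            counts[arm] = int((row[have] == PRESENT).sum()) if have else 0
        if counts["arm1"] >= min_per_arm and counts["arm2"] >= min_per_arm:
            included.append(sp)
    return included


@dataclass
class Supermatrix:
    """Concatenated alignment with a named column partition (1-based,
    inclusive intervals, the common phylogenetics convention)."""

    rows: dict
    partitions: list  # (block name, start, end)

    def __post_init__(self):
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ArmrootError("supermatrix rows differ in length")
        total = lengths.pop() if lengths else 0
        expect = 1
        for name, start, end in self.partitions:
            if start != expect or end < start:
                raise ArmrootError(f"partition {name!r} not contiguous")
            expect = end + 1
        if self.partitions and expect != total + 1:
            raise ArmrootError("partitions do not cover the supermatrix")

    @property
    def length(self):
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def partition_table(self):
        return "\n".join(f"{n}\t{s}\t{e}" for n, s, e in self.partitions) + "\n"


@dataclass
class ArmSupermatrix(Supermatrix):
    """Supermatrix over species × arm pseudo-taxa."""

    included_species: list = field(default_factory=list)

    def __post_init__(self):
        super().__post_init__()
        for sp in self.included_species:
            if "__" in sp:
                raise ArmrootError(
                    f"species name {sp!r} contains the reserved '__' separator"
                )
            for suffix in ARM_SUFFIXES:
                if sp + suffix not in self.rows:
                    raise ArmrootError(f"missing pseudo-taxon row {sp + suffix!r}")


def _pad_block(row, length):
    return row if row is not None else "-" * length


def build_arm_supermatrix(
    alignments,
    paralog_map,
    included_species,
    trim_keep_fraction=0.05,
    merged_alignments=None,
):
    """Assemble the arm supermatrix.

    ``alignments`` maps subunit -> {species: aligned row}.  For each paralog
    pair the two subunit alignments are merged (or taken pre-merged from
    ``merged_alignments[pair.name]``, keyed "<subunit>::<species>", for
    externally aligned input), trimmed, and appended as one partition block.
    The arm1 pseudo-taxon of a species carries its arm1-member sequence in
    that block, the arm2 pseudo-taxon the partner's; missing subunits are
    gap-padded.  A species whose pseudo-taxon row ends up all-gap violates
    the coverage filter and raises an error.
    """
    rows = {sp + suf: [] for sp in included_species for suf in ARM_SUFFIXES}
    partitions = []
    pos = 1
    for pair in paralog_map.pairs:
        if merged_alignments is not None and pair.name in merged_alignments:
            merged = merged_alignments[pair.name]
        else:
            msa_u = {
                f"{pair.arm1_member}::{sp}": row
                for sp, row in alignments.get(pair.arm1_member, {}).items()
            }
            msa_v = {
                f"{pair.arm2_member}::{sp}": row
                for sp, row in alignments.get(pair.arm2_member, {}).items()
            }
            if msa_u and msa_v:
                merged = profile_merge_align(msa_u, msa_v)
            elif msa_u or msa_v:
                merged = dict(msa_u or msa_v)
            else:
                raise ArmrootError(f"no alignments for pair {pair.name!r}")
        if trim_keep_fraction is not None:
            merged, _ = trim_columns(merged, trim_keep_fraction)
        block_len = len(next(iter(merged.values())))
        for sp in included_species:
            rows[sp + "__arm1"].append(
                _pad_block(merged.get(f"{pair.arm1_member}::{sp}"), block_len)
            )
            rows[sp + "__arm2"].append(
                _pad_block(merged.get(f"{pair.arm2_member}::{sp}"), block_len)
            )
        partitions.append((pair.name, pos, pos + block_len - 1))
        pos += block_len
    joined = {name: "".join(parts) for name, parts in rows.items()}
    for name, row in joined.items():
        if set(row) == {"-"}:
            raise ArmrootError(
                f"pseudo-taxon {name!r} is all-gap; arm-coverage filter "
                "violated upstream"
            )
    return ArmSupermatrix(
        rows=joined, partitions=partitions, included_species=list(included_species)
    )


def build_full_concatenation(alignments, species, trim_keep_fraction=None):
    """Plain one-row-per-species concatenation of subunit alignments
    (optionally trimmed per block); blocks in ``alignments`` order."""
    rows = {sp: [] for sp in species}
    partitions = []
    pos = 1
    for subunit, msa in alignments.items():
        if not msa:
            raise ArmrootError(f"alignment for subunit {subunit!r} is empty")
        block = dict(msa)
        if trim_keep_fraction is not None:
            block, _ = trim_columns(block, trim_keep_fraction)
        block_len = len(next(iter(block.values())))
        for sp in species:
            rows[sp].append(_pad_block(block.get(sp), block_len))
        partitions.append((subunit, pos, pos + block_len - 1))
        pos += block_len
    return Supermatrix(
        rows={sp: "".join(parts) for sp, parts in rows.items()},
        partitions=partitions,
    )
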