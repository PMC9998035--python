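"""Rigid-body superposition of paralogous subunit chains (Kabsch) and RMSD.

The optimal proper rotation is obtained from the SVD of the coordinate
cross-covariance matrix with the usual sign correction on the smallest
singular component, so reflections are never returned — protein chains are
chiral.  RMSD is unweighted over all supplied Cα pairs, with no trimming
or outlier rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import ArmrootError


@dataclass
class CoordSet:
    """Ordered Cα trace of one chain: coordinates (Å), residue numbers
    (1-based, as in the source PDB), chain id, one-letter sequence."""

    coords: object
    residue_ids: list
    chain_id: str = "A"
    sequence: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ArmrootError("coordinates must be an N x 3 array")
        if not np.all(np.isfinite(self.coords)):
            raise ArmrootError("non-finite coordinates")
        if len(self.residue_ids) != len(self.coords):
            raise ArmrootError("residue ids and coordinates differ in length")
        if self.sequence and len(self.sequence) != len(self.coords):
            raise ArmrootError("sequence and coordinates differ in length")

    def __len__(self):
        return len(self.coords)


@dataclass
class SuperpositionResult:
    """Proper rotation R (applied to the mobile set), translation t, and the
    minimised RMSD: ``mobile @ R.T + t`` superposes onto the reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def __post_init__(self):
        r = np.asarray(self.rotation)
        if np.linalg.norm(r.T @ r - np.eye(3)) > 1e-8:
            raise ArmrootError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ArmrootError("rotation is a reflection")

    def apply(self, coords):
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch_superpose(reference, mobile):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Both arguments are N x 3 arrays (or CoordSets) with established
    one-to-one correspondence, N >= 3 and not collinear.
    """
    a = np.asarray(reference.coords if isinstance(reference, CoordSet) else reference, float)
    b = np.asarray(mobile.coords if isinstance(mobile, CoordSet) else mobile, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ArmrootError("coordinate sets must be equal-shape N x 3 arrays")
    n = len(a)
    if n < 3:
        raise ArmrootError(f"superposition needs >= 3 point pairs, got {n}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # Collinear (rank < 2) sets leave a rotation degree of freedom undetermined.
    if np.linalg.matrix_rank(a0, tol=1e-9) < 2 or np.linalg.matrix_rank(b0, tol=1e-9) < 2:
        raise ArmrootError("degenerate (collinear) coordinate set")
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ca - rotation @ cb
    diff = b0 @ rotation.T - a0
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return SuperpositionResult(rotation=rotation, translation=translation,
                               rmsd=rmsd, n_pairs=n)


_aligner = None


def _global_aligner():
    global _aligner
    if _aligner is None:
        al = Align.PairwiseAligner()
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -11
        al.extend_gap_score = -1
        al.mode = "global"
        _aligner = al
    return _aligner


def pair_correspondence(coords_a, seq_a, coords_b, seq_b, mode="sequence_align"):
    """Residue index pairs relating two chains.

    ``sequence_align`` derives the correspondence from the gap-free columns
    of a global protein alignment of the two sequences; ``one_to_one``
    simply pairs positions and requires equal lengths.
    """
    if len(seq_a) != len(coords_a) or len(seq_b) != len(coords_b):
        raise ArmrootError("sequence length does not match coordinate count")
    if mode == "one_to_one":
        if len(seq_a) != len(seq_b):
            raise ArmrootError("one_to_one correspondence requires equal lengths")
        pairs = list(zip(range(len(seq_a)), range(len(seq_b))))
    elif mode == "sequence_align":
        aln = _global_aligner().align(seq_a, seq_b)[0]
        idx = np.asarray(aln.indices)  # 2 x L, -1 in gap columns
        pairs = [(int(i), int(j)) for i, j in zip(idx[0], idx[1]) if i >= 0 and j >= 0]
    else:
        raise ArmrootError(f"unknown correspondence mode {mode!r}")
    if not pairs:
        raise ArmrootError("empty correspondence between chains")
    return pairs


def paralog_rmsd_table(structure, paralog_map, mode="sequence_align"):
    """Superpose each paralog pair of a structure and tabulate RMSDs.

    ``structure`` maps subunit name -> CoordSet (with sequence).  Pairs
    whose correspondence drops below 3 residues are reported as failed
    rather than omitted.  Returns a pandas DataFrame with one row per pair.
    """
    import pandas as pd

    rows = []
    for pair in paralog_map.pairs:
        u, v = pair.arm1_member, pair.arm2_member
        for name in (u, v):
            if name not in structure:
                raise ArmrootError(f"subunit {name!r} missing from structure")
        cu, cv = structure[u], structure[v]
        try:
            pairs = pair_correspondence(cu.coords, cu.sequence, cv.coords,
                                        cv.sequence, mode=mode)
            res = kabsch_superpose(cu.coords[[i for i, _ in pairs]],
                                   cv.coords[[j for _, j in pairs]])
            rows.append((u, v, res.rmsd, res.n_pairs, "ok"))
        except ArmrootError as exc:
            rows.append((u, v, float("nan"), 0, f"failed: {exc}"))
    return pd.DataFrame(
        rows, columns=["subunit_a", "subunit_b", "rmsd", "n_pairs", "status"]
    )
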