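"""Merge contract, gap-threshold trimming, and supermatrix assembly."""

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from armroot.io import ArmrootError, read_fasta
from armroot.profiles import PresenceMatrix
from armroot.supermatrix import (
    DEFAULT_PARALOG_MAP,
    ParalogMap,
    ParalogPair,
    _check_msa,
    _column_scores,
    build_arm_supermatrix,
    build_full_concatenation,
    profile_merge_align,
    select_species_by_arm_coverage,
    trim_columns,
)

from conftest import random_msa

ALPHA = "ARNDCQEGHILKMFPSTWYV"
_b62 = substitution_matrices.load("BLOSUM62")
SUB = np.array([[_b62[x][y] for y in ALPHA] for x in ALPHA], float)
GO, GE = -11.0, -1.0


def recover_submsa(merged, keys):
    rows = {k: merged[k] for k in keys}
    arr = np.array([list(s) for s in rows.values()])
    keep = ~(arr == "-").all(axis=0)
    return {k: "".join(np.array(list(v))[keep]) for k, v in rows.items()}


def ops_from_merged(merged, msa_a, msa_b):
    la, lb = _check_msa(msa_a, "a"), _check_msa(msa_b, "b")
    a_rows, b_rows = list(msa_a), list(msa_b)
    ops, ia, ib = [], 0, 0
    for j in range(len(next(iter(merged.values())))):
        a_gap = all(merged[r][j] == "-" for r in a_rows)
        b_gap = all(merged[r][j] == "-" for r in b_rows)
        if not a_gap and not b_gap:
            ops.append(("M", ia, ib)); ia += 1; ib += 1
        elif not a_gap:
            ops.append(("X", ia, None)); ia += 1
        else:
            ops.append(("Y", None, ib)); ib += 1
    assert ia == la and ib == lb
    return ops


def score_ops(ops, scores):
    total, last = 0.0, None
    for op, ia, ib in ops:
        if op == "M":
            total += scores[ia, ib]
        else:
            total += GE if last == op else GO
        last = op
    return total


def exhaustive_best_score(la, lb, scores):
    """Enumerate every monotone column alignment (no DP) and keep the best."""
    best = [-np.inf]

    def rec(ia, ib, last, acc):
        if ia == la and ib == lb:
            best[0] = max(best[0], acc)
            return
        if ia < la and ib < lb:
            rec(ia + 1, ib + 1, "M", acc + scores[ia, ib])
        if ia < la:
            rec(ia + 1, ib, "X", acc + (GE if last == "X" else GO))
        if ib < lb:
            rec(ia, ib + 1, "Y", acc + (GE if last == "Y" else GO))

    rec(0, 0, None, 0.0)
    return best[0]


class TestProfileMergeAlign:
    def test_identical_single_sequences(self):
        merged = profile_merge_align({"a": "MKV"}, {"b": "MKV"})
        assert merged == {"a": "MKV", "b": "MKV"}

    def test_submsa_preservation_random_instances(self, rng):
        for _ in range(300):
            msa_a = random_msa(rng, int(rng.integers(1, 5)),
                               int(rng.integers(1, 14)), "a")
            msa_b = random_msa(rng, int(rng.integers(1, 5)),
                               int(rng.integers(1, 14)), "b")
            merged = profile_merge_align(msa_a, msa_b)
            assert recover_submsa(merged, list(msa_a)) == msa_a
            assert recover_submsa(merged, list(msa_b)) == msa_b

    def test_column_pairing_matches_exhaustive_oracle(self, rng):
        for trial in range(30):
            la, lb = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            msa_a = random_msa(rng, int(rng.integers(1, 4)), la, "a")
            msa_b = random_msa(rng, int(rng.integers(1, 4)), lb, "b")
            scores = _column_scores(msa_a, la, msa_b, lb, SUB, ALPHA)
            merged = profile_merge_align(msa_a, msa_b)
            dp = score_ops(ops_from_merged(merged, msa_a, msa_b), scores)
            assert dp == pytest.approx(exhaustive_best_score(la, lb, scores))

    def test_overlapping_row_ids_rejected(self):
        with pytest.raises(ArmrootError, match="both alignments"):
            profile_merge_align({"x": "MK"}, {"x": "MK"})

    def test_empty_alignment_rejected(self):
        with pytest.raises(ArmrootError, match="empty"):
            profile_merge_align({}, {"b": "MK"})


class TestTrimColumns:
    def test_reference_gap_threshold_boundary(self):
        # 30 rows: a 1-residue column (3.3%) falls below gt=0.05, a
        # 2-residue column (6.7%) stays
        rows = {f"s{i}": ("A" if i < 1 else "-") + ("C" if i < 2 else "-")
                for i in range(30)}
        trimmed, kept = trim_columns(rows, 0.05)
        assert kept == [1]
        assert trimmed["s0"] == "C"

    def test_vendored_reference_fixture_byte_identical(self, tmp_path):
        from pathlib import Path

        data = Path(__file__).parent / "data"
        msa = read_fasta(data / "synthetic_trim_input.fasta")
        trimmed, _ = trim_columns(msa, 0.05)
        expected = read_fasta(data / "synthetic_trim_expected_gt05.fasta")
        assert trimmed == expected

    def test_tiny_threshold_keeps_all(self, rng):
        msa = random_msa(rng, 5, 20, "r")
        trimmed, kept = trim_columns(msa, 1e-9)
        assert trimmed == msa and len(kept) == 20

    def test_threshold_one_keeps_only_gapfree(self):
        msa = {"a": "MK-V", "b": "MKL-"}
        trimmed, kept = trim_columns(msa, 1.0)
        assert kept == [0, 1]

    def test_idempotent(self, rng):
        msa = random_msa(rng, 6, 30, "r", gap_p=0.5, no_allgap_columns=False)
        once, _ = trim_columns(msa, 0.4)
        twice, _ = trim_columns(once, 0.4)
        assert once == twice

    def test_all_columns_removed_is_diagnostic_error(self):
        msa = {f"s{i}": "-A" if i == 0 else "--" for i in range(40)}
        with pytest.raises(ArmrootError, match="removed all"):
            trim_columns(msa, 0.5)


def presence_from_counts(arm1_counts, arm2_counts, pmap):
    """Matrix where species i has the first k subunits of each arm."""
    species = [f"sp{i}" for i in range(len(arm1_counts))]
    cols = ["Ndc80"] + pmap.arm1 + pmap.arm2
    data = pd.DataFrame(0, index=species, columns=cols, dtype="int8")
    data["Ndc80"] = 1
    for i, (c1, c2) in enumerate(zip(arm1_counts, arm2_counts)):
        for s in pmap.arm1[:c1]:
            data.loc[species[i], s] = 1
        for s in pmap.arm2[:c2]:
            data.loc[species[i], s] = 1
    return PresenceMatrix(data, {"Dam1-C": pmap.arm1 + pmap.arm2})


class TestArmCoverageFilter:
    def test_one_sided_species_excluded(self):
        m = presence_from_counts([4], [0], DEFAULT_PARALOG_MAP)
        assert select_species_by_arm_coverage(m, DEFAULT_PARALOG_MAP, 2) == []

    def test_exactly_two_per_arm_included(self):
        m = presence_from_counts([2], [2], DEFAULT_PARALOG_MAP)
        assert select_species_by_arm_coverage(m, DEFAULT_PARALOG_MAP, 2) == ["sp0"]

    def test_matches_bruteforce_counting(self, rng):
        pmap = DEFAULT_PARALOG_MAP
        counts1 = list(rng.integers(0, 5, 20))
        counts2 = list(rng.integers(0, 5, 20))
        m = presence_from_counts(counts1, counts2, pmap)
        got = select_species_by_arm_coverage(m, pmap, 2)
        expect = [f"sp{i}" for i in range(20)
                  if counts1[i] >= 2 and counts2[i] >= 2]
        assert got == expect


class TestBuildSupermatrices:
    def _alignments(self, species, pmap, length=6):
        rng = np.random.default_rng(1)
        out = {}
        for sub in pmap.arm1 + pmap.arm2:
            out[sub] = {sp: "".join(rng.choice(list(ALPHA), length))
                        for sp in species}
        return out

    def test_two_species_two_pairs_shape(self):
        pmap = ParalogMap(pairs=[ParalogPair("U-V", "U", "V"),
                                 ParalogPair("W-X", "W", "X")])
        aln = self._alignments(["sp1", "sp2"], pmap)
        sm = build_arm_supermatrix(aln, pmap, ["sp1", "sp2"],
                                   trim_keep_fraction=0.05)
        assert len(sm.rows) == 4
        assert len(sm.partitions) == 2
        assert sm.length == sum(e - s + 1 for _, s, e in sm.partitions)
        assert set(sm.rows) == {"sp1__arm1", "sp1__arm2",
                                "sp2__arm1", "sp2__arm2"}

    def test_missing_subunit_gap_padded(self):
        pmap = ParalogMap(pairs=[ParalogPair("U-V", "U", "V"),
                                 ParalogPair("W-X", "W", "X")])
        aln = self._alignments(["sp1", "sp2"], pmap)
        del aln["W"]["sp2"]
        sm = build_arm_supermatrix(aln, pmap, ["sp1", "sp2"],
                                   trim_keep_fraction=None)
        name, start, end = sm.partitions[1]
        block = sm.rows["sp2__arm1"][start - 1:end]
        assert set(block) == {"-"}
        assert len(sm.rows["sp2__arm1"]) == sm.length

    def test_all_gap_pseudo_taxon_rejected(self):
        pmap = ParalogMap(pairs=[ParalogPair("U-V", "U", "V")])
        aln = self._alignments(["sp1"], pmap)
        aln["U"] = {"sp1": aln["U"]["sp1"]}
        aln["V"] = {}
        # sp2 has no data at all -> its rows would be all-gap
        with pytest.raises(ArmrootError, match="all-gap"):
            build_arm_supermatrix(
                {"U": aln["U"], "V": {}}, pmap, ["sp1", "sp2"],
                trim_keep_fraction=None,
            )

    def test_full_concatenation_single_subunit_identity(self):
        aln = {"U": {"sp1": "MKV", "sp2": "MLV"}}
        sm = build_full_concatenation(aln, ["sp1", "sp2"])
        assert sm.rows == aln["U"]
        assert sm.partitions == [("U", 1, 3)]

    def test_full_concatenation_matches_manual_fixture(self):
        aln = {
            "U": {"sp1": "MK", "sp2": "ML", "sp3": "MI"},
            "V": {"sp1": "AW", "sp3": "AF"},
        }
        sm = build_full_concatenation(aln, ["sp1", "sp2", "sp3"])
        assert sm.rows == {"sp1": "MKAW", "sp2": "ML--", "sp3": "MIAF"}
        assert sm.partitions == [("U", 1, 2), ("V", 3, 4)]
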