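"""Likelihoods, tree search, and RELL/KH/AU topology tests."""

import itertools
import math

import numpy as np
import pytest

from armroot.io import ArmrootError, read_newick
from armroot.phylo import (
    AA_ORDER,
    PhyloModel,
    SiteLogLikTable,
    au_test,
    discrete_gamma_rates,
    displays_constraint,
    empirical_frequencies,
    kh_test,
    nj_tree,
    nni_search,
    optimize_branch_lengths,
    rell_bootstrap,
    root_split_report,
    site_loglik,
    site_loglik_table,
    tree_bipartitions,
)

from conftest import AA, simulate_on_tree


def brute_force_site_loglik(tree, alignment, model):
    """Sum over all internal-state assignments (no pruning)."""
    from armroot.phylo import encode_alignment

    coded = encode_alignment(alignment)
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    n_sites = len(next(iter(coded.values())))
    out = np.zeros(n_sites)
    for site in range(n_sites):
        total_classes = []
        for rate, w in zip(model.rates, model.rate_weights):
            total = 0.0
            for assign in itertools.product(range(20), repeat=len(internals)):
                amap = dict(zip(internals, assign))
                p = model.frequencies[amap[tree.seed_node]]
                for node in nodes:
                    if node is tree.seed_node:
                        continue
                    pm = model.transition_matrix(node.edge.length or 0.0, rate)
                    parent = amap[node.parent_node]
                    if node.is_leaf():
                        c = coded[node.taxon.label][site]
                        p *= 1.0 if c < 0 else pm[parent, c]
                    else:
                        p *= pm[parent, amap[node]]
                total += p
            total_classes.append(w * total)
        out[site] = math.log(sum(total_classes))
    return out


class TestModel:
    @pytest.mark.parametrize("name", ["POISSON", "LG"])
    def test_transition_matrix_is_stochastic_and_stationary(self, name):
        m = PhyloModel(name)
        p = m.transition_matrix(0.7)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(m.frequencies @ p, m.frequencies, atol=1e-12)
        assert np.allclose(m.transition_matrix(0.0), np.eye(20), atol=1e-10)

    def test_rate_matrix_normalised_to_one_substitution(self):
        for name in ("POISSON", "LG"):
            m = PhyloModel(name)
            mu = -(m.frequencies * np.diag(m.rate_matrix)).sum()
            assert mu == pytest.approx(1.0)

    def test_discrete_gamma_rates_mean_one(self):
        for alpha in (0.2, 1.0, 5.0):
            rates = discrete_gamma_rates(alpha, 4)
            assert np.mean(rates) == pytest.approx(1.0, abs=1e-10)
            assert all(a < b for a, b in zip(rates, rates[1:]))

    def test_empirical_frequencies_sum_to_one(self, rng):
        aln = {"a": "".join(rng.choice(AA, 50)), "b": "".join(rng.choice(AA, 50))}
        f = empirical_frequencies(aln)
        assert f.sum() == pytest.approx(1.0)


class TestSiteLoglik:
    def test_single_leaf_equilibrium_draw(self):
        t = read_newick("A;", rooted=True)
        ll = site_loglik(t, {"A": "A"}, PhyloModel("POISSON"))
        assert ll[0] == pytest.approx(math.log(1 / 20))

    def test_zero_branch_identical_sites(self):
        t = read_newick("(A:0.0,B:0.0);", rooted=True)
        m = PhyloModel("LG")
        ll = site_loglik(t, {"A": "W", "B": "W"}, m)
        w_index = AA_ORDER.index("W")
        assert ll[0] == pytest.approx(math.log(m.frequencies[w_index]), abs=1e-9)

    @pytest.mark.parametrize(
        "model",
        [
            PhyloModel("POISSON"),
            PhyloModel("LG"),
            PhyloModel("LG", rate_model="GAMMA", gamma_classes=2,
                       gamma_alpha=0.6),
        ],
        ids=["poisson", "lg", "lg_gamma"],
    )
    def test_matches_bruteforce_on_quartets(self, model, quartet_tree, rng):
        for _ in range(2):
            aln = {n: "".join(rng.choice(AA, 10)) for n in "ABCD"}
            aln["B"] = aln["B"][:4] + "-X" + aln["B"][6:]  # missing data
            mine = site_loglik(quartet_tree, aln, model)
            oracle = brute_force_site_loglik(quartet_tree, aln, model)
            assert np.abs(mine - oracle).max() < 1e-10

    def test_total_invariant_under_rerooting(self, rng):
        t = read_newick("((A:0.3,B:0.5):0.2,(C:0.1,D:0.7):0.4);", rooted=True)
        model = PhyloModel("LG")
        aln = {n: "".join(rng.choice(AA, 30)) for n in "ABCD"}
        base = site_loglik(t, aln, model).sum()
        t2 = t.clone(depth=1)
        leaf = next(l for l in t2.leaf_node_iter() if l.taxon.label == "C")
        t2.reroot_at_edge(leaf.edge, length1=0.05, length2=0.05,
                          update_bipartitions=False)
        assert site_loglik(t2, aln, model).sum() == pytest.approx(base, abs=1e-8)

    def test_taxa_mismatch_lists_difference(self, quartet_tree):
        with pytest.raises(ArmrootError, match="alignment-only.*'E'"):
            site_loglik(quartet_tree,
                        {n: "A" for n in "ABCE"}, PhyloModel("POISSON"))


class TestBranchOptimisation:
    def test_two_taxon_matches_closed_form(self, rng):
        n, p_target = 400, 0.25
        a = "".join(rng.choice(AA, n))
        b = list(a)
        for i in rng.choice(n, int(n * p_target), replace=False):
            b[i] = AA[(AA.index(b[i]) + 3) % 20]
        aln = {"A": a, "B": "".join(b)}
        t = read_newick("(A:0.05,B:0.05);", rooted=True)
        optimize_branch_lengths(t, aln, PhyloModel("POISSON"), tol=1e-9)
        total = sum(e.length for e in t.preorder_edge_iter() if e.length)
        p_hat = np.mean([x != y for x, y in zip(aln["A"], aln["B"])])
        closed = -(19 / 20) * math.log(1 - 20 * p_hat / 19)
        assert total == pytest.approx(closed, abs=1e-6)

    def test_zero_difference_data_shrinks_branches(self):
        aln = {"A": "MKVW" * 20, "B": "MKVW" * 20}
        t = read_newick("(A:0.4,B:0.4);", rooted=True)
        optimize_branch_lengths(t, aln, PhyloModel("POISSON"))
        total = sum(e.length for e in t.preorder_edge_iter() if e.length)
        assert total < 1e-6

    def test_loglik_never_decreases(self, quartet_tree, rng):
        model = PhyloModel("POISSON")
        aln = simulate_on_tree(quartet_tree, model, 60,
                               int(rng.integers(2**31)))
        before = site_loglik(quartet_tree, aln, model).sum()
        after = optimize_branch_lengths(quartet_tree, aln, model)
        assert after >= before - 1e-9


class TestTreeSearch:
    def test_quartet_recovery_from_every_start(self, rng):
        model = PhyloModel("POISSON")
        true = read_newick("((A:0.1,B:0.1):0.3,(C:0.1,D:0.1):0.3);",
                           rooted=True)
        aln = simulate_on_tree(true, model, 300, 11)
        want = tree_bipartitions(true)
        starts = [
            "((A:0.2,B:0.2):0.2,(C:0.2,D:0.2):0.2);",
            "((A:0.2,C:0.2):0.2,(B:0.2,D:0.2):0.2);",
            "((A:0.2,D:0.2):0.2,(B:0.2,C:0.2):0.2);",
        ]
        for s in starts:
            best, ll = nni_search(read_newick(s, rooted=True), aln, model)
            assert tree_bipartitions(best) == want

    def test_nj_then_nni_never_worse_than_start(self, rng):
        model = PhyloModel("POISSON")
        true = read_newick(
            "(((A:0.1,B:0.1):0.2,(C:0.1,D:0.1):0.2):0.1,(E:0.1,F:0.1):0.3);",
            rooted=True,
        )
        aln = simulate_on_tree(true, model, 150, 3)
        start = nj_tree(aln, model)
        from armroot.phylo import _rooted_at_leaf

        start_ll = optimize_branch_lengths(
            _rooted_at_leaf(start), aln, model, tol=1e-3, max_rounds=2
        )
        _, final_ll = nni_search(start, aln, model)
        assert final_ll >= start_ll - 1e-9

    def test_constraint_respected_and_incompatibility_rejected(self, rng):
        model = PhyloModel("POISSON")
        true = read_newick("((A:0.1,B:0.1):0.3,(C:0.1,D:0.1):0.3);",
                           rooted=True)
        aln = simulate_on_tree(true, model, 200, 7)
        constraint = read_newick("((A,B),(C,D));")
        best, _ = nni_search(read_newick(
            "((A:0.2,B:0.2):0.2,(C:0.2,D:0.2):0.2);", rooted=True),
            aln, model, constraint=constraint)
        assert displays_constraint(best, constraint)
        bad_start = read_newick("((A:0.2,C:0.2):0.2,(B:0.2,D:0.2):0.2);",
                                rooted=True)
        with pytest.raises(ArmrootError, match="constraint"):
            nni_search(bad_start, aln, model, constraint=constraint)

    def test_constraint_taxa_must_be_in_tree(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);", rooted=True)
        c = read_newick("((A,E),(B,C));")
        with pytest.raises(ArmrootError, match="missing"):
            displays_constraint(t, c)


class TestRellAndTopologyTests:
    def _table(self, rng, n_sites=100, shift=0.0):
        base = rng.normal(-3, 1, n_sites)
        return SiteLogLikTable(
            ["t0", "t1"],
            np.vstack([base, base + rng.normal(shift, 0.3, n_sites)]),
        )

    def test_rell_reproducible_under_seed(self, rng):
        tab = self._table(rng)
        a = rell_bootstrap(tab, 200, seed=9)
        b = rell_bootstrap(tab, 200, seed=9)
        assert np.array_equal(a, b)
        assert a.shape == (2, 200)

    def test_rell_scale_changes_resample_size(self, rng):
        tab = self._table(rng)
        small = rell_bootstrap(tab, 500, seed=1, scale=0.5)
        # totals at scale 0.5 average about half the full-data total
        assert abs(small.mean() - 0.5 * tab.totals.mean()) < abs(
            tab.totals.mean()) * 0.1

    def test_identical_site_vectors_give_half_p_au(self, rng):
        l = rng.normal(-3, 1, 150)
        tab = SiteLogLikTable(["a", "b"], np.vstack([l, l]))
        res = au_test(tab, n_reps=2000, seed=0)
        assert np.allclose(res.p_values, 0.5, atol=0.05)
        assert kh_test(tab, n_reps=500, seed=0).tolist() == [1.0, 1.0]

    def test_dominant_topology_wins(self, rng):
        l = rng.normal(-3, 1, 100)
        tab = SiteLogLikTable(["good", "bad"], np.vstack([l, l - 0.5]))
        res = au_test(tab, n_reps=1000, seed=0)
        assert res.p_values[1] == 0.0 and res.degenerate[1]
        assert res.p_values[0] > 0.5
        kh = kh_test(tab, n_reps=1000, seed=0)
        assert kh[0] > 0.9 and kh[1] < 0.01


class TestRootSplit:
    def _arm_alignment(self, rng, good=True):
        from armroot.simulate import (DuplicationHistory,
                                      simulate_complex_sequences,
                                      simulate_species_tree)
        from armroot.supermatrix import DEFAULT_PARALOG_MAP, build_arm_supermatrix
        from conftest import scale_tree

        t = scale_tree(simulate_species_tree(n_species=5, seed=17), 0.4)
        aln, _ = simulate_complex_sequences(
            t, DuplicationHistory(arm_divergence=1.0), seq_length=150, seed=17
        )
        species = [l.taxon.label for l in t.leaf_node_iter()]
        sm = build_arm_supermatrix(aln, DEFAULT_PARALOG_MAP, species, 0.05)
        return sm

    def test_planted_split_found_rooted_and_supported(self, rng):
        sm = self._arm_alignment(rng)
        model = PhyloModel("POISSON")
        tree = nj_tree(sm.rows, model)
        rep = root_split_report(tree, alignment=sm.rows, model=model,
                                n_reps=300, seed=0)
        assert rep.bipartition_present
        assert rep.support > 0.9
        roots = rep.rooted_tree.seed_node.child_nodes()
        sides = [{l.taxon.label for l in c.leaf_iter()} for c in roots]
        suffixes = [{s.rsplit("__", 1)[1] for s in side} for side in sides]
        assert suffixes == [{"arm1"}, {"arm2"}] or suffixes == [{"arm2"}, {"arm1"}]

    def test_shuffled_labels_have_no_split(self, rng):
        sm = self._arm_alignment(rng)
        rows = dict(sm.rows)
        # swap arm labels for one species: bipartition must disappear
        a = rows.pop("S1__arm1")
        b = rows.pop("S1__arm2")
        rows["S1__arm1"], rows["S1__arm2"] = b, a
        tree = nj_tree(rows, PhyloModel("POISSON"))
        rep = root_split_report(tree)
        assert not rep.bipartition_present
        assert rep.rooted_tree is None

    def test_minimal_four_leaf_case(self):
        t = read_newick(
            "((X__arm1:0.1,Y__arm1:0.1):0.5,(X__arm2:0.1,Y__arm2:0.1):0.5);",
            rooted=True,
        )
        rep = root_split_report(t)
        assert rep.bipartition_present
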