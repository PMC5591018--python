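"""Distances, neighbor joining (with independent skbio oracle), bootstrap
supports and the generation calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ygc
from ygc.phylogeny import CalibrationParams, calibrate_generations, nonrecurrent_sites

from conftest import make_snv_matrix


class TestPairwiseDistance:
    def test_identical_rows_zero(self):
        m = make_snv_matrix(["a", "b"], ["ACGT", "ACGT"])
        d = ygc.pairwise_distance(m)
        assert d[0, 1] == 0

    def test_single_difference(self):
        m = make_snv_matrix(["a", "b"], ["ACGT", "ACGA"])
        assert ygc.pairwise_distance(m)[0, 1] == 1

    def test_pairwise_deletion_excludes_missing(self):
        m = make_snv_matrix(["a", "b"], ["ACGT", "ACNA"])
        # site 3 missing in b; site 4 differs -> distance 1
        assert ygc.pairwise_distance(m)[0, 1] == 1

    def test_no_joint_sites_errors_unless_allowed(self):
        m = make_snv_matrix(["a", "b"], ["ANN", "NAC"])
        with pytest.raises(ValueError):
            ygc.pairwise_distance(m)
        d = ygc.pairwise_distance(m, allow_undefined=True)
        assert np.isnan(d[0, 1])

    @settings(derandomize=True, max_examples=25)
    @given(st.permutations(list(range(4))))
    def test_sample_order_invariance(self, perm):
        rows = ["ACGTAC", "ACGAAC", "TCGAAC", "TCGTGG"]
        names = ["s1", "s2", "s3", "s4"]
        m1 = make_snv_matrix(names, rows)
        m2 = make_snv_matrix([names[i] for i in perm], [rows[i] for i in perm])
        d1 = ygc.pairwise_distance(m1)
        d2 = ygc.pairwise_distance(m2)
        for a in range(4):
            for b in range(4):
                assert d1[a, b] == d2[perm.index(a), perm.index(b)]


def _additive_distance(tree):
    """Leaf-to-leaf path lengths on a Phylogeny (oracle helper)."""
    names = tree.leaf_names()
    depth = {}
    parent = {}
    for node in tree.preorder():
        parent[node.name] = node.parent.name if node.parent else None
        depth[node.name] = (
            0.0 if node.parent is None else depth[node.parent.name] + (node.length or 0)
        )

    def path_up(name):
        out = []
        while name is not None:
            out.append(name)
            name = parent[name]
        return out

    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi = path_up(names[i])
            pj = set(path_up(names[j]))
            lca = next(x for x in pi if x in pj)
            d[i, j] = d[j, i] = (
                depth[names[i]] + depth[names[j]] - 2 * depth[lca]
            )
    return d, names


class TestNJ:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 7, 11], [7, 0, 10], [11, 10, 0]], float)
        t = ygc.nj_tree(d, ["A", "B", "C"], outgroup="C")
        # pendant lengths solve the 3-point equations:
        # lA = (dAB + dAC - dBC)/2 = 4, lB = 3, lC = 7
        got = {l.name: l.length for l in t.leaves()}
        assert got["A"] == pytest.approx(4)
        assert got["B"] == pytest.approx(3)
        # C's pendant edge is split in half by the root
        assert got["C"] == pytest.approx(3.5)

    def test_four_taxa_additive_recovery(self):
        source = ygc.Phylogeny.from_newick("((A:2,B:3)x:1,(C:4,D:5)y:1)r;")
        d, names = _additive_distance(source)
        t = ygc.nj_tree(d, names)
        assert t.bipartitions() == source.bipartitions()
        # recovered tree is additive: its induced distances match the input
        d2, names2 = _additive_distance(t)
        order = [names2.index(n) for n in names]
        assert np.allclose(d2[np.ix_(order, order)], d)

    def test_matches_skbio_on_random_additive_matrices(self):
        """Independent oracle: scikit-bio's NJ yields the same unrooted
        topology on random additive matrices."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(0)
        for rep in range(5):
            n = 7
            p = ygc.SimParams(n_samples=n, n_families=0, total_generations=500, seed=rep)
            source = ygc.simulate_tree(p, rng=rng)
            d, names = _additive_distance(source)
            mine = ygc.nj_tree(d, names)
            sk = skbio_nj(DistanceMatrix(d, names))
            sk_splits = set()
            all_leaves = frozenset(names)
            anchor = min(names)
            for node in sk.non_tips():
                side = frozenset(t.name for t in node.tips())
                if anchor in side:
                    side = all_leaves - side
                if 1 < len(side) < n - 1:
                    sk_splits.add(side)
            assert mine.bipartitions() == sk_splits

    def test_recovers_topology_from_simulated_snvs(self):
        """NJ on substitution-count distances from simulated haploid SNVs
        recovers the generating 6-leaf topology (>=50 SNVs per branch)."""
        source = ygc.Phylogeny.from_newick(
            "(((A:1,B:1)n4:1,(C:1,D:1)n5:1)n2:1,(E:2,F:2)n3:1)n1;"
        )
        for node in source.preorder():  # scale so each branch expects ~60 SNVs
            if node.parent is not None:
                node.length = node.length * 4000.0
        p = ygc.SimParams(
            n_samples=6, n_families=0, xdeg_length_bp=500_000, seed=21
        )
        m, _ = ygc.simulate_xdeg_snvs(source, p)
        assert m.n_sites > 300
        t = ygc.nj_tree(ygc.pairwise_distance(m), m.samples)
        assert t.bipartitions() == source.bipartitions()

    def test_undefined_distances_rejected(self):
        d = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        with pytest.raises(ValueError):
            ygc.nj_tree(d, ["a", "b", "c"])


class TestBootstrap:
    def test_compatible_signal_full_support(self):
        # 4 clean splits repeated over 100 sites -> every bipartition at 100%
        rows = [
            "A" * 50 + "A" * 50,
            "A" * 50 + "C" * 50,
            "G" * 50 + "C" * 50,
            "G" * 50 + "T" * 50,
        ]
        m = make_snv_matrix(["a", "b", "c", "d"], rows)
        t = ygc.bootstrap_support(m, n_reps=50, seed=1)
        supports = [n.support for n in t.preorder()
                    if not n.is_leaf and n.support is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_rep_supports_binary(self):
        rows = ["AAAA", "AACA", "GGCC", "GGCT"]
        m = make_snv_matrix(["a", "b", "c", "d"], rows)
        t = ygc.bootstrap_support(m, n_reps=1, seed=2)
        for n in t.preorder():
            if n.support is not None:
                assert n.support in (0.0, 100.0)

    def test_conflicting_half_signal_intermediate_support(self):
        """Half the sites support ab|cd, half support ac|bd: the focal split
        keeps roughly half support over replicates."""
        rows = [
            "A" * 40 + "A" * 40,
            "A" * 40 + "T" * 40,
            "T" * 40 + "A" * 40,
            "T" * 40 + "T" * 40,
        ]
        m = make_snv_matrix(["a", "b", "c", "d"], rows)
        t = ygc.bootstrap_support(m, n_reps=200, seed=3)
        supports = [n.support for n in t.preorder()
                    if not n.is_leaf and n.support is not None]
        # the resolved split exists but is contested: support well below 100
        assert supports
        assert all(20.0 <= s <= 80.0 for s in supports)

    def test_invalid_reps(self):
        m = make_snv_matrix(["a", "b", "c"], ["AAT", "ATA", "TTT"])
        with pytest.raises(ValueError):
            ygc.bootstrap_support(m, n_reps=0)


class TestCalibration:
    def test_study_scale_arithmetic(self):
        # 3126 SNVs at 3.14e-8 PPPG over 8.1 Mb
        gens = calibrate_generations(CalibrationParams(3126, 3.14e-8, 8.1e6))
        assert gens == pytest.approx(12290.6, abs=0.1)

    def test_zero_snvs(self):
        assert calibrate_generations(CalibrationParams(0, 1e-8, 1e6)) == 0

    def test_inverse_identity(self):
        mu, L, k = 1e-8, 6.06e10, 606
        n = int(round(k * mu * L))
        assert calibrate_generations(
            CalibrationParams(n, mu, L)
        ) == pytest.approx(k)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.integers(min_value=1, max_value=10_000),
        st.floats(min_value=1e-9, max_value=1e-7),
        st.floats(min_value=1e5, max_value=1e8),
    )
    def test_linearity(self, n, mu, L):
        g = calibrate_generations(CalibrationParams(n, mu, L))
        g2 = calibrate_generations(CalibrationParams(2 * n, mu, L))
        assert g2 == pytest.approx(2 * g)
        gh = calibrate_generations(CalibrationParams(n, 2 * mu, L))
        assert gh == pytest.approx(g / 2)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            CalibrationParams(10, 0.0, 1e6)
        with pytest.raises(ValueError):
            CalibrationParams(10, 1e-8, 0.0)


class TestNonrecurrentFilter:
    def test_clade_variants_kept_homoplasies_flagged(self, six_leaf_tree):
        # site 1: derived in clade {A,B}  -> non-recurrent
        # site 2: derived in {A, E}       -> needs two origins
        m = make_snv_matrix(
            ["A", "B", "C", "D", "E", "F"],
            ["GT", "GA", "AA", "AA", "AT", "AA"],
        )
        mask = nonrecurrent_sites(m, six_leaf_tree)
        assert mask.tolist() == [True, False]

    def test_full_pipeline_calibration_on_simulation(self):
        p = ygc.SimParams(
            n_samples=10, n_families=2, total_generations=12265,
            xdeg_length_bp=500_000, seed=13,
        )
        t = ygc.simulate_tree(p)
        m, _ = ygc.simulate_xdeg_snvs(t, p)
        gens, _, mask = ygc.calibrate_from_matrix(m, p.mu_xdeg, p.xdeg_length_bp)
        # infinite-sites simulation: all variants single-origin, calibration
        # recovers the simulated span to Poisson accuracy
        assert mask.all()
        se = np.sqrt(m.n_sites) / (p.mu_xdeg * p.xdeg_length_bp)
        assert abs(gens - 12265) < 3 * se
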