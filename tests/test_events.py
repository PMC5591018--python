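"""Fitch reconstruction, event calling and classification, checked against
an exhaustive minimum-parsimony oracle and the simulator's truth log."""

import itertools

import numpy as np
import pytest

import ygc
from ygc.containers import HET, HOM_ALT, HOM_REF, MISSING
from ygc.events import _BIT

from conftest import brute_force_parsimony, make_pdm


class TestDepthFilter:
    def test_bounds_inclusive(self):
        m = make_pdm(
            ["a", "b", "c", "d"],
            [[HET], [HET], [HET], [HET]],
            depth=np.array([[49], [50], [250], [251]]),
        )
        out = ygc.depth_filter(m, 50, 250)
        assert out.genotypes[:, 0].tolist() == [MISSING, HET, HET, MISSING]

    def test_all_in_range_unchanged(self):
        m = make_pdm(["a", "b"], [[HET, HOM_REF], [HOM_ALT, HET]])
        out = ygc.depth_filter(m)
        assert np.array_equal(out.genotypes, m.genotypes)

    def test_invalid_bounds(self):
        m = make_pdm(["a", "b"], [[HET], [HET]])
        with pytest.raises(ValueError):
            ygc.depth_filter(m, 100, 50)

    def test_tightening_never_adds_events(self, six_leaf_tree):
        """Turning calls to MISSING relaxes the parsimony problem: the
        number of called events is monotone non-increasing."""
        rng = np.random.default_rng(5)
        samples = list("ABCDEF")
        g = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        depth = rng.poisson(60, size=(6, 40)).astype(np.int32)
        m = make_pdm(samples, g, depth=depth)
        counts = []
        for lo, hi in [(0, 10_000), (40, 90), (50, 80), (55, 70)]:
            filt = ygc.depth_filter(m, lo, hi)
            assign = ygc.fitch_bottom_up(six_leaf_tree, filt)
            res = ygc.resolve_top_down(assign, filt, six_leaf_tree)
            counts.append(len(ygc.call_events(six_leaf_tree, res,
                                              suppress_unresolved_root=False)))
        assert counts == sorted(counts, reverse=True)


class TestFitchSets:
    def test_intersection_and_union(self, three_leaf_tree):
        m = make_pdm(["A", "B", "C"], [[HET, HOM_REF], [HET, HET], [HET, HET]])
        assign = ygc.fitch_bottom_up(three_leaf_tree, m)
        n2 = assign.node_index("n2")
        # site 1: children {HET},{HET} -> {HET}
        assert assign.state_sets[n2, 0] == _BIT[HET]
        # site 2: children {HOM_REF},{HET} -> union
        assert assign.state_sets[n2, 1] == (_BIT[HOM_REF] | _BIT[HET])

    def test_missing_leaf_contributes_universe(self, three_leaf_tree):
        m = make_pdm(["A", "B", "C"], [[MISSING], [HOM_ALT], [HOM_ALT]])
        assign = ygc.fitch_bottom_up(three_leaf_tree, m)
        n2 = assign.node_index("n2")
        assert assign.state_sets[n2, 0] == _BIT[HOM_ALT]

    def test_leaf_absent_errors(self, three_leaf_tree):
        m = make_pdm(["A", "B", "X"], [[HET], [HET], [HET]])
        with pytest.raises(ValueError):
            ygc.fitch_bottom_up(three_leaf_tree, m)


def _implied_changes(tree, matrix, outgroup_states=None):
    assign = ygc.fitch_bottom_up(tree, matrix)
    res = ygc.resolve_top_down(assign, matrix, tree, outgroup_states)
    return len(ygc.call_events(tree, res, suppress_unresolved_root=False))


class TestParsimonyOracle:
    @pytest.mark.parametrize(
        "newick",
        [
            "((A:1,B:1)n2:1,C:1)n1;",
            "(((A:1,B:1)n3:1,C:1)n2:1,D:1)n1;",
            "((A:1,B:1)n2:1,(C:1,D:1)n3:1)n1;",
            "((((A:1,B:1)n4:1,C:1)n3:1,D:1)n2:1,E:1)n1;",
        ],
    )
    def test_exhaustive_state_patterns(self, newick):
        """Over every leaf-state combination (incl. missing) on small trees,
        the implied change count equals the brute-force minimum over all
        ancestral labelings."""
        tree = ygc.Phylogeny.from_newick(newick)
        leaves = tree.leaf_names()
        states = (HOM_REF, HET, HOM_ALT, MISSING)
        patterns = list(itertools.product(states, repeat=len(leaves)))
        g = np.array(patterns, dtype=np.int8).T  # leaves x patterns
        m = make_pdm(leaves, g)
        assign = ygc.fitch_bottom_up(tree, m)
        res = ygc.resolve_top_down(assign, m, tree)
        events = ygc.call_events(tree, res, suppress_unresolved_root=False)
        per_site = np.zeros(len(patterns), dtype=int)
        site_of = {int(p): i for i, p in enumerate(m.positions)}
        for e in events:
            per_site[site_of[e.site]] += 1
        for k, pattern in enumerate(patterns):
            expected = brute_force_parsimony(tree, dict(zip(leaves, pattern)))
            assert per_site[k] == expected, f"pattern {pattern}"

    def test_six_leaf_random_patterns(self, six_leaf_tree):
        rng = np.random.default_rng(11)
        leaves = six_leaf_tree.leaf_names()
        g = rng.integers(-1, 3, size=(6, 60)).astype(np.int8)
        m = make_pdm(leaves, g)
        assign = ygc.fitch_bottom_up(six_leaf_tree, m)
        res = ygc.resolve_top_down(assign, m, six_leaf_tree)
        events = ygc.call_events(six_leaf_tree, res, suppress_unresolved_root=False)
        per_site = {int(p): 0 for p in m.positions}
        for e in events:
            per_site[e.site] += 1
        for k, pos in enumerate(m.positions):
            expected = brute_force_parsimony(
                six_leaf_tree, dict(zip(leaves, g[:, k]))
            )
            assert per_site[int(pos)] == expected


class TestResolveTopDown:
    def test_root_takes_outgroup_when_allowed(self, three_leaf_tree):
        m = make_pdm(["A", "B", "C"], [[HOM_REF], [HET], [HOM_REF]])
        assign = ygc.fitch_bottom_up(three_leaf_tree, m)
        res = ygc.resolve_top_down(
            assign, m, three_leaf_tree, outgroup_states={1: HOM_REF}
        )
        assert res.resolved[0, 0] == HOM_REF
        assert res.root_from_outgroup[0]
        assert res.ancestral_allele[0] == "A"  # ref allele of the fixture

    def test_het_root_means_unknown_ancestral(self, three_leaf_tree):
        m = make_pdm(["A", "B", "C"], [[HET], [HET], [HET]])
        assign = ygc.fitch_bottom_up(three_leaf_tree, m)
        res = ygc.resolve_top_down(assign, m, three_leaf_tree)
        assert res.resolved[0, 0] == HET
        assert res.ancestral_allele[0] is None

    def test_outgroup_outside_root_set_ignored(self, three_leaf_tree):
        m = make_pdm(["A", "B", "C"], [[HET], [HET], [HET]])
        assign = ygc.fitch_bottom_up(three_leaf_tree, m)
        res = ygc.resolve_top_down(
            assign, m, three_leaf_tree, outgroup_states={1: HOM_ALT}
        )
        # root set is {HET}; outgroup HOM_ALT cannot be taken, but its
        # homozygous allele still polarizes the site
        assert res.resolved[0, 0] == HET
        assert not res.root_from_outgroup[0]
        assert res.ancestral_allele[0] == "G"


class TestCallAndClassify:
    def test_mutation_and_conversion_worked_fixture(self):
        """3 individuals, 4 positions: one private mutation (HOM->HET on a
        terminal branch) and two conversions (HET->HOM), with an ancestrally
        heterozygous site resolving on two different branches."""
        tree = ygc.Phylogeny.from_newick("((A:1,B:1)n2:1,C:2)n1;")
        #       pos1      pos2      pos3      pos4
        g = [
            [HET, HET, HOM_REF, HOM_REF],      # A
            [HET, HOM_REF, HOM_REF, HOM_REF],  # B: conversion at pos2
            [HOM_REF, HET, HET, HOM_REF],      # C: conversion at pos1,
        ]                                      #    mutation at pos3
        m = make_pdm(
            ["A", "B", "C"],
            g,
            ref=np.array(["A", "C", "A", "T"]),
            alt=np.array(["G", "T", "C", "C"]),
        )
        og = {1: HET, 2: HET, 3: HOM_REF, 4: HOM_REF}
        assign = ygc.fitch_bottom_up(tree, m)
        res = ygc.resolve_top_down(assign, m, tree, outgroup_states=og)
        events = ygc.classify_events(
            ygc.call_events(tree, res),
            res, m, tree, {"A": "famA", "B": "famB", "C": "famC"},
        )
        by = {(e.branch[1], e.site): e for e in events}
        assert len(events) == 3
        conv = by[("B", 2)]
        assert conv.kind == "conversion"
        assert conv.parent_state == "HET" and conv.child_state == "HOM_REF"
        conv2 = by[("C", 1)]
        assert conv2.kind == "conversion"
        # the ancestral state at pos1 is heterozygous: polarity undecidable
        assert conv2.polarity == "ambiguous"
        mut = by[("C", 3)]
        assert mut.kind == "mutation"
        assert mut.privacy == "private"

    def test_conversion_polarity_and_direction_labels(self):
        e = ygc.EventCall(("p", "c"), 10, "conversion", "HET", "HOM_REF")
        tree = ygc.Phylogeny.from_newick("((A:1,B:1)c:1,C:2)p;")
        out = ygc.classify_event(
            e, ("G", "A"), "G", tree, {"A": "f1", "B": "f1", "C": "f2"}
        )
        # survivor G (= ancestral): derived->ancestral, to_GC, transition
        assert out.polarity == "der_to_anc"
        assert out.gc_direction == "to_GC"
        assert out.substitution_class == "transition"
        assert out.privacy == "private"  # A and B share a family

    def test_private_mutation_on_cherry_terminal(self):
        e = ygc.EventCall(("p", "A"), 5, "mutation", "HOM_REF", "HET")
        tree = ygc.Phylogeny.from_newick("((A:1,B:1)p:1,C:2)r;")
        out = ygc.classify_event(
            e, ("C", "T"), "C", tree, {"A": "f1", "B": "f1", "C": "f2"}
        )
        assert out.privacy == "private"
        assert out.gc_direction == "to_AT"
        assert out.substitution_class == "transition"

    def test_bad_allele_rejected(self):
        e = ygc.EventCall(("p", "c"), 1, "mutation", "HOM_REF", "HET")
        tree = ygc.Phylogeny.from_newick("(A:1,B:1)p;")
        with pytest.raises(ValueError):
            ygc.classify_event(e, ("A", "X"), None, tree, {})

    def test_deterministic_output_order(self, six_leaf_tree):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, size=(6, 30)).astype(np.int8)
        m = make_pdm(list("ABCDEF"), g)
        assign = ygc.fitch_bottom_up(six_leaf_tree, m)
        res = ygc.resolve_top_down(assign, m, six_leaf_tree)
        ev = ygc.call_events(six_leaf_tree, res, suppress_unresolved_root=False)
        keys = [(e.site,) for e in ev]
        assert keys == sorted(keys)


class TestSimulationRecovery:
    def test_sparse_recovery_matches_truth(self):
        """In the sparse regime (conversion targets spread over many
        standing het sites) called events match the truth log on branch,
        site and kind for >= 95% of events, aggregated over replicates."""
        rec = tot = 0
        for seed in (1, 2, 3, 4, 5):
            p = ygc.SimParams(
                n_samples=20, n_families=5, total_generations=12265,
                arm_length_bp=100_000, xdeg_length_bp=500_000,
                root_het_density=2e-3, seed=seed,
            )
            t = ygc.simulate_tree(p)
            mat, truth = ygc.simulate_palindrome(t, p)
            og = ygc.truth_outgroup_states(mat, truth)
            assign = ygc.fitch_bottom_up(t, mat)
            res = ygc.resolve_top_down(assign, mat, t, outgroup_states=og)
            called = {
                (e.branch, e.site, e.kind) for e in ygc.call_events(t, res)
            }
            for br, site, kind, _, _, _ in truth.events:
                if kind not in ("mutation", "conversion"):
                    continue
                tot += 1
                rec += (br, site, kind) in called
        assert tot > 250
        assert rec / tot >= 0.95

    def test_event_conservation(self):
        """mutations + conversions + complex = number of branch-site state
        changes in the resolved assignment."""
        p = ygc.SimParams(
            n_samples=12, n_families=3, total_generations=12265,
            arm_length_bp=100_000, xdeg_length_bp=500_000, seed=8,
        )
        t = ygc.simulate_tree(p)
        mat, truth = ygc.simulate_palindrome(t, p)
        assign = ygc.fitch_bottom_up(t, mat)
        res = ygc.resolve_top_down(
            assign, mat, t, ygc.truth_outgroup_states(mat, truth)
        )
        events = ygc.call_events(t, res, suppress_unresolved_root=False)
        idx = {name: i for i, name in enumerate(res.node_order)}
        n_changes = 0
        for parent, child in t.branches():
            pr = res.resolved[idx[parent.name]]
            cr = res.resolved[idx[child.name]]
            n_changes += int(
                np.sum((pr != cr) & (pr != MISSING) & (cr != MISSING))
            )
        assert len(events) == n_changes
        assert all(e.kind in ("mutation", "conversion", "complex") for e in events)


class TestTractMerging:
    def test_adjacent_same_branch_conversions_merge(self):
        evs = [
            ygc.EventCall(("p", "c"), 100, "conversion", "HET", "HOM_REF"),
            ygc.EventCall(("p", "c"), 600, "conversion", "HET", "HOM_REF"),
            ygc.EventCall(("p", "c"), 5000, "conversion", "HET", "HOM_REF"),
            ygc.EventCall(("p", "d"), 700, "conversion", "HET", "HOM_REF"),
            ygc.EventCall(("p", "c"), 650, "mutation", "HOM_REF", "HET"),
        ]
        tracts = ygc.merge_conversion_tracts(evs, max_gap_bp=1000)
        sizes = sorted(len(t) for t in tracts)
        assert sizes == [1, 1, 2]  # (100,600) merge; 5000 and branch-d alone
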