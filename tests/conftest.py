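import itertools

import numpy as np
import pytest

from ygc import HaploidSNVMatrix, Phylogeny, PseudoDiploidMatrix
from ygc.containers import HET, HOM_ALT, HOM_REF, MISSING


@pytest.fixture
def three_leaf_tree():
    return Phylogeny.from_newick("((A:1,B:1)n2:1,C:2)n1;")


@pytest.fixture
def six_leaf_tree():
    return Phylogeny.from_newick(
        "(((A:1,B:1)n4:1,(C:1,D:1)n5:1)n2:1,(E:1,F:2)n3:1)n1;"
    )


def make_pdm(samples, genotypes, positions=None, ref=None, alt=None, depth=None):
    """Small pseudo-diploid matrix builder for hand-written fixtures."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    if positions is None:
        positions = np.arange(1, m + 1)
    if ref is None:
        ref = np.array(["A"] * m)
    if alt is None:
        alt = np.array(["G"] * m)
    if depth is None:
        depth = np.full((n, m), 60, dtype=np.int32)
    return PseudoDiploidMatrix(
        list(samples), np.asarray(positions), np.asarray(ref), np.asarray(alt),
        genotypes, np.asarray(depth),
    )


def make_snv_matrix(samples, rows):
    """rows: list of strings, one per sample, one character per site."""
    alleles = np.array([list(r) for r in rows], dtype="<U1")
    return HaploidSNVMatrix(
        list(samples), np.arange(1, alleles.shape[1] + 1), alleles
    )


def brute_force_parsimony(tree, leaf_states, states=(HOM_REF, HET, HOM_ALT)):
    """Exhaustive minimum over all internal labelings; unit cost per branch
    change. Missing leaves impose no constraint and their branches never
    count. The independent oracle for the Fitch machinery."""
    internal = [n.name for n in tree.preorder() if not n.is_leaf]
    branches = [(p.name, c.name) for p, c in tree.branches()]
    leaf_names = set(tree.leaf_names())
    best = None
    for combo in itertools.product(states, repeat=len(internal)):
        labels = dict(zip(internal, combo))
        for leaf in leaf_names:
            labels[leaf] = leaf_states[leaf]
        score = 0
        for p, c in branches:
            if labels[c] == MISSING or labels[p] == MISSING:
                continue
            if labels[p] != labels[c]:
                score += 1
        if best is None or score < best:
            best = score
    return best
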