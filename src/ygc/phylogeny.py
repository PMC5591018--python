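"""Sample tree from X-degenerate SNVs and generation calibration.

Pairwise distances are raw substitution counts with pairwise deletion of
missing data; the tree is Saitou-Nei neighbor joining with deterministic
lowest-index tie-breaking, rooted on a named outgroup edge or at the midpoint.
The total number of generations spanned by the tree is calibrated as
n_snvs / (mu * callable_bp) from non-recurrent SNVs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import HaploidSNVMatrix
from .tree import Node, Phylogeny

__all__ = [
    "CalibrationParams",
    "pairwise_distance",
    "nj_tree",
    "bootstrap_support",
    "calibrate_generations",
    "nonrecurrent_sites",
    "calibrate_from_matrix",
]

MISSING_ALLELE = "N"


def pairwise_distance(
    matrix: HaploidSNVMatrix, allow_undefined: bool = False
) -> np.ndarray:
    """Substitution-count distance with pairwise deletion.

    d(i, j) = number of sites where both samples are called and their alleles
    differ. A pair with no jointly called site has no defined distance: an
    error, or NaN when ``allow_undefined``.
    """
    alleles = matrix.alleles
    n = len(matrix.samples)
    called = alleles != MISSING_ALLELE
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            joint = called[i] & called[j]
            if not joint.any():
                if not allow_undefined:
                    raise ValueError(
                        f"no jointly called sites for pair "
                        f"({matrix.samples[i]}, {matrix.samples[j]})"
                    )
                d[i, j] = d[j, i] = np.nan
                continue
            d[i, j] = d[j, i] = np.sum(alleles[i, joint] != alleles[j, joint])
    return d


def _nj_unrooted(dist: np.ndarray, names: list[str]) -> Node:
    """Saitou-Nei agglomeration; returns an arbitrarily rooted binary tree
    whose unrooted topology and branch lengths are the NJ tree."""
    nodes = [Node(name) for name in names]
    d = dist.astype(float).copy()
    active = list(range(len(names)))
    counter = [0]

    while len(active) > 2:
        r = len(active)
        sub = d[np.ix_(active, active)]
        R = sub.sum(axis=1)
        q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) among minima for determinism
        flat = np.argwhere(q <= q.min() + 1e-12 * max(1.0, abs(q.min())))
        ai, aj = min((int(a), int(b)) for a, b in flat if a < b)
        i, j = active[ai], active[aj]

        dij = d[i, j]
        li = dij / 2.0 + (R[ai] - R[aj]) / (2.0 * (r - 2))
        lj = dij - li
        counter[0] += 1
        parent = Node(f"nj{counter[0]:03d}")
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])

        # distances to the new node
        new_row = 0.5 * (d[i, active] + d[j, active] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        d[k, active] = new_row
        d[active, k] = new_row
        d[k, k] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [k]

    i, j = active
    root = Node("njroot")
    nodes[i].length = float(d[i, j])
    nodes[j].length = 0.0
    root.add_child(nodes[i])
    root.add_child(nodes[j])
    return root


def nj_tree(
    dist: np.ndarray,
    names: list[str],
    outgroup: str | None = None,
) -> Phylogeny:
    """Neighbor-joining tree, rooted on the outgroup pendant edge (splitting
    its length in half) when an outgroup is named, else at the midpoint."""
    dist = np.asarray(dist, dtype=float)
    n = len(names)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match names")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(dist).any():
        raise ValueError("undefined distances in matrix")
    if outgroup is not None and outgroup not in names:
        raise ValueError(f"outgroup {outgroup!r} not among taxa")

    tree = Phylogeny(_nj_unrooted(dist, list(names)))
    dtree = tree.to_dendropy()
    if outgroup is not None:
        og = None
        for leaf in dtree.leaf_node_iter():
            if leaf.taxon.label == outgroup:
                og = leaf
                break
        half = (og.edge.length or 0.0) / 2.0
        dtree.reroot_at_edge(og.edge, length1=half, length2=half)
    else:
        dtree.reroot_at_midpoint()
    dtree.suppress_unifurcations()
    rooted = Phylogeny.from_dendropy(dtree)
    rooted.relabel_internal()
    return rooted


def bootstrap_support(
    matrix: HaploidSNVMatrix,
    n_reps: int = 500,
    seed: int | np.random.Generator = 0,
    outgroup: str | None = None,
) -> Phylogeny:
    """NJ tree with internal-node bootstrap supports (% of site-resampled
    replicates containing each bipartition)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    main = nj_tree(pairwise_distance(matrix), matrix.samples, outgroup=outgroup)
    counts: dict[frozenset[str], int] = {split: 0 for split in main.bipartitions()}

    for _ in range(n_reps):
        idx = rng.integers(0, matrix.n_sites, size=matrix.n_sites)
        rep = matrix.take_sites(idx)
        rep_tree = nj_tree(pairwise_distance(rep), rep.samples, outgroup=outgroup)
        for split in rep_tree.bipartitions():
            if split in counts:
                counts[split] += 1

    below = main.leaf_sets()
    all_leaves = frozenset(main.leaf_names())
    anchor = min(all_leaves)
    for node in main.preorder():
        if node.is_leaf or node.parent is None:
            continue
        side = below[node.name]
        if anchor in side:
            side = all_leaves - side
        if side in counts:
            node.support = 100.0 * counts[side] / n_reps
    return main


@dataclass
class CalibrationParams:
    """Inputs for the generation-span calibration."""

    n_snvs: int
    mu: float
    callable_bp: float

    def __post_init__(self):
        if self.n_snvs < 0:
            raise ValueError("n_snvs must be >= 0")
        if self.mu <= 0 or self.callable_bp <= 0:
            raise ValueError("mu and callable_bp must be > 0")


def calibrate_generations(cal: CalibrationParams) -> float:
    """Total generations spanned by the tree: n_snvs / (mu * callable_bp)."""
    return cal.n_snvs / (cal.mu * cal.callable_bp)


def nonrecurrent_sites(matrix: HaploidSNVMatrix, tree: Phylogeny) -> np.ndarray:
    """Boolean mask of sites whose allele split is a clade on the tree.

    A site is non-recurrent iff the carriers of one of its alleles form a
    clade (restricted to samples called at the site), i.e. the variant needs
    only one origin on the phylogeny.
    """
    below = tree.leaf_sets()
    clades = {frozenset(s) for s in below.values()}
    mask = np.zeros(matrix.n_sites, dtype=bool)
    sample_set = set(matrix.samples)
    for s in matrix.samples:
        if s not in {l for ls in clades for l in ls}:
            raise ValueError("tree leaves do not cover matrix samples")
    for k in range(matrix.n_sites):
        col = matrix.alleles[:, k]
        called = col != MISSING_ALLELE
        obs = {}
        for i, sample in enumerate(matrix.samples):
            if called[i]:
                obs.setdefault(str(col[i]), set()).add(sample)
        if len(obs) != 2:
            mask[k] = len(obs) == 1  # monomorphic-as-called: trivially one origin
            continue
        carriers = [frozenset(v) for v in obs.values()]
        called_set = {s for s in sample_set if called[matrix.sample_index(s)]}
        ok = False
        for clade in clades:
            restricted = frozenset(clade & called_set)
            if restricted in carriers:
                ok = True
                break
        mask[k] = ok
    return mask


def calibrate_from_matrix(
    matrix: HaploidSNVMatrix,
    mu: float,
    callable_bp: float,
    outgroup: str | None = None,
) -> tuple[float, Phylogeny, np.ndarray]:
    """Build an NJ tree, drop recurrent sites, rebuild once, and calibrate.

    Returns (generations, tree, non-recurrent site mask over original sites).
    """
    tree = nj_tree(pairwise_distance(matrix), matrix.samples, outgroup=outgroup)
    mask = nonrecurrent_sites(matrix, tree)
    if mask.sum() < matrix.n_sites:
        kept = matrix.take_sites(np.flatnonzero(mask))
        if kept.n_sites >= 1:
            try:
                tree = nj_tree(pairwise_distance(kept), kept.samples, outgroup=outgroup)
                mask = np.zeros(matrix.n_sites, dtype=bool)
                mask[np.flatnonzero(nonrecurrent_sites(matrix, tree))] = True
            except ValueError:
                warnings.warn("could not rebuild tree on filtered sites; using first pass")
    n = int(mask.sum())
    gens = calibrate_generations(CalibrationParams(n, mu, callable_bp))
    return gens, tree, mask
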