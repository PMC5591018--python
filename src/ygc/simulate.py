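"""Forward simulator for Y-chromosome palindrome dynamics.

Generates (i) a rooted sample phylogeny with father-son cherry pairs,
(ii) haploid X-degenerate SNVs used for tree building and generation
calibration, (iii) pseudo-diploid palindrome-arm genotypes produced by a
forward model of arm mutation and inter-arm gene conversion, and (iv) Poisson
read-depth tracks for copy-number work. Every stochastic event is logged in a
:class:`~ygc.containers.SimTruth` so inference stages can be scored against
ground truth.

Model sketch
------------
A palindrome arm pair of length L is a vector of pseudo-diploid states.  The
root starts homozygous-ancestral except for a small set of standing
pseudo-heterozygous sites (arm pairs are >99.9% identical, not 100%).  On a
branch spanning t generations:

* mutations arrive ~ Poisson(mu_pal * 2L * t); each flips one arm base at a
  homozygous site, creating a pseudo-het.  The new base is A/T with
  probability b_at (AT-biased mutation), else G/C.
* gene conversions arrive ~ Poisson(gamma * 2L * t); each picks a currently
  heterozygous site uniformly and resolves it to one allele.  The surviving
  allele x is drawn with P(x) proportional to w_gc(x) * w_anc(x), where w_gc
  favours the G/C allele with weight b_gc when the two alleles differ in GC
  class, and w_anc favours the ancestral allele with weight b_anc when the
  ancestral allele is known.  This factorized form reproduces both marginal
  biases.

Rates are quoted per physical base summed over both arms (the convention in
which observed event counts are divided by 2 x arm length), hence the 2L
factors above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    AT_BASES,
    BASES,
    GC_BASES,
    HET,
    HOM_ALT,
    HOM_REF,
    CoverageTrack,
    HaploidSNVMatrix,
    PseudoDiploidMatrix,
    SimTruth,
)
from .tree import Node, Phylogeny

__all__ = [
    "SimParams",
    "simulate_tree",
    "simulate_xdeg_snvs",
    "simulate_palindrome",
    "simulate_depth",
    "replay_leaf_states",
    "truth_outgroup_states",
    "family_map",
]


@dataclass
class SimParams:
    """Study-condition parameters for the synthetic generator.

    Defaults follow the real study design: 62 samples including 17 father-son
    pairs, a tree spanning 12265 generations in total branch length, a haploid
    X-degenerate SNV rate of 3.14e-8 per position per generation (PPPG),
    palindrome mutation/conversion rates of 1.76e-8 / 1.21e-8 PPPG, an AT
    mutation bias of 56:44, a GC conversion bias of 259:417 and an ancestral
    conversion bias of 171:271, 1.4 Mb arms, 8.1 Mb of X-degenerate sequence
    and 30X depth per sequence copy (60X over a two-copy arm pair).
    """

    n_samples: int = 62
    n_families: int = 17
    total_generations: float = 12265.0
    mu_xdeg: float = 3.14e-8
    mu_pal: float = 1.76e-8
    gamma: float = 1.21e-8
    b_at: float = 0.56
    b_gc: float = 259 / 417
    b_anc: float = 171 / 271
    arm_length_bp: int = 1_400_000
    xdeg_length_bp: int = 8_100_000
    depth_per_copy: float = 30.0
    root_het_density: float = 2.5e-4
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_families < 0 or 2 * self.n_families > self.n_samples:
            raise ValueError("n_families must satisfy 0 <= n_families <= n_samples/2")
        for name in ("mu_xdeg", "mu_pal", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("b_at", "b_gc", "b_anc", "root_het_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.arm_length_bp < 1 or self.xdeg_length_bp < 1:
            raise ValueError("sequence lengths must be >= 1")
        if self.total_generations <= 0:
            raise ValueError("total_generations must be > 0")
        if self.depth_per_copy < 0:
            raise ValueError("depth_per_copy must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def family_map(params: SimParams) -> dict[str, str]:
    """Sample -> family/individual identifier (cherry pairs share one id)."""
    fam: dict[str, str] = {}
    for i in range(1, params.n_families + 1):
        fam[f"fam{i:02d}_f"] = f"fam{i:02d}"
        fam[f"fam{i:02d}_s"] = f"fam{i:02d}"
    for i in range(1, params.n_samples - 2 * params.n_families + 1):
        fam[f"ind{i:02d}"] = f"ind{i:02d}"
    return fam


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------


def simulate_tree(params: SimParams, rng: np.random.Generator | None = None) -> Phylogeny:
    """Random coalescent-like topology with father-son cherries.

    Each father-son family forms a cherry whose two terminal branches span
    exactly 1 generation; all remaining branch lengths are exponential draws
    rescaled so the total branch length equals ``total_generations`` (minus
    the fixed cherry generations).
    """
    rng = params.rng() if rng is None else rng
    n_single = params.n_samples - 2 * params.n_families

    units: list[Node] = []
    cherry_leaf_edges: set[int] = set()
    node_counter = [0]

    def new_internal() -> Node:
        node_counter[0] += 1
        return Node(f"n{node_counter[0]:03d}")

    for i in range(1, params.n_families + 1):
        parent = new_internal()
        for tag in ("f", "s"):
            leaf = parent.add_child(Node(f"fam{i:02d}_{tag}", length=1.0))
            cherry_leaf_edges.add(id(leaf))
        units.append(parent)
    for i in range(1, n_single + 1):
        units.append(Node(f"ind{i:02d}"))

    while len(units) > 1:
        i, j = sorted(rng.choice(len(units), size=2, replace=False))
        joint = new_internal()
        joint.add_child(units[i])
        joint.add_child(units[j])
        units = [u for k, u in enumerate(units) if k not in (i, j)]
        units.append(joint)

    tree = Phylogeny(units[0])

    free_edges = [
        n
        for n in tree.preorder()
        if n.parent is not None and id(n) not in cherry_leaf_edges
    ]
    fixed = 2.0 * params.n_families
    budget = params.total_generations - fixed
    if free_edges:
        if budget <= 0:
            raise ValueError(
                "total_generations too small for the requested number of families"
            )
        draws = rng.exponential(1.0, size=len(free_edges))
        draws *= budget / draws.sum()
        for node, t in zip(free_edges, draws):
            node.length = float(t)
    return tree


# ---------------------------------------------------------------------------
# Haploid X-degenerate SNVs
# ---------------------------------------------------------------------------


def _draw_new_base(anc: str, b_at: float, rng: np.random.Generator) -> str:
    """Mutate ``anc`` to a different base, choosing the A/T class with
    probability b_at (falling back to the only non-empty class)."""
    at = [b for b in AT_BASES if b != anc]
    gc = [b for b in GC_BASES if b != anc]
    pool = at if rng.random() < b_at else gc
    return str(rng.choice(pool))


def simulate_xdeg_snvs(
    tree: Phylogeny, params: SimParams, rng: np.random.Generator | None = None
) -> tuple[HaploidSNVMatrix, SimTruth]:
    """Infinite-sites haploid SNVs on the tree's branches.

    Mutation counts per branch are Poisson(mu_xdeg * xdeg_length_bp * t); each
    mutation gets a unique position and the derived allele is carried by every
    leaf below the branch.
    """
    if params.xdeg_length_bp < 1:
        raise ValueError("xdeg_length_bp must be >= 1")
    rng = params.rng() if rng is None else rng

    branches = tree.branches()
    counts = [
        rng.poisson(params.mu_xdeg * params.xdeg_length_bp * (child.length or 0.0))
        for _, child in branches
    ]
    total = int(np.sum(counts))
    if total > params.xdeg_length_bp:
        raise ValueError("more SNVs than X-degenerate positions; increase length")
    positions = rng.choice(params.xdeg_length_bp, size=total, replace=False) + 1

    leaf_names = tree.leaf_names()
    leaf_idx = {name: i for i, name in enumerate(leaf_names)}
    below = tree.leaf_sets()

    truth = SimTruth()
    anc_bases = rng.choice(BASES, size=total)
    alleles = np.repeat(anc_bases[None, :], len(leaf_names), axis=0).astype("<U1")
    k = 0
    for (parent, child), n_mut in zip(branches, counts):
        for _ in range(n_mut):
            pos = int(positions[k])
            anc = str(anc_bases[k])
            der = _draw_new_base(anc, params.b_at, rng)
            rows = [leaf_idx[s] for s in below[child.name]]
            alleles[rows, k] = der
            truth.events.append(((parent.name, child.name), pos, "snv", anc, der, anc))
            k += 1

    order = np.argsort(positions, kind="stable")
    matrix = HaploidSNVMatrix(leaf_names, positions[order], alleles[:, order])
    return matrix, truth


# ---------------------------------------------------------------------------
# Palindrome arm-pair forward model
# ---------------------------------------------------------------------------


def _survivor_weights(
    pair: tuple[str, str], anc: str | None, params: SimParams
) -> np.ndarray:
    """Unnormalized survival weights for the two alleles of a het site."""
    w = np.ones(2)
    a, b = pair
    gc_flags = [x in GC_BASES for x in (a, b)]
    if gc_flags[0] != gc_flags[1]:
        for i, is_gc in enumerate(gc_flags):
            w[i] *= params.b_gc if is_gc else 1.0 - params.b_gc
    if anc is not None and anc in pair:
        for i, x in enumerate((a, b)):
            w[i] *= params.b_anc if x == anc else 1.0 - params.b_anc
    return w


def simulate_palindrome(
    tree: Phylogeny, params: SimParams, rng: np.random.Generator | None = None
) -> tuple[PseudoDiploidMatrix, SimTruth]:
    """Forward-simulate pseudo-diploid palindrome genotypes down the tree.

    Sites are finite with at most one segregating allele pair each (a mutation
    landing on a currently heterozygous site is redrawn). Events within a
    branch occur at sampled times and are applied in time order, so a
    conversion can only target a site that is heterozygous at that moment.
    Emitted sites are those carrying a non-reference allele in at least one
    leaf (a variant caller sees nothing else); truth events at fully reverted
    sites remain in the log.
    """
    rng = params.rng() if rng is None else rng
    L = params.arm_length_bp

    truth = SimTruth()
    # site -> (ref, alt); genotype states per lineage: dict site -> code
    site_pair: dict[int, tuple[str, str]] = {}
    site_anc: dict[int, str | None] = {}

    n_standing = int(round(params.root_het_density * L))
    n_standing = min(n_standing, L)
    root_state: dict[int, int] = {}
    if n_standing:
        standing = rng.choice(L, size=n_standing, replace=False) + 1
        for pos in sorted(int(p) for p in standing):
            ref = str(rng.choice(BASES))
            alt = str(rng.choice([b for b in BASES if b != ref]))
            site_pair[pos] = (ref, alt)
            site_anc[pos] = None  # polarity predates the tree
            root_state[pos] = HET
    truth.root_states = dict(root_state)

    leaf_states: dict[str, dict[int, int]] = {}

    def apply_branch(parent: Node, child: Node, state: dict[int, int]) -> None:
        t = child.length or 0.0
        lam = 2.0 * L * t
        n_mut = rng.poisson(params.mu_pal * lam)
        n_conv = rng.poisson(params.gamma * lam)
        schedule = [("mutation", rng.random()) for _ in range(n_mut)]
        schedule += [("conversion", rng.random()) for _ in range(n_conv)]
        schedule.sort(key=lambda e: e[1])
        branch = (parent.name, child.name)

        for kind, _ in schedule:
            if kind == "mutation":
                for _ in range(100):
                    pos = int(rng.integers(1, L + 1))
                    if state.get(pos, HOM_REF) != HET:
                        break
                else:  # pragma: no cover - saturated arm
                    continue
                current = state.get(pos, HOM_REF)
                if pos not in site_pair:
                    ref = str(rng.choice(BASES))
                    alt = _draw_new_base(ref, params.b_at, rng)
                    site_pair[pos] = (ref, alt)
                    site_anc[pos] = ref
                    frm, to = ref, alt
                else:
                    ref, alt = site_pair[pos]
                    frm, to = (ref, alt) if current == HOM_REF else (alt, ref)
                state[pos] = HET
                truth.events.append((branch, pos, "mutation", frm, to, site_anc[pos]))
            else:
                het_sites = [p for p, g in state.items() if g == HET]
                if not het_sites:
                    continue  # no mismatch for conversion machinery to act on
                pos = int(het_sites[rng.integers(len(het_sites))])
                pair = site_pair[pos]
                w = _survivor_weights(pair, site_anc[pos], params)
                survivor_idx = int(rng.random() < w[1] / w.sum())
                survivor = pair[survivor_idx]
                lost = pair[1 - survivor_idx]
                state[pos] = HOM_REF if survivor == pair[0] else HOM_ALT
                truth.events.append(
                    (branch, pos, "conversion", lost, survivor, site_anc[pos])
                )

    def descend(node: Node, state: dict[int, int]) -> None:
        if node.is_leaf:
            leaf_states[node.name] = state
            return
        for child in node.children:
            child_state = dict(state)
            apply_branch(node, child, child_state)
            descend(child, child_state)

    descend(tree.root, dict(root_state))
    truth.ancestral_allele = dict(site_anc)
    truth.site_pairs = dict(site_pair)

    # Emit sites with a non-reference allele observed in >=1 leaf, plus
    # standing het sites (a caller sees those as pseudo-SNVs too).
    observed: set[int] = set()
    for state in leaf_states.values():
        observed.update(p for p, g in state.items() if g != HOM_REF)
    positions = np.array(sorted(observed), dtype=np.int64)
    pos_idx = {int(p): i for i, p in enumerate(positions)}

    leaf_names = tree.leaf_names()
    genotypes = np.zeros((len(leaf_names), len(positions)), dtype=np.int8)
    for i, name in enumerate(leaf_names):
        for pos, g in leaf_states[name].items():
            if pos in pos_idx:
                genotypes[i, pos_idx[pos]] = g

    depth = rng.poisson(
        2.0 * params.depth_per_copy, size=genotypes.shape
    ).astype(np.int32)
    ref = np.array([site_pair[int(p)][0] for p in positions], dtype="<U1")
    alt = np.array([site_pair[int(p)][1] for p in positions], dtype="<U1")
    matrix = PseudoDiploidMatrix(leaf_names, positions, ref, alt, genotypes, depth)
    return matrix, truth


def replay_leaf_states(tree: Phylogeny, truth: SimTruth) -> dict[str, dict[int, int]]:
    """Independent replay oracle: apply the truth log event-by-event along
    each root-to-leaf path and return the implied leaf states."""
    by_branch: dict[tuple[str, str], list[tuple]] = {}
    for ev in truth.events:
        if ev[2] in ("mutation", "conversion"):
            by_branch.setdefault(ev[0], []).append(ev)

    out: dict[str, dict[int, int]] = {}

    def walk(node: Node, state: dict[int, int], pairs: dict[int, tuple[str, str]]):
        if node.is_leaf:
            out[node.name] = state
            return
        for child in node.children:
            st = dict(state)
            prs = dict(pairs)
            for _, pos, kind, frm, to, _anc in by_branch.get(
                (node.name, child.name), []
            ):
                if kind == "mutation":
                    if pos not in prs:
                        prs[pos] = (frm, to)
                    st[pos] = HET
                else:
                    ref, _ = prs[pos]
                    st[pos] = HOM_REF if to == ref else HOM_ALT
            walk(child, st, prs)

    walk(tree.root, dict(truth.root_states), dict(truth.site_pairs))
    return out


def truth_outgroup_states(
    matrix: PseudoDiploidMatrix, truth: SimTruth
) -> dict[int, int]:
    """Outgroup pseudo-genotypes implied by the truth log: an outgroup
    individual branching below the root carries the root's state at every
    emitted site (HOM_REF wherever no standing het existed)."""
    return {
        int(pos): truth.root_states.get(int(pos), HOM_REF) for pos in matrix.positions
    }


# ---------------------------------------------------------------------------
# Read depth
# ---------------------------------------------------------------------------


def simulate_depth(
    regions: dict[str, tuple[int, int]],
    params: SimParams,
    cn_spec: dict[tuple[str, str], int],
    samples: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[tuple[str, str], CoverageTrack], SimTruth]:
    """Poisson depth tracks: depth ~ Poisson(depth_per_copy * copy number).

    ``regions`` maps region name -> (start, end) 1-based inclusive; ``cn_spec``
    maps (sample, region) -> integer copy number (default 2, the two-copy arm
    baseline, when a pair is absent).
    """
    rng = params.rng() if rng is None else rng
    if samples is None:
        samples = sorted({s for s, _ in cn_spec})
    truth = SimTruth()
    tracks: dict[tuple[str, str], CoverageTrack] = {}
    for sample in samples:
        for region, (start, end) in regions.items():
            cn = cn_spec.get((sample, region), 2)
            if cn < 0:
                raise ValueError("copy number must be >= 0")
            n = end - start + 1
            depth = rng.poisson(params.depth_per_copy * cn, size=n).astype(np.int32)
            tracks[(sample, region)] = CoverageTrack(start, end, depth, name=region)
            truth.cn_segments.append((sample, region, cn))
    return tracks, truth
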