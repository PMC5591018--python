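"""Ancestral pseudo-genotype reconstruction and event calling.

The algorithm is a Fitch-style small parsimony on the three pseudo-diploid
states. Bottom-up, each internal node receives the intersection of its
children's state sets (union when the intersection is empty; a missing leaf
contributes the universal set). Top-down, each node is resolved to its
parent's state when possible, the root preferring the outgroup-consensus
state. Every branch where resolved parent and child states differ is one
event: HOM -> HET is a mutation (one arm base changed), HET -> HOM is a gene
conversion (the arm mismatch was overwritten), HOM -> opposite HOM is labeled
"complex" and excluded from the mutation/conversion tallies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    AT_BASES,
    GC_BASES,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    PURINES,
    STATE_NAMES,
    EventCall,
    PseudoDiploidMatrix,
)
from .tree import Phylogeny

__all__ = [
    "depth_filter",
    "AncestralAssignment",
    "fitch_bottom_up",
    "resolve_top_down",
    "call_events",
    "classify_event",
    "classify_events",
    "merge_conversion_tracts",
]

_BIT = {HOM_REF: 1, HET: 2, HOM_ALT: 4}
_UNIVERSE = 7
# resolution preference (determinism when a state must be picked freely)
_PREFERENCE = (HOM_REF, HET, HOM_ALT)


def depth_filter(
    matrix: PseudoDiploidMatrix, min_depth: int = 50, max_depth: int = 250
) -> PseudoDiploidMatrix:
    """Mask genotypes whose depth falls outside [min_depth, max_depth]
    (bounds inclusive, matching a 'between 50 and 250' filter)."""
    if min_depth > max_depth:
        raise ValueError("min_depth must be <= max_depth")
    out = matrix.copy()
    bad = (out.depth < min_depth) | (out.depth > max_depth)
    out.genotypes[bad] = MISSING
    return out


@dataclass
class AncestralAssignment:
    """Per-node state sets (bitmasks over {HOM_REF, HET, HOM_ALT}) and, after
    top-down resolution, a single resolved state per node per site."""

    node_order: list[str]  # preorder; index 0 is the root
    positions: np.ndarray
    state_sets: np.ndarray  # (n_nodes, n_sites) uint8 bitmask
    resolved: np.ndarray | None = None  # (n_nodes, n_sites) int8, MISSING allowed
    ancestral_allele: list[str | None] | None = None
    root_from_outgroup: np.ndarray | None = None  # (n_sites,) bool

    def node_index(self, name: str) -> int:
        return self.node_order.index(name)


def fitch_bottom_up(tree: Phylogeny, matrix: PseudoDiploidMatrix) -> AncestralAssignment:
    """Bottom-up Fitch pass over all sites at once."""
    order = [n.name for n in tree.preorder()]
    idx = {name: i for i, name in enumerate(order)}
    n_sites = matrix.n_sites
    sets = np.zeros((len(order), n_sites), dtype=np.uint8)

    sample_row = {s: i for i, s in enumerate(matrix.samples)}
    for node in tree.postorder():
        i = idx[node.name]
        if node.is_leaf:
            if node.name not in sample_row:
                raise ValueError(f"leaf {node.name!r} absent from genotype matrix")
            g = matrix.genotypes[sample_row[node.name]]
            row = np.empty(n_sites, dtype=np.uint8)
            row[g == HOM_REF] = _BIT[HOM_REF]
            row[g == HET] = _BIT[HET]
            row[g == HOM_ALT] = _BIT[HOM_ALT]
            row[g == MISSING] = _UNIVERSE
            sets[i] = row
        else:
            if len(node.children) != 2:
                raise ValueError("Fitch pass expects a binary tree")
            a = sets[idx[node.children[0].name]]
            b = sets[idx[node.children[1].name]]
            inter = a & b
            sets[i] = np.where(inter != 0, inter, a | b)

    return AncestralAssignment(order, matrix.positions.copy(), sets)


def _preferred(masks: np.ndarray) -> np.ndarray:
    """Lowest-preference state present in each bitmask."""
    out = np.full(masks.shape, MISSING, dtype=np.int8)
    for state in reversed(_PREFERENCE):
        out[(masks & _BIT[state]) != 0] = state
    return out


def resolve_top_down(
    assign: AncestralAssignment,
    matrix: PseudoDiploidMatrix,
    tree: Phylogeny,
    outgroup_states: dict[int, int] | None = None,
) -> AncestralAssignment:
    """Resolve one state per node per site, and infer the ancestral allele.

    The root takes the outgroup state when that state is in its Fitch set,
    else the first available state in the preference order HOM_REF > HET >
    HOM_ALT. Each descendant takes its parent's state when allowed, else the
    preference order again. Observed leaf states are kept as observed
    (missing leaves stay missing). The per-site ancestral allele is the
    allele of the resolved root state when homozygous, else the outgroup's
    homozygous allele when available, else unknown.
    """
    order = assign.node_order
    idx = {name: i for i, name in enumerate(order)}
    sets = assign.state_sets
    n_sites = sets.shape[1]
    resolved = np.full(sets.shape, MISSING, dtype=np.int8)

    og = np.full(n_sites, MISSING, dtype=np.int8)
    if outgroup_states:
        pos_idx = {int(p): k for k, p in enumerate(assign.positions)}
        for pos, state in outgroup_states.items():
            if int(pos) in pos_idx and state in (_BIT.keys()):
                og[pos_idx[int(pos)]] = state

    root_sets = sets[0]
    root_from_og = np.zeros(n_sites, dtype=bool)
    root_state = _preferred(root_sets)
    for k in range(n_sites):
        s = og[k]
        if s != MISSING and (root_sets[k] & _BIT[int(s)]):
            root_state[k] = s
            root_from_og[k] = True
    resolved[0] = root_state

    sample_row = {s: i for i, s in enumerate(matrix.samples)}
    for node in tree.preorder():
        i = idx[node.name]
        if node.parent is None:
            continue
        p = resolved[idx[node.parent.name]]
        own = sets[i]
        take_parent = np.zeros(n_sites, dtype=bool)
        ok = p != MISSING
        take_parent[ok] = (own[ok] & np.array([_BIT[int(x)] for x in p[ok]], dtype=np.uint8)) != 0
        resolved[i] = np.where(take_parent, p, _preferred(own))
        if node.is_leaf:
            # leaves keep their observed states, including MISSING
            resolved[i] = matrix.genotypes[sample_row[node.name]]

    anc: list[str | None] = []
    for k in range(n_sites):
        ref, alt = matrix.alleles_at(k)
        rs = int(resolved[0, k])
        if rs == HOM_REF:
            anc.append(ref)
        elif rs == HOM_ALT:
            anc.append(alt)
        elif og[k] == HOM_REF:
            anc.append(ref)
        elif og[k] == HOM_ALT:
            anc.append(alt)
        else:
            anc.append(None)

    return AncestralAssignment(
        order,
        assign.positions.copy(),
        sets,
        resolved=resolved,
        ancestral_allele=anc,
        root_from_outgroup=root_from_og,
    )


def call_events(
    tree: Phylogeny,
    assign: AncestralAssignment,
    suppress_unresolved_root: bool = True,
) -> list[EventCall]:
    """One EventCall per (branch, site) where resolved parent != child.

    Events on the root's immediate branches depend on the root state, which
    is arbitrary when no outgroup pinned it; such events are suppressed by
    default (they cannot be polarized between the root's two children).
    Output is ordered by (site, preorder branch).
    """
    if assign.resolved is None:
        raise ValueError("assignment must be resolved (run resolve_top_down)")
    idx = {name: i for i, name in enumerate(assign.node_order)}
    resolved = assign.resolved
    root_children = {c.name for c in tree.root.children}
    events: list[EventCall] = []
    for b, (parent, child) in enumerate(tree.branches()):
        p = resolved[idx[parent.name]]
        c = resolved[idx[child.name]]
        for k in np.flatnonzero((p != c) & (p != MISSING) & (c != MISSING)):
            if (
                suppress_unresolved_root
                and child.name in root_children
                and assign.root_from_outgroup is not None
                and not assign.root_from_outgroup[k]
            ):
                continue
            ps, cs = int(p[k]), int(c[k])
            if ps in (HOM_REF, HOM_ALT) and cs == HET:
                kind = "mutation"
            elif ps == HET and cs in (HOM_REF, HOM_ALT):
                kind = "conversion"
            else:
                kind = "complex"
            events.append(
                EventCall(
                    branch=(parent.name, child.name),
                    site=int(assign.positions[k]),
                    kind=kind,
                    parent_state=STATE_NAMES[ps],
                    child_state=STATE_NAMES[cs],
                )
            )
        # keep per-branch grouping; overall (site, preorder-branch) sort below
    events.sort(key=lambda e: (e.site, _branch_order(tree)[e.branch]))
    return events


def _branch_order(tree: Phylogeny) -> dict[tuple[str, str], int]:
    cached = getattr(tree, "_branch_order", None)
    if cached is None:
        cached = {
            (p.name, c.name): i for i, (p, c) in enumerate(tree.branches())
        }
        tree._branch_order = cached
    return cached


def _is_transition(a: str, b: str) -> bool:
    return (a in PURINES) == (b in PURINES)


def classify_event(
    event: EventCall,
    alleles: tuple[str, str],
    ancestral: str | None,
    tree: Phylogeny,
    families: dict[str, str],
    _leaf_sets: dict[str, frozenset[str]] | None = None,
) -> EventCall:
    """Fill direction labels on an event.

    gc_direction: gained G/C for lost A/T -> to_GC; the reverse -> to_AT;
    within-class changes -> neutral. substitution_class: purine<->purine or
    pyrimidine<->pyrimidine is a transition. privacy: private iff every leaf
    below the branch belongs to one individual or one father-son family.
    polarity (conversions only): surviving allele vs the ancestral allele.
    """
    ref, alt = alleles
    for base in (ref, alt):
        if base not in AT_BASES | GC_BASES:
            raise ValueError(f"allele {base!r} is not one of A/C/G/T")

    parent_state = event.parent_state
    child_state = event.child_state
    if event.kind == "mutation":
        lost = ref if parent_state == "HOM_REF" else alt
        gained = alt if lost == ref else ref
    elif event.kind == "conversion":
        gained = ref if child_state == "HOM_REF" else alt
        lost = alt if gained == ref else ref
    else:  # complex: both arm bases replaced
        gained = ref if child_state == "HOM_REF" else alt
        lost = alt if gained == ref else ref

    if gained in GC_BASES and lost in AT_BASES:
        gc_direction = "to_GC"
    elif gained in AT_BASES and lost in GC_BASES:
        gc_direction = "to_AT"
    else:
        gc_direction = "neutral"

    substitution_class = "transition" if _is_transition(ref, alt) else "transversion"

    below = _leaf_sets if _leaf_sets is not None else tree.leaf_sets()
    leaves = below[event.branch[1]]
    fams = {families.get(leaf, leaf) for leaf in leaves}
    privacy = "private" if len(fams) == 1 else "common"

    polarity = None
    if event.kind == "conversion":
        if ancestral is None or ancestral not in (ref, alt):
            polarity = "ambiguous"
        elif gained == ancestral:
            polarity = "der_to_anc"
        else:
            polarity = "anc_to_der"

    event.gained_allele = gained
    event.lost_allele = lost
    event.gc_direction = gc_direction
    event.substitution_class = substitution_class
    event.privacy = privacy
    event.polarity = polarity
    return event


def classify_events(
    events: list[EventCall],
    assign: AncestralAssignment,
    matrix: PseudoDiploidMatrix,
    tree: Phylogeny,
    families: dict[str, str],
) -> list[EventCall]:
    """Classify a list of called events in place (returns the list)."""
    pos_idx = {int(p): k for k, p in enumerate(assign.positions)}
    below = tree.leaf_sets()
    for ev in events:
        k = pos_idx[ev.site]
        anc = assign.ancestral_allele[k] if assign.ancestral_allele else None
        classify_event(
            ev, matrix.alleles_at(k), anc, tree, families, _leaf_sets=below
        )
    return events


def merge_conversion_tracts(
    events: list[EventCall], max_gap_bp: int = 1000
) -> list[list[EventCall]]:
    """Group same-branch conversions within ``max_gap_bp`` into candidate
    multi-site tracts (the parsimonious single-event reading of adjacent
    conversions). Returns a list of tracts; singletons stay singleton."""
    conv = sorted(
        (e for e in events if e.kind == "conversion"),
        key=lambda e: (e.branch, e.site),
    )
    tracts: list[list[EventCall]] = []
    for ev in conv:
        if (
            tracts
            and tracts[-1][-1].branch == ev.branch
            and ev.site - tracts[-1][-1].site <= max_gap_bp
        ):
            tracts[-1].append(ev)
        else:
            tracts.append([ev])
    return tracts
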