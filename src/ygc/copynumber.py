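"""Read-depth copy-number estimation, father-son concordance, and counting
copy-number changes on the phylogeny.

Copy number is the median depth over a gene divided by the median depth over
a single-copy X-degenerate reference region, rounded half-up. Father-son
pairs are concordant at a gene when their normalized coverages differ by less
than 0.5. The number of copy-number changes a gene underwent on the tree is
the small-parsimony minimum with unit cost per change; for very-high-copy
genes (the TSPY regime, where +/-1 copy is below resolution) leaf values
within one copy of the haplogroup rounded mean are collapsed first.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CoverageTrack
from .tree import Phylogeny

__all__ = [
    "CopyNumberTable",
    "estimate_copy_number",
    "cn_concordance",
    "count_cn_changes",
    "detect_segment_cnv",
    "haplogroup_collapse",
    "Segment",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def estimate_copy_number(
    gene_track: CoverageTrack, reference_track: CoverageTrack
) -> tuple[float, int]:
    """(normalized coverage, rounded copy number) for one gene in one sample.

    The reference region is single-copy, so median(gene) / median(reference)
    estimates the copy number directly; per-copy depth ~30X makes the ratio
    of a two-copy arm pair ~2.0.
    """
    ref_median = reference_track.median()
    if ref_median <= 0:
        raise ValueError("reference track median must be > 0")
    norm = gene_track.median() / ref_median
    return norm, _round_half_up(norm)


@dataclass
class CopyNumberTable:
    """Tidy per-sample, per-gene normalized coverage and copy number."""

    data: pd.DataFrame  # columns: sample, gene, normalized_coverage, copy_number

    @classmethod
    def from_tracks(
        cls,
        gene_tracks: dict[tuple[str, str], CoverageTrack],
        reference_tracks: dict[str, CoverageTrack],
    ) -> "CopyNumberTable":
        rows = []
        for (sample, gene), track in sorted(gene_tracks.items()):
            norm, cn = estimate_copy_number(track, reference_tracks[sample])
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "normalized_coverage": norm,
                    "copy_number": cn,
                }
            )
        return cls(pd.DataFrame(rows))

    def lookup(self, sample: str, gene: str) -> float | None:
        df = self.data
        hit = df[(df["sample"] == sample) & (df["gene"] == gene)]
        if hit.empty:
            return None
        return float(hit["normalized_coverage"].iloc[0])

    def leaf_copy_numbers(self, gene: str) -> dict[str, int]:
        df = self.data[self.data["gene"] == gene]
        if df.empty:
            raise ValueError(f"gene {gene!r} not in table")
        return dict(zip(df["sample"], df["copy_number"].astype(int)))


def cn_concordance(
    table: CopyNumberTable,
    pairs: list[tuple[str, str]],
    threshold: float = 0.5,
) -> tuple[float, list[tuple[str, str, str]]]:
    """Father-son copy-number concordance over all pair x gene combinations.

    A pair-gene is concordant iff |normalized_father - normalized_son| <
    threshold (strictly; a difference of exactly 0.5 is discordant). Returns
    (percentage to 1 decimal, list of discordant (father, son, gene)).
    """
    genes = sorted(table.data["gene"].unique())
    n_total = 0
    discordant: list[tuple[str, str, str]] = []
    for father, son in pairs:
        for gene in genes:
            nf = table.lookup(father, gene)
            ns = table.lookup(son, gene)
            if nf is None or ns is None:
                warnings.warn(
                    f"missing member for pair ({father}, {son}) at gene {gene}; skipped"
                )
                continue
            n_total += 1
            if not abs(nf - ns) < threshold:
                discordant.append((father, son, gene))
    if n_total == 0:
        raise ValueError("no scorable pair-genes")
    rate = round(100.0 * (n_total - len(discordant)) / n_total, 1)
    return rate, discordant


def _fitch_changes(tree: Phylogeny, leaf_states: dict[str, int]) -> int:
    """Minimum number of unit-cost state changes explaining integer leaf
    states (unordered-state small parsimony; optimal labelings never need
    states outside the observed set)."""
    sets: dict[str, frozenset[int]] = {}
    changes = 0
    for node in tree.postorder():
        if node.is_leaf:
            sets[node.name] = frozenset([leaf_states[node.name]])
        else:
            acc = None
            for child in node.children:
                s = sets[child.name]
                if acc is None:
                    acc = s
                else:
                    inter = acc & s
                    if inter:
                        acc = inter
                    else:
                        acc = acc | s
                        changes += 1
            sets[node.name] = acc
    return changes


def count_cn_changes(
    tree: Phylogeny,
    table: CopyNumberTable,
    gene: str,
    baseline_rule=None,
) -> int:
    """Minimum number of copy-number changes of ``gene`` on the tree.

    ``baseline_rule`` (optional) maps the leaf copy-number dict to a
    transformed dict before counting; see :func:`haplogroup_collapse` for the
    high-copy-gene rule.
    """
    values = table.leaf_copy_numbers(gene)
    missing = set(tree.leaf_names()) - set(values)
    if missing:
        raise ValueError(f"no copy number for leaves: {sorted(missing)}")
    if baseline_rule is not None:
        values = baseline_rule(values)
    return _fitch_changes(tree, values)


def haplogroup_collapse(haplogroups: dict[str, str], radius: int = 1):
    """Conservative high-copy rule: within each haplogroup, leaf values
    within ``radius`` of the haplogroup's rounded mean collapse onto it, so
    only changes by more than ``radius`` copies are counted."""

    def rule(values: dict[str, int]) -> dict[str, int]:
        out = dict(values)
        groups: dict[str, list[str]] = {}
        for sample in values:
            groups.setdefault(haplogroups[sample], []).append(sample)
        for _, members in groups.items():
            mean = _round_half_up(float(np.mean([values[m] for m in members])))
            for m in members:
                if abs(values[m] - mean) <= radius:
                    out[m] = mean
        return out

    return rule


@dataclass
class Segment:
    start: int  # 1-based inclusive, track coordinates
    end: int
    ratio: float
    copy_number: int


def detect_segment_cnv(
    track: CoverageTrack,
    baseline_depth: float,
    window_bp: int = 5000,
) -> list[Segment]:
    """Windowed copy-number segmentation of one coverage track.

    Non-overlapping windows of ``window_bp``; each window's median depth is
    divided by the single-copy baseline and rounded half-up; consecutive
    windows with equal rounded copy number merge into one segment whose ratio
    is the segment-wide median over baseline. A track shorter than one window
    yields a single whole-track segment.
    """
    if baseline_depth <= 0:
        raise ValueError("baseline_depth must be > 0")
    depth = np.asarray(track.depth, dtype=float)
    n = len(depth)
    if n == 0:
        raise ValueError("empty track")
    bounds = list(range(0, n, window_bp)) or [0]
    windows = [(lo, min(lo + window_bp, n)) for lo in bounds]

    cn_per_window = [
        _round_half_up(float(np.median(depth[lo:hi])) / baseline_depth)
        for lo, hi in windows
    ]
    segments: list[Segment] = []
    seg_lo, seg_cn = 0, cn_per_window[0]
    for w, cn in enumerate(cn_per_window[1:], start=1):
        if cn != seg_cn:
            lo, hi = windows[seg_lo][0], windows[w - 1][1]
            segments.append(_make_segment(track, depth, lo, hi, baseline_depth, seg_cn))
            seg_lo, seg_cn = w, cn
    lo, hi = windows[seg_lo][0], windows[-1][1]
    segments.append(_make_segment(track, depth, lo, hi, baseline_depth, seg_cn))
    return segments


def _make_segment(track, depth, lo, hi, baseline, cn) -> Segment:
    ratio = float(np.median(depth[lo:hi])) / baseline
    return Segment(track.start + lo, track.start + hi - 1, ratio, cn)
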