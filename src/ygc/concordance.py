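"""Father-son scaffold concordance from pairwise alignments.

Columns of a two-sequence alignment are classified as match / mismatch /
masked / gap. Repeat intervals and N-containing columns are masked, and a
mismatch within ``gap_flank`` alignment columns of any gap column is masked
too (alignment edges around indels are unreliable). Concordance is reported
in non-overlapping windows of alignment columns as matches over
matches + mismatches; gap and masked columns do not enter the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AlignmentPair", "mask_alignment", "window_concordance",
           "MATCH", "MISMATCH", "MASKED", "GAP"]

MATCH, MISMATCH, MASKED, GAP = 0, 1, 2, 3
STATUS_NAMES = {MATCH: "match", MISMATCH: "mismatch", MASKED: "masked", GAP: "gap"}


@dataclass
class AlignmentPair:
    """Two aligned sequences over {A,C,G,T,N,-} plus repeat-mask intervals
    (0-based half-open, alignment coordinates)."""

    seq_a: str
    seq_b: str
    mask: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")
        for lo, hi in self.mask:
            if not (0 <= lo <= hi <= len(self.seq_a)):
                raise ValueError(f"mask interval ({lo}, {hi}) out of bounds")

    def __len__(self) -> int:
        return len(self.seq_a)


def _distance_to_gap(is_gap: np.ndarray) -> np.ndarray:
    """Per column, distance (in columns) to the nearest gap column."""
    n = len(is_gap)
    inf = n + 1
    fwd = np.full(n, inf)
    last = -inf
    for i in range(n):
        if is_gap[i]:
            last = i
        fwd[i] = i - last
    bwd = np.full(n, inf)
    nxt = n + inf
    for i in range(n - 1, -1, -1):
        if is_gap[i]:
            nxt = i
        bwd[i] = nxt - i
    return np.minimum(fwd, bwd)


def mask_alignment(pair: AlignmentPair, gap_flank: int = 50) -> np.ndarray:
    """Column status vector for an alignment pair.

    Precedence per column: gap > masked (repeat interval or N) > mismatch
    within ``gap_flank`` of a gap (masked) > mismatch > match.
    """
    a = np.frombuffer(pair.seq_a.encode(), dtype="S1")
    b = np.frombuffer(pair.seq_b.encode(), dtype="S1")
    n = len(a)
    is_gap = (a == b"-") | (b == b"-")
    has_n = (a == b"N") | (b == b"N")
    in_repeat = np.zeros(n, dtype=bool)
    for lo, hi in pair.mask:
        in_repeat[lo:hi] = True

    status = np.where(a == b, MATCH, MISMATCH).astype(np.int8)
    near_gap = _distance_to_gap(is_gap) <= gap_flank
    status[(status == MISMATCH) & near_gap] = MASKED
    status[in_repeat | has_n] = MASKED
    status[is_gap] = GAP
    return status


def window_concordance(statuses: np.ndarray, window_bp: int = 10000) -> pd.DataFrame:
    """Per-window concordance: matches / (matches + mismatches).

    Windows are non-overlapping in alignment coordinates; a window with no
    scorable column is skipped. Columns: start (0-based), end (exclusive),
    n_match, n_mismatch, concordance.
    """
    statuses = np.asarray(statuses)
    rows = []
    for lo in range(0, len(statuses), window_bp):
        win = statuses[lo : lo + window_bp]
        n_match = int(np.sum(win == MATCH))
        n_mismatch = int(np.sum(win == MISMATCH))
        if n_match + n_mismatch == 0:
            continue
        rows.append(
            {
                "start": lo,
                "end": lo + len(win),
                "n_match": n_match,
                "n_mismatch": n_mismatch,
                "concordance": n_match / (n_match + n_mismatch),
            }
        )
    return pd.DataFrame(rows, columns=["start", "end", "n_match", "n_mismatch", "concordance"])
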