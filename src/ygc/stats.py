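"""Per-generation event rates and the chi-square bias tests.

Rates are events per position per generation (PPPG): the event count divided
by the generations spanned by the tree and the sequence length analysed (for
palindromes, both arms: 2 x arm length). Bias tests are 1-df chi-square
goodness-of-fit against a 1:1 split, without continuity correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats as sps

from .containers import EventCall

__all__ = [
    "RateEstimate",
    "ChiSquareResult",
    "estimate_rate",
    "chi_square_gof",
    "summarize_biases",
    "round_sig",
]


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, digits - 1 - exponent)


@dataclass
class RateEstimate:
    n_events: int
    generations: float
    length_bp: float
    rate: float

    def rounded(self, digits: int = 3) -> float:
        return round_sig(self.rate, digits)


def estimate_rate(n_events: int, generations: float, length_bp: float) -> RateEstimate:
    """Exact PPPG quotient; report with :meth:`RateEstimate.rounded`."""
    if generations <= 0 or length_bp <= 0:
        raise ValueError("generations and length_bp must be > 0")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    return RateEstimate(
        n_events, generations, length_bp, n_events / (generations * length_bp)
    )


@dataclass
class ChiSquareResult:
    observed: tuple[int, int]
    statistic: float
    p_value: float


def chi_square_gof(count_a: int, count_b: int) -> ChiSquareResult:
    """1-df goodness of fit of (a, b) against a 1:1 split, no continuity
    correction; upper-tail p-value."""
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be >= 0")
    if count_a + count_b == 0:
        raise ValueError("both counts are zero")
    res = sps.chisquare([count_a, count_b])
    return ChiSquareResult((count_a, count_b), float(res.statistic), float(res.pvalue))


def _section(name, label_a, n_a, label_b, n_b, min_n=2, test=True):
    total = n_a + n_b
    entry = {
        "section": name,
        "labels": (label_a, label_b),
        "counts": (n_a, n_b),
        "percent": (
            (round(100 * n_a / total), round(100 * n_b / total)) if total else (0, 0)
        ),
        "statistic": None,
        "p_value": None,
    }
    if test and total >= min_n and total > 0:
        chi = chi_square_gof(n_a, n_b)
        entry["statistic"] = chi.statistic
        entry["p_value"] = chi.p_value
    return entry


def summarize_biases(events: list[EventCall], min_n: int = 2) -> list[dict]:
    """Tabulate and test the direction biases of classified events.

    Sections: conversion polarity (ancestral vs derived winner), conversion
    GC direction, mutation GC direction (all, and private-only), and the
    polarity of GC-neutral conversions (reported without a significance
    claim: the GC and ancestral pulls are confounded everywhere else, so this
    subtable is descriptive).
    """
    if not events:
        warnings.warn("no events to summarize")
        return []
    conv = [e for e in events if e.kind == "conversion"]
    mut = [e for e in events if e.kind == "mutation"]

    def n(evts, attr, value):
        return sum(1 for e in evts if getattr(e, attr) == value)

    report = [
        _section(
            "conversion_polarity",
            "anc_to_der",
            n(conv, "polarity", "anc_to_der"),
            "der_to_anc",
            n(conv, "polarity", "der_to_anc"),
            min_n,
        ),
        _section(
            "conversion_gc",
            "to_GC",
            n(conv, "gc_direction", "to_GC"),
            "to_AT",
            n(conv, "gc_direction", "to_AT"),
            min_n,
        ),
        _section(
            "mutation_gc",
            "to_AT",
            n(mut, "gc_direction", "to_AT"),
            "to_GC",
            n(mut, "gc_direction", "to_GC"),
            min_n,
        ),
        _section(
            "mutation_gc_private",
            "to_AT",
            n([e for e in mut if e.privacy == "private"], "gc_direction", "to_AT"),
            "to_GC",
            n([e for e in mut if e.privacy == "private"], "gc_direction", "to_GC"),
            min_n,
        ),
        _section(
            "conversion_polarity_gc_neutral",
            "der_to_anc",
            n(
                [e for e in conv if e.gc_direction == "neutral"],
                "polarity",
                "der_to_anc",
            ),
            "anc_to_der",
            n(
                [e for e in conv if e.gc_direction == "neutral"],
                "polarity",
                "anc_to_der",
            ),
            min_n,
            test=False,
        ),
    ]
    return report
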