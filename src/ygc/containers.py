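"""In-memory containers: haploid SNV matrices, pseudo-diploid palindrome
genotype matrices, event calls, and coverage tracks."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

# Pseudo-diploid genotype codes. A collapsed palindrome arm pair is modelled
# as a diploid locus: both arms equal the reference base (HOM_REF), the arms
# differ (HET), or both arms carry the alternative base (HOM_ALT).
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

STATE_NAMES = {HOM_REF: "HOM_REF", HET: "HET", HOM_ALT: "HOM_ALT", MISSING: "MISSING"}
STATE_CODES = {v: k for k, v in STATE_NAMES.items()}

PURINES = {"A", "G"}
GC_BASES = {"G", "C"}
AT_BASES = {"A", "T"}
BASES = ("A", "C", "G", "T")


@dataclass
class HaploidSNVMatrix:
    """Haploid alleles per sample per site; 'N' marks missing calls."""

    samples: list[str]
    positions: np.ndarray  # (n_sites,) int
    alleles: np.ndarray  # (n_samples, n_sites) '<U1'

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype="<U1")
        if self.alleles.shape != (len(self.samples), len(self.positions)):
            raise ValueError("allele matrix shape does not match samples x sites")
        if len(self.samples) < 2:
            raise ValueError("need at least two samples")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sample_index(self, name: str) -> int:
        return self.samples.index(name)

    def take_sites(self, idx: Sequence[int]) -> "HaploidSNVMatrix":
        idx = np.asarray(idx)
        return HaploidSNVMatrix(
            list(self.samples), self.positions[idx], self.alleles[:, idx]
        )


@dataclass
class PseudoDiploidMatrix:
    """Biallelic pseudo-diploid genotypes with per-call read depth.

    ``genotypes`` uses the codes HOM_REF/HET/HOM_ALT/MISSING above; ``depth``
    is the read depth backing each call (0 where unknown).
    """

    samples: list[str]
    positions: np.ndarray  # (n_sites,) int, 1-based arm coordinates
    ref: np.ndarray  # (n_sites,) '<U1'
    alt: np.ndarray  # (n_sites,) '<U1'
    genotypes: np.ndarray  # (n_samples, n_sites) int8
    depth: np.ndarray  # (n_samples, n_sites) int32

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype="<U1")
        self.alt = np.asarray(self.alt, dtype="<U1")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        shape = (len(self.samples), len(self.positions))
        if self.genotypes.shape != shape or self.depth.shape != shape:
            raise ValueError("genotype/depth shape does not match samples x sites")
        if np.any(self.depth < 0):
            raise ValueError("negative read depth")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sample_index(self, name: str) -> int:
        return self.samples.index(name)

    def alleles_at(self, site_idx: int) -> tuple[str, str]:
        return str(self.ref[site_idx]), str(self.alt[site_idx])

    def copy(self) -> "PseudoDiploidMatrix":
        return replace(
            self,
            samples=list(self.samples),
            genotypes=self.genotypes.copy(),
            depth=self.depth.copy(),
        )


@dataclass
class EventCall:
    """One inferred mutation or gene conversion on a branch of the phylogeny.

    kind: "mutation" (parent HOM -> child HET), "conversion" (parent HET ->
    child HOM) or "complex" (HOM -> opposite HOM). Direction labels are filled
    by :func:`ygc.events.classify_event`.
    """

    branch: tuple[str, str]  # (parent node name, child node name)
    site: int  # 1-based arm position
    kind: str
    parent_state: str
    child_state: str
    gained_allele: str | None = None
    lost_allele: str | None = None
    polarity: str | None = None  # conversions: anc_to_der / der_to_anc / ambiguous
    gc_direction: str | None = None  # to_GC / to_AT / neutral
    substitution_class: str | None = None  # transition / transversion
    privacy: str | None = None  # private / common


@dataclass
class CoverageTrack:
    """Per-position read depth over a 1-based inclusive region."""

    start: int
    end: int
    depth: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.depth = np.asarray(self.depth)
        if np.any(self.depth < 0):
            raise ValueError("negative depth")
        if len(self.depth) != self.end - self.start + 1:
            raise ValueError("depth length does not match region span")

    def median(self) -> float:
        return float(np.median(self.depth))


@dataclass
class SimTruth:
    """Ground-truth log emitted by the simulator.

    events: (branch, site, kind, from_allele, to_allele, ancestral_allele)
    tuples in time order within each branch; ancestral_allele is None for
    standing heterozygous sites whose pre-tree polarity is undefined.
    """

    events: list[tuple] = field(default_factory=list)
    cn_segments: list[tuple] = field(default_factory=list)
    root_states: dict[int, int] = field(default_factory=dict)
    ancestral_allele: dict[int, str | None] = field(default_factory=dict)
    site_pairs: dict[int, tuple[str, str]] = field(default_factory=dict)
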