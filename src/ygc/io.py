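"""Plain-text readers/writers for the pipeline's interchange formats.

VCF (pseudo-diploid genotypes, GT/DP), TSV (haploid SNV matrix, event table,
truth log, family map, outgroup states), Newick (trees), BED (region specs,
0-based half-open) and a flat key=value config for simulation parameters.
VCF reading goes through pysam; everything else is pandas/dendropy.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .containers import (
    MISSING,
    STATE_CODES,
    STATE_NAMES,
    EventCall,
    HaploidSNVMatrix,
    PseudoDiploidMatrix,
)
from .simulate import SimParams
from .tree import Phylogeny

ARM_CONTIG = "palindrome_arm"

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


# -- VCF --------------------------------------------------------------------


def write_pseudodiploid_vcf(matrix: PseudoDiploidMatrix, path: str | Path) -> None:
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={ARM_CONTIG}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Pseudo-diploid genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples),
    ]
    for k in range(matrix.n_sites):
        fields = [
            ARM_CONTIG,
            str(int(matrix.positions[k])),
            ".",
            str(matrix.ref[k]),
            str(matrix.alt[k]),
            ".",
            "PASS",
            ".",
            "GT:DP",
        ]
        for i in range(len(matrix.samples)):
            g = int(matrix.genotypes[i, k])
            fields.append(f"{_GT_STRING[g]}:{int(matrix.depth[i, k])}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def read_pseudodiploid_vcf(path: str | Path) -> PseudoDiploidMatrix:
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        positions, refs, alts, gts, dps = [], [], [], [], []
        for rec in vcf:
            positions.append(rec.pos)
            refs.append(rec.ref)
            alts.append(rec.alts[0] if rec.alts else "N")
            row_gt, row_dp = [], []
            for s in samples:
                call = rec.samples[s]
                alleles = call["GT"]
                if alleles is None or None in alleles:
                    row_gt.append(MISSING)
                else:
                    row_gt.append(int(sum(alleles)))
                dp = call.get("DP")
                row_dp.append(0 if dp is None else int(dp))
            gts.append(row_gt)
            dps.append(row_dp)
    return PseudoDiploidMatrix(
        samples,
        np.array(positions, dtype=np.int64),
        np.array(refs, dtype="<U1"),
        np.array(alts, dtype="<U1"),
        np.array(gts, dtype=np.int8).T,
        np.array(dps, dtype=np.int32).T,
    )


# -- haploid SNV matrix ------------------------------------------------------


def write_snv_tsv(matrix: HaploidSNVMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        matrix.alleles.T, index=matrix.positions, columns=matrix.samples
    )
    df.index.name = "position"
    df.to_csv(path, sep="\t")


def read_snv_tsv(path: str | Path) -> HaploidSNVMatrix:
    df = pd.read_csv(path, sep="\t", index_col="position", dtype=str)
    return HaploidSNVMatrix(
        list(df.columns),
        df.index.to_numpy(dtype=np.int64),
        df.to_numpy(dtype="<U1").T,
    )


# -- newick ------------------------------------------------------------------


def write_newick(tree: Phylogeny, path: str | Path, include_support: bool = False) -> None:
    Path(path).write_text(tree.to_newick(include_support=include_support) + "\n")


def read_newick(path: str | Path) -> Phylogeny:
    return Phylogeny.from_newick(Path(path).read_text())


# -- event table -------------------------------------------------------------

_EVENT_COLUMNS = [
    "parent",
    "child",
    "site",
    "kind",
    "parent_state",
    "child_state",
    "gained_allele",
    "lost_allele",
    "polarity",
    "gc_direction",
    "substitution_class",
    "privacy",
]


def write_events_tsv(events: list[EventCall], path: str | Path) -> None:
    rows = []
    for e in events:
        d = dataclasses.asdict(e)
        d["parent"], d["child"] = d.pop("branch")
        rows.append(d)
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> list[EventCall]:
    df = pd.read_csv(path, sep="\t", dtype={"site": int})
    events = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        none = lambda v: None if pd.isna(v) else v
        events.append(
            EventCall(
                branch=(d["parent"], d["child"]),
                site=int(d["site"]),
                kind=d["kind"],
                parent_state=d["parent_state"],
                child_state=d["child_state"],
                gained_allele=none(d["gained_allele"]),
                lost_allele=none(d["lost_allele"]),
                polarity=none(d["polarity"]),
                gc_direction=none(d["gc_direction"]),
                substitution_class=none(d["substitution_class"]),
                privacy=none(d["privacy"]),
            )
        )
    return events


# -- misc tables -------------------------------------------------------------


def write_truth_tsv(truth, path: str | Path) -> None:
    rows = [
        {
            "parent": br[0],
            "child": br[1],
            "site": site,
            "kind": kind,
            "from_allele": frm,
            "to_allele": to,
            "ancestral_allele": anc if anc is not None else ".",
        }
        for br, site, kind, frm, to, anc in truth.events
    ]
    pd.DataFrame(
        rows,
        columns=["parent", "child", "site", "kind", "from_allele", "to_allele",
                 "ancestral_allele"],
    ).to_csv(path, sep="\t", index=False)


def write_family_tsv(families: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(families.items()), columns=["sample", "family"]
    ).to_csv(path, sep="\t", index=False)


def read_family_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample"], df["family"]))


def write_outgroup_states_tsv(states: dict[int, int], path: str | Path) -> None:
    pd.DataFrame(
        [(pos, STATE_NAMES[s]) for pos, s in sorted(states.items())],
        columns=["position", "state"],
    ).to_csv(path, sep="\t", index=False)


def read_outgroup_states_tsv(path: str | Path) -> dict[int, int]:
    df = pd.read_csv(path, sep="\t")
    return {int(p): STATE_CODES[s] for p, s in zip(df["position"], df["state"])}


def write_bed(regions: dict[str, tuple[int, int]], path: str | Path,
              chrom: str = ARM_CONTIG) -> None:
    """Regions as BED (0-based half-open) from 1-based inclusive spans."""
    with open(path, "w") as fh:
        for name, (start, end) in sorted(regions.items(), key=lambda kv: kv[1]):
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


def read_bed(path: str | Path) -> dict[str, tuple[int, int]]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"])
    return {
        str(r.name_): (int(r.start) + 1, int(r.end))
        for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
    }


def read_alignment_pair(fasta_path: str | Path, bed_path: str | Path | None = None):
    """Two-record aligned FASTA (+ optional BED repeat mask in alignment
    coordinates) -> AlignmentPair."""
    from .concordance import AlignmentPair

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"expected 2 aligned records, found {len(records)}")
    mask: list[tuple[int, int]] = []
    if bed_path is not None:
        df = pd.read_csv(bed_path, sep="\t", header=None, usecols=[0, 1, 2],
                         names=["chrom", "start", "end"])
        mask = [(int(r.start), int(r.end)) for r in df.itertuples(index=False)]
    return AlignmentPair(str(records[0].seq), str(records[1].seq), mask=mask)


def write_config(params: SimParams, path: str | Path) -> None:
    lines = [
        f"{f.name}={getattr(params, f.name)}" for f in dataclasses.fields(SimParams)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> SimParams:
    kwargs = {}
    types = {f.name: f.type for f in dataclasses.fields(SimParams)}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in types:
            raise ValueError(f"unknown parameter {key!r}")
        kwargs[key] = int(value) if types[key] == "int" else float(value)
    return SimParams(**kwargs)
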