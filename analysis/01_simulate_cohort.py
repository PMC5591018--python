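#!/usr/bin/env python
"""Generate the synthetic study cohort.

62 Y chromosomes (17 father-son pairs plus 28 unrelated men) on a random
coalescent-like phylogeny spanning 12265 generations, with haploid
X-degenerate SNVs, pseudo-diploid palindrome-arm genotypes (with a logged
ground truth of every mutation and gene-conversion event), outgroup states
and the family map. Sequence lengths are scaled down (100 kb arm, 500 kb
X-degenerate) so the whole pipeline reruns in seconds.

Writes results/sim/.
"""

from pathlib import Path

import ygc
from ygc import io as yio

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"

PARAMS = ygc.SimParams(
    n_samples=62,
    n_families=17,
    total_generations=12265,
    arm_length_bp=100_000,
    xdeg_length_bp=500_000,
    seed=20170828,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tree = ygc.simulate_tree(PARAMS)
    snvs, _ = ygc.simulate_xdeg_snvs(tree, PARAMS)
    pal, truth = ygc.simulate_palindrome(tree, PARAMS)

    yio.write_config(PARAMS, OUT / "sim.cfg")
    yio.write_newick(tree, OUT / "tree_true.nwk")
    yio.write_snv_tsv(snvs, OUT / "xdeg_snvs.tsv")
    yio.write_pseudodiploid_vcf(pal, OUT / "palindrome.vcf")
    yio.write_truth_tsv(truth, OUT / "truth_events.tsv")
    yio.write_family_tsv(ygc.family_map(PARAMS), OUT / "families.tsv")
    yio.write_outgroup_states_tsv(
        ygc.truth_outgroup_states(pal, truth), OUT / "outgroup_states.tsv"
    )

    n_mut = sum(1 for e in truth.events if e[2] == "mutation")
    n_conv = sum(1 for e in truth.events if e[2] == "conversion")
    print(f"tree: {len(tree.leaf_names())} leaves, "
          f"{tree.total_branch_length():.0f} generations total")
    print(f"X-degenerate SNVs: {snvs.n_sites}")
    print(f"palindrome sites emitted: {pal.n_sites}")
    print(f"true events: {n_mut} mutations, {n_conv} conversions")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
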