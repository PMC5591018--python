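# Methods notes

## The inference model

A palindrome arm pair, collapsed by read mapping onto one arm, is treated as
a biallelic pseudo-diploid locus per position: HOM_REF (arms agree with the
reference base), HET (arms differ), HOM_ALT (arms agree on the alternative
base). On a phylogeny of haploid Y chromosomes, every branch-wise change of
the reconstructed pseudo-genotype is one event:

- HOM → HET: an **arm mutation** (one arm base changed);
- HET → HOM: a **gene conversion** (non-allelic homologous recombination
  copied one arm over the other, erasing the mismatch);
- HOM → opposite HOM: labeled **complex** and excluded from the
  mutation/conversion tallies and rates. Such a jump needs at least two
  underlying events on one branch; at realistic event densities it is rare,
  and counting it as either kind would be a guess.

Ancestral pseudo-genotypes are reconstructed by small parsimony on the
three states: a bottom-up pass assigns each internal node the intersection
of its children's state sets, or the union when the intersection is empty
(a missing leaf contributes the full universe — the standard treatment);
a top-down pass then resolves each node to its parent's state whenever that
state is in its own set. The root takes the outgroup-consensus state when
that state is in its set. Free choices (root without outgroup help, a child
whose set excludes its parent's state) follow the fixed preference
HOM_REF > HET > HOM_ALT; this is purely a determinism device, and the
resolved labeling always attains the parsimony minimum (the test suite
checks this against exhaustive enumeration on all leaf-state patterns of
3–6-leaf trees). Events on the root's two branches are suppressed unless an
outgroup pinned the root state, since without it the assignment of a change
to one side of the root is arbitrary.

The per-site ancestral allele is the allele of the resolved root state when
the root is homozygous, else the outgroup's homozygous allele, else
unknown. Conversions are polarized against it (derived→ancestral vs
ancestral→derived, "ambiguous" when unknown — in particular at sites whose
arms already differed at the root of the tree).

## Rates and tests

Rates are events per position per generation (PPPG):
`rate = n_events / (G × L)`, with `G` the total branch length of the tree
in generations and `L` the physical sequence analysed counted over both
arms (2 × arm length). `G` is calibrated from haploid X-degenerate SNVs:
`G = n_SNVs / (μ × callable_bp)` with μ = 3.14e-8 PPPG. Only
"non-recurrent" SNVs count — variants whose carrier set is a clade on the
tree, i.e. variants needing a single origin; the filter builds a tree,
flags non-clade sites, and rebuilds once on the kept sites.

Direction biases (conversion polarity, conversion GC direction, mutation
AT/GC direction, all and private-only) are tested with a 1-df chi-square
goodness of fit against 1:1, no continuity correction. The GC-neutral
conversion polarity subtable (A/T or G/C arm pairs, where GC bias cannot
act) is reported descriptively without a test. The chi-square tail
approximates the exact binomial two-tail to within 10–16% relative at the
count totals this analysis produces (a few hundred events); the test suite
documents this approximation against the exact and Monte-Carlo binomial
nulls.

## The synthetic cohort

The generator emulates the study design rather than any particular dataset:

| parameter | default | meaning |
| --- | --- | --- |
| n_samples / n_families | 62 / 17 | cohort size; father-son cherry pairs |
| total_generations | 12265 | total branch length of the tree (generations) |
| mu_xdeg | 3.14e-8 | haploid X-degenerate SNV rate, PPPG |
| mu_pal | 1.76e-8 | arm mutation rate, PPPG over both arms |
| gamma | 1.21e-8 | gene-conversion rate, PPPG over both arms |
| b_at | 0.56 | P(new mutant allele is A/T) |
| b_gc | 259/417 | P(conversion keeps the G/C allele of a GC/AT pair) |
| b_anc | 171/271 | P(conversion keeps the ancestral allele) |
| arm_length_bp | 1.4e6 | one palindrome arm (tests and demos use 1e5) |
| xdeg_length_bp | 8.1e6 | callable X-degenerate sequence (tests use 5e5) |
| depth_per_copy | 30 | expected read depth per sequence copy (60X arms) |
| root_het_density | 2.5e-4 | standing arm differences at the tree root |

Topology: father-son pairs are cherries with 1-generation terminal
branches; the units above them join in random order (a stand-in for the
data-determined topology of a real cohort). All remaining branch lengths
are exponential draws rescaled so the branch-length sum hits
`total_generations` exactly.

Within a branch of `t` generations, mutation and conversion events arrive
as Poisson counts with means `mu_pal·2L·t` and `gamma·2L·t`, are given
uniform times, and are applied in time order; a conversion can only target
a site that is heterozygous at that moment. Sites are finite with at most
one segregating allele pair (a mutation landing on a current het is
redrawn). The conversion survivor is drawn with
`P(x) ∝ w_gc(x) · w_anc(x)`: `w_gc` puts weight `b_gc` on the G/C allele of
a GC/AT pair (equal weights otherwise), `w_anc` puts `b_anc` on the
ancestral allele when known. The bias tabulations are marginal over
overlapping event sets, and this factorized form reproduces both marginals
to well within the sampling noise of a few hundred events (checked by the
bias-recovery tests).

`root_het_density` seeds the root with standing arm differences. Arms are
>99.9% identical, not 100%: a conversion machinery needs standing
mismatches to act on, and an all-homozygous root would starve early
conversions and depress the realized conversion rate below `gamma`.
Standing sites have no defined ancestral allele; conversions there come out
"ambiguous", matching the real analysis's residual class where the
inferred ancestral genotype was itself heterozygous.

What the generator does **not** model: read-level data (depth is Poisson
per position, genotypes are error-free apart from the depth filter), indels
and STRs, sequence context, conversion tract length (events are single-site;
the tract-merging step groups same-branch neighbours instead), and
cross-palindrome exchange (the multi-copy r/g/b arms are excluded from the
analysed complement, as in the real study). Passing recovery tests
therefore demonstrate the correctness of the inference machinery under the
stated stochastic model, not robustness to genotyping error.

## What recovery means, and when it degrades

With outgroup states available and events spread thinly over het sites, the
caller recalls ≥95% of logged events with the correct kind (acceptance
property, pooled over replicates). Two effects erode recall as density
rises, both visible in the realistic-density demo pipeline (~75–90%):

- a mutation followed on the same or a descendant branch by a conversion
  back to the ancestral allele is cheaper to explain as one event (or
  none); parsimony picks the cheaper history, and `b_anc > 1/2` makes such
  reverting pairs common;
- two conversions of the same standing het on nested branches without an
  intervening witness lineage merge into one deeper call.

These are properties of parsimony on this data type, not implementation
artifacts; the real analysis is subject to the same undercount. The
depth filter adds missing genotypes (~8% of calls at 60X with the 50–250X
bounds), which relaxes per-site parsimony further.

## Numerical and design choices

- Depth bounds are inclusive ([50, 250]); tightening the filter can only
  reduce the number of called events (masking relaxes the parsimony
  problem), which the suite asserts.
- Neighbor joining is Saitou–Nei with the Q-criterion minimum taken at the
  lowest index pair on ties; the unrooted result is rooted on the named
  outgroup's pendant edge (split in half) or at the midpoint. Branch
  lengths may be negative on non-additive inputs and are left as computed.
- Copy numbers round half-up (2.5 → 3), a stated convention rather than
  banker's rounding; the father-son threshold is strict (a difference of
  exactly 0.5 is discordant).
- Copy-number changes on the tree are unordered-state small parsimony
  (unit cost per change, any magnitude); for very-high-copy arrays where
  ±1 copy is below depth resolution, leaf values within 1 of the
  haplogroup's rounded mean are collapsed onto it first (configurable
  radius).
- Segmentation windows are non-overlapping; alignment-concordance windows
  are in alignment coordinates, with gap and masked columns excluded from
  the denominator; the gap-proximity rule masks mismatches at ≤50 columns
  from the nearest gap column.
- The calibration arithmetic is exposed with `callable_bp` explicit:
  3126 SNVs at μ = 3.14e-8 over exactly 8.1 Mb gives 12290.6 generations;
  the canonical 12265-generation figure corresponds to a slightly longer
  callable length and is used as an input constant where a fixed span is
  wanted. Downstream consumers take the unrounded value.
- The canonical conversion-rate figure divides by 2 × 1.4 Mb; the analysed
  palindrome complement is also quoted as 2.7 Mb under a different rounding
  convention. `estimate_rate` takes `length_bp` explicitly so either is
  reproducible.

## Problem sizes

Tests and the demo pipeline run on scaled-down sequence (100 kb arms,
500 kb X-degenerate) and 8–62 samples, keeping the full suite under a
minute; rate and bias recovery use 100 and 20 replicate simulations
respectively. The estimators operate on counts and ratios, so scale enters
only through Poisson noise, which the 3-SE acceptance bands account for.
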