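# Methods

This note documents the statistical machinery, the synthetic data model,
the numerical choices, and what the bundled tests do and do not establish.

## Window statistics

The genome is tiled per chromosome with sliding windows (default size
40 kb, step 20 kb); windows start at multiples of the step and trailing
partial windows are dropped, so every window has full size. Windows are
defined on the chromosome layout, not on the observed variant span: empty
chromosome ends simply yield invalid windows. A uniform validity rule
discards windows with fewer than three informative variants (for Tajima's
D, three *segregating* sites) before standardization; applying the same
rule to all three statistics keeps their Z nulls comparable.

**Pooled heterozygosity.** Per site the major/minor allele counts are
taken from the channel being scanned — chromosome counts of called
genotypes for the focal individuals, raw read counts for a pool — and
summed over the window: Hp = 2·ΣnMAJ·ΣnMIN/(ΣnMAJ+ΣnMIN)². Hp lies in
[0, 0.5]; it is 0 iff the window is monomorphic in that channel, 0.5 at
balanced counts. Exact 50/50 major/minor ties break to the reference
allele; Hp is symmetric in major/minor so the statistic is unaffected.

**Tajima's D.** Computed from alt-allele dosages, folded (no ancestral
polarisation). The normalising constants use n = 2 × (number of
individuals); per-site pairwise diversity uses the site's called
chromosome count, so sporadic missingness shrinks a site's contribution
rather than biasing it. Degenerate cases: at n = 2 (and exactly at n = 3,
where the constants c1 and c2 vanish) the variance term is zero; when the
numerator is also zero the statistic is reported as 0, otherwise the
window is invalid.

**Weir–Cockerham FST.** The method-of-moments estimator with
among-population (a), among-individual (b) and within-individual (c)
variance components, summed over the sites of a window and combined as
Σa/Σ(a+b+c) ("window as a locus"). When one side of a comparison is a
pool channel there is no individual-level heterozygosity, so both sides
collapse to allele counts and the haploid-sample variant is used
(documented approximation: read counts are treated as independent allele
draws; overlapping reads from the same chromosome are ignored, which is
reasonable at ~5× pool depth).

**Standardization.** z = (x − mean)/sd over the valid windows of one scan
(per statistic, per comparison), with the sample (n−1) standard
deviation — the choice is immaterial at hundreds-to-thousands of windows
but stated for exactness. Scans with fewer than two valid windows or zero
variance raise instead of emitting garbage.

The raw Tajima's D level of the synthetic data is strongly positive
(~+2): the generator draws site frequencies from a uniform-ish law, not
from the neutral coalescent 1/j spectrum that D is centred against. This
is harmless for sweep calling, which thresholds the genome-wide Z-scores,
and the D implementation itself is calibrated in the tests against
neutral coalescent simulations (msprime), where its windowed mean is near
zero and its per-window values match tskit's site-mode Tajima's D.

## Sweep regions and interval calculus

Windows whose Z passes a strict threshold (z < −4 for Hp and Tajima's D,
z > +4 for FST; a window exactly at the threshold is not flagged — ties
are measure-zero) are merged when they overlap or abut in coordinates,
which under the default 20 kb step is the same as consecutive window
indices. Region coordinates are 0-based half-open everywhere, including
BED output, so abutting regions share no base. Overlap between region
sets is any-shared-base, not reciprocal-fraction, and a region of set A
overlapping several regions of set B counts once at the region level.
Gene proximity distinguishes genes intersecting the region itself
("within") from genes only intersecting the region expanded by the margin
(default 40 kb) on both sides ("margin").

## Variant filtering

Two filters are applied: the variant (alt) allele must be supported by at
least 2 units of evidence, and genotype completeness must reach 80%.
Support is counted per channel: reads summed across all pools for the
pool channels (the across-all interpretation of "supported by two reads"
is an assumption, flagged here), and carrier chromosomes across the focal
sample for the genotype channel, where fixtures carry no per-sample read
depths. The channels are filtered separately: a failing channel is masked
at that site (genotypes to missing; pool counts to zero, which downstream
consumers treat as "no information" — the painter samples 50/50 at
zero-coverage sites), and a site is dropped outright only when every
present channel fails. The operation is idempotent.

## Haplotype-copying painter

A Li–Stephens copying HMM: hidden states are donor haplotypes, the switch
probability between adjacent sites is 1 − exp(−Ne·g) spread uniformly
over donors (including the current one), and emissions match the donor
allele with probability 1 − Mut. g is the inter-site genetic distance in
Morgans from a recombination map when supplied, otherwise a uniform
per-base rate (default 1 cM/Mb). Defaults Ne = 3166 and Mut = 0.0287574
are fixed values of the kind obtained from a single genome-wide E–M
estimation pass; re-estimating them per run is deliberately out of scope
and both are overridable.

Summaries come from the forward–backward posterior: the copying fraction
per donor group is the mean posterior group mass over sites, and the
expected chunk count per group is the expected number of entries into the
group's states along the sequence (initial-site mass plus posterior
transition expectations). Posterior expectations rather than Viterbi
segment counts are the default because they are deterministic and match
"expected number of segments" semantics; a Viterbi mode is provided for
comparison. Missing alleles (recipient or donor) emit probability 1 for
every state, informationally skipping the site. Group chunk counts are
divided by the number of haplotypes in the group before any comparison,
so unequal donor-panel sizes do not masquerade as similarity; raw counts
grow sub-linearly when a group is duplicated, normalised counts stay on
one scale.

Donor haplotypes for pool-sequenced comparison populations are
pseudo-haplotypes: at each site an allele is drawn with probability equal
to the pool's alt read fraction (50/50 at zero coverage). These are not
real haplotypes — they carry no linkage — but against a focal haplotype
fixed by a sweep they retain the frequency signal that distinguishes the
source populations.

## Origin assignment

Per region, two lines of evidence: pairwise FST of the focal population
against each source pool over the region's sites (haploid route), and the
painter's normalised chunk counts per donor group. The verdict is
"domestic" only when the focal sample is *further* from wild by FST and
copies *more* per domestic donor; "wild" for the mirror; anything else —
disagreement, ties, undefined inputs, unphased or empty regions — is
"ambiguous" with the reason logged. Disagreeing evidence therefore can
never produce a wrong source call, only an ambiguous one; a wrong call
requires both lines of evidence to err together, which on the synthetic
study configuration happens in a small minority of replicates. A
fine-scale mode re-profiles a region in 10 kb subwindows (FST per pool
and mean posterior copying per group from one region-wide painting) to
resolve regions whose parts have different origins.

## Synthetic data model

* **Sources.** Per site, an ancestral frequency p ~ Uniform(0.05, 0.95);
  wild and domestic frequencies are Balding–Nichols draws
  Beta(p(1−F)/F, (1−p)(1−F)/F) with F = `divergence_fst` (default 0.2, a
  typical wild-vs-domestic divergence); haplotypes are Bernoulli per
  site. At F → 0 the sources coincide.
* **Admixed focal population.** Each focal haplotype is a mosaic of
  source haplotypes from a two-state Markov switch process with per-base
  switch rate `recomb_rate × n_admix_generations` (defaults 1e-8 and 30:
  a few decades of admixture at a typical per-generation recombination
  rate, giving multi-megabase ancestry tracts); at each switch the source
  is domestic with probability `admixture_prop` (default 0.8, a mostly
  domestic-derived feral population) and the donor haplotype is uniform
  within the source. An explicit pedigree simulation is not attempted:
  the Markov mosaic is sufficient to create the tract and LD structure
  the painter and FST contrasts consume, at desk scale.
* **Planted sweeps.** A `hardness` fraction of focal haplotypes (1.0 =
  complete sweep) copies one fixed haplotype of the stated origin across
  the interval. Truth (intervals, origins, swept haplotype ids, ancestry
  tracts) is kept alongside the panels.
* **Observation layer.** Focal genotypes are emitted with a per-allele
  miscall probability `genotype_error` (default 0.005, a realistic rate
  for ~5× joint genotype calling). This layer matters structurally: a
  complete sweep with error-free genotypes has zero segregating sites, so
  Tajima's D windows inside it would be undefined rather than extreme;
  miscalls re-create the rare-variant excess low-coverage pipelines see
  in swept regions. Pools are observed as Poisson(`pool_depth`) reads per
  site (default 5, the whole-pool mean — depth is per pool, not per
  individual), each read drawn at the pool allele frequency and flipped
  with probability `pool_error` (default 0.002). Sites monomorphic across
  all latent panels are dropped before writing, and only biallelic SNPs
  are simulated.

What the generator does **not** emulate: coalescent LD within the source
panels (sites are independent given frequencies), selection dynamics
through time, variable recombination or mutation rate along the genome,
indels/multiallelics, and read-level artefacts (mapping bias, base
quality). Passing recovery tests therefore show that the scan-and-assign
chain is correct and well calibrated under a clean admixture-with-sweeps
model — not that its thresholds are optimal for any particular real
dataset.

## Problem sizes and determinism

The bundled study configuration is 2 chromosomes × 5 Mb at ~1 site/kb
(≈500 windows), 23 focal diploids, 8 + 8 source diploids, three planted
120–200 kb hardness-1.0 sweeps; null calibration uses 20 replicates of a
no-sweep variant (5.1 Mb per chromosome, ≈508 windows) and origin
accuracy uses 10 replicates. These sizes exercise every code path while
keeping the full suite and the acceptance script in the seconds-to-
minutes range. All stages consume explicit seeds; identical seed and
config give byte-identical outputs (array RNG streams are split per
stage, so adding sweeps does not perturb the source draw).

## Known limitations

* The haploid FST route treats pool reads as independent allele draws;
  at high depth per individual this overstates the effective sample size.
* Pseudo-haplotype donors carry no linkage, so painter chunk counts
  against pools measure frequency-weighted similarity more than true
  haplotype sharing; with phased donor panels the painter uses them as-is.
* Tajima's D inherits the genotype channel only; a genotype-likelihood
  version for very low coverage is out of scope.
* The generator's flat site-frequency law makes absolute (non-Z) levels
  of D and Hp non-comparable to coalescent expectations; comparisons
  should stay within a scan.
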