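# Methods

peachscan re-implements, at desk scale, the family of bespoke computations
that typically sit behind a wild-relative crop-genomics study: genome-size
estimation from a k-mer survey, bulked-segregant trait mapping, a windowed
two-group selective-sweep scan, gene-origin assignment for hybridization
analysis, pan-genome gene-family classification, and the 4DTv divergence
statistic.  Raw sequencing data are replaced by seeded generators that
reproduce the statistical structure each stage assumes; every generator also
emits a truth record so recovery can be scored without external data.

## Coordinate and genotype conventions

All coordinates are 1-based inclusive; BED input/output converts at the
boundary (half-open start + 1).  Genotypes are alt-allele dosages {0, 1, 2}
with −1 for a missing call; a missing call is never encoded as 0, so a
masked sample can never masquerade as a reference homozygote.

## Population SNP filter

A site passes when its mapping quality is ≥ 20 and, after masking each
sample call with read depth < 5 or Phred genotype quality < 5, the missing
fraction is < 0.2.  The depth rule is applied per sample (masking that
call) rather than per site: the missingness rule that follows is only
meaningful once unreliable calls have been converted to missing.  Absent
depth/quality fields count as failing (conservative).  The filter is
idempotent: masked calls fail the same per-sample tests on a second pass
and site-level quantities do not change.

Multi-allelic records are skipped by default (everything downstream assumes
biallelic sites); a `split` mode emits one biallelic record per alt allele,
with calls involving another alt set missing.

## k-mer genome-size estimation

Genome size is the total k-mer instance count divided by the depth of the
k-mer coverage peak (k = 17 by default).  Two numerical choices matter:

* **Error-peak exclusion.**  Depths below `min_depth` (default 4) are
  excluded from peak finding *and* from the instance total.  Sequencing
  errors generate near-unique k-mers concentrated at depth 1; leaving them
  in the numerator would inflate the estimate roughly by the error
  fraction even though they never move the peak.
* **Peak smoothing.**  The peak is the argmax of a moving-window total
  (half-width 6 bins, window clipped at `min_depth`), not of the raw
  counts.  A sampled coverage histogram has near-tied neighbouring bins
  around its mode (a Poisson with integer mean has two exactly tied
  modes), so the raw argmax is a coin flip that shifts the estimate by a
  full depth unit (2.5% at depth 40).  The windowed total resolves the
  peak from the surrounding mass; for sparse, hand-specified histograms it
  coincides with the raw argmax, so closed-form examples are unaffected.
  Ties still break toward the smaller depth for determinism.

Heterozygosity and repeat-structure modelling (GenomeScope-style mixture
fits) are out of scope; the estimator assumes an essentially single-copy
genome, which is what the simulator generates.

## Bulked-segregant Δ(SNP-index) mapping

Informative markers are sites where the two parents are homozygous for
different alleles; the donor (resistant-parent) allele is recorded so that
the SNP index — the fraction of pooled reads carrying the donor allele —
is referenced consistently.  With that convention Δ = index_res − index_sus
is +0.5 in expectation at a dominant resistance locus in a BC₁ (resistant
pool heterozygous, susceptible pool recurrent-homozygous) and 0 at unlinked
markers.

Loci with an index below 0.3 in **both** pools or above 0.7 in **both**
pools are removed: such loci are non-segregating or systematically biased
and carry no mapping signal.  The alternative, stricter reading (drop when
either pool is outside [0.3, 0.7]) is available as `mode="either"` but
would also discard exactly the loci that map the trait (index_res ≈ 0.5,
index_sus ≈ 0 near a dominant locus).  Boundary values are kept.

Δ is averaged in sliding windows (defaults 1 Mb window, 100 kb step —
configurable; the windows exist to smooth binomial read noise across
linked markers).  The candidate region is called from windows whose
|mean Δ| exceeds the genome-wide 95th percentile; passing windows are
grouped into runs tolerating gaps up to one window length, and the longest
run is reported together with the single most extreme window as the peak
(ties toward the smaller coordinate).  The gap tolerance matters: on a
fine step grid the linkage plateau around a causal locus spans many
overlapping windows, and sampling noise decides which of them clear a
genome-wide quantile threshold; requiring strict adjacency fragments the
plateau and occasionally reports a flank instead of the locus.

No simulation-based confidence envelope is computed; thresholding is by
the genome-wide |Δ| quantile.

## Selective-sweep scan

The scan compares a putatively selected ("high") group against a reference
("low") group in 50-kb windows stepped by 10 kb.  Per window:

* π per bp = Σ 2p(1−p)·n/(n−1) / L over SNPs in the window, with p the
  alt frequency and n the allele sample size at the site.  The denominator
  is the full window length — invariant-site counts are unavailable from a
  SNP-only matrix, and the constant denominator cancels in the ratio.
* Tajima's D = (θ̂_π − θ̂_W)/√(e₁S + e₂S(S−1)) with the classical
  constants a₁…e₂.  The variance formula assumes a fixed allele sample
  size, so with missing data the window uses its modal n and excludes
  sites deviating from it by more than 20% (configurable); D is undefined
  (NaN) when S = 0 or n < 4.
* F_ST is the Hudson ratio-of-sums estimator (the Bhatia et al.
  recommendation): numerator (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)
  and denominator p₁(1−p₂) + p₂(1−p₁), summed over sites before dividing.

Windows in the lowest 5% of π_high/π_low, the most negative 5% of
D_high − D_low, and the highest 5% of F_ST are selected; the default
combines the three by intersection (union and any-two are available).
Thresholds are empirical order statistics over windows where each
statistic is defined, ties included.  Two deliberate choices:

* The "D ratio" between groups is operationalised as the difference
  D_high − D_low: a ratio of signed, near-zero quantities is unstable.
* A window whose D_high is undefined because the high group has **no**
  segregating sites — while the low group still does — counts as hitting
  the D criterion.  Complete loss of variation is the extreme of the
  rare-variant signal, not an absence of evidence; without this rule a
  strong sweep (where the selected group is fully swept) could never be
  selected in intersection mode.  Such windows stay out of the threshold
  quantile itself.

Selected windows are merged (overlapping or abutting) into sweep regions
and genes overlapping ≥ 1 bp are attached via an interval tree.

## Gene-origin assignment

Each query gene is aligned against every donor species' candidate
orthologs with a self-contained affine-gap Smith–Waterman (match +1,
mismatch −2, gap open −5, gap extend −2; a length-L gap costs
open + L·extend; `N` matches nothing and scores as a mismatch).  The
species attaining the strict maximum score is assigned, provided the score
reaches `min_score` and beats the runner-up by `margin` (both default 0);
ties are "ambiguous".  The margin generalises a bare argmax; at the
defaults the behaviour is exactly best-score assignment with ties
ambiguous.  The inner DP loop is JIT-compiled with numba, with a pure
Python fallback.

Gene families are classified from a presence/absence matrix: *core* =
present in every species, *specific* = present in exactly one,
*dispensable* = anything in between.

## 4DTv

A site is eligible iff both codons are fourfold degenerate under the
standard code, share their first two positions, and contain no gap or
ambiguity; differences at positions 1–2 disqualify the site (the
conservative standard).  The statistic is the raw proportion of eligible
third positions differing by a transversion; block values pool counts over
gene pairs (ratio of sums — a pair with more eligible sites weighs more
than in a mean of per-pair ratios).  No multiple-substitution (HKY-style)
correction is applied.

## Synthetic data: what it emulates, and what it does not

* **BC₁ population** (`simulate_bc1`): donor parent homozygous for the alt
  allele at 500 markers over a 25-Mb chromosome; each offspring is one
  recombinant F₁ gamete (Haldane map, no interference, 4 cM/Mb — a typical
  plant genome-wide average) plus a recurrent gamete; resistance is
  dominant at the causal marker (6.5 Mb); 20/20 phenotype pools at read
  depth 50 with binomial read sampling.  Real data add genotyping error,
  depth variation, segregation distortion and marker-density
  heterogeneity, none of which are modelled — passing recovery tests shows
  the pipeline extracts the signal its model implies, not that it is
  robust to every artefact of real pools.
* **Sweep matrix** (`simulate_sweep`): 10 vs 27 samples, 10 Mb, one SNP
  per 500 bp, shared Beta(0.5, 0.5) background frequencies,
  Hardy–Weinberg genotypes, and a 100-kb interval where high-group
  frequencies are warped toward the nearer boundary (exponent γ, default
  8; γ = 1 is the null).  Frequency warping produces the three target
  signatures (low π, negative/undefined D, high F_ST) controllably at
  desk scale but has no linkage disequilibrium, no demography and no
  shared haplotype structure — a coalescent backend is a non-goal.
* **k-mer histogram** (`simulate_kmer_histogram`): Poisson coverage over
  G distinct single-copy k-mers plus depth-1 error singletons; no repeats
  or heterozygous branches.
* **Codon pairs / origin fixtures**: controlled third-position
  transversion/transition rates; queries diverged `near` (default 2%)
  from their true donor and `far` (default 10%) from the others,
  independent sites, no indels.

All generators are deterministic given a seed.

## Problem sizes and numerical checks

Statistic implementations are checked against independently coded
brute-force oracles (explicit allele enumeration and pairwise comparison,
quadratic-space alignment DP, exhaustive translation of all 64 codons) to
10⁻¹⁰ on ~1,000 random windows and 200 random sequence pairs.  End-to-end
recovery runs 100 BC₁ replicates and 50 sweep replicates at the design
points above — sizes chosen so the whole suite completes in well under a
minute per stage on one CPU while keeping binomial confidence intervals
tight enough to be meaningful.

## Known limitations

* Window π assumes SNP-only input; with invariant sites present the
  denominator convention would over-count window length.
* Tajima's D with heavy, unevenly distributed missingness discards sites
  far from the modal allele count rather than re-weighting them.
* The aligner computes scores, not alignments; no traceback is kept.
* The BSA caller's quantile threshold is genome-wide; on very small or
  single-chromosome inputs the top-5% set is narrow and the gap-tolerant
  merge is what keeps the call stable.
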