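# Methods

`binqtl` implements the analysis path from sparse, low-coverage
genotyping-by-sequencing (GBS) observations on a large biparental
recombinant-inbred-line (RIL) population to a recombination-bin map, a
genetic map, and minor-effect QTLs, together with a synthetic-data
generator that reproduces the statistical structure the pipeline
assumes. This note records the models, the parameters that matter, the
numerical choices, and the limits of what the bundled simulations can
demonstrate.

## The population and observation model (synthetic data)

The generator produces an F1 between two fully homozygous parents (P1,
P2) and selfs it for `n_selfing_generations` (default 6, giving F7
lines) under single-seed descent: each generation, two gametes are
drawn from the current individual and form the next. Per meiosis, the
crossover count on a chromosome is Poisson with mean equal to its
genetic length in Morgans; crossover positions are drawn uniformly, or
from an optional per-Mb intensity track when a structured
recombination landscape is wanted. Crossover interference is not
modelled: counts are pure Poisson and positions independent. Residual
heterozygosity therefore decays as (1/2)^g per site, 1.5625% at F7,
which the tests verify against a three-state Markov-chain oracle.

GBS observation is modelled at the SNP-call level, not the read level.
Each parental SNP is observed in each line independently with
probability `site_sampling_rate` (default 0.08: at ~0.08x depth a site
is effectively seen at most once, so deeper read-level simulation adds
nothing the caller would consume). A true heterozygous site emits one
parental allele at random. The emitted allele is miscalled as the
other parent with a parent-specific error rate (defaults 0.006 for P1
calls and 0.009 for P2 calls, the two parental GBS error rates the
pipeline is designed to tolerate). The default SNP scaffold spaces
parental SNPs every 4 kb so that sampling at 0.08 leaves roughly one
observed SNP per 50 kb per line — the working marker density of a
dense GBS panel. Restriction-site structure, barcode handling and
alignment artefacts are out of scope; error is i.i.d. per site, which
matters for interpretation (see Limitations).

Phenotypes are additive: y_ij = mu + env_j + sum_k a_k x_ik + e_ij
with x in {-1, 0, +1} coding {P1, HET, P2} at each planted locus and
Gaussian residuals. Backcross progeny of an introgression line inherit
the donor's heterozygous segment with probability 1/2 (one dose,
phenotype shift effect/2), with optional recombination inside the
segment.

## Genotype calling

The caller slides a 15-SNP window one SNP at a time over a line's
observed sites and calls the window homozygous for a parent when
strictly more than 11 of 15 sites carry that parent's allele,
heterozygous otherwise. With per-site error at 0.9%, the probability
of calling the opposite homozygote inside a true homozygous tract is
the binomial tail P(X >= 12 | 15, 0.009) < 1e-18 — error robustness is
structural, not tuned.

Crossovers appear as short runs of heterozygous windows. Maximal HET
runs shorter than seven windows are treated as breakpoints: flanked by
two different homozygotes they are split at the run midpoint (odd runs
give the extra window to the left — an arbitrary, fixed tie-break);
flanked by the same genotype they adopt it; at chromosome ends they
adopt the single flank. Runs of seven or more windows are genuine
residual heterozygosity and are kept.

Window calls map back to per-SNP genotypes by window centre (edge SNPs
take the terminal window's call); same-genotype SNP runs become
physical blocks, with the boundary between adjacent blocks at the
midpoint between their flanking observed SNPs and terminal blocks
extended to the chromosome ends. Filters, all strict inequalities
(ties keep the item):

* blocks with fewer than 5 observed SNPs or shorter than 300 kb are
  set missing (guarding against false double crossovers);
* runs of consecutive *small* called blocks (below the heterozygous
  block minima) showing at least 3 genotype switches within any 10
  such blocks are consolidated into one heterozygous block. Limiting
  the rule to small blocks is deliberate: applied to all blocks it
  would consolidate ordinary chromosomes, since 3-4 real crossovers
  among the ~6 large blocks of a normal chromosome are expected, and
  simulations showed whole chromosomes erased that way. The switch
  count and span are `CallerConfig` knobs;
* heterozygous blocks with fewer than 15 SNPs or shorter than 1 Mb are
  set missing;
* same-genotype blocks separated only by missing runs are merged.

Lines with more than 15% heterozygous called length or more than 360
breakpoints are excluded. Heterozygosity is measured over called
physical length (not block count), a convention this package fixes
explicitly. On the default simulation the caller recovers >= 95% of
crossovers whose flanking segments survive the block filters (>= 90%
of all true crossovers — segments below the 300 kb floor are
invisible by design) and >= 99% length-weighted genotype concordance.

## Bin map, distortion screening, imputation, genetic map

Bin boundaries are the union of all retained lines' block boundaries
per chromosome; bins shorter than 5 kb merge into their right
neighbour (left at the chromosome end), and a merged bin takes the
genotype of the largest-overlap block per line. Segregation distortion
is screened two ways: bins with a parental-frequency ratio above 2/1
or heterozygous frequency above 15% are discarded outright, and a
chi-square goodness-of-fit against 1:1 (HET/missing ignored, df = 1,
Bonferroni over testable bins, flag at adjusted p < 0.01) reports the
distortion landscape. The hard discard runs before the chi-square
screen; the order is configurable.

For mapping, heterozygous cells are set missing and every missing cell
is filled by most-probable-path (Viterbi) decoding of a two-state
Markov chain per line and chromosome: transition probabilities between
adjacent bins are their observed discordance fractions R (floored at
1e-4), emissions are correct with probability 1 - epsilon
(epsilon = 1e-4). A single pass is used; the transition estimates come
from the same adjacent discordances that define the map, so a second
map-impute iteration changes nothing material on simulated data.

The observed recombinant fraction R between selfed-RIL bins reflects
generations of meiosis; the per-meiosis fraction is recovered by the
Haldane–Waddington fixed point R = 2r/(1+2r), i.e. r = R/(2(1-R)),
clamped to [0, 0.5). The tests verify this against a brute-force
two-locus selfing recursion iterated to fixation. Map distances use
the Kosambi function d = 25 ln((1+2r)/(1-2r)) cM, with the exact
inverse r = tanh(d/50)/2 (round-trip < 1e-12). The map is built from
adjacent-bin intervals only — with thousands of bins in physical
order, the chain structure makes full multipoint re-estimation
redundant; this is an intentional simplification relative to
EM-based multipoint map estimation. Mean adjacent interval is
reported both as total/(bins-1) and as the mean of midpoint-to-
midpoint intervals, since summary-table conventions differ.

The recombination landscape divides each adjacent-bin interval's cM
over fixed 1-Mb windows in proportion to physical overlap of the
midpoint-to-midpoint span, yielding cM/Mb per window plus SNP density
and Pearson correlations against any supplied per-window annotation
track. Crossover counts are genotype transitions between consecutive
called bins within a line; the simulator additionally reports the
cumulative meiotic crossover count (most meiotic crossovers leave no
trace in an inbred mosaic, so the two conventions differ several-fold
and both are exposed).

## QTL scanning

With ~100 kb bins there is nothing between adjacent markers to
interpolate, so composite interval mapping is realized as marker
regression at each bin with background cofactors — the dense-map
analogue of CIM and the one intentional methodological simplification
in this module. Cofactors are chosen by forward stepwise regression
(partial-F entry at p < 1e-3, at most 5), and any cofactor within
`cofactor_window_cM` of the tested bin on the same chromosome is
dropped from both models at that bin. The default window is 30 cM:
with minor-effect QTLs the stepwise cofactor can land 10-20 cM from
the causal bin, and a narrower window then leaves it in the model at
the causal position, absorbing the linked signal and displacing the
reported peak — recovery simulations showed interval coverage
collapsing from ~100% to ~50% at a 10 cM window. The score is

    LOD = (n/2) log10(RSS_reduced / RSS_full) = -(n/2) log10(1 - rho^2)

with rho the partial correlation of the bin against the
cofactor-residualized phenotype; with no cofactors this is exactly the
single-locus least-squares LOD, an identity the tests check to 1e-9.

Genome-wide significance is the empirical (1 - alpha) quantile
(conservative `higher` interpolation) of the per-permutation maximum
LOD over phenotype permutations (default 1000, alpha 0.05), with
cofactors reselected inside every permutation so the null accounts for
selection. Permutations draw from the sorted multiset of phenotype
values, making the threshold exactly invariant to line relabelling.
Calibration at 200 permutations puts the family-wise error within
binomial bounds of the nominal 5%.

Peaks are local maxima at or above the threshold; two maxima on one
chromosome stay distinct only if the profile between them drops at
least 1.5 LOD below the lesser one. The support interval is the span
of bins within 1.5 LOD of the peak inside the peak's basin (basins
split at the deepest valley between retained peaks), extended one bin
outward — span semantics, because on dense maps the profile is jagged
at the 0.01-LOD scale and a strict contiguous-run rule truncates
intervals at meaningless dips. Additive effect and PVE come from the
single-locus fit on parental homozygotes: a = half the class-mean
difference (positive when the P2 allele increases the trait),
PVE = 100 R^2.

## Multi-environment phenotypes

Line values for scanning are BLUPs from y_ij = mu + env_j + g_i + e_ij
with environments fixed and lines random; variance components by REML
(statsmodels MixedLM) with a closed-form method-of-moments fallback
for degenerate fits. Replicates, when present, pool as additional
observations; the field-trial block structure is simplified to
environment + line terms because block layouts are not part of the
data model. Heritability is reported on the entry-mean basis
h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 / n_env) — the convention is
declared rather than inferred, and is written into output metadata.

## Progeny-test verification

A recombinant introgression line heterozygous over a known segment,
backcrossed to the recurrent parent, yields progeny segregating 1:1;
a two-sample t-test between the heterozygous and homozygous classes
places the QTL inside the segment (p < alpha) or outside it.
Refinement is set algebra: intersect the segments of significant
families, subtract the segments of adequately powered non-significant
families, clip to the prior interval. Non-significant families whose
smaller class has fewer than 20 progeny are recorded as weak evidence
and not subtracted — an underpowered negative excludes nothing. An
empty result raises a contradiction flag instead of an interval.
Marker genotypes are taken as error-free (PCR-grade markers).

## Problem sizes used by the test and reproducibility suites

The bundled experiments run at desk scale: calibration uses 100 null
traits on a 500-line x 500-bin matrix with 200 permutations; recovery
uses 20 replicates of 500 lines x 2000 bins with planted QTLs of 8, 5
and 2% PVE; the end-to-end smoke run simulates 200 lines on two 150 Mb
chromosomes. These sizes were chosen as the smallest at which the
statistical claims under test (calibration bands, power at the stated
effect sizes) are meaningful.

## Limitations

* Error is i.i.d. per site; real GBS error clusters near paralogous
  regions, so real-data robustness may be worse than the binomial-tail
  argument suggests.
* No crossover interference; map-function behaviour under strong
  interference is untested.
* The scan is single-QTL marker regression with cofactors; closely
  linked QTLs in repulsion within one cofactor window can still be
  mis-estimated, and no multiple-QTL model or epistasis scan is
  provided.
* The 2% PVE planted QTL sits near the power boundary at 500 lines by
  design; its detection rate is reported, not guaranteed.
* Passing simulation suites demonstrates internal consistency of the
  implementation under the generator's assumptions, not performance on
  real populations with segregation-distorting loci, structural
  variation or genotyping batch effects.
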