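# Methods

`paleoclock` measures molecular traces of reproductive control in time-series
of low-coverage, pseudo-haploid genomes: per-genome generation counts from a
mutation clock and a recombination clock, close-kin mating from runs of
homozygosity (ROH), and temporal shifts in generation time from a weighted
penalized-spline regression. Because real ancient-genome panels are large and
access-restricted, every stage is validated against a serial-coalescent
synthetic-data generator that reproduces the data-generating process the
estimators assume: serially sampled haploids, diploid pairing,
pseudo-haploidization.

## The synthetic cohort generator

`simdata` simulates a single panmictic population under a piecewise-constant
demography (10 stock scenarios: constant size, contractions and expansions of
several magnitudes and onset times, with and without recovery) using
msprime's coalescent with recombination. Haploid lineages are sampled in
cohorts of 20 every 100 generations from 900 generations ago to the present.
Within each time bin haploids are randomly paired into diploids (random
mating); the most recent bin is self-paired — each haploid duplicated into a
fully homozygous diploid — to emulate the elevated inbreeding of modern
cohorts. Finally each diploid is pseudo-haploidized: one allele drawn
uniformly per site, independently across sites, mimicking the standard
ancient-DNA genotype proxy.

Mutations follow an infinite-sites binary model, polarized to the
simulator's true ancestral allele (a perfect outgroup), and all variants are
labelled transversions: the real-data transversion filter is an ascertainment
step orthogonal to the clocks' arithmetic, so modelling a Ti/Tv mixture would
only dilute the site count without exercising anything new. No sequencing
error or post-mortem damage is simulated; coverage variation is emulated at
the call level by independent allele dropout (`genotypes.downsample_calls`).
Consequences: passing recovery tests demonstrate the estimators' statistical
behaviour under idealized calling, not robustness to damage, contamination,
reference bias or polarization error. Polarization stress can be probed
separately by corrupting the outgroup table fed to `genotypes.polarize`.

Default genome scale is 4 chromosomes x 10 Mb with mutation rate 2.3e-8 and
recombination rate 1e-8 per bp per generation (1 cM/Mb), i.e. a ~25x
downscaled genome at the real per-bp rates; the full-scale design (31 x
75 Mb) is available through `SimulationDesign`. The constant-size validation
demography uses Ne = 1,000 diploids so that the expected genealogy depth
(~4Ne = 4,000 generations) makes the 900-generation sampling window a
substantial fraction of the tree, as in a domestication-era time series.
Seeds are split hierarchically (one child seed per chromosome plus one for
pairing), so outputs are bit-stable for a fixed seed.

### Genealogical truth

For each marginal tree the root-to-sample path length in generations is the
root time minus the sampling time. With fully coalesced trees (one root per
marginal tree) the span-weighted mean path equals the span-weighted mean
root height minus the sampling time, which is what `CohortTruth` records per
diploid. Two consequences used by the tests: within one simulation the true
path difference between two sampling bins is exactly their age difference,
and the mutation clock's target pi/mu equals this mean path.

## Site matrix and filters

`genotypes.SiteMatrix` holds calls in {0 ancestral, 1 derived, -1 missing}
over 1-based positions, plus per-sample callable genome lengths. The
canonical ancient-DNA filter cascade is: transversions only (A/C, A/T, G/C,
G/T) -> outgroup polarization (a site is oriented when all non-missing
outgroups, of up to three, agree and the agreed allele is one of the site's
two alleles; everything else is dropped; a stricter all-three rule is
optional) -> missingness (a site missing in >= 30% of samples is dropped;
the boundary is inclusive) -> adjacency thinning (one randomly chosen site
retained per maximal run of consecutive-bp sites). All filters are
idempotent and only remove sites.

The derived fraction pi_i divides derived calls by the *callable* genome
length (variant plus invariant assayed sites), not by the SNP-panel size;
using panel sites alone would make the mutation clock depend on
ascertainment. Allele dropout rescales the callable length by the retention
probability, keeping pi_i unbiased. Pseudo-haploid calling from read counts
requires two reads (configurable) and draws one read uniformly otherwise.

## Genetic map and windows

`genmap.GeneticMap` interpolates physical to genetic coordinates linearly
between anchors; beyond the terminal anchors positions clamp to the terminal
cM value — off-map sites fall into terminal windows rather than inventing
recombination outside the map. Windows tile each chromosome's mapped span in
half-open 1-cM intervals anchored at the first mapped position (the last
window may be shorter; the final mapped position closes into it). Synthetic
mode uses a uniform 1 cM/Mb map matching the simulated recombination rate.

## ROH and close-kin detection

Inbreeding is profiled without allele frequencies: two alleles are sampled
independently per site (two reads in real data; two seeded draws from the
diploid genotype in synthetic mode) and the mismatch rate is computed per
1-cM window. A true heterozygote yields mismatching draws with probability
1/2, so windowed rates sit at half the true heterozygosity; the 0.005 ROH
threshold is calibrated on that same two-draw scale and no correction is
applied. Windows need at least 20 informative sites (an artifact choice;
sparse windows are flagged missing and *break* ROH runs rather than bridging
them — conservative against false long ROH in sparse data). Windows with
rate strictly below 0.005 are ROH; maximal runs of contiguous ROH windows
merge into segments with boundaries at window edges (no sub-window
refinement). Genome fractions are reported in the size classes [1,2), [2,4),
[4,8), [8,15), [15,inf) cM, and a genome is flagged close-kin when any
segment reaches 15 cM. The genetic-distance (cM) frame is used throughout
for consistency with the 1-cM windows; a physical-frame variant would simply
substitute the map. Note that detecting the [15,inf) class requires
chromosomes longer than 15 cM, hence the ROH validation cohorts use 25-Mb
(25-cM) chromosomes.

## Mutation clock

G_mut = pi_i / mu estimates the number of generations separating genome i
from the ancestral sequence, with mu on the scale of the retained sites
(transversion-rescaled in real data; the simulated rate in synthetic mode).
Sampling s generations before present removes s generations of mutation
accumulation, so the regression of G_mut on sampling time has slope -1 —
the generator-based recovery check. Per-sample variance comes from a
leave-one-chromosome-out jackknife: var = (m-1)/m * sum((theta_j - mean)^2).

## Recombination clock

The observable is, per genome, the probability that two called
same-chromosome SNPs at genetic distance d are both derived, in bins of d
(bin edges in milliMorgans). The statistic is computed *exactly* over all
pairs with windowed prefix sums (O(bins x sites) per genome, the count of
derived partners in a distance window being a difference of prefix sums);
seeded per-bin subsampling remains available but is no longer a
computational necessity. An exhaustive double-loop oracle verifies the fast
path on small instances.

On a panel of segregating sites, the ancestral state at a locus is the local
tree root, whose height r(x) fluctuates along the genome. A genome sampled s
generations ago carries a derived allele with per-site probability
proportional to its root-to-sample path t = r - s, so

    P_i(both derived at d) = m^2 [ C(d) + t_i^2 ],        C(d) = Cov(r(x), r(y)),

with m the per-panel-site mutation scale. The root-height autocovariance
C(d) decays with genetic distance at a rate set by the sample set's
genealogy — it is *shared* by every genome, young or old. Dividing by the
squared panel derived fraction (pi_i ~ m t_i) gives the fitted observable

    N2_i(d) = P_i(d) / pi_i^2 = p_i (1 + C(d) / t_i^2),

so each genome reads out in the *amplitude* of the shared decay curve:
older genomes (shorter paths) show larger normalized excess. An earlier
design iteration assumed the opposite — a per-sample decay *rate*
exp(-d t_i) from haplotype survival — and produced inverted recovery on
simulated cohorts; the amplitude parameterization above is the one the
simulated data supports (the bin-0/bin-900 amplitude ratio matches
(t_900/t_0)^-2), and is what ships.

Fitting is joint weighted least squares over the nonparametric shared curve
C(d_b) (one value per occupied bin, constrained non-negative) and per-sample
amplitudes, solved by alternating linear least squares (each conditional
update is exact; convergence by the change in the normalized curve).
Weights are per-bin called-pair counts deflated for window overlap: pairs
sharing an anchor site are correlated, so a bin with n pairs over m sites
contributes roughly n / (1 + 0.25 n/m) independent units. The per-sample
nuisance amplitude p_i is fixed at 1 by default — appropriate when all
genomes were processed identically, as in the synthetic cohorts — and can be
freed (`nuisance="intercept"`) to absorb depth- and error-driven amplitude
variation in heterogeneous real panels.

C(d) and {t_i} trade off by an exact gauge freedom (C -> c^2 C, t_i -> c
t_i), so the pair data identify all path lengths only up to one global
scale. The scale is anchored by matching the geometric mean of t_i to the
geometric mean of the mutation-clock estimates; relative values, time-bin
differences and rank orderings come from the pair statistic alone. The
reported T is this anchor scale. Jackknife variances refit after dropping
each chromosome from both the curves and the anchor.

Desk-scale precision: on a 40-Mb genome the per-sample amplitude noise
corresponds to a t_i standard error of roughly 200 generations, so per-bin
means (10-20 genomes) recover the 900-generation serial gap within 15%,
while per-sample rank correlation with truth plateaus near 0.89 — a genome-
length information limit, not an estimator artifact; at 31 x 75 Mb the same
noise shrinks by ~sqrt(58) and the correlation is effectively 1. Default
distance bins are 40 log-spaced bins over 0.1-100 mM for deep genealogies;
the desk-scale cohorts use 50 log bins over 0.005-30 mM, matching where
their C(d) support lies (decay scale ~1/(4Ne) Morgans).

## Generation-time trend

`trends.fit_generation_trend` regresses generations-since-MRCA on calendar
date (signed years, BCE negative) with a cubic B-spline in date (default
basis dimension 20) plus linear covariates (structure coordinates, depth
proxy), weighted by inverse jackknife variances. The smoothing penalty is
selected by generalized cross-validation on a log grid (the backend's
built-in selector is unusable in the installed statsmodels version, so the
GCV loop is implemented directly). A weighted linear fit provides the null
for an approximate F-test of linearity using effective degrees of freedom.
Degenerate inputs: rank-deficient designs raise an error naming the
collinear columns; exactly-interpolated (zero-residual) responses are
refitted with a negligible deterministic jitter because the IRLS backend
rejects perfect fits.

Dates and generations both increase toward the present, so the date
derivative of the smooth is positive and its reciprocal is the generation
time in years. The derivative uses central finite differences with a 1-year
step (indistinguishable from the analytic basis derivative at the spline's
scale), with pointwise bands by the delta method on the smooth coefficients;
per-1,000-year-bin values average the derivative over a 25-year grid. Bins
whose derivative is not positive report NaN rather than a negative
inversion. The per-bin band ignores covariance between grid points within a
bin, which makes it slightly conservative. A spline cannot be epoch-pure
within one smoothing bandwidth of a rate change, so bins adjacent to a
change date absorb part of the transition; recovery assertions therefore
target bins at least one bin away from the change.

The long-term average generation time is the reciprocal of the weighted
linear slope of generations on date over the most recent 15,000-year window.

The two-epoch validation cohort (`simulate_piecewise_cohort`) draws n = 200
dates uniformly over 8,000 years, accumulates generations at 1/8 then 1/4
generations per year after the change date, and adds Gaussian noise with SD
30 generations — the scale of leave-one-chromosome-out jackknife errors for
desk-scale recombination-clock estimates — with var_jk set accordingly, so
inverse-variance weighting is correctly specified. Detection power at this
noise level: the linearity F-test rejects at alpha = 0.01 in ~100% of
replicates, and the largest consecutive-bin generation-time drop falls in
the bin starting at the change date.

## Calendar arithmetic

`chronology` converts generation counts to calendar years BCE on a
continuous signed-year axis (the historical absence of year 0 is ignored —
inert for prehistoric dates). `date_before(anchor, n, g)` returns anchor +
n*g rounded to the nearest year; `gen_time_from_fold` divides a long-term
average by a fold-acceleration, rounded to one decimal for reporting;
`calbp_to_bce` subtracts 1950. The worked examples reproduced by the tests:
80 generations of 8 (7-12) years before 3500 bce gives 4140 (4060-4460)
bce; 100 generations before 1864 bce gives 2664 (2564-3064) bce; a 2.1-fold
(1.8-fold) acceleration of a 7.4-year average gives 3.5 (4.1) years.

## Known limitations

- Single panmictic population; no migration, selection, or multi-population
  structure in the generator.
- No damage, sequencing error or contamination model; dropout only.
- The recombination clock's absolute scale is calibrated against the
  mutation clock; a systematic bias in mu or in polarization propagates to
  t_i through the anchor (relative comparisons are unaffected).
- Real-data mode expects pre-called pseudo-haploid VCFs; no BAM-level
  processing.
- The close-kin flag is a threshold rule on the longest ROH class, not a
  likelihood-based kinship estimate.
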