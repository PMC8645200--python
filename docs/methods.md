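# Methods

## Scientific setting

`sdscan` implements a singleton-density selection analysis for a diploid
population that has passed through a strong recent bottleneck, modelled on
domesticated cattle (Holstein-type demography: present-day diploid Ne of
order 10^2–10^3, pre-domestication Ne of order 10^4–10^5, ~5 years per
generation).  A recent rise of a derived allele shortens the external (tip)
branches of the genealogy of its carriers, depleting the singletons that
accumulate on those tips.  The package scores this depletion per SNP,
standardizes scores within derived-allele-frequency (DAF) bins, tests trait
QTL sets for a collective signal, and quantifies by simulation both the
timescale over which the statistic is informative and its power under the
bottleneck.

## The singleton-density score

### Gap model

For a test SNP at position x on a chromosome of length L, each individual
contributes the distance from x to its nearest singleton upstream and
downstream ("gaps").  Singletons on a haplotype are modelled as a
homogeneous point process with intensity proportional to that haplotype's
tip length, so for an individual whose two tips have lengths (t1, t2) each
gap is Exponential with rate c·(t1+t2).  Genotype classes at the test SNP
(0, 1, 2 derived copies) map to tip pairs (ta,ta), (ta,td), (td,td); the
heterozygote rate is constrained to the mean of the homozygote rates
(additivity of tip lengths).  A side with no singleton contributes an
exponential survival term censored at the distance to the chromosome end;
singletons at x itself are ignored.

### Estimation

Writing λ0, λ1 = (λ0+λ2)/2, λ2 for the class rates, the log-likelihood
depends on the data only through the per-class number of uncensored sides
U_g and total gap length T_g.  Given the ratio ρ = λ2/λ0 the overall scale
has a closed form, so the MLE is found by a one-dimensional bounded search
on log ρ (profile likelihood, |log ρ| ≤ 25, xatol 1e-10).  The raw score is

    raw SDS = log(ta_hat) − log(td_hat) = log λ0_hat − log λ2_hat,

positive when derived tips are shorter, i.e. the derived allele has risen
recently.  The returned value is the antisymmetrised estimator
(fit(D) − fit(swap(D)))/2, identical to the MLE in exact arithmetic and
exactly antisymmetric under exchanging the genotype labels 0 and 2 in
floating point.

A score is *undefined* when (i) fewer than a configurable number of
individuals have at least one uncensored side (default: undefined when more
than 10 individuals lack one — the threshold through which a bottleneck
destroys power), or (ii) either homozygote class contributes no uncensored
observation.  Condition (ii) is not cosmetic: the heterozygote likelihood
constrains only λ0+λ2, so without a direct observation of one homozygote
rate the profile likelihood can increase monotonically toward an infinite
log-ratio and the MLE does not exist.

### Information scaling and standardization

The sampling spread of the raw log-ratio varies enormously between SNPs
(local singleton density, genotype-class counts, censoring), so raw scores
are not comparable across sites.  Each score is therefore divided by its
asymptotic standard error from the observed Fisher information of the
two-parameter likelihood (a Wald score) before standardization; the
information matrix has a closed form in (log λ0, log λ2) coordinates.
Scores are then z-scored (population SD) within DAF bins of width 0.05,
giving sSDS with exact per-bin mean 0 / SD 1; bins with fewer than two
scores are dropped.  On data simulated from the gap model at cohort sizes
around 100, sSDS is indistinguishable from N(0,1) by a Kolmogorov–Smirnov
test at 2,000 scores.  Genuinely coalescent (rather than model-generated)
panels need cohorts of roughly 50 diploids or more before this calibration
is reliable; at a dozen individuals the per-individual singleton counts are
so overdispersed by genealogical noise that DAF bins become mixtures over
genotype configurations and the scan's tails are inflated.  The shipped
scan-level type-I check therefore uses 50-diploid cohorts.

### Significance and annotation

P-values come from the standard-normal upper tail by default (the scan
targets significantly *high* sSDS; a two-sided option exists), q-values
from Benjamini–Hochberg, and the family-wise cutoff from Bonferroni at
alpha/m.  Candidate genes are those whose interval, expanded by a 10-kb
flank on both sides (closed), contains a significant SNP — 10 kb because
linkage disequilibrium in dairy-cattle breeds stays appreciable over that
range.  tSDS re-signs sSDS so positive values mean selection for the
trait-increasing allele; SNPs with unknown orientation are excluded.

## Variant and singleton filters

Sites must be biallelic SNPs with mean depth inside configurable bounds
(default 0.5–2× the genome-wide mean; no canonical cutoffs exist for this
kind of cohort, so the bounds are editable), call rate
≥ 0.9, and position outside detected over-assembled regions (OARs).
OARs — collapsed duplications that masquerade as selection signals — are
called by 10-kb sliding windows (5-kb step) in which *both* mean depth and
mean heterozygote fraction exceed the genome-wide window mean + 3 SD;
flagged windows are merged.  Requiring the two signals jointly reflects
what a collapsed duplication does (reads from two loci pile onto one),
and keeps either signal alone from spuriously masking real variation.

Polarization assigns the ancestral allele from outgroup calls: at least
`min_agree` outgroups must agree, the agreed allele must be one of the two
panel alleles, and any disagreement drops the site (conservative; with a
single outgroup a discordant call silently mis-polarizes the site, which is
why the synthetic generator plants a known fraction of discordant calls).
Singletons are sites with derived-allele count exactly one, carried
heterozygously, whose carrier has a derived-read fraction in [0.25, 0.75]
with ≥ 3 reads per allele, and whose site depth passes the depth bounds.

## Polygenic test

QTLs supported in at least `min_pops` of the contributing mapping
populations (default 6 of 7) are matched to the nearest scored SNP within
±10 kb (ties to the lower coordinate).  The test statistic is the Spearman
correlation between |log10 QTL P-value| (an effect-size proxy) and tSDS,
with an OLS slope reported for trend plots and an option to drop the
single most extreme effect proxy.  Because sSDS is autocorrelated through
LD, significance comes from a permutation null: each QTL SNP's score is
replaced by a uniformly drawn genome SNP from the same chromosome and DAF
bin (QTL SNPs excluded from the pools, so each stratum's marginal
distribution is preserved), and the one-sided upper-tail empirical p uses
the add-one correction (1 + #{ρ_perm ≥ ρ_obs})/(1 + n_perm).  A replacement
SNP has no trait annotation; by default its sign is flipped with
probability ½ per draw (the orientation of a random SNP relative to a
trait is arbitrary), with an "inherit the QTL's orientation" rule available
— neither convention is asserted as the original study's, which did not
state one.

## Coalescent studies

### Demography

Models are piecewise-constant diploid-Ne epoch lists.  The two shipped
Holstein-style models put the present-day Ne at 793 (sequence-based
estimate) or 49 (pedigree-based), declining log-spaced to an ancestral
70,000 at 2,000 generations.  These epochs are an explicit placeholder
with the right orders of magnitude; the files under `src/sdscan/data/`
are meant to be edited with published Holstein epoch estimates when exact
literature numbers are wanted.

### Tip ages

Mean tip age is the average external-branch length (generations) over
single-locus genealogies simulated with msprime on the diploid time scale;
for constant Ne the analytic total external branch length 4N gives 4N/n
per tip, which the simulations reproduce within confidence intervals.  A
log-log linear fit across sample sizes extrapolates the look-back horizon
to any cohort size (slope −1 for constant Ne; flatter under the decline).

### Sweep simulations

A partial sweep is simulated at the midpoint of a region with msprime's
structured sweep coalescent, conditioned to end at the configured current
frequency.  The default sweep is *young and strong* — s = 0.3 and a
current derived frequency of 0.2, a sweep phase of roughly 20
generations.  This choice is deliberate: under the bottleneck demography
the mean tip age at 204 sampled alleles is only tens of generations, so a
slow sweep (say s = 0.05, whose rise to 50% takes ~300 generations)
completes its coalescent restructuring *before* the window singletons can
see, and leaves no singleton-density signal at all.  Only sweeps whose
duration is within the tip horizon are detectable by construction of the
statistic, and only those reproduce the qualitative behaviour the method
is meant to probe (depleted carrier-class singletons, elevated sweep-site
sSDS, partially defined scores at the elevated mutation rate).  Both
parameters are configurable.

Two approximations are forced by the simulator and are applied identically
to both arms of every comparison:

* the sweep phase cannot process demographic events, so epoch changes
  earlier than a conservative sweep-duration bound (~(2/s)·ln 2N0, doubled
  on retry) are deferred to that bound — the population sits at present-day
  Ne during the sweep;
* the sweep model does not emit the selected mutation.  The derived allele
  is planted on the local-tree node whose sample fraction is nearest the
  target frequency; in the selected case that is the candidate with the
  most recent MRCA (the swept lineages coalesced during the sweep, whereas
  the complementary root-sibling subtree is ancient), and in the neutral
  case a candidate is drawn with probability proportional to the branch
  length above it, which is how a neutral derived allele at that frequency
  arises.  If no node lies within ±0.05 of the target the replicate is
  rejected and re-simulated (bounded retries) — frequency-matched controls
  by construction.

Mutation and recombination default to cattle-like rates (mu 1.2e-8 per bp
per generation; recombination mu/3.25, reflecting a mutation/recombination
ratio just over three).  An elevated-mutation variant multiplies mu by 10
while keeping recombination at the standard rate — it models a hypermutable
region, not elevated recombination.  Emitted panels are already polarized
(the simulation knows ancestral states) and carry noise-free depth fields,
so the scoring pipeline runs on them unchanged while read-level filters
pass vacuously.

The power study contrasts neutral and selected replicates at the sweep
site: per-individual singleton counts (total and split by genotype class
at the test SNP), the count of zero-singleton individuals (which drives
undefined scores), the fraction of replicates with a defined score,
pooled-standardized sSDS per case, and a two-sided Wilcoxon rank-sum
comparison.  Watterson's estimator (theta_W = S/a_n,
Ne = theta_W/(4 mu L)) converts segregating-site counts into the
equivalent constant Ne, a one-number summary of how the bottleneck caps
diversity.

One result of this reconstruction deserves emphasis.  In the sampling
regime of interest — hundreds of haplotypes drawn from a present-day Ne
of a few hundred — the expected *total* external branch length of a
coalescent tree is ~4N irrespective of the number of samples.  A partial
sweep therefore redistributes singletons rather than removing them: the
carrier class is stripped (derived-allele carriers at the sweep site
retain a few percent of the neutral singleton load), but the non-swept
class, having lost coalescent partners, regenerates essentially the full
neutral budget on its own, and the background partitioning during the
sweep phase can push the cohort-wide total *above* neutral.  Across the
parameter ranges explored (s 0.05–0.5, current frequency 0.1–0.9, regions
1–10 Mb), the net per-individual singleton count in the selected case
fluctuates around the neutral value with large genealogical variance and
shows no reproducible net reduction, while the carrier-class depletion and
the sweep-site sSDS elevation are robust in every configuration with a
sweep inside the tip horizon.  The shipped checks treat the class-level
depletion and score elevation as the sweep signal, and test the net-total
direction separately as a sign test over replicate pairs, which the reader
should expect to be unstable for the reason above.

### Problem sizes

The full-scale configuration (10-Mb regions, 102 diploids, 100 replicates)
remains the `SweepSimConfig` default.  The shipped checks run the contrast
at 3-Mb regions with 20 replicate pairs (30 in the standalone
reproduction script) at the elevated mutation rate — the smallest
configuration at which sweep-site scores are reliably defined under this
demography — and the tip-age grid at 2,000 replicates per point.  These
sizes are the package's own desk-scale choices; all are parameters, not
constants.

## Synthetic cohorts

The generator emulates a re-sequencing cohort's inputs end to end:
coalescent genotypes
under the bottleneck demography written as VCF v4.2 with GT and AD fields
(Poisson read depths around mean 12; heterozygote AD binomial(depth, ½);
singleton carriers forced to balanced, well-covered ADs), planted OARs
(depth ×2, heterozygosity forced to 0.9), planted midpoint sweeps, toy GFF3
genes tiled near sweep sites, QTL tables whose P-values couple to planted
sweep strength, and a JSON truth file sufficient to recompute every
expected outcome.  The derived allele is written as REF at ~30% of sites so
polarization is non-trivial, and the outgroup table carries configurable
missing (2%), discordant (1%) and third-allele (0.5%) fractions.

The outgroup is emitted from the simulation's known ancestral states rather
than from a simulated divergent lineage: the structured sweep coalescent is
single-population, so a genuinely co-simulated outgroup would preclude
planted sweeps in the same cohort.  Consequences: no ILS-driven
polarization error beyond the configured discordance, and outgroup error
is independent of local genealogy — both conservative simplifications for
testing the drop rules, not a model of real outgroup divergence.

A score-level generator (`generate_score_table`) emits a genome-wide sSDS
table plus QTL table directly, with the QTL scores rebuilt as
sign·(c·z_effect + sqrt(1−c²)·noise) for coupling c; c = 0 is an exact
null.  Permutation-test calibration (200 cohorts) runs at this level —
the permutation machinery consumes score tables, and cohort-level
simulation adds nothing to that check but cost.  The documented operating
point c = 0.5 gives rejection in a clear majority of cohorts.

What the generator does *not* emulate: real read-level error processes
(depths are independent Poisson draws), linkage between OAR artifacts and
genotyping error, multi-population structure, and real QTL architectures.
Passing tests on these cohorts therefore demonstrate the pipeline's
statistical behaviour under its stated model, not performance on any real
dataset.

## Numerical choices and degenerate inputs

* Profile-likelihood search bounded at |log ρ| ≤ 25; boundary solutions and
  non-convergence return "undefined" rather than a number.
* Gaps are clamped to ≥ 1 bp (a test SNP at a chromosome end would
  otherwise yield a zero-length censored gap).
* Degenerate (constant) margins in Spearman correlations give ρ = 0 instead
  of NaN; permutation p-values use the add-one correction throughout.
* Empty permutation strata raise an error naming the stratum rather than
  silently shrinking the null.
* Chromosomes whose singleton set defines no score are skipped with a
  warning (the analysis drops such chromosomes rather than emitting noise).
* All simulation seeds are drawn from a single `numpy` Generator per run
  and kept below 2^31; identical configuration + seed reproduces
  byte-identical output files.

## Known limitations

* The likelihood is a reconstruction of the singleton-density idea, not
  the original release: the published method regularizes tip lengths with
  demography-calibrated gamma priors, which are not reproduced here.  The
  Wald/bin standardization compensates empirically at cohort sizes ≳ 50.
* Holding Ne at the present-day value during the sweep phase slightly
  shortens deep coalescence times in the selected arm relative to a fully
  time-varying sweep; both arms share the approximation, so contrasts are
  unbiased to first order.
* The placeholder demography reproduces orders of magnitude, not published
  epoch-by-epoch estimates; tip-age extrapolations under it are indicative
  until real epochs are substituted.
* Unphased diploid genotype classes are assumed throughout; no use of
  phased haplotypes.
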