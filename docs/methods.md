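# Methods

This package implements a probe-level copy-number association (CNV-GWAS)
pipeline together with the surrounding analyses a biobank CNV study
needs: encoding of quality-scored CNV calls into dosage models,
genome-wide scans with conditional analysis, CNV-region definition and
cross-model merging, replication with directional p-adjustment and power
simulation, microarray-vs-WGS call concordance, and per-sample CNV-burden
analyses with modifier-region correction. A synthetic cohort generator
provides study material with the statistical structure the pipeline
assumes, so every stage is testable without access to restricted biobank
data.

## Model and rationale

CNVs called from genotyping arrays are uncertain in both identity and
breakpoints. The pipeline therefore works at the probe level: each call
carries a quality score QS in [-1, 1] whose sign encodes the type
(negative = likely deletion) and whose magnitude the confidence that the
call is real; calls with |QS| >= 0.5 are treated as high confidence.
Projected onto the probe grid, these give a probe x sample QS matrix
(0 = copy neutral), from which three biallelic dosage encodings are built
(alleles A/T, with T counting copies):

| QS class              | mirror | duplication-only | deletion-only |
|-----------------------|--------|------------------|---------------|
| deletion (QS <= -0.5) | 0 (AA) | missing (00)     | 2 (TT)        |
| copy neutral          | 1 (AT) | 1 (AT)           | 1 (AT)        |
| duplication (QS >= 0.5)| 2 (TT)| 2 (TT)           | missing (00)  |

The mirror model assumes each additional copy shifts the trait by a
constant amount (so deletion and duplication act in opposite directions);
the type-specific models estimate one type's effect while blanking the
other type's carriers, and together they can reveal U-shaped effects
(both types shifting the trait the same way). Under the mirror encoding
the T dosage equals CN - 1, which the tests assert as an invariant.

Per-probe frequencies are computed from the mirror encoding as
`100 * N_class / (N_cnv + N_neutral)` (percent, non-missing denominator),
and association scans are restricted to probes with the model-relevant
frequency >= 0.005% and genotype missingness <= 5%.

## Numerical and procedural choices

**QS boundary.** A call at exactly |QS| = 0.5 counts as high confidence
and is classed by sign; `strict_boundary=True` switches to strict
inequalities. When two retained calls hit one probe x sample cell (e.g.
nested events), the larger |QS| wins, keeping the matrix single-valued.

**Probe overlap.** A call covers a probe when the 1-based inclusive call
interval contains the probe position. All interval logic in the package
is 1-based inclusive; BED inputs are converted at the reader boundary.

**Trait preparation.** Traits are rank-based inverse-normal transformed
(Blom offset 3/8, ties averaged; the offset is configurable) and then
residualized on an intercept, sex, age, age^2, genotyping-batch dummies,
and principal components. The per-probe model is then a simple linear
regression of the prepared trait on dosage (residualize-then-regress).
This is marginally different from carrying the covariates inside each
per-probe regression; with covariates orthogonalized out beforehand the
difference is a degrees-of-freedom correction that is negligible at
biobank n, and the single-regressor form vectorizes across all probes.
Constant or linearly dependent covariate columns are dropped with a
warning rather than failing the run.

**Sign homogenization.** PLINK file sets store A1 as the minor allele
(ties to T), and regression runs on the A1 dosage; reported effects are
homogenized to the T scale by flipping the sign whenever A1 is "A", so
betas always read "per additional copy-counting allele".

**Pruning and effective tests.** Probes are pruned greedily left to
right at r^2 > 0.9999 in 500-probe windows stepped by 250 (windows never
span chromosomes; r^2 is pairwise-complete over missing cells;
zero-variance probes are removed first). Because retained CNV-proxy
probes remain highly correlated, Bonferroni correction uses an effective
number of tests: per chromosome, the probe correlation matrix (missing
dosages mean-imputed) is eigendecomposed and the number of leading
eigenvalues needed to reach 99.5% of total variance is accumulated
(simpleM-style). This is one of several Neff conventions in use; the
method tag is recorded on the estimate, and the genome-wide threshold is
always computed from the data at hand (0.05/Neff), never hard-coded.

**Conditional analysis.** The lead probe's dosage (missing cells
mean-imputed for the conditioning step only) is regressed out of the
trait and the scan repeated until no testable probe passes the
threshold; ties in p break by genomic position, and a 20-round cap
raises with diagnostics. Probes with fewer than two dosage classes among
phenotyped samples are reported with an `untestable` flag rather than
silently dropped.

**Regions and merging.** A CNV region is bounded by the most distant
probes within +/-3 Mb of the lead at r^2 >= 0.5 (the lead always
qualifies, so an uncorrelated lead yields a zero-length region).
Signals merge when they share the trait, overlap by >= 1 bp, and agree
in per-copy direction (deletion-only betas count with flipped sign);
agreement is required pairwise within a merged group, so a U-shaped
dup/del pair never merges. Merged regions keep union boundaries and the
most significant model's statistics; the output is invariant to input
order (union-find grouping, canonical sort).

**Exact tests.** The SNP-signal density test is an exact binomial:
successes = signals inside the union of a trait's regions, trials =
union length in bp, null rate = total signals / autosomal genome length
(2,881,033,286 bp), two-sided by the minimum-likelihood rule (stated
because two-sided conventions differ). Carrier-group comparisons use
Welch t-tests (the variance assumption is not pinned down by the study
design, so the unequal-variance form is the default), exact binomial
enrichment tests, and Fisher's exact test whose odds ratio is the
conditional MLE of the noncentral hypergeometric likelihood. The CMLE
solver is R-compatible by default: it reproduces `fisher.test`'s
branching and default root tolerance (Brent on the reciprocal scale,
tolerance eps^0.25), because R is the reference implementation against
which published odds ratios are read; on extreme tables that default
tolerance is visible in the third significant digit, and passing
`tol=1e-12` gives the fully converged estimate. A zero-margin table has
no defined OR and is flagged rather than raised.

**Replication.** For each discovery region the most significant testable
replication probe inside the discovery boundaries is selected under the
winning model (p ties break by position; regions with no testable probe
are flagged unassessable). Raw p-values are adjusted one-sidedly for
direction: p/2 on sign agreement with discovery, 1 - p/2 otherwise; a
zero replication beta counts as discordant (conservative). This map
preserves U(0,1) under random concordance, which is property-tested.
Power per signal is estimated by simulation: binary carrier genotypes at
the observed carrier frequency, trait = beta x carrier + N(0,1), and the
per-probe regression p-value, 10,000 replicates; simulations that draw
zero carriers yield missing p-values and are excluded from the power
denominator. The implementation samples the sufficient statistics of
that regression (Binomial carrier count, Gaussian group contrast,
scaled chi-square residual variance) rather than raw per-individual
vectors; the distribution of the test statistic is identical and the
cost is independent of cohort size. Expected replications = mean power x
number of assessed signals, exactly.

**Concordance.** WGS-style calls are merged across gaps <= 20% of the
merged span (greedy left-to-right per sample/chromosome/type, iterated
to a fixed point; the iteration order is a convention, and idempotence
is property-tested), then size-filtered (duplications < 1 kb, deletions
< 2 kb, anything > 10 Mb removed). Probe x sample profiles in
{-1, 0, +1} are compared by per-probe Pearson correlation across
samples; probes constant on either side have undefined r. Classes -
monomorphic, concordant (both-called, r >= 0.75), discordant
(both-called, lower r), apparent false positive (array-only), false
negative (WGS-only) - partition the probe set. An apparent false
positive is rescued when a probe within +/-250 kb whose *array* profile
correlates with it at r >= 0.5 itself shows high array-WGS concordance,
the signature of a fragmented or shifted WGS call rather than a wrong
array call.

**Burden.** Per-sample burden is the total load of high-confidence
autosomal CNVs, in affected Mb or in disrupted genes; a gene counts only
when a CNV overlaps a qualifying feature class (exon, splice site,
non-coding RNA, 3'/5' UTR), not merely the gene span. mb_cnv =
mb_dup + mb_del holds exactly. Zero-CNV samples contribute burden 0 to
regressions (they are informative about the null); sibling-sharing
fractions are undefined for them and skipped. Modifier correction
collects the trait's associated regions into a sample x region matrix G
(+1 duplication, -1 deletion; type-specific burdens zero the other type;
a sample with both types overlapping one region keeps the type with the
larger total overlap; a CNV overlapping several regions contributes to
each column), residualizes the trait on G, subtracts the region-
overlapping calls' full Mb/gene load from the burden (clipped at 0), and
reruns the regression. With no associated regions the correction is the
identity. Sibling sharing counts an index CNV as shared when the sibling
carries a same-type call on the same chromosome overlapping by
>= 25 kb; the control re-pairs index samples randomly without
replacement. The sex-difference test is a two-sided Wilcoxon rank-sum
(exact for small tie-free groups, otherwise normal approximation with
tie and continuity corrections, mirroring common statistical practice),
and cross-cohort burden effects combine by inverse-variance fixed-effects
meta-analysis.

## The synthetic cohort generator

The generator emulates the features of a biobank CNV landscape the
pipeline relies on: recurrent CNV regions with declared duplication and
deletion carrier frequencies (defaults in the study scenarios range
0.5%-5%, within the "individually rare, collectively common" regime;
the eligibility cut of 0.005% corresponds to the rarest testable
probes), uniform breakpoint jitter of +/-jitter_bp at each boundary
(truncated at chromosome edges - one parameter reproducing breakpoint
variability), true-call quality scores |QS| ~ U(0.5, 1) against spurious
calls at |QS| ~ U(0, 0.5) (placing truth and noise on either side of the
0.5 cut; the real QS distribution of the upstream scoring model is not
public, so these are conventions, not estimates), a per-call miss rate
that drops true calls below the confidence cut, Poisson-distributed
spurious calls per sample, round-robin plates of 96, covariates
(sex ~ Bernoulli(0.5), age ~ U(40, 70), PCs ~ N(0, 1), small fixed
coefficients - enough to exercise residualization without claiming
realism), sibling pairs that receive each index call with a set
transmission probability on top of an independent draw from the same
architecture (so random-pair sharing has its architecture-driven
baseline), and WGS-style call sets fragmented so that the gap-rule merge
can provably reassemble them.

Phenotypes follow the four effect models (mirror, dup-only, del-only,
U-shape) plus optional per-Mb burden effects and Gaussian noise, all
deterministic for a fixed seed.

What the generator does *not* model - LD with SNPs, intensity-level
data (LRR/BAF), CN states beyond {1, 2, 3}, population stratification,
non-uniform breakpoint distributions, genuine batch artifacts - bounds
what passing tests show: they validate the statistical machinery
(calibration, recovery of planted effects, invariances), not the
upstream calling pipeline or robustness to artifacts the generator does
not produce.

## Problem sizes

The test suite and the analysis scripts run on cohorts of 3,000-20,000
samples and 120-600 probes with two to forty CNV regions; power
simulations use 10,000 replicates per signal. These sizes were chosen so
that planted-effect recovery operates in the same
rare-carrier/large-n regime as a biobank scan while every check
completes in seconds.

## Known limitations

- The Neff convention (99.5% eigenvalue rule per chromosome) is one of
  several in the literature; absolute thresholds depend on it.
- The residualize-then-regress design slightly understates per-probe
  standard errors relative to a joint model (one lost degree of freedom
  per covariate at scan time); immaterial at the intended n.
- Chromosome X is handled as autosome-like dosage (the upstream
  convention of labeling all samples as one sex); hemizygous calling is
  out of scope.
- Homozygous CNV states (CN 0 or 4) are not modeled; observed cohorts
  show them to be rare, and the encoding collapses them into the
  carrier classes.
- The modifier-correction convention ties each burden type to its
  matching association model (total <- mirror, dup <- dup-only,
  del <- del-only); a purely U-shaped trait can retain a total-burden
  association after correction because no mirror-model region exists to
  correct with.
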