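# cnvgwas

A probe-level copy-number association (CNV-GWAS) pipeline for
quantitative traits, with the companion analyses a biobank CNV study
needs: replication in a second cohort, microarray-vs-WGS call
concordance, and per-sample CNV-burden analysis. It is aimed at
statistical geneticists who have PennCNV-style CNV calls with per-call
quality scores and want trustworthy CNV-trait associations despite rare
carriers, variable breakpoints, and noisy array calls.

## The model

Calls carry a quality score QS in [-1, 1]: the sign encodes the type
(negative = likely deletion), the magnitude the probability the call is
real, and |QS| >= 0.5 marks high confidence. High-confidence calls are
projected onto the array's probe grid and encoded as biallelic T-allele
dosages under three association models:

* **mirror** - dosage = CN - 1 (del 0, neutral 1, dup 2): each
  additional copy shifts the trait by beta;
* **duplication-only** - deletions set to missing: beta estimates the
  duplication effect;
* **deletion-only** - duplications set to missing: beta estimates the
  deletion effect (on the per-copy scale its sign is flipped).

Each eligible probe (model-relevant frequency >= 0.005%, missingness
<= 5%) is tested by OLS of the inverse-normal-transformed,
covariate-residualized trait on dosage, with Bonferroni correction over
the *effective* number of tests Neff (eigenvalue rule on the probe
correlation matrix, threshold p <= 0.05/Neff) and stepwise conditional
analysis to isolate independent leads. Leads expand into CNV regions
(most distant probe with r^2 >= 0.5 within +/-3 Mb), which merge across
models when the trait matches, intervals overlap, and per-copy
directions agree. Downstream: directional replication p-adjustment
(p/2 on sign agreement, else 1 - p/2), simulation-based replication
power, exact binomial and Fisher tests (conditional-MLE odds ratio,
R-compatible), Mb/gene burden regressions with modifier-region
correction, and sibling CNV-sharing estimation.

A synthetic cohort generator (recurrent CNV regions, breakpoint jitter,
QS noise, four phenotype effect models, plates, sibling pairs,
fragmented WGS-style call sets) makes the whole pipeline testable
without restricted data. See `docs/methods.md` for conventions and
limitations.

## Worked example

Simulate one recurrent CNV region (2% duplication and 2% deletion
carriers, a true mirror effect of 0.3 trait SD per copy) in 10,000
samples, encode, scan, and map the region:

```python
from cnvgwas.association import (PreparedTrait, bonferroni_threshold,
                                 estimate_neff, stepwise_conditional)
from cnvgwas.encoding import (build_qs_matrix, compute_frequencies,
                              encode_model, filter_probes)
from cnvgwas.regions import define_cnvr
from cnvgwas.synthetic import (CNVArchitecture, EffectSpec, QSNoise, RegionSpec,
                               generate_probe_map, simulate_cohort,
                               simulate_phenotypes)

chrom_len = {"1": 12_000_000}
probes = generate_probe_map(80, chrom_len, seed=1)
arch = CNVArchitecture(regions=(
    RegionSpec("1", 3_000_000, 3_800_000, dup_frequency=0.02,
               del_frequency=0.02, breakpoint_jitter_bp=50_000,
               effects=(EffectSpec("height", "mirror", 0.3),)),
))
cohort = simulate_cohort(arch, 10_000, qs_noise=QSNoise(0, 0), seed=2,
                         probe_map=probes, chromosome_lengths=chrom_len)
trait = simulate_phenotypes(cohort, seed=3)["height"]

qs = build_qs_matrix(cohort.calls, probes, samples=cohort.samples)
mirror = encode_model(qs, "mirror")
mirror = mirror.subset_probes(filter_probes(compute_frequencies(mirror), "mirror"))
neff = estimate_neff(mirror)
threshold = bonferroni_threshold(0.05, neff.n_effective)
leads = stepwise_conditional(mirror, PreparedTrait("height", trait), threshold)
print(f"{len(mirror.probes)} eligible probes, Neff={neff.n_effective}, "
      f"threshold={threshold:.1e}")
for _, lead in leads.iterrows():
    chrom, start, end = define_cnvr(lead["probe_id"], mirror)
    print(f"lead {lead['probe_id']}: beta={lead['beta']:.3f} "
          f"(se {lead['se']:.3f}), p={lead['p']:.1e}, "
          f"CNVR chr{chrom}:{start}-{end}")
```

```
10 eligible probes, Neff=2, threshold=2.5e-02
lead probe_1_3083905: beta=0.300 (se 0.051), p=4.8e-09, CNVR chr1:3083905-3741978
```

Ten probes fall inside the CNV region but tag essentially two
independent dosage patterns (Neff = 2); the scan recovers the planted
effect (beta = 0.30 per copy) and the conditional analysis collapses the
correlated probes to a single lead whose tagged region spans the
simulated CNV.

## The analysis scripts

`analysis/01_simulate_cohorts.py` ... `07_burden.py` run a complete
two-cohort synthetic study end to end: cohort generation, sample QC and
PLINK encoding, the three-model discovery scan with conditional
analysis, region definition/merging and SNP-density testing,
replication with power simulation, array-vs-WGS concordance, and the
burden analyses with modifier correction and sibling sharing. Each
script prints what it found and writes small summary tables under
`results/`; bulky per-sample material lives under `scratch/` and is
regenerated by script 01.

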