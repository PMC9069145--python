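"""Shared scenario, paths, and seed for the numbered analysis scripts.

The study emulates a two-cohort CNV-GWAS: a discovery cohort with two
recurrent CNV regions carrying true mirror effects on a quantitative
trait, and a smaller replication cohort in which the same regions
segregate at different carrier frequencies. Bulky per-sample tables live
under scratch/ (regenerated by 01_simulate_cohorts.py); small summary
tables go to results/.
"""

from pathlib import Path

from cnvgwas.synthetic import CNVArchitecture, EffectSpec, RegionSpec

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"

SEED = 20_260_928
TRAIT = "trait_a"
TRUE_BETA = 0.3  # trait SD per additional copy

CHROM_LEN = {"1": 12_000_000, "2": 12_000_000}
N_PROBES = 160
N_DISCOVERY = 20_000
N_REPLICATION = 8_000
N_SIB_PAIRS = 3_000

DISCOVERY_ARCH = CNVArchitecture(
    regions=(
        RegionSpec("1", 3_000_000, 3_800_000, dup_frequency=0.02, del_frequency=0.02,
                   breakpoint_jitter_bp=50_000,
                   effects=(EffectSpec(TRAIT, "mirror", TRUE_BETA),)),
        RegionSpec("2", 7_000_000, 7_900_000, dup_frequency=0.015, del_frequency=0.015,
                   breakpoint_jitter_bp=50_000,
                   effects=(EffectSpec(TRAIT, "mirror", TRUE_BETA),)),
    )
)

REPLICATION_ARCH = CNVArchitecture(
    regions=(
        RegionSpec("1", 3_000_000, 3_800_000, dup_frequency=0.01, del_frequency=0.03,
                   breakpoint_jitter_bp=50_000,
                   effects=(EffectSpec(TRAIT, "mirror", TRUE_BETA),)),
        RegionSpec("2", 7_000_000, 7_900_000, dup_frequency=0.02, del_frequency=0.01,
                   breakpoint_jitter_bp=50_000,
                   effects=(EffectSpec(TRAIT, "mirror", TRUE_BETA),)),
    )
)
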