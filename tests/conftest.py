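import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cnvgwas.probes import ProbeMap
from cnvgwas.synthetic import (
    CNVArchitecture,
    EffectSpec,
    RegionSpec,
    generate_probe_map,
    simulate_cohort,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

CHROM_LENGTHS = {"1": 10_000_000, "2": 8_000_000}


@pytest.fixture(scope="session")
def probe_map() -> ProbeMap:
    return generate_probe_map(300, CHROM_LENGTHS, seed=11)


@pytest.fixture(scope="session")
def two_region_architecture() -> CNVArchitecture:
    return CNVArchitecture(
        regions=(
            RegionSpec(
                "1",
                2_000_000,
                2_600_000,
                dup_frequency=0.02,
                del_frequency=0.02,
                breakpoint_jitter_bp=120_000,
                effects=(EffectSpec("height", "mirror", 0.5),),
            ),
            RegionSpec(
                "2",
                1_000_000,
                1_500_000,
                dup_frequency=0.02,
                del_frequency=0.01,
                breakpoint_jitter_bp=80_000,
                effects=(EffectSpec("height", "dup-only", 0.6),),
            ),
        )
    )


@pytest.fixture(scope="session")
def small_cohort(two_region_architecture, probe_map):
    return simulate_cohort(
        two_region_architecture,
        4_000,
        seed=7,
        probe_map=probe_map,
        chromosome_lengths=CHROM_LENGTHS,
    )


def toy_calls(rows) -> pd.DataFrame:
    """rows: (sample_id, chrom, start, end, cn, qs)"""
    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "cn", "qs"])
    df.insert(5, "n_probes", 0)
    return df


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
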