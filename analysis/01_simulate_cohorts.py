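#!/usr/bin/env python
"""Generate the synthetic two-cohort study material.

Writes, under scratch/sim/: PennCNV-style call tables with quality scores,
a BIM-style probe map, phenotype and covariate tables for both cohorts,
and the sibling-pair tables for the discovery cohort. The scenario
(regions, frequencies, effects) is recorded as YAML under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import (  # noqa: E402
    CHROM_LEN, DISCOVERY_ARCH, N_DISCOVERY, N_PROBES, N_REPLICATION, N_SIB_PAIRS,
    REPLICATION_ARCH, RESULTS, SCRATCH, SEED, TRAIT,
)

from cnvgwas.io import architecture_to_yaml, write_calls, write_probe_map, write_table
from cnvgwas.synthetic import (
    QSNoise,
    generate_probe_map,
    simulate_cohort,
    simulate_phenotypes,
    simulate_siblings,
)


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    probe_map = generate_probe_map(N_PROBES, CHROM_LEN, seed=SEED)
    write_probe_map(probe_map, SCRATCH / "probes.bim")

    noise = QSNoise(miss_rate=0.05, fp_rate=0.1)
    for label, arch, n, seed in (
        ("discovery", DISCOVERY_ARCH, N_DISCOVERY, SEED + 1),
        ("replication", REPLICATION_ARCH, N_REPLICATION, SEED + 2),
    ):
        cohort = simulate_cohort(arch, n, qs_noise=noise, seed=seed,
                                 probe_map=probe_map, chromosome_lengths=CHROM_LEN)
        phenos = simulate_phenotypes(cohort, seed=seed + 10, extra_null_traits=["trait_null"])
        # a second trait carrying a pure per-Mb burden effect (-0.4 SD/Mb),
        # no per-region effect specs
        phenos["trait_burden"] = simulate_phenotypes(
            cohort, burden_beta=-0.4, seed=seed + 11, extra_null_traits=["trait_burden"]
        )["trait_burden"]
        write_calls(cohort.calls, SCRATCH / f"{label}_calls.tsv", seed=seed)
        write_table(phenos, SCRATCH / f"{label}_phenotypes.tsv")
        write_table(cohort.covariates, SCRATCH / f"{label}_covariates.tsv")
        cohort.plates.rename_axis("sample_id").to_frame().to_csv(
            SCRATCH / f"{label}_plates.tsv", sep="\t"
        )
        hc = (cohort.calls["qs"].abs() >= 0.5).sum()
        print(f"{label}: {n} samples, {len(cohort.calls)} calls "
              f"({hc} high-confidence), {phenos.shape[1]} traits")
        if label == "discovery":
            pairs, sib_calls = simulate_siblings(
                cohort, N_SIB_PAIRS, transmission_rate=0.5, seed=seed + 20
            )
            pairs.to_csv(SCRATCH / "sibling_pairs.tsv", sep="\t", index=False)
            write_calls(sib_calls, SCRATCH / "sibling_calls.tsv", seed=seed + 20)
            print(f"discovery: {len(pairs)} sibling pairs, {len(sib_calls)} sibling calls")

    architecture_to_yaml(DISCOVERY_ARCH, RESULTS / "scenario_discovery.yaml", seed=SEED)
    architecture_to_yaml(REPLICATION_ARCH, RESULTS / "scenario_replication.yaml", seed=SEED)
    print(f"scenario written to {RESULTS}/scenario_*.yaml; cohorts under {SCRATCH}/")


if __name__ == "__main__":
    main()
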