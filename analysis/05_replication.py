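#!/usr/bin/env python
"""Replication of discovery regions in the second cohort.

For each discovery region the most significant replication probe inside
the boundaries (under the winning model) is selected, p-values are
adjusted for directional concordance, Bonferroni-corrected, and the
nominal-replication enrichment plus the simulation-based expected number
of replications are reported.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import N_REPLICATION, RESULTS, SCRATCH, SEED, TRAIT  # noqa: E402

from cnvgwas.association import bonferroni_threshold, prepare_trait, run_scan
from cnvgwas.io import read_calls, read_table
from cnvgwas.plink import read_plink
from cnvgwas.replication import (
    expected_replications,
    nominal_enrichment,
    power_simulation,
    replicate_regions,
)


def main() -> None:
    regions = pd.read_csv(RESULTS / "regions.tsv", sep="\t", dtype={"chrom": str})
    phenos = read_table(SCRATCH / "replication_phenotypes.tsv")
    covars = read_table(SCRATCH / "replication_covariates.tsv")
    trait = prepare_trait(phenos[TRAIT], covars)

    scans = {}
    for model, tag in (("mirror", "cnv"), ("dup-only", "dup"), ("del-only", "del")):
        geno = read_plink(SCRATCH / f"replication_{tag}", model=model)
        scans[model] = run_scan(geno, trait)

    table = replicate_regions(regions, scans)
    assessed = table[table["assessable"]]
    alpha = bonferroni_threshold(0.05, max(len(assessed), 1))
    table["replicated"] = table["rep_p_adj"] <= alpha
    table.to_csv(RESULTS / "replication.tsv", sep="\t", index=False)
    n_nominal = int((assessed["rep_p_adj"] <= 0.05).sum())
    print(f"{len(assessed)}/{len(table)} regions assessable; "
          f"{int(table['replicated'].sum())} replicate at p<={alpha:.1e}; "
          f"{n_nominal} nominal")
    if len(assessed):
        fold, p = nominal_enrichment(n_nominal, len(assessed), 0.05)
        print(f"nominal enrichment: fold={fold:.1f}, p={p:.2e}")

    calls = read_calls(SCRATCH / "replication_calls.tsv")
    powers = []
    for i, row in assessed.iterrows():
        in_region = calls[
            (calls["chrom"] == str(row["chrom"]))
            & (calls["start"] <= row["end"]) & (calls["end"] >= row["start"])
            & (calls["qs"].abs() >= 0.5)
        ]
        freq = max(in_region["sample_id"].nunique() / N_REPLICATION, 1e-4)
        powers.append(power_simulation(row["discovery_beta"], freq, N_REPLICATION,
                                       alpha=alpha, n_sims=10_000, seed=SEED + 50 + i))
    if powers:
        print(f"mean replication power {100 * sum(powers) / len(powers):.1f}%, "
              f"expected replications {expected_replications(powers):.2f} "
              f"(observed {int(table['replicated'].sum())})")


if __name__ == "__main__":
    main()
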