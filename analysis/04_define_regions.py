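#!/usr/bin/env python
"""CNV-region definition, cross-model merging, and SNP-density testing.

Each independent lead is expanded to its CNVR (r^2 >= 0.5 within +/-3 Mb,
computed on the unpruned eligible probe set), signals are merged across
models under the direction-concordance rule, and the merged regions are
tested for enrichment of (synthetic) SNP-GWAS signal positions against
the genome-wide density.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CHROM_LEN, RESULTS, SCRATCH, SEED, TRAIT  # noqa: E402

from cnvgwas.plink import read_plink
from cnvgwas.regions import define_cnvr, merge_signals, snp_density_binomial_test


def main() -> None:
    leads = pd.read_csv(RESULTS / "discovery_leads.tsv", sep="\t", dtype={"chrom": str})
    genos = {
        model: read_plink(SCRATCH / f"discovery_{tag}", model=model)
        for model, tag in (("mirror", "cnv"), ("dup-only", "dup"), ("del-only", "del"))
    }
    rows = []
    for _, lead in leads.iterrows():
        chrom, start, end = define_cnvr(lead["probe_id"], genos[lead["model"]])
        rows.append({"trait": TRAIT, "model": lead["model"], "chrom": chrom,
                     "start": start, "end": end, "lead_probe": lead["probe_id"],
                     "beta": lead["beta"], "se": lead["se"], "p": lead["p"]})
    signals = pd.DataFrame(rows)
    regions = merge_signals(signals)
    regions.to_csv(RESULTS / "regions.tsv", sep="\t", index=False)
    print(f"{len(signals)} per-model signals merged into {len(regions)} regions:")
    print(regions[["chrom", "start", "end", "model", "beta", "p", "models"]].to_string())

    # synthetic SNP-GWAS signal list: half placed inside the regions,
    # half uniform over the genome, to exercise the density test
    rng = np.random.default_rng(SEED + 40)
    genome_bp = sum(CHROM_LEN.values())
    inside, outside = [], []
    for _, r in regions.iterrows():
        inside += [{"chrom": r["chrom"],
                    "pos": int(rng.integers(r["start"], r["end"] + 1))} for _ in range(10)]
    for _ in range(200):
        chrom = str(rng.choice(list(CHROM_LEN)))
        outside.append({"chrom": chrom, "pos": int(rng.integers(1, CHROM_LEN[chrom] + 1))})
    snps = pd.DataFrame(inside + outside)
    out = snp_density_binomial_test(regions, snps, total_snp_signals=len(snps),
                                    genome_length_bp=genome_bp)
    print(f"SNP-density inside regions: {out['successes']}/{out['trials']} bp, "
          f"fold={out['fold']:.1f}, p={out['p']:.2e}")
    pd.DataFrame([out]).to_csv(RESULTS / "snp_density_test.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
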