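#!/usr/bin/env python
"""Sample QC and probe-level encoding of both cohorts.

Applies the call-level sample QC (>200 calls, single call >10 Mb, noisy
plates), builds the QS matrices, writes the three PLINK file sets per
cohort (mirror / duplication-only / deletion-only), and stores the
per-probe frequency table. Probes eligible per model (frequency >= 0.005%,
missingness <= 5%) are reported.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH  # noqa: E402

from cnvgwas.encoding import (
    build_qs_matrix,
    compute_frequencies,
    encode_model,
    filter_probes,
    qc_samples,
)
from cnvgwas.io import read_calls, read_probe_map, read_table
from cnvgwas.plink import write_plink


def main() -> None:
    probe_map = read_probe_map(SCRATCH / "probes.bim")
    for label in ("discovery", "replication"):
        calls = read_calls(SCRATCH / f"{label}_calls.tsv")
        plates = read_table(SCRATCH / f"{label}_plates.tsv")["plate"]
        samples = list(plates.index)
        kept, report = qc_samples(calls, plates)
        print(f"{label}: {len(report)} samples excluded by QC "
              f"({len(calls) - len(kept)} calls dropped)")
        report.to_csv(RESULTS / f"{label}_qc_exclusions.tsv", sep="\t", index=False)
        keep_samples = [s for s in samples if s not in set(report["sample_id"])]

        qs = build_qs_matrix(kept, probe_map, samples=keep_samples)
        mirror = encode_model(qs, "mirror")
        freq = compute_frequencies(mirror)
        freq.round(4).to_csv(RESULTS / f"{label}_probe_frequencies.tsv", sep="\t", index=False)
        for model, tag in (("mirror", "cnv"), ("dup-only", "dup"), ("del-only", "del")):
            geno = encode_model(qs, model)
            eligible = filter_probes(freq, model)
            write_plink(geno.subset_probes(eligible), SCRATCH / f"{label}_{tag}")
            print(f"  {model}: {len(eligible)} eligible probes -> "
                  f"{label}_{tag}.bed/.bim/.fam")


if __name__ == "__main__":
    main()
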