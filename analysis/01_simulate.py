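#!/usr/bin/env python
"""Generate the synthetic EHR extract used by the downstream analyses.

Emulates a referral-center pediatric population of 400 patients over the
2018-06-02 .. 2025-05-31 study window, ~8% of whom carry a latent
hyperinflammatory state that drives correlated HLH-2004 criterion
exceedances, ICD-10 D76.1 coding, HLH-directed treatment, and mortality.
Writes the extract CSVs plus generator ground truth to
results/extract/.
"""

from pathlib import Path

from hlh_phenotyping import write_extract
from hlh_phenotyping.synthetic import GeneratorConfig, generate, write_ground_truth

OUT = Path(__file__).resolve().parents[1] / "results" / "extract"
SEED = 11


def main() -> None:
    cfg = GeneratorConfig(n_patients=400, seed=SEED)
    extract, gt = generate(cfg)
    write_extract(extract, OUT)
    write_ground_truth(gt, OUT)
    n_latent = int(gt.patients["latent"].sum())
    print(f"wrote extract to {OUT}")
    print(f"  patients: {len(extract.patients)} ({n_latent} latent hyperinflammatory)")
    print(f"  encounters: {len(extract.encounters)}, labs: {len(extract.labs)}, "
          f"notes: {len(extract.notes)}")


if __name__ == "__main__":
    main()
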