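#!/usr/bin/env python
"""Phenome-wide scan of the genetic score over the simulated cohort.

Maps the ICD records to phecodes, applies the 200-case filter, and runs
the covariate-adjusted logistic scan plus its two sensitivity variants
(no BMI adjustment; BMI<25 / BMI>=25 strata), writing results under
results/phewas/.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from milkmr.config import load_config
from milkmr.datasets import phecode_map_mini
from milkmr.pipeline import phewas_stage
from milkmr.tableio import read_tsv


def main() -> None:
    config = load_config(ROOT / "configs" / "default.yaml")
    sim = ROOT / "results" / "sim"
    outdir = ROOT / "results" / "phewas"
    paths = phewas_stage(
        config, sim / "cohort.tsv", sim / "icd_records.tsv", outdir,
        phecode_map_mini(), no_bmi_sensitivity=True, stratify_bmi=True,
    )
    res = read_tsv(paths["results"], dtype={"phecode": str})
    n_sig = int(res["significant"].sum())
    print(f"scanned {len(res)} phenotypes with >= {config.scan.min_cases} cases; "
          f"{n_sig} significant at FDR {config.scan.fdr_level}")
    top = res.sort_values("p").head(5)
    for _, r in top.iterrows():
        print(f"  {r['phecode']:>7} {r['label'][:40]:40s} "
              f"OR {r['or']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f}) p={r['p']:.2e} q={r['q']:.3f}")
    print(f"outputs under {outdir}")


if __name__ == "__main__":
    sys.exit(main())
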