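#!/usr/bin/env python
"""Publication-style outputs from the scan results.

Builds the side-by-side (with / without BMI adjustment) association table
and the Manhattan-plot data under results/report/, and renders the
Manhattan plot itself to results/report/manhattan.png.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from milkmr.config import load_config
from milkmr.pipeline import report_stage
from milkmr.tableio import read_tsv


def plot_manhattan(mh, out_path) -> None:
    fig, ax = plt.subplots(figsize=(8, 4))
    categories = list(dict.fromkeys(mh["category"]))
    xticks, xlabels = [], []
    x0 = 0
    for i, cat in enumerate(categories):
        block = mh[mh["category"] == cat]
        x = range(x0, x0 + len(block))
        ax.scatter(list(x), block["neg_log10_p"], s=28, color=f"C{i % 10}",
                   marker="o", edgecolors="none")
        for xi, (_, row) in zip(x, block.iterrows()):
            if row["significant"]:
                ax.annotate(row["phecode"], (xi, row["neg_log10_p"]),
                            textcoords="offset points", xytext=(0, 4), fontsize=7)
        xticks.append(x0 + len(block) / 2 - 0.5)
        xlabels.append(cat)
        x0 += len(block) + 1
    ax.set_xticks(xticks)
    ax.set_xticklabels(xlabels, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.set_title("Genetically predicted milk consumption vs phecode phenotypes")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def main() -> None:
    config = load_config(ROOT / "configs" / "default.yaml")
    scan = ROOT / "results" / "phewas"
    outdir = ROOT / "results" / "report"
    paths = report_stage(
        config, scan / "phewas_results.tsv", outdir,
        results_no_bmi_path=scan / "phewas_results_no_bmi.tsv",
    )
    table = Path(paths["table"]).read_text().splitlines()
    print("association table (top rows):")
    for line in table[:4]:
        cells = line.split("\t")
        print("  " + " | ".join(cells[:2] + cells[6:8]))
    mh = read_tsv(paths["manhattan"], dtype={"phecode": str})
    plot_manhattan(mh, outdir / "manhattan.png")
    print(f"{int(mh['significant'].sum())} phenotypes flagged at FDR 0.05")
    print(f"outputs under {outdir}")


if __name__ == "__main__":
    sys.exit(main())
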