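#!/usr/bin/env python
"""Enrichment of the differential genes and qPCR validation.

Reads enrichment.tsv, qpcr_expression.tsv and qpcr_concordance.tsv from
results/run/, draws the enrichment bubble plot and prints/writes the
validation summary (results/validation_summary.tsv).
"""

from pathlib import Path

import pandas as pd

from methylrad.plots import enrichment_bubbles

ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = ROOT / "results" / "run"
SIM_DIR = ROOT / "results" / "sim"
OUT = ROOT / "results"


def main() -> None:
    enr = pd.read_csv(RUN_DIR / "enrichment.tsv", sep="\t", index_col=0)
    expr = pd.read_csv(RUN_DIR / "qpcr_expression.tsv", sep="\t", index_col=0)
    conc = pd.read_csv(RUN_DIR / "qpcr_concordance.tsv", sep="\t", index_col=0)
    truth = pd.read_csv(SIM_DIR / "truth_genes.tsv", sep="\t", index_col=0)

    enrichment_bubbles(enr, OUT / "enrichment.png")
    print("enrichment (q < 0.05):")
    hits = enr[enr["q_value"] < 0.05]
    print(hits[["term_name", "k", "K", "p_value", "q_value"]].to_string())

    summary = conc.join(expr[["treated_mean", "control_mean"]], how="left")
    summary = summary.join(truth[["role", "true_lfc"]], how="left")
    summary.to_csv(OUT / "validation_summary.tsv", sep="\t")
    changed = summary[summary["true_lfc"] != 0]
    print(
        f"\nqPCR concordance among planted-change genes: "
        f"{int(changed['concordant'].sum())}/{len(changed)}"
    )
    print(summary.round(3).to_string())


if __name__ == "__main__":
    main()
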