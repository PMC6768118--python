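#!/usr/bin/env python
"""Candidate screen results and clustering heat map.

Reads the screen decisions from results/run/, recomputes gene-level RPM
for the significant genes and draws the hierarchical-clustering heat map
(results/cluster_heatmap.png); writes the decision table with the planted
roles attached (results/screen_with_truth.tsv).
"""

from pathlib import Path

import pandas as pd

from methylrad.screen import cluster_genes
from methylrad.plots import cluster_heatmap

ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = ROOT / "results" / "run"
SIM_DIR = ROOT / "results" / "sim"
OUT = ROOT / "results"


def main() -> None:
    screen = pd.read_csv(RUN_DIR / "screen.tsv", sep="\t", index_col=0)
    gene_diff = pd.read_csv(RUN_DIR / "gene_diff.tsv", sep="\t", index_col=0)
    counts = pd.read_csv(RUN_DIR / "counts.tsv", sep="\t", index_col=0)
    anns = pd.read_csv(RUN_DIR / "site_annotations.tsv", sep="\t", index_col=0)
    truth = pd.read_csv(SIM_DIR / "truth_genes.tsv", sep="\t", index_col=0)

    merged = screen.join(truth[["role", "true_lfc"]], how="left")
    merged.to_csv(OUT / "screen_with_truth.tsv", sep="\t")

    selected = sorted(screen.index[screen["selected"]])
    expected = sorted(
        truth.index[
            truth["role"].str.contains("hyper|hypo")
            & truth.index.isin(screen.index[screen["cond_pathway"]])
        ]
    )
    print(f"selected candidates: {selected}")
    print(f"planted concordant pathway genes: {expected}")
    print(f"agreement: {selected == expected}")

    sig = gene_diff.index[gene_diff["significant"]]
    genic = anns.dropna(subset=["gene_id"])
    gene_counts = (
        counts.loc[counts.index.intersection(genic.index)]
        .groupby(genic["gene_id"])
        .sum()
    )
    gene_rpm = gene_counts / counts.sum(axis=0) * 1e6
    sub = gene_rpm.loc[gene_rpm.index.intersection(sig)]
    if len(sub) >= 2:
        res = cluster_genes(sub)
        cluster_heatmap(res.zscores, res.leaf_order, OUT / "cluster_heatmap.png")
        print(f"cluster leaf order: {res.leaf_order}")
    else:
        print("fewer than two significant genes; no heat map drawn")


if __name__ == "__main__":
    main()
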