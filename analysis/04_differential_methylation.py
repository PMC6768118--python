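#!/usr/bin/env python
"""Differential-methylation summary at site and gene level.

Reads site_diff.tsv and gene_diff.tsv from results/run/ and writes the
hyper/hypo tallies (results/diff_summary.tsv) and the significant gene
table with their strongest sites (results/significant_genes.tsv).
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = ROOT / "results" / "run"
OUT = ROOT / "results"


def main() -> None:
    site = pd.read_csv(RUN_DIR / "site_diff.tsv", sep="\t", index_col=0)
    gene = pd.read_csv(RUN_DIR / "gene_diff.tsv", sep="\t", index_col=0)
    anns = pd.read_csv(RUN_DIR / "site_annotations.tsv", sep="\t", index_col=0)

    rows = []
    for level, table in (("site", site), ("gene", gene)):
        rows.append(
            {
                "level": level,
                "tested": len(table),
                "significant": int(table["significant"].sum()),
                "hyper": int((table["direction"] == "hyper").sum()),
                "hypo": int((table["direction"] == "hypo").sum()),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "diff_summary.tsv", sep="\t", index=False)

    sig_genes = gene[gene["significant"]].copy()
    site_with_gene = site.join(anns[["gene_id", "element"]], how="left")
    best_site = (
        site_with_gene.dropna(subset=["gene_id"])
        .sort_values("p_value")
        .groupby("gene_id")
        .head(1)
        .set_index("gene_id")
    )
    sig_genes["best_site_p"] = best_site["p_value"].reindex(sig_genes.index)
    sig_genes["best_site_element"] = best_site["element"].reindex(sig_genes.index)
    sig_genes.to_csv(OUT / "significant_genes.tsv", sep="\t")

    print(summary.to_string(index=False))
    print(f"\nsignificant genes ({len(sig_genes)}):")
    print(
        sig_genes[["log2fc", "p_value", "q_value", "direction"]]
        .round(4)
        .to_string()
    )


if __name__ == "__main__":
    main()
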