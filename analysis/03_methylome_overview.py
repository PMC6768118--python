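#!/usr/bin/env python
"""Methylome overview: replicate agreement and element distribution.

Reads the pipeline tables from results/run/ and writes the sample
correlation heatmap, the per-element bar chart of authentic sites, and a
small summary table (results/overview_summary.tsv).
"""

from pathlib import Path

import pandas as pd

from methylrad.plots import correlation_heatmap, element_distribution_bars

ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = ROOT / "results" / "run"
OUT = ROOT / "results"


def main() -> None:
    corr = pd.read_csv(RUN_DIR / "sample_correlation.tsv", sep="\t", index_col=0)
    dist = pd.read_csv(RUN_DIR / "element_distribution.tsv", sep="\t", index_col=0)

    correlation_heatmap(corr, OUT / "sample_correlation.png")
    element_distribution_bars(dist, OUT / "element_distribution.png")

    treated = [c for c in corr.columns if c.startswith("T")]
    control = [c for c in corr.columns if c.startswith("C")]
    def off_diag_range(block):
        vals = [
            block.iloc[i, j]
            for i in range(len(block))
            for j in range(len(block))
            if i != j
        ]
        return min(vals), max(vals)

    t_lo, t_hi = off_diag_range(corr.loc[treated, treated])
    c_lo, c_hi = off_diag_range(corr.loc[control, control])
    frac_nongenic = (
        dist.loc[["intergenic", "intron"]].sum().sum() / dist.sum().sum()
    )
    summary = pd.DataFrame(
        [
            {"metric": "within_treated_corr_min", "value": round(t_lo, 3)},
            {"metric": "within_treated_corr_max", "value": round(t_hi, 3)},
            {"metric": "within_control_corr_min", "value": round(c_lo, 3)},
            {"metric": "within_control_corr_max", "value": round(c_hi, 3)},
            {"metric": "fraction_sites_intergenic_or_intron", "value": round(frac_nongenic, 3)},
        ]
    )
    summary.to_csv(OUT / "overview_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
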