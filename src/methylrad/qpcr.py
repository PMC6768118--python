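"""qPCR validation: 2^-ΔΔCt relative expression and methylation concordance.

Relative expression follows the Livak method with an assumed perfect
amplification efficiency of 2: per sample, ΔCt = Ct(target) − Ct(reference)
averaged over technical replicates; ΔΔCt subtracts the mean control-group
ΔCt, so the control group mean relative expression is 1 by construction.
Group differences are tested by Welch's t-test, on log2 relative expression
by default (ratio data), with a raw-scale mode available. A gene's
expression change is concordant with its methylation change when the signs
are opposite (hypermethylation with repression, hypomethylation with
induction).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_ct_table",
    "ddct_fold_change",
    "expression_group_test",
    "methylation_expression_concordance",
]

CT_COLUMNS = ("sample_id", "group", "gene_id", "ct_target", "ct_reference")


def load_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
    bad = df[(df["ct_target"] <= 0) | (df["ct_target"] >= 45)]
    if len(bad):
        raise ValueError(
            f"Ct values outside (0, 45) for sample(s): {sorted(bad['sample_id'].unique())}"
        )
    return df


@dataclass
class DdctResult:
    per_sample: pd.DataFrame  # sample_id, group, delta_ct, ddct, rel_expr
    group_stats: pd.DataFrame  # group -> mean, sem, n


def ddct_fold_change(
    measurements: pd.DataFrame, control_group: str = "control"
) -> DdctResult:
    """2^-ΔΔCt relative expression for one gene's Ct measurements.

    *measurements* holds one gene's rows (sample_id, group, ct_target,
    ct_reference, optionally replicate). Technical replicates are averaged
    per sample before ΔCt.
    """
    if measurements["ct_reference"].isna().any():
        bad = measurements.loc[measurements["ct_reference"].isna(), "sample_id"]
        raise ValueError(f"missing reference Ct for sample(s): {sorted(set(bad))}")
    per_sample = (
        measurements.groupby(["sample_id", "group"], as_index=False)[
            ["ct_target", "ct_reference"]
        ].mean()
    )
    per_sample["delta_ct"] = per_sample["ct_target"] - per_sample["ct_reference"]
    controls = per_sample[per_sample["group"] == control_group]
    if controls.empty:
        raise ValueError(f"no samples in control group {control_group!r}")
    if (per_sample["group"] != control_group).sum() == 0:
        raise ValueError("no non-control samples present")
    baseline = controls["delta_ct"].mean()
    per_sample["ddct"] = per_sample["delta_ct"] - baseline
    per_sample["rel_expr"] = 2.0 ** (-per_sample["ddct"])
    gs = per_sample.groupby("group")["rel_expr"].agg(["mean", "sem", "count"])
    gs = gs.rename(columns={"count": "n"})
    return DdctResult(per_sample=per_sample, group_stats=gs)


def expression_group_test(
    rel_expr: pd.Series,
    groups: pd.Series,
    log_scale: bool = True,
) -> tuple[float, float]:
    """Welch two-sample t-test of relative expression between groups.

    Returns (t statistic, p-value). With identical degenerate groups
    (zero variance, equal means) p is 1 by convention.
    """
    groups = pd.Series(groups)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    x = rel_expr[groups == labels[0]].to_numpy(dtype=float)
    y = rel_expr[groups == labels[1]].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 samples per group")
    if log_scale:
        x, y = np.log2(x), np.log2(y)
    if np.var(x) == 0 and np.var(y) == 0:
        if np.isclose(x.mean(), y.mean()):
            return 0.0, 1.0
        return float("inf"), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def methylation_expression_concordance(
    gene_diff: pd.DataFrame,
    expression_log2fc: pd.Series | dict,
) -> pd.DataFrame:
    """Direction-agreement report between methylation and expression.

    *gene_diff* is the gene-level differential-methylation table (indexed
    by gene_id, with log2fc); *expression_log2fc* maps gene_id to log2
    treated/control relative expression. A gene is concordant when
    sign(methylation log2FC) == -sign(expression log2FC).
    """
    expr = pd.Series(expression_log2fc, dtype=float)
    common = gene_diff.index.intersection(expr.index)
    rows = []
    for gid in common:
        m = float(gene_diff.loc[gid, "log2fc"])
        e = float(expr[gid])
        rows.append(
            {
                "gene_id": gid,
                "methylation_log2fc": m,
                "expression_log2fc": e,
                "concordant": bool(np.sign(m) == -np.sign(e) and np.sign(m) != 0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.set_index("gene_id")
    return out
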