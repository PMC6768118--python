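"""Differential methylation testing from site/gene count data.

The between-group comparison is a negative-binomial conditional exact test
on two groups of count replicates, in the spirit of the classic exact test
for overdispersed count data: counts are scaled to a common (geometric
mean) library size, a single common dispersion phi is estimated by pooled
method of moments, and the p-value is computed from the conditional
distribution of the treated-group sum given the two-group total, with
NB marginals (the sum of n i.i.d. NB(mu, phi) replicates is NB(n*mu,
phi/n)). At phi = 0 the marginals are Poisson and the conditional law is
binomial, so the test reduces to the classic conditional binomial (Poisson
exact) test. Two-sided p-values use the minimum-likelihood rule: the sum of
conditional probabilities of all outcomes no more probable than the one
observed.

Effect size is log2((mean RPM treated + c) / (mean RPM control + c)) with
pseudocount c = 0.5, and the significance call follows the rule
p < 0.05 and |log2FC| > 1; hyper/hypo direction is the sign of the fold
change among significant features. Benjamini-Hochberg q-values are reported
alongside but do not drive the call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .annotate import SiteAnnotation

__all__ = [
    "GENIC_ELEMENTS",
    "aggregate_to_gene",
    "scale_to_common_library",
    "estimate_dispersion",
    "exact_nb_test",
    "log2_fold_change",
    "call_differential",
    "differential_test",
]

GENIC_ELEMENTS = frozenset({"promoter", "UTR5", "exon", "intron", "UTR3"})
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_P_CUT = 0.05
DEFAULT_LFC_CUT = 1.0


def aggregate_to_gene(
    counts: pd.DataFrame, annotations: dict[str, SiteAnnotation]
) -> pd.DataFrame:
    """Sum site counts to gene counts over promoter/UTR/exon/intron sites.

    Sites without a gene (intergenic, CTCF-only) are excluded. Summation is
    depth-weighted by construction: a deep site contributes proportionally.
    """
    gene_of = {
        sid: ann.gene_id
        for sid, ann in annotations.items()
        if ann.gene_id is not None and ann.element in GENIC_ELEMENTS
    }
    keep = counts.index.intersection(gene_of.keys())
    if len(keep) == 0:
        return pd.DataFrame(columns=counts.columns, dtype=int)
    sub = counts.loc[keep]
    genes = pd.Series({sid: gene_of[sid] for sid in keep})
    out = sub.groupby(genes).sum()
    out.index.name = "gene_id"
    return out.sort_index()


def _group_columns(groups: pd.Series) -> tuple[list, list]:
    groups = pd.Series(groups)
    treated = list(groups[groups == "treated"].index)
    control = list(groups[groups == "control"].index)
    if not treated or not control:
        raise ValueError("both 'treated' and 'control' groups are required")
    return treated, control


def scale_to_common_library(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample's counts to the geometric-mean library size (rounded).

    The conditional exact test requires exchangeable totals under the null,
    which holds only at equal effective library sizes.
    """
    libs = counts.sum(axis=0).astype(float)
    if (libs <= 0).any():
        raise ValueError(
            f"zero library size for sample(s): {list(libs.index[libs <= 0])}"
        )
    geo = float(np.exp(np.mean(np.log(libs))))
    scaled = counts * (geo / libs)
    return scaled.round().astype(np.int64)


def estimate_dispersion(counts: pd.DataFrame, groups: pd.Series) -> float:
    """Common NB dispersion, pooled method of moments over all features.

    Within each group the NB model gives E[s^2] = mu + phi*mu^2; the
    estimator pools numerator sum(s^2 - m) and denominator sum(m^2 - s^2/n)
    across features and groups (the denominator correction removes the
    E[m^2] = mu^2 + Var(X)/n bias of the squared sample mean). Floored at 0.
    """
    treated, control = _group_columns(groups)
    if len(treated) < 2 or len(control) < 2:
        raise ValueError(
            "dispersion estimation requires >= 2 replicates per group; "
            "replication is required for differential testing"
        )
    scaled = scale_to_common_library(counts) if counts.to_numpy().sum() > 0 else counts
    num = 0.0
    den = 0.0
    for cols in (treated, control):
        block = scaled[cols].to_numpy(dtype=float)
        n = block.shape[1]
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        mask = m > 0
        num += float(np.sum(v[mask] - m[mask]))
        den += float(np.sum(m[mask] ** 2 - v[mask] / n))
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def _conditional_log_pmf(total: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """log P(sum_A = y | sum_A + sum_B = total) for y = 0..total."""
    y = np.arange(total + 1)
    if phi <= 0:
        # Poisson marginals -> binomial conditional
        return stats.binom.logpmf(y, total, n_a / (n_a + n_b))
    mu = total / (n_a + n_b)
    r_a, r_b = n_a / phi, n_b / phi
    mu_a, mu_b = n_a * mu, n_b * mu
    la = stats.nbinom.logpmf(y, r_a, r_a / (r_a + mu_a))
    lb = stats.nbinom.logpmf(total - y, r_b, r_b / (r_b + mu_b))
    joint = la + lb
    return joint - logsumexp(joint)


def exact_nb_test(
    counts_a: np.ndarray | list,
    counts_b: np.ndarray | list,
    phi: float,
) -> float:
    """Two-sided conditional exact p-value for one feature.

    *counts_a*, *counts_b* are the per-replicate counts of the two groups,
    already scaled to a common library size. Minimum-likelihood two-sided
    rule; a zero two-group total gives p = 1.
    """
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    ya, yb = int(a.sum()), int(b.sum())
    total = ya + yb
    if total == 0:
        return 1.0
    logp = _conditional_log_pmf(total, len(a), len(b), phi)
    obs = logp[ya]
    p = float(np.exp(logsumexp(logp[logp <= obs + 1e-10])))
    return min(1.0, p)


def log2_fold_change(
    mean_treated: float, mean_control: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """log2 ratio of group mean RPM with a symmetric pseudocount."""
    if mean_treated < 0 or mean_control < 0:
        raise ValueError("RPM means must be non-negative")
    return float(
        np.log2((mean_treated + pseudocount) / (mean_control + pseudocount))
    )


def call_differential(
    results: pd.DataFrame,
    p_cut: float = DEFAULT_P_CUT,
    lfc_cut: float = DEFAULT_LFC_CUT,
) -> pd.DataFrame:
    """Apply the significance rule p < p_cut and |log2fc| > lfc_cut (strict)."""
    out = results.copy()
    out["significant"] = (out["p_value"] < p_cut) & (out["log2fc"].abs() > lfc_cut)
    direction = np.where(
        out["significant"] & (out["log2fc"] > 0),
        "hyper",
        np.where(out["significant"] & (out["log2fc"] < 0), "hypo", "none"),
    )
    out["direction"] = direction
    return out


def differential_test(
    counts: pd.DataFrame,
    groups: pd.Series,
    phi: float | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    p_cut: float = DEFAULT_P_CUT,
    lfc_cut: float = DEFAULT_LFC_CUT,
) -> pd.DataFrame:
    """Full per-feature differential table, sorted by p-value.

    Columns: mean_rpm_treated, mean_rpm_control, log2fc, p_value, q_value
    (Benjamini-Hochberg), significant, direction. The dispersion is
    estimated from the data when not supplied.
    """
    treated, control = _group_columns(groups)
    if phi is None:
        phi = estimate_dispersion(counts, groups)
    scaled = scale_to_common_library(counts)
    libs = counts.sum(axis=0).astype(float)
    rpm = counts / libs * 1e6
    mean_t = rpm[treated].mean(axis=1)
    mean_c = rpm[control].mean(axis=1)
    a = scaled[treated].to_numpy()
    b = scaled[control].to_numpy()
    pvals = np.array(
        [exact_nb_test(a[i], b[i], phi) for i in range(scaled.shape[0])]
    )
    lfc = np.log2((mean_t + pseudocount) / (mean_c + pseudocount))
    qvals = (
        multipletests(pvals, method="fdr_bh")[1] if len(pvals) else np.array([])
    )
    out = pd.DataFrame(
        {
            "mean_rpm_treated": mean_t,
            "mean_rpm_control": mean_c,
            "log2fc": lfc,
            "p_value": pvals,
            "q_value": qvals,
        },
        index=counts.index,
    )
    out = call_differential(out, p_cut=p_cut, lfc_cut=lfc_cut)
    out.attrs["dispersion"] = phi
    return out.sort_values("p_value", kind="mergesort")
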