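"""Candidate-gene screening and clustering of differentially methylated genes.

A gene is nominated as a cleft-palate candidate when it satisfies three
conditions simultaneously: (i) it carries at least one significantly
differentially methylated site; (ii) the direction of change of its
significant sites corresponds to the gene-level call (strict mode: every
significant site agrees; majority mode: more than half agree); and (iii) it
belongs to the supplied CP-related pathway gene list. Hierarchical
clustering of significant genes (average linkage, Euclidean distance on
row-z-scored log2(RPM + 1)) orders the genes for heat-map display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .annotate import SiteAnnotation
from .diff import GENIC_ELEMENTS

__all__ = ["ScreenDecision", "screen_genes", "cluster_genes", "ClusterResult"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenDecision:
    gene_id: str
    cond_site_dm: bool
    cond_concordant: bool
    cond_pathway: bool

    @property
    def selected(self) -> bool:
        return self.cond_site_dm and self.cond_concordant and self.cond_pathway


def screen_genes(
    site_results: pd.DataFrame,
    gene_results: pd.DataFrame,
    annotations: dict[str, SiteAnnotation],
    pathway_genes: set[str],
    concordance: str = "strict",
) -> pd.DataFrame:
    """Apply the three-condition candidate screen to every tested gene.

    *site_results* and *gene_results* are differential tables (indexed by
    site_id / gene_id, with ``significant`` and ``direction`` columns).
    Returns one row per gene in *gene_results* with the three condition
    flags and the final ``selected`` call.
    """
    if concordance not in ("strict", "majority"):
        raise ValueError("concordance must be 'strict' or 'majority'")
    if not pathway_genes:
        logger.warning("empty pathway gene list: condition (iii) false for all genes")
    gene_of = {
        sid: ann.gene_id
        for sid, ann in annotations.items()
        if ann.gene_id is not None and ann.element in GENIC_ELEMENTS
    }
    sig_sites = site_results[site_results["significant"]]
    sig_dirs_by_gene: dict[str, list[str]] = {}
    for sid, row in sig_sites.iterrows():
        gid = gene_of.get(sid)
        if gid is not None:
            sig_dirs_by_gene.setdefault(gid, []).append(row["direction"])

    rows = []
    for gid, grow in gene_results.iterrows():
        dirs = sig_dirs_by_gene.get(gid, [])
        cond_site = len(dirs) > 0
        gene_dir = grow["direction"]
        if not cond_site or gene_dir == "none":
            cond_conc = False
        elif concordance == "strict":
            cond_conc = all(d == gene_dir for d in dirs)
        else:
            cond_conc = sum(d == gene_dir for d in dirs) > len(dirs) / 2
        dec = ScreenDecision(
            gene_id=gid,
            cond_site_dm=cond_site,
            cond_concordant=cond_conc,
            cond_pathway=gid in pathway_genes,
        )
        rows.append(
            {
                "gene_id": dec.gene_id,
                "cond_site_dm": dec.cond_site_dm,
                "cond_concordant": dec.cond_concordant,
                "cond_pathway": dec.cond_pathway,
                "selected": dec.selected,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class ClusterResult:
    linkage: np.ndarray
    leaf_order: list[str]
    zscores: pd.DataFrame  # gene x sample, row-z-scored log2(RPM+1)


def cluster_genes(gene_rpm: pd.DataFrame) -> ClusterResult:
    """Average-linkage hierarchical clustering of significant genes.

    Rows of log2(RPM + 1) are z-scored (constant rows are left at zero) and
    clustered on Euclidean distance. Ties break deterministically by input
    row order (scipy's agglomeration is deterministic for a fixed distance
    vector).
    """
    if gene_rpm.shape[0] < 2:
        raise ValueError(
            "clustering needs >= 2 significant genes; relax thresholds or "
            "check the differential step"
        )
    if gene_rpm.shape[1] < 2:
        raise ValueError("clustering needs >= 2 samples")
    log_rpm = np.log2(gene_rpm.to_numpy(dtype=float) + 1.0)
    mu = log_rpm.mean(axis=1, keepdims=True)
    sd = log_rpm.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (log_rpm - mu) / sd
    link = hierarchy.linkage(pdist(z, metric="euclidean"), method="average")
    order = hierarchy.leaves_list(link)
    zdf = pd.DataFrame(z, index=gene_rpm.index, columns=gene_rpm.columns)
    return ClusterResult(
        linkage=link,
        leaf_order=[gene_rpm.index[i] for i in order],
        zscores=zdf,
    )
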