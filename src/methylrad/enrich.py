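"""Hypergeometric over-representation testing against term-to-gene maps.

Given a query gene set (e.g. differentially methylated genes), a universe
(default: all genes carrying at least one signature site) and any
term-to-gene map (GO- or KEGG-style), each term with at least one query
member is scored by the upper-tail hypergeometric probability
P(X >= k) with k = |query ∩ term|, K = |term|, n = |query|, N = |universe|,
and Benjamini-Hochberg q-values are computed across the tested terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["TermMap", "hypergeom_upper_tail", "enrich", "read_gmt", "read_term_tsv"]

logger = logging.getLogger(__name__)


@dataclass
class TermMap:
    """One annotation term and its member genes."""

    term_id: str
    term_name: str = ""
    category: str = ""
    members: set[str] = field(default_factory=set)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValueError(
            f"invalid hypergeometric bounds: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: set[str],
    terms: list[TermMap],
    universe: set[str],
    correction: str = "fdr_bh",
) -> pd.DataFrame:
    """Over-representation test of *query* against every term.

    Query genes outside the universe are dropped with a warning; term
    memberships are intersected with the universe. Terms with zero query
    overlap are not tested (and do not enter the correction). Result rows
    are sorted by p-value.
    """
    outside = query - universe
    if outside:
        logger.warning(
            "%d query gene(s) outside the universe dropped: %s",
            len(outside),
            sorted(outside)[:5],
        )
    query = query & universe
    if not query:
        logger.warning("empty query after universe restriction")
        return pd.DataFrame(
            columns=["term_name", "category", "k", "K", "n", "N", "p_value", "q_value"]
        )
    N, n = len(universe), len(query)
    rows = []
    for t in terms:
        members = t.members & universe
        k = len(query & members)
        if k == 0:
            continue
        rows.append(
            {
                "term_id": t.term_id,
                "term_name": t.term_name,
                "category": t.category,
                "k": k,
                "K": len(members),
                "n": n,
                "N": N,
                "p_value": hypergeom_upper_tail(k, len(members), n, N),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_name", "category", "k", "K", "n", "N", "p_value", "q_value"]
        )
    out = pd.DataFrame(rows).set_index("term_id")
    method = {"fdr_bh": "fdr_bh", "bonferroni": "bonferroni"}[correction]
    out["q_value"] = multipletests(out["p_value"].to_numpy(), method=method)[1]
    return out.sort_values("p_value", kind="mergesort")


def read_gmt(path: str | Path) -> list[TermMap]:
    """Read a GMT file (term, description, members...)."""
    terms = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms.append(
                TermMap(
                    term_id=parts[0],
                    term_name=parts[1],
                    members={g for g in parts[2:] if g},
                )
            )
    return terms


def read_term_tsv(path: str | Path) -> list[TermMap]:
    """Read a long-format TSV: term_id <tab> gene_id [<tab> term_name [<tab> category]]."""
    by_id: dict[str, TermMap] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("term_id\t"):
                continue
            parts = line.split("\t")
            term_id, gene = parts[0], parts[1]
            t = by_id.setdefault(term_id, TermMap(term_id=term_id))
            t.members.add(gene)
            if len(parts) > 2 and parts[2]:
                t.term_name = parts[2]
            if len(parts) > 3 and parts[3]:
                t.category = parts[3]
    return list(by_id.values())
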