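"""Site-level methylation quantification.

Because a MethylRAD library consists of fixed-length signature fragments,
read-to-site assignment reduces to near-exact matching of the read prefix
against the indexed fragment set (both orientations, at most one
substitution by default); ambiguous and unmatched reads are discarded but
counted. Depth at a site then measures its methylation: a site covered by
at least three reads in a sample is called an authentic methylated site,
and levels are expressed as reads per million assigned reads (RPM).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .digest import FRAGMENT_LENGTH, SiteCatalog, reverse_complement

__all__ = [
    "AssignmentReport",
    "SiteCountTable",
    "assign_reads",
    "call_authentic",
    "authentic_mask",
    "rpm_normalize",
    "sample_correlation",
]

DEFAULT_MIN_DEPTH = 3
_BASES = "ACGT"


@dataclass
class AssignmentReport:
    total: int = 0
    assigned: int = 0
    unassigned: int = 0
    ambiguous: int = 0

    def __post_init__(self) -> None:
        pass

    @property
    def conserved(self) -> bool:
        return self.assigned + self.unassigned + self.ambiguous == self.total


@dataclass
class SiteCountTable:
    """Site x sample read counts with per-sample group labels.

    ``counts`` is a DataFrame indexed by site_id with one column per
    sample; library size is the per-sample total of assigned reads, i.e.
    the column sum.
    """

    counts: pd.DataFrame
    groups: pd.Series  # sample_id -> "treated" | "control"

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.rename_axis("site_id").to_csv(path, sep="\t")


def _mismatch_neighbors(seq: str):
    for i, base in enumerate(seq):
        for alt in _BASES:
            if alt != base:
                yield seq[:i] + alt + seq[i + 1 :]


def _lookup_sites(index: Mapping[str, list[str]], keys: Iterable[str]) -> set[str]:
    hits: set[str] = set()
    for key in keys:
        ids = index.get(key)
        if ids:
            hits.update(ids)
    return hits


def assign_reads(
    reads: Iterable[str],
    catalog: SiteCatalog,
    max_mismatches: int = 1,
) -> tuple[Counter, AssignmentReport]:
    """Assign each read to at most one catalog site.

    A read is compared, in both orientations and trimmed to each fragment
    length present in the catalog, against the fragment index: an exact hit
    wins; otherwise single-substitution neighbours are tried (when
    ``max_mismatches`` >= 1). Reads hitting no site are unassigned; reads
    tied between distinct sites at their best distance are ambiguous. Both
    are discarded but tallied, so assigned + unassigned + ambiguous equals
    the input count.
    """
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    index = catalog.index
    lengths = sorted({FRAGMENT_LENGTH[s.motif_class] for s in catalog}, reverse=True)
    counts: Counter = Counter()
    report = AssignmentReport()
    for seq in reads:
        report.total += 1
        seq = seq.upper()
        prefixes = []
        rc = reverse_complement(seq)
        for L in lengths:
            if len(seq) >= L:
                prefixes.append(seq[:L])
                prefixes.append(rc[:L])
        if not prefixes:
            report.unassigned += 1
            continue
        hits = _lookup_sites(index, prefixes)
        if not hits and max_mismatches >= 1:
            neighbor_keys = itertools.chain.from_iterable(
                _mismatch_neighbors(p) for p in prefixes
            )
            hits = _lookup_sites(index, neighbor_keys)
        if len(hits) == 1:
            counts[next(iter(hits))] += 1
            report.assigned += 1
        elif not hits:
            report.unassigned += 1
        else:
            report.ambiguous += 1
    return counts, report


def call_authentic(count: int, min_depth: int = DEFAULT_MIN_DEPTH) -> bool:
    """A site is an authentic methylated site when covered by >= min_depth reads."""
    if count < 0:
        raise ValueError("negative count")
    return count >= min_depth


def authentic_mask(counts: pd.DataFrame, min_depth: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """Per-sample boolean authenticity calls for a whole count matrix."""
    return counts >= min_depth


def rpm_normalize(table: SiteCountTable) -> pd.DataFrame:
    """Reads-per-million matrix: count / library_size * 1e6 per cell."""
    libs = table.library_sizes
    zero = libs[libs == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return table.counts / libs * 1e6


def sample_correlation(
    rpm: pd.DataFrame, authentic: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlation of samples on log2(RPM + 1).

    Restricted to sites authentic in at least one sample when an
    authenticity mask is given. A sample with a constant profile yields NaN
    entries (undefined correlation) rather than a silent zero.
    """
    if rpm.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if authentic is not None:
        keep = authentic.any(axis=1)
        rpm = rpm.loc[keep]
    if rpm.shape[0] < 3:
        raise ValueError("need at least 3 sites shared across samples")
    log_rpm = np.log2(rpm + 1.0)
    corr = log_rpm.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr
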