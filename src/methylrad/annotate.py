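"""Genomic-element annotation of methylation sites.

Each signature site is placed into exactly one element class — 5'UTR,
3'UTR, exon, intron, promoter, CTCF region or intergenic — by overlapping
the recognition-motif midpoint with gene models, resolving overlaps by a
most-specific-wins precedence (UTR5 > UTR3 > exon > intron > promoter >
CTCF > intergenic). The promoter is the configurable window (default
2,000 bp) upstream of the strand-aware TSS; CTCF regions are optional
user-supplied intervals. The per-sample tabulation of authentic sites over
elements gives the genome-component distribution of the methylome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .digest import ReferenceSite

__all__ = [
    "GeneModel",
    "SiteAnnotation",
    "AnnotationIndex",
    "ELEMENT_PRECEDENCE",
    "load_annotation",
    "load_ctcf_bed",
    "annotate_site",
    "annotate_catalog",
    "element_distribution",
]

logger = logging.getLogger(__name__)

ELEMENT_PRECEDENCE = ("UTR5", "UTR3", "exon", "intron", "promoter", "CTCF", "intergenic")
DEFAULT_PROMOTER_BP = 2000


@dataclass
class GeneModel:
    """A gene with the intervals used for site annotation (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    promoter: tuple[int, int] | None = None

    @property
    def introns(self) -> list[tuple[int, int]]:
        if not self.exons:
            return []
        exons = sorted(self.exons)
        out = []
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


@dataclass(frozen=True)
class SiteAnnotation:
    site_id: str
    element: str
    gene_id: str | None = None


def _promoter_interval(strand: str, tx_start: int, tx_end: int, promoter_bp: int) -> tuple[int, int]:
    if strand == "-":
        return (tx_end, tx_end + promoter_bp)
    return (max(0, tx_start - promoter_bp), tx_start)


def load_annotation(
    gff_path: str | Path,
    promoter_bp: int = DEFAULT_PROMOTER_BP,
    known_contigs: set[str] | None = None,
) -> list[GeneModel]:
    """Parse a GFF3 into gene models (coordinates converted to 0-based half-open).

    Features on contigs absent from *known_contigs* (when given) are skipped
    with a warning.
    """
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if known_contigs is not None and gene.seqid not in known_contigs:
            logger.warning("gene %s references unknown contig %s; skipped", gene.id, gene.seqid)
            continue
        tx_start, tx_end = gene.start - 1, gene.end
        model = GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand if gene.strand in "+-" else "+",
            tx_start=tx_start,
            tx_end=tx_end,
            promoter=_promoter_interval(gene.strand, tx_start, tx_end, promoter_bp),
        )
        for ftype, target in (
            ("exon", model.exons),
            ("five_prime_UTR", model.utr5),
            ("three_prime_UTR", model.utr3),
        ):
            for feat in db.children(gene, featuretype=ftype, order_by="start"):
                target.append((feat.start - 1, feat.end))
        models.append(model)
    return models


def load_ctcf_bed(bed_path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read CTCF-region intervals from a BED file (chrom, start, end, ...)."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.setdefault(chrom, []).append((int(start), int(end)))
    return intervals


class AnnotationIndex:
    """Interval-tree index over gene-model elements for midpoint queries."""

    def __init__(
        self,
        models: list[GeneModel],
        ctcf: dict[str, list[tuple[int, int]]] | None = None,
    ):
        self.models = models
        self._trees: dict[str, IntervalTree] = {}
        for m in models:
            tree = self._trees.setdefault(m.chrom, IntervalTree())
            for kind, ivals in (
                ("UTR5", m.utr5),
                ("UTR3", m.utr3),
                ("exon", m.exons),
                ("intron", m.introns),
                ("promoter", [m.promoter] if m.promoter else []),
            ):
                for s, e in ivals:
                    if e > s:
                        tree.addi(s, e, (kind, m.gene_id))
        for chrom, ivals in (ctcf or {}).items():
            tree = self._trees.setdefault(chrom, IntervalTree())
            for s, e in ivals:
                if e > s:
                    tree.addi(s, e, ("CTCF", None))

    def classify(self, chrom: str, pos: int) -> tuple[str, str | None]:
        tree = self._trees.get(chrom)
        if tree is None:
            return "intergenic", None
        hits = {}
        for iv in tree.at(pos):
            kind, gene_id = iv.data
            # deterministic: keep the lexically smallest gene per element kind
            if kind not in hits or (gene_id or "") < (hits[kind] or ""):
                hits[kind] = gene_id
        for kind in ELEMENT_PRECEDENCE[:-1]:
            if kind in hits:
                return kind, hits[kind]
        return "intergenic", None


def annotate_site(
    site: ReferenceSite,
    index: AnnotationIndex,
) -> SiteAnnotation:
    """Classify one site by its motif midpoint; gene_id attached for genic elements."""
    element, gene_id = index.classify(site.chrom, site.midpoint)
    return SiteAnnotation(site_id=site.site_id, element=element, gene_id=gene_id)


def annotate_catalog(
    catalog,
    models: list[GeneModel],
    ctcf: dict[str, list[tuple[int, int]]] | None = None,
) -> dict[str, SiteAnnotation]:
    index = AnnotationIndex(models, ctcf)
    return {s.site_id: annotate_site(s, index) for s in catalog}


def element_distribution(
    annotations: dict[str, SiteAnnotation],
    authentic: pd.DataFrame,
) -> pd.DataFrame:
    """Count authentic sites per element per sample (element x sample table)."""
    elements = pd.Series(
        {sid: ann.element for sid, ann in annotations.items()}, name="element"
    )
    table = pd.DataFrame(
        0, index=list(ELEMENT_PRECEDENCE), columns=list(authentic.columns)
    )
    common = authentic.index.intersection(elements.index)
    auth = authentic.loc[common]
    elem = elements.loc[common]
    for sample in auth.columns:
        counts = elem[auth[sample]].value_counts()
        for element, n in counts.items():
            table.loc[element, sample] = int(n)
    return table


def annotations_to_tsv(annotations: dict[str, SiteAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\telement\tgene_id\n")
        for sid in sorted(annotations):
            a = annotations[sid]
            fh.write(f"{a.site_id}\t{a.element}\t{a.gene_id or ''}\n")
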