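"""In-silico FspEI digestion: signature-site discovery on a reference genome.

FspEI is an MspJI-family methylation-dependent restriction enzyme. It
recognizes 5mC/5hmC in CCGG and CCWGG (W = A or T) contexts and cleaves on
both sides of the recognition site, releasing a short fragment with the
motif at its center: 32 bp for CCGG (14 + 4 + 14) and 31 bp for CCWGG
(13 + 5 + 13). A MethylRAD library consists of exactly these fragments, so
the set of all such "signature" intervals over a genome is the reference
against which reads are counted.

CCGG is its own reverse complement and the reverse complement of CCAGG is
CCTGG (also a recognition motif), so every recognition locus is seen by the
enzyme on both strands; each distinct motif offset on the forward text is
emitted once with strand "both".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from pyfaidx import Fasta

__all__ = [
    "ReferenceSite",
    "SiteCatalog",
    "scan_motifs",
    "extract_fragment",
    "build_catalog",
    "write_catalog",
    "load_catalog",
    "reverse_complement",
    "MOTIF_CLASS",
    "FLANK",
    "FRAGMENT_LENGTH",
]

# forward-text motifs and the class each belongs to
MOTIF_CLASS = {"CCGG": "CCGG", "CCAGG": "CCWGG", "CCTGG": "CCWGG"}
FLANK = {"CCGG": 14, "CCWGG": 13}
FRAGMENT_LENGTH = {"CCGG": 32, "CCWGG": 31}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_RE = re.compile(r"[^ACGTN]")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceSite:
    """One FspEI recognition locus and its signature fragment interval.

    Coordinates are 0-based half-open. The fragment is centered on the
    motif: equal flanks of 14 (CCGG) or 13 (CCWGG) bp on each side.
    """

    site_id: str
    chrom: str
    motif_start: int
    motif_class: str  # "CCGG" | "CCWGG"
    motif_strand: str  # "+" | "-" | "both"
    fragment_start: int
    fragment_end: int
    fragment_seq: str

    @property
    def motif_length(self) -> int:
        return 4 if self.motif_class == "CCGG" else 5

    @property
    def midpoint(self) -> int:
        return self.motif_start + self.motif_length // 2


@dataclass
class SiteCatalog:
    """Ordered collection of reference sites with a fragment-sequence index.

    ``index`` maps both the fragment sequence and its reverse complement to
    the list of site_ids carrying it, so read lookup is orientation-free.
    """

    sites: list[ReferenceSite]
    genome_id: str = ""
    index: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site_ids in catalog")
        if not self.index:
            self.rebuild_index()

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[ReferenceSite]:
        return iter(self.sites)

    def rebuild_index(self) -> None:
        index: dict[str, list[str]] = {}
        for s in self.sites:
            for key in (s.fragment_seq, reverse_complement(s.fragment_seq)):
                index.setdefault(key, [])
                if s.site_id not in index[key]:
                    index[key].append(s.site_id)
        self.index = index

    def by_id(self) -> dict[str, ReferenceSite]:
        return {s.site_id: s for s in self.sites}


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    m = _VALID_RE.search(seq)
    if m:
        raise ValueError(
            f"non-nucleotide character {seq[m.start()]!r} at position {m.start()}"
        )
    return seq


def _site_id(chrom: str, motif_start: int, motif_class: str) -> str:
    return f"{chrom}:{motif_start}:{motif_class}"


def scan_motifs(sequence: str, chrom: str) -> list[ReferenceSite]:
    """Find every FspEI recognition locus in *sequence* and emit its site.

    Each forward-text occurrence of CCGG, CCAGG or CCTGG is one locus
    (palindromy / the CCAGG-CCTGG pairing means every locus is cut on both
    strands, so ``motif_strand`` is "both"). Loci whose centered fragment
    would run past a sequence edge, or whose fragment contains an N, are
    dropped: such signatures cannot appear in (or be mapped from) a library.
    """
    seq = _validate_sequence(sequence)
    n = len(seq)
    sites: list[ReferenceSite] = []
    for motif, mclass in MOTIF_CLASS.items():
        flank = FLANK[mclass]
        start = seq.find(motif)
        while start != -1:
            frag_start = start - flank
            frag_end = start + len(motif) + flank
            if frag_start >= 0 and frag_end <= n:
                frag = seq[frag_start:frag_end]
                if "N" not in frag:
                    sites.append(
                        ReferenceSite(
                            site_id=_site_id(chrom, start, mclass),
                            chrom=chrom,
                            motif_start=start,
                            motif_class=mclass,
                            motif_strand="both",
                            fragment_start=frag_start,
                            fragment_end=frag_end,
                            fragment_seq=frag,
                        )
                    )
            start = seq.find(motif, start + 1)
    sites.sort(key=lambda s: (s.chrom, s.motif_start, s.motif_class))
    return sites


def extract_fragment(site: ReferenceSite, genome) -> str:
    """Return the signature fragment for *site* from a genome accessor.

    *genome* is any mapping from chromosome name to a sliceable sequence
    (a ``pyfaidx.Fasta``, a dict of strings, ...).
    """
    try:
        chrom_seq = genome[site.chrom]
    except KeyError as exc:
        raise KeyError(f"site {site.site_id}: unknown chromosome {site.chrom}") from exc
    chrom_len = len(chrom_seq)
    if site.fragment_start < 0 or site.fragment_end > chrom_len:
        raise ValueError(
            f"site {site.site_id}: fragment [{site.fragment_start}, "
            f"{site.fragment_end}) outside chromosome of length {chrom_len}"
        )
    frag = chrom_seq[site.fragment_start : site.fragment_end]
    return str(frag).upper()


def build_catalog(genome_fasta: str | Path, genome_id: str | None = None) -> SiteCatalog:
    """Scan a multi-contig FASTA and return the full signature-site catalog.

    Sites are ordered (chrom, motif_start, motif_class) within each contig,
    contigs in file order; the fragment index includes reverse complements.
    """
    genome_fasta = Path(genome_fasta)
    fa = Fasta(str(genome_fasta), duplicate_action="stop", rebuild=True)
    contigs = list(fa.keys())
    if not contigs:
        raise ValueError(f"empty FASTA: {genome_fasta}")
    sites: list[ReferenceSite] = []
    for name in contigs:
        sites.extend(scan_motifs(str(fa[name][:]), name))
    sites.sort(key=lambda s: (s.chrom, s.motif_start, s.motif_class))
    return SiteCatalog(sites=sites, genome_id=genome_id or genome_fasta.stem)


def write_catalog(catalog: SiteCatalog, out_prefix: str | Path) -> dict[str, Path]:
    """Write a catalog as BED6 + TSV sidecar + signature FASTA.

    Returns the mapping of output kind to path. The TSV carries every field
    needed to reload the catalog without the genome.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    bed = out_prefix.with_suffix(".bed")
    tsv = out_prefix.with_suffix(".sites.tsv")
    fasta = out_prefix.with_suffix(".frags.fa")
    with open(bed, "w") as bh, open(tsv, "w") as th, open(fasta, "w") as fh:
        th.write(
            "site_id\tchrom\tmotif_start\tmotif_class\tmotif_strand\t"
            "fragment_start\tfragment_end\tfragment_seq\n"
        )
        for s in catalog:
            strand = "." if s.motif_strand == "both" else s.motif_strand
            bh.write(
                f"{s.chrom}\t{s.fragment_start}\t{s.fragment_end}\t{s.site_id}\t0\t{strand}\n"
            )
            th.write(
                f"{s.site_id}\t{s.chrom}\t{s.motif_start}\t{s.motif_class}\t"
                f"{s.motif_strand}\t{s.fragment_start}\t{s.fragment_end}\t{s.fragment_seq}\n"
            )
            fh.write(f">{s.site_id}\n{s.fragment_seq}\n")
    return {"bed": bed, "tsv": tsv, "fasta": fasta}


def load_catalog(tsv_path: str | Path, genome_id: str = "") -> SiteCatalog:
    """Reload a catalog from the TSV sidecar written by :func:`write_catalog`."""
    sites = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sites.append(
                ReferenceSite(
                    site_id=f[cols["site_id"]],
                    chrom=f[cols["chrom"]],
                    motif_start=int(f[cols["motif_start"]]),
                    motif_class=f[cols["motif_class"]],
                    motif_strand=f[cols["motif_strand"]],
                    fragment_start=int(f[cols["fragment_start"]]),
                    fragment_end=int(f[cols["fragment_end"]]),
                    fragment_seq=f[cols["fragment_seq"]],
                )
            )
    return SiteCatalog(sites=sites, genome_id=genome_id)
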