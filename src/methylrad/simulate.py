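"""Synthetic MethylRAD study generator with known ground truth.

Emulates the design of the ATRA-induced cleft-palate experiment: two groups
of three biological replicates (treated vs control), a small multi-contig
genome with planted FspEI recognition sites distributed over gene elements
(promoter, UTRs, exons, introns, CTCF regions, intergenic), per-group
methylation states with planted hyper- and hypomethylated genes, negative
binomial read depth, and qPCR Ct values coupled (anti-correlated) to the
planted methylation changes.

Two planted genes mirror the study's candidates: an "fgf16-like" gene whose
hypermethylated sites sit in its promoter and an adjacent CTCF region, and
a "tbx22-like" gene hypermethylated across its 5'UTR, exons and 3'UTR. One
planted gene carries deliberately discordant site directions to exercise
the concordance condition of the candidate screen, and a configurable
fraction of deliberately failing reads (low quality / high N) exercises the
QC rules.

The genome background is motif-scrubbed in strict mode: outside the planted
positions no CCGG/CCWGG occurs, so the digestion catalog equals the planted
site list exactly. Identical seed and configuration reproduce every output
file byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .digest import FLANK, MOTIF_CLASS, SiteCatalog, build_catalog, reverse_complement

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genome_and_annotation",
    "simulate_reads",
    "simulate_qpcr",
    "simulate_all",
]

_MOTIF_STRINGS = ("CCGG", "CCAGG", "CCTGG")

# gene-body geometry, relative to tx_start (plus strand)
_TX_LEN = 3000
_EXONS = [(0, 600), (1500, 2100), (2400, 3000)]
_UTR5_PLUS = (0, 200)
_UTR3_PLUS = (2700, 3000)
_UTR5_MINUS = (2800, 3000)
_UTR3_MINUS = (0, 300)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions.

    Two groups of ``n_per_group`` = 3 samples; site read depth follows
    NB(mean = baseline_depth * methylation level, dispersion phi); planted
    differential genes carry log2 fold change ``planted_lfc``.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 100_000
    gc_content: float = 0.42
    n_genes: int = 30
    n_hyper_genes: int = 3  # includes the fgf16-like and tbx22-like genes
    n_hypo_genes: int = 2
    n_discordant_genes: int = 1
    planted_lfc: float = 2.0
    baseline_depth: float = 50.0
    phi: float = 0.1
    # site methylation levels are bimodal (as CpG methylation is): a high
    # mode and a low mode mixed at low_meth_frac; signature capture
    # efficiency varies log-normally across sites (sd in natural log)
    meth_prob_range: tuple[float, float] = (0.5, 1.0)
    low_meth_range: tuple[float, float] = (0.02, 0.15)
    low_meth_frac: float = 0.35
    efficiency_sd: float = 1.0
    promoter_bp: int = 2000
    error_rate: float = 0.002
    qc_fail_frac: float = 0.05
    n_per_group: int = 3
    qpcr_slope: float = 1.0
    ct_noise_sd: float = 0.2
    base_delta_ct: float = 4.0
    reference_ct: float = 16.0

    def __post_init__(self) -> None:
        for name in ("gc_content", "error_rate", "qc_fail_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.baseline_depth <= 0:
            raise ValueError("baseline_depth must be > 0")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        n_planted = self.n_hyper_genes + self.n_hypo_genes + self.n_discordant_genes
        if n_planted > self.n_genes:
            raise ValueError("more planted genes than genes")

    @property
    def sample_ids(self) -> list[str]:
        return [f"T{i+1}" for i in range(self.n_per_group)] + [
            f"C{i+1}" for i in range(self.n_per_group)
        ]

    @property
    def groups(self) -> pd.Series:
        return pd.Series(
            {
                s: ("treated" if s.startswith("T") else "control")
                for s in self.sample_ids
            }
        )


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed consistently with the pipeline."""

    sites: pd.DataFrame  # site_id, chrom, motif_start, motif_class, element, gene_id, mu_control, mu_treated
    genes: pd.DataFrame  # gene_id, role, true_lfc, in_pathway
    pathway_genes: list[str] = field(default_factory=list)
    expected_selected: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        self.sites.to_csv(out_dir / "truth_sites.tsv", sep="\t", index=False)
        self.genes.to_csv(out_dir / "truth_genes.tsv", sep="\t", index=False)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)


def _find_motifs(seq: str) -> list[tuple[int, str]]:
    hits = []
    for motif in _MOTIF_STRINGS:
        start = seq.find(motif)
        while start != -1:
            hits.append((start, motif))
            start = seq.find(motif, start + 1)
    return hits


def _scrub(seq: np.ndarray, rng: np.random.Generator, protected: list[tuple[int, int]] | None = None) -> None:
    """Mutate bases until no recognition motif remains outside protected spans."""
    protected = protected or []
    for _ in range(200):
        text = seq.tobytes().decode()
        dirty = [
            (pos, motif)
            for pos, motif in _find_motifs(text)
            if not any(ps <= pos and pos + len(motif) <= pe for ps, pe in protected)
        ]
        if not dirty:
            return
        for pos, motif in dirty:
            # mutate one base of the occurrence that is not inside a protected span
            for off in rng.permutation(len(motif)):
                p = pos + int(off)
                if not any(ps <= p < pe for ps, pe in protected):
                    current = seq[p]
                    choices = [b for b in (b"A", b"C", b"G", b"T") if b != current]
                    seq[p] = choices[int(rng.integers(len(choices)))]
                    break
    raise RuntimeError("failed to scrub genome background of recognition motifs")


def _gene_layout(cfg: SimulationConfig) -> list[dict]:
    """Deterministic placement of gene models along the chromosomes."""
    genes = []
    if cfg.n_genes == 0:
        return genes
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chromosomes))
    stride = cfg.chrom_length // per_chrom
    if stride < _TX_LEN + cfg.promoter_bp + 3000:
        raise ValueError(
            "requested genes exceed genome capacity: increase chrom_length "
            "or reduce n_genes"
        )
    for g in range(cfg.n_genes):
        chrom_idx = g // per_chrom
        block = (g % per_chrom) * stride
        strand = "+" if g % 2 == 0 else "-"
        tx_start = block + cfg.promoter_bp + 2000
        genes.append(
            {
                "gene_id": f"g{g+1:02d}",
                "chrom": f"chr{chrom_idx+1}",
                "strand": strand,
                "tx_start": tx_start,
                "tx_end": tx_start + _TX_LEN,
                "block_start": block,
            }
        )
    return genes


def _site_plan(cfg: SimulationConfig, genes: list[dict], rng: np.random.Generator) -> list[dict]:
    """Choose motif positions per element for every gene plus intergenic/CTCF."""
    plan = []

    def add(chrom, pos, motif, element, gene_id):
        plan.append(
            {
                "chrom": chrom,
                "motif_start": int(pos),
                "motif": motif,
                "element": element,
                "gene_id": gene_id,
            }
        )

    for i, g in enumerate(genes):
        ts, te, chrom, gid = g["tx_start"], g["tx_end"], g["chrom"], g["gene_id"]
        plus = g["strand"] == "+"
        motifs = ["CCGG", "CCAGG" if i % 2 else "CCTGG", "CCGG", "CCAGG", "CCTGG", "CCGG"]
        if plus:
            add(chrom, ts - 1000, motifs[0], "promoter", gid)
            add(chrom, ts + 100, motifs[1], "UTR5", gid)
            add(chrom, ts + 1700, motifs[2], "exon", gid)
            add(chrom, ts + 800, motifs[3], "intron", gid)
            add(chrom, ts + 2250, motifs[4], "intron", gid)
            add(chrom, ts + 2850, motifs[5], "UTR3", gid)
        else:
            add(chrom, te + 1000, motifs[0], "promoter", gid)
            add(chrom, ts + 2900, motifs[1], "UTR5", gid)
            add(chrom, ts + 1700, motifs[2], "exon", gid)
            add(chrom, ts + 800, motifs[3], "intron", gid)
            add(chrom, ts + 2250, motifs[4], "intron", gid)
            add(chrom, ts + 150, motifs[5], "UTR3", gid)
        # intergenic sites per gene block, clear of promoter/tx/CTCF intervals;
        # together with the introns they hold ~60% of all sites, matching the
        # empirical concentration of methylation sites outside exons/UTRs
        for j in range(4):
            add(
                chrom,
                g["block_start"] + 200 + j * 250,
                "CCGG" if (i + j) % 2 else ("CCAGG" if j % 2 else "CCTGG"),
                "intergenic",
                None,
            )

    # CTCF region adjacent to (upstream of) the first gene's promoter
    if genes:
        g0 = genes[0]
        prom_start = g0["tx_start"] - cfg.promoter_bp
        ctcf_start, ctcf_end = prom_start - 800, prom_start - 400
        add(g0["chrom"], ctcf_start + 80, "CCGG", "CTCF", None)
        add(g0["chrom"], ctcf_start + 250, "CCAGG", "CTCF", None)
    plan.sort(key=lambda d: (d["chrom"], d["motif_start"]))
    # sanity: planted motifs must not collide (spacing governs scrub safety)
    by_chrom: dict[str, int] = {}
    for d in plan:
        last = by_chrom.get(d["chrom"], -100)
        if d["motif_start"] - last < 50:
            raise ValueError("planted motifs closer than 50 bp; adjust layout")
        by_chrom[d["chrom"]] = d["motif_start"]
    return plan


def _assign_roles(cfg: SimulationConfig) -> pd.DataFrame:
    roles = []
    for g in range(cfg.n_genes):
        gid = f"g{g+1:02d}"
        if g == 0:
            role = "fgf16_like_hyper"
        elif g == 1:
            role = "tbx22_like_hyper"
        elif g < cfg.n_hyper_genes:
            role = "hyper"
        elif g < cfg.n_hyper_genes + cfg.n_hypo_genes:
            role = "hypo"
        elif g < cfg.n_hyper_genes + cfg.n_hypo_genes + cfg.n_discordant_genes:
            role = "discordant"
        else:
            role = "null"
        true_lfc = (
            cfg.planted_lfc
            if "hyper" in role
            else (-cfg.planted_lfc if role == "hypo" else 0.0)
        )
        roles.append({"gene_id": gid, "role": role, "true_lfc": true_lfc})
    df = pd.DataFrame(roles, columns=["gene_id", "role", "true_lfc"])
    # pathway membership: the expected candidates, the discordant decoy and
    # two null genes (so condition iii is non-trivial in both directions)
    pathway = set(
        df.loc[df["role"].isin(["fgf16_like_hyper", "tbx22_like_hyper"]), "gene_id"]
    )
    hypo = list(df.loc[df["role"] == "hypo", "gene_id"])
    if hypo:
        pathway.add(hypo[0])
    pathway.update(df.loc[df["role"] == "discordant", "gene_id"])
    nulls = list(df.loc[df["role"] == "null", "gene_id"])
    pathway.update(nulls[:2])
    df["in_pathway"] = df["gene_id"].isin(pathway)
    return df


def _write_gff(genes: list[dict], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            chrom, gid, strand = g["chrom"], g["gene_id"], g["strand"]
            ts, te = g["tx_start"], g["tx_end"]
            fh.write(
                f"{chrom}\tsim\tgene\t{ts+1}\t{te}\t.\t{strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{chrom}\tsim\tmRNA\t{ts+1}\t{te}\t.\t{strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}\n"
            )
            for es, ee in _EXONS:
                fh.write(
                    f"{chrom}\tsim\texon\t{ts+es+1}\t{ts+ee}\t.\t{strand}\t.\t"
                    f"Parent={gid}.t1\n"
                )
            u5 = _UTR5_PLUS if strand == "+" else _UTR5_MINUS
            u3 = _UTR3_PLUS if strand == "+" else _UTR3_MINUS
            fh.write(
                f"{chrom}\tsim\tfive_prime_UTR\t{ts+u5[0]+1}\t{ts+u5[1]}\t.\t"
                f"{strand}\t.\tParent={gid}.t1\n"
            )
            fh.write(
                f"{chrom}\tsim\tthree_prime_UTR\t{ts+u3[0]+1}\t{ts+u3[1]}\t.\t"
                f"{strand}\t.\tParent={gid}.t1\n"
            )


def simulate_genome_and_annotation(
    cfg: SimulationConfig, out_dir: str | Path
) -> GroundTruth:
    """Write genome FASTA, GFF3, CTCF BED and ground-truth tables.

    The background is motif-scrubbed, so the digestion catalog over the
    emitted genome contains exactly the planted sites.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_layout(cfg)
    plan = _site_plan(cfg, genes, rng)
    roles = _assign_roles(cfg)
    role_of = roles.set_index("gene_id")["role"].to_dict()

    chroms = {
        f"chr{i+1}": _random_sequence(rng, cfg.chrom_length, cfg.gc_content)
        for i in range(cfg.n_chromosomes)
    }
    protected: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for d in plan:
        seq = chroms[d["chrom"]]
        pos, motif = d["motif_start"], d["motif"]
        seq[pos : pos + len(motif)] = np.frombuffer(motif.encode(), dtype="S1")
        protected[d["chrom"]].append((pos, pos + len(motif)))
    for chrom, seq in chroms.items():
        _scrub(seq, rng, protected[chrom])

    with open(out_dir / "genome.fa", "w") as fh:
        for chrom in sorted(chroms):
            text = chroms[chrom].tobytes().decode()
            fh.write(f">{chrom}\n")
            for i in range(0, len(text), 80):
                fh.write(text[i : i + 80] + "\n")
    _write_gff(genes, out_dir / "genes.gff3")

    with open(out_dir / "ctcf.bed", "w") as fh:
        if genes:
            g0 = genes[0]
            prom_start = g0["tx_start"] - cfg.promoter_bp
            fh.write(f"{g0['chrom']}\t{prom_start-800}\t{prom_start-400}\tCTCF1\n")

    # per-site methylation means by group
    site_rows = []
    for d in plan:
        mclass = MOTIF_CLASS[d["motif"]]
        site_id = f"{d['chrom']}:{d['motif_start']}:{mclass}"
        role = role_of.get(d["gene_id"], "null") if d["gene_id"] else "null"
        planted_dm = role != "null" or d["element"] == "CTCF"
        if planted_dm:
            # candidate sites are robustly methylated with mild efficiency spread
            meth = rng.uniform(*cfg.meth_prob_range)
            eff = float(np.exp(rng.normal(0.0, min(0.3, cfg.efficiency_sd))))
        else:
            if rng.random() < cfg.low_meth_frac:
                meth = rng.uniform(*cfg.low_meth_range)
            else:
                meth = rng.uniform(*cfg.meth_prob_range)
            eff = float(np.exp(rng.normal(0.0, cfg.efficiency_sd)))
        mu_c = cfg.baseline_depth * meth * eff
        factor = 1.0
        if "hyper" in role:
            factor = 2.0**cfg.planted_lfc
        elif role == "hypo":
            factor = 2.0**-cfg.planted_lfc
        elif role == "discordant":
            up = d["element"] in ("promoter", "UTR5", "exon")
            factor = 2.0**cfg.planted_lfc if up else 2.0**-cfg.planted_lfc
        # CTCF sites adjacent to the fgf16-like gene are hypermethylated too
        if d["element"] == "CTCF":
            factor = 2.0**cfg.planted_lfc
        site_rows.append(
            {
                "site_id": site_id,
                "chrom": d["chrom"],
                "motif_start": d["motif_start"],
                "motif_class": mclass,
                "element": d["element"],
                "gene_id": d["gene_id"] or "",
                "mu_control": mu_c,
                "mu_treated": mu_c * factor,
            }
        )
    site_columns = [
        "site_id", "chrom", "motif_start", "motif_class", "element",
        "gene_id", "mu_control", "mu_treated",
    ]
    sites = (
        pd.DataFrame(site_rows, columns=site_columns)
        .sort_values(["chrom", "motif_start"])
        .reset_index(drop=True)
    )
    pathway = sorted(roles.loc[roles["in_pathway"], "gene_id"])
    expected = sorted(
        roles.loc[
            roles["in_pathway"] & roles["role"].str.contains("hyper|hypo"), "gene_id"
        ]
    )
    truth = GroundTruth(
        sites=sites, genes=roles, pathway_genes=pathway, expected_selected=expected
    )
    truth.write(out_dir)
    with open(out_dir / "pathway_genes.txt", "w") as fh:
        for gid in pathway:
            fh.write(gid + "\n")
    return truth


_QUAL_HIGH = np.arange(35, 41)  # mean 37.5 -> passes the Phred>=30 rule


def _mutate_read(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    errs = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in errs:
        current = arr[i]
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != current]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def simulate_reads(
    cfg: SimulationConfig,
    catalog: SiteCatalog,
    truth: GroundTruth,
    out_dir: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write per-sample FASTQ files; return (expected counts, sample sheet).

    Per site and sample the read count is NB(mean = group mean from the
    ground truth, dispersion phi); each read is the signature fragment (in
    either orientation) with substitution errors at ``error_rate`` and
    passing quality strings. A ``qc_fail_frac`` fraction of extra reads is
    deliberately failing (low mean quality or >8% N), labelled in the read
    id, to exercise the QC rules.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 1)
    mu = truth.sites.set_index("site_id")[["mu_control", "mu_treated"]]
    frag_of = {s.site_id: s.fragment_seq for s in catalog}
    missing = set(mu.index) - set(frag_of)
    if missing:
        raise ValueError(f"ground-truth sites absent from catalog: {sorted(missing)[:5]}")

    samples = cfg.sample_ids
    groups = cfg.groups
    expected = pd.DataFrame(0, index=list(mu.index), columns=samples, dtype=int)
    sheet_rows = []
    for sample in samples:
        col = "mu_treated" if groups[sample] == "treated" else "mu_control"
        fq = out_dir / f"{sample}.fastq"
        n_good = 0
        with open(fq, "w") as fh:
            for site_id, m in mu[col].items():
                if m <= 0:
                    continue
                if cfg.phi > 0:
                    r = 1.0 / cfg.phi
                    count = int(rng.negative_binomial(r, r / (r + m)))
                else:
                    count = int(rng.poisson(m))
                expected.loc[site_id, sample] = count
                frag = frag_of[site_id]
                for i in range(count):
                    seq = frag if rng.random() < 0.5 else reverse_complement(frag)
                    seq = _mutate_read(seq, rng, cfg.error_rate)
                    qual = "".join(
                        chr(q + 33) for q in rng.choice(_QUAL_HIGH, size=len(seq))
                    )
                    fh.write(f"@{sample}:{site_id}:{i}\n{seq}\n+\n{qual}\n")
                    n_good += 1
            n_fail = int(round(cfg.qc_fail_frac * n_good))
            all_sites = list(mu.index)
            for j in range(n_fail):
                frag = frag_of[all_sites[int(rng.integers(len(all_sites)))]]
                if j % 2 == 0:  # low mean quality
                    qual = "".join(
                        chr(int(q) + 33) for q in rng.integers(10, 25, size=len(frag))
                    )
                    fh.write(f"@{sample}:FAILQ:{j}\n{frag}\n+\n{qual}\n")
                else:  # >8% N content
                    arr = np.frombuffer(frag.encode(), dtype="S1").copy()
                    n_n = max(1, int(np.ceil(0.15 * len(arr))))
                    idx = rng.choice(len(arr), size=n_n, replace=False)
                    arr[idx] = b"N"
                    qual = "".join(
                        chr(q + 33) for q in rng.choice(_QUAL_HIGH, size=len(arr))
                    )
                    fh.write(f"@{sample}:FAILN:{j}\n{arr.tobytes().decode()}\n+\n{qual}\n")
        sheet_rows.append(
            {"sample_id": sample, "group": groups[sample], "fastq": str(fq)}
        )
    sheet = pd.DataFrame(sheet_rows)
    sheet.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
    expected.rename_axis("site_id").to_csv(out_dir / "expected_counts.tsv", sep="\t")
    return expected, sheet


def simulate_qpcr(
    cfg: SimulationConfig,
    truth: GroundTruth,
    genes: list[str] | None = None,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Ct table coupled to planted methylation: dCt rises with methylation.

    For treated samples dCt = base + slope * true methylation log2FC (plus
    Gaussian noise per replicate), so a hypermethylated gene comes out
    repressed: at slope 1 and planted log2FC 2 the expected expression fold
    change is 2^-2 = 0.25.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    roles = truth.genes.set_index("gene_id")
    if genes is None:
        genes = sorted(roles.index[roles["role"] != "null"])
    rows = []
    for gid in genes:
        lfc = float(roles.loc[gid, "true_lfc"])
        for sample in cfg.sample_ids:
            treated = cfg.groups[sample] == "treated"
            dct = cfg.base_delta_ct + (cfg.qpcr_slope * lfc if treated else 0.0)
            for rep in range(n_replicates):
                noise = rng.normal(0.0, cfg.ct_noise_sd) if cfg.ct_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "sample_id": sample,
                        "group": cfg.groups[sample],
                        "gene_id": gid,
                        "replicate": rep + 1,
                        "ct_target": cfg.reference_ct + dct + noise,
                        "ct_reference": cfg.reference_ct,
                    }
                )
    return pd.DataFrame(rows)


def _write_term_map(truth: GroundTruth, path: Path) -> None:
    """Term-to-gene map with one genuinely CP-enriched term plus fillers."""
    all_genes = list(truth.genes["gene_id"])
    planted = list(
        truth.genes.loc[truth.genes["role"] != "null", "gene_id"]
    )
    terms = {
        "TERM:palate_fusion": ("palatal fusion signaling", planted),
        "TERM:housekeeping": ("housekeeping", all_genes[::2]),
        "TERM:misc_a": ("misc process A", all_genes[1::3]),
        "TERM:misc_b": ("misc process B", all_genes[2::4] or all_genes[:1]),
    }
    with open(path, "w") as fh:
        fh.write("term_id\tgene_id\tterm_name\tcategory\n")
        for tid, (name, members) in terms.items():
            for gid in members:
                fh.write(f"{tid}\t{gid}\t{name}\tpathway\n")


def simulate_all(cfg: SimulationConfig, out_dir: str | Path) -> dict:
    """Generate the complete synthetic study into *out_dir*.

    Returns a dict with the ground truth, the digestion catalog and every
    output path. Identical config (including seed) reproduces all files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = simulate_genome_and_annotation(cfg, out_dir)
    catalog = build_catalog(out_dir / "genome.fa")
    expected, sheet = simulate_reads(cfg, catalog, truth, out_dir)
    ct = simulate_qpcr(cfg, truth)
    ct.to_csv(out_dir / "ct.tsv", sep="\t", index=False)
    _write_term_map(truth, out_dir / "terms.tsv")
    cfg_dict = {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()
    }
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    return {
        "truth": truth,
        "catalog": catalog,
        "expected_counts": expected,
        "sample_sheet": sheet,
        "paths": {
            "genome": out_dir / "genome.fa",
            "gff": out_dir / "genes.gff3",
            "ctcf": out_dir / "ctcf.bed",
            "samples": out_dir / "samples.tsv",
            "ct": out_dir / "ct.tsv",
            "terms": out_dir / "terms.tsv",
            "pathway_genes": out_dir / "pathway_genes.txt",
            "config": out_dir / "config.yaml",
        },
    }
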