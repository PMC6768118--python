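"""End-to-end orchestration of the MethylRAD analysis stages.

Runs, in dependency order: in-silico digestion -> read QC -> site
quantification -> element annotation -> differential methylation (site and
gene level) -> candidate screen -> enrichment -> qPCR validation, from a
single config mapping, and writes a run manifest (config hash, input
checksums, per-stage record counts) that fully determines reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (
    annotate_catalog,
    annotations_to_tsv,
    element_distribution,
    load_annotation,
    load_ctcf_bed,
)
from .diff import aggregate_to_gene, differential_test
from .digest import build_catalog, write_catalog
from .enrich import enrich, read_term_tsv
from .qc import filter_fastq
from .qpcr import ddct_fold_change, load_ct_table, methylation_expression_concordance
from .quant import (
    SiteCountTable,
    assign_reads,
    authentic_mask,
    rpm_normalize,
    sample_correlation,
)
from .screen import cluster_genes, screen_genes

__all__ = ["run_all", "load_config"]

logger = logging.getLogger(__name__)

_INPUT_KEYS = ("genome", "gff", "samples")
_OPTIONAL_INPUT_KEYS = ("ctcf", "ct", "terms", "pathway_genes")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_fastq_seqs(path: Path):
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            yield seq


def run_all(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute every stage; returns in-memory results and writes all tables.

    *config* is a mapping (or YAML path) with input paths ``genome``,
    ``gff``, ``samples`` (sample sheet TSV: sample_id, group, fastq) and
    optional ``ctcf``, ``ct``, ``terms``, ``pathway_genes``, plus parameter
    overrides (min_phred, max_n_frac, min_depth, promoter_bp, p_cut,
    lfc_cut). Inputs are validated upfront: a missing file aborts before
    any stage runs.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(out_dir or config.get("out_dir", "methylrad_run"))
    out_dir.mkdir(parents=True, exist_ok=True)

    # upfront validation
    inputs: dict[str, Path] = {}
    for key in _INPUT_KEYS:
        if key not in config:
            raise ValueError(f"config missing required input: {key}")
        inputs[key] = Path(config[key])
    for key in _OPTIONAL_INPUT_KEYS:
        if config.get(key):
            inputs[key] = Path(config[key])
    sheet = pd.read_csv(inputs["samples"], sep="\t")
    for col in ("sample_id", "group", "fastq"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet missing column {col}")
    fastqs = {row.sample_id: Path(row.fastq) for row in sheet.itertuples()}
    missing = [
        str(p)
        for p in list(inputs.values()) + list(fastqs.values())
        if not p.exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")

    params = {
        "min_phred": float(config.get("min_phred", 30)),
        "max_n_frac": float(config.get("max_n_frac", 0.08)),
        "min_depth": int(config.get("min_depth", 3)),
        "promoter_bp": int(config.get("promoter_bp", 2000)),
        "p_cut": float(config.get("p_cut", 0.05)),
        "lfc_cut": float(config.get("lfc_cut", 1.0)),
        "max_mismatches": int(config.get("max_mismatches", 1)),
    }
    manifest: dict = {
        "tool_version": __version__,
        "seed": config.get("seed"),
        "parameters": params,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "input_checksums": {k: _sha256(p) for k, p in inputs.items()},
        "stages": {},
    }

    # --- digestion ---------------------------------------------------------
    logger.info("stage digest: scanning %s", inputs["genome"])
    try:
        catalog = build_catalog(inputs["genome"])
        write_catalog(catalog, out_dir / "catalog")
    except Exception as exc:
        raise RuntimeError(f"stage digest failed: {exc}") from exc
    manifest["stages"]["digest"] = {"sites": len(catalog)}

    # --- QC ----------------------------------------------------------------
    qc_dir = out_dir / "qc"
    qc_dir.mkdir(exist_ok=True)
    qc_counts = {}
    filtered = {}
    try:
        for sample, fq in fastqs.items():
            out_fq = qc_dir / f"{sample}.filtered.fastq"
            rep = filter_fastq(
                fq,
                out_fq,
                min_phred=params["min_phred"],
                max_n_frac=params["max_n_frac"],
            )
            rep.to_tsv(qc_dir / f"{sample}.qc.tsv")
            qc_counts[sample] = {"reads_in": rep.records_in, "reads_kept": rep.records_kept}
            filtered[sample] = out_fq
    except Exception as exc:
        raise RuntimeError(f"stage qc failed: {exc}") from exc
    manifest["stages"]["qc"] = qc_counts

    # --- quantification ----------------------------------------------------
    try:
        groups = pd.Series(sheet.set_index("sample_id")["group"])
        cols = {}
        assign_counts = {}
        for sample, fq in filtered.items():
            counts, rep = assign_reads(
                _read_fastq_seqs(fq), catalog, max_mismatches=params["max_mismatches"]
            )
            cols[sample] = counts
            assign_counts[sample] = {
                "total": rep.total,
                "assigned": rep.assigned,
                "unassigned": rep.unassigned,
                "ambiguous": rep.ambiguous,
            }
        site_ids = [s.site_id for s in catalog]
        counts_df = pd.DataFrame(
            {
                sample: [cols[sample].get(sid, 0) for sid in site_ids]
                for sample in fastqs
            },
            index=pd.Index(site_ids, name="site_id"),
        )
        table = SiteCountTable(counts=counts_df, groups=groups)
        rpm = rpm_normalize(table)
        auth = authentic_mask(counts_df, params["min_depth"])
        corr = sample_correlation(rpm, auth)
        table.to_tsv(out_dir / "counts.tsv")
        rpm.rename_axis("site_id").to_csv(out_dir / "rpm.tsv", sep="\t")
        corr.to_csv(out_dir / "sample_correlation.tsv", sep="\t")
    except Exception as exc:
        raise RuntimeError(f"stage quant failed: {exc}") from exc
    manifest["stages"]["quant"] = {
        "assignment": assign_counts,
        "authentic_sites_any_sample": int(auth.any(axis=1).sum()),
    }

    # --- annotation --------------------------------------------------------
    try:
        models = load_annotation(inputs["gff"], promoter_bp=params["promoter_bp"])
        ctcf = load_ctcf_bed(inputs["ctcf"]) if "ctcf" in inputs else None
        annotations = annotate_catalog(catalog, models, ctcf)
        annotations_to_tsv(annotations, out_dir / "site_annotations.tsv")
        dist = element_distribution(annotations, auth)
        dist.rename_axis("element").to_csv(out_dir / "element_distribution.tsv", sep="\t")
    except Exception as exc:
        raise RuntimeError(f"stage annotate failed: {exc}") from exc
    manifest["stages"]["annotate"] = {
        "genes": len(models),
        "element_totals": {
            e: int(n) for e, n in Counter(a.element for a in annotations.values()).items()
        },
    }

    # --- differential methylation ------------------------------------------
    try:
        keep = auth.any(axis=1)
        site_counts = counts_df.loc[keep]
        site_diff = differential_test(
            site_counts, groups, p_cut=params["p_cut"], lfc_cut=params["lfc_cut"]
        )
        gene_counts = aggregate_to_gene(site_counts, annotations)
        gene_diff = differential_test(
            gene_counts, groups, p_cut=params["p_cut"], lfc_cut=params["lfc_cut"]
        )
        site_diff.rename_axis("site_id").to_csv(out_dir / "site_diff.tsv", sep="\t")
        gene_diff.rename_axis("gene_id").to_csv(out_dir / "gene_diff.tsv", sep="\t")
    except Exception as exc:
        raise RuntimeError(f"stage diff failed: {exc}") from exc
    manifest["stages"]["diff"] = {
        "sites_tested": int(len(site_diff)),
        "sites_significant": int(site_diff["significant"].sum()),
        "genes_tested": int(len(gene_diff)),
        "genes_significant": int(gene_diff["significant"].sum()),
        "site_dispersion": float(site_diff.attrs["dispersion"]),
        "gene_dispersion": float(gene_diff.attrs["dispersion"]),
    }

    # --- candidate screen --------------------------------------------------
    try:
        pathway: set[str] = set()
        if "pathway_genes" in inputs:
            pathway = {
                line.strip()
                for line in open(inputs["pathway_genes"])
                if line.strip()
            }
        decisions = screen_genes(site_diff, gene_diff, annotations, pathway)
        decisions.to_csv(out_dir / "screen.tsv", sep="\t")
        sig_genes = gene_diff.index[gene_diff["significant"]]
        cluster = None
        if len(sig_genes) >= 2:
            gene_rpm = gene_counts.loc[sig_genes] / counts_df.sum(axis=0) * 1e6
            cluster = cluster_genes(gene_rpm)
            pd.Series(cluster.leaf_order, name="gene_id").to_csv(
                out_dir / "cluster_order.tsv", sep="\t", index=False
            )
    except Exception as exc:
        raise RuntimeError(f"stage screen failed: {exc}") from exc
    selected = sorted(decisions.index[decisions["selected"]])
    manifest["stages"]["screen"] = {
        "genes_screened": int(len(decisions)),
        "genes_selected": selected,
    }

    # --- enrichment --------------------------------------------------------
    enrichment = None
    if "terms" in inputs:
        try:
            terms = read_term_tsv(inputs["terms"])
            universe = {
                a.gene_id for a in annotations.values() if a.gene_id is not None
            }
            query = set(gene_diff.index[gene_diff["significant"]]) & universe
            enrichment = enrich(query, terms, universe)
            enrichment.rename_axis("term_id").to_csv(out_dir / "enrichment.tsv", sep="\t")
            manifest["stages"]["enrich"] = {
                "terms_tested": int(len(enrichment)),
                "terms_q_lt_0.05": int((enrichment["q_value"] < 0.05).sum())
                if len(enrichment)
                else 0,
            }
        except Exception as exc:
            raise RuntimeError(f"stage enrich failed: {exc}") from exc

    # --- qPCR validation ---------------------------------------------------
    qpcr_results = None
    concordance = None
    if "ct" in inputs:
        try:
            ct = load_ct_table(inputs["ct"])
            rows = []
            expr_lfc = {}
            for gid, sub in ct.groupby("gene_id"):
                res = ddct_fold_change(sub)
                gm = res.group_stats
                ratio = float(gm.loc["treated", "mean"] / gm.loc["control", "mean"])
                expr_lfc[gid] = float(np.log2(ratio))
                rows.append(
                    {
                        "gene_id": gid,
                        "treated_mean": float(gm.loc["treated", "mean"]),
                        "treated_sem": float(gm.loc["treated", "sem"]),
                        "control_mean": float(gm.loc["control", "mean"]),
                        "control_sem": float(gm.loc["control", "sem"]),
                        "expression_log2fc": expr_lfc[gid],
                    }
                )
            qpcr_results = pd.DataFrame(rows).set_index("gene_id")
            concordance = methylation_expression_concordance(
                gene_diff, pd.Series(expr_lfc)
            )
            qpcr_results.to_csv(out_dir / "qpcr_expression.tsv", sep="\t")
            concordance.to_csv(out_dir / "qpcr_concordance.tsv", sep="\t")
        except Exception as exc:
            raise RuntimeError(f"stage qpcr failed: {exc}") from exc
        manifest["stages"]["qpcr"] = {
            "genes_validated": int(len(qpcr_results)),
            "genes_concordant": int(concordance["concordant"].sum())
            if len(concordance)
            else 0,
        }

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "catalog": catalog,
        "counts": counts_df,
        "rpm": rpm,
        "authentic": auth,
        "correlation": corr,
        "annotations": annotations,
        "element_distribution": dist,
        "site_diff": site_diff,
        "gene_diff": gene_diff,
        "screen": decisions,
        "cluster": cluster,
        "enrichment": enrichment,
        "qpcr": qpcr_results,
        "concordance": concordance,
        "manifest": manifest,
        "out_dir": out_dir,
    }
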