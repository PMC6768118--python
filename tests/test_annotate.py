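"""Element annotation: promoter arithmetic, precedence, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from methylrad.annotate import (
    ELEMENT_PRECEDENCE,
    AnnotationIndex,
    GeneModel,
    annotate_catalog,
    element_distribution,
    load_annotation,
    load_ctcf_bed,
)
from methylrad.digest import build_catalog


def write_gff(path, genes):
    """genes: list of dicts with gene_id, chrom, strand, start/end (1-based
    inclusive) and optional exons/utr5/utr3 interval lists (1-based)."""
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g['gene_id']}"
        lines.append(
            "\t".join(
                [g["chrom"], "sim", "gene", str(g["start"]), str(g["end"]),
                 ".", g["strand"], ".", attrs]
            )
        )
        for ftype, key in (
            ("exon", "exons"),
            ("five_prime_UTR", "utr5"),
            ("three_prime_UTR", "utr3"),
        ):
            for k, (s, e) in enumerate(g.get(key, [])):
                lines.append(
                    "\t".join(
                        [g["chrom"], "sim", ftype, str(s), str(e), ".",
                         g["strand"], ".",
                         f"ID={g['gene_id']}.{ftype}.{k};Parent={g['gene_id']}"]
                    )
                )
    path.write_text("\n".join(lines) + "\n")


class TestLoadAnnotation:
    def test_coordinates_converted_and_promoter_plus_strand(self, tmp_path):
        gff = tmp_path / "a.gff3"
        write_gff(
            gff,
            [{"gene_id": "gA", "chrom": "c1", "strand": "+",
              "start": 5001, "end": 8000, "exons": [(5001, 5600)]}],
        )
        (m,) = load_annotation(gff, promoter_bp=2000)
        assert (m.tx_start, m.tx_end) == (5000, 8000)
        assert m.exons == [(5000, 5600)]
        # promoter: 2 kb immediately upstream of the plus-strand TSS
        assert m.promoter == (3000, 5000)

    def test_promoter_minus_strand_is_downstream_in_text_coordinates(self, tmp_path):
        gff = tmp_path / "a.gff3"
        write_gff(
            gff,
            [{"gene_id": "gB", "chrom": "c1", "strand": "-",
              "start": 5001, "end": 8000}],
        )
        (m,) = load_annotation(gff, promoter_bp=2000)
        assert m.promoter == (8000, 10000)

    def test_promoter_clipped_at_contig_start(self, tmp_path):
        gff = tmp_path / "a.gff3"
        write_gff(
            gff,
            [{"gene_id": "gC", "chrom": "c1", "strand": "+",
              "start": 501, "end": 900}],
        )
        (m,) = load_annotation(gff, promoter_bp=2000)
        assert m.promoter == (0, 500)

    def test_unknown_contig_skipped(self, tmp_path):
        gff = tmp_path / "a.gff3"
        write_gff(
            gff,
            [{"gene_id": "gD", "chrom": "cX", "strand": "+",
              "start": 1, "end": 100}],
        )
        assert load_annotation(gff, known_contigs={"c1"}) == []


class TestIntrons:
    def test_gaps_between_exons(self):
        m = GeneModel("g", "c", "+", 0, 3000,
                      exons=[(0, 600), (1500, 2100), (2400, 3000)])
        assert m.introns == [(600, 1500), (2100, 2400)]

    def test_single_exon_no_intron(self):
        m = GeneModel("g", "c", "+", 0, 100, exons=[(0, 100)])
        assert m.introns == []


def naive_classify(models, ctcf, chrom, pos):
    """Independent oracle: linear scan of every element interval."""
    hits = {}
    for m in models:
        if m.chrom != chrom:
            continue
        for kind, ivals in (
            ("UTR5", m.utr5),
            ("UTR3", m.utr3),
            ("exon", m.exons),
            ("intron", m.introns),
            ("promoter", [m.promoter] if m.promoter else []),
        ):
            for s, e in ivals:
                if s <= pos < e:
                    prev = hits.get(kind)
                    if prev is None or m.gene_id < prev:
                        hits[kind] = m.gene_id
    for s, e in (ctcf or {}).get(chrom, []):
        if s <= pos < e:
            hits.setdefault("CTCF", None)
            hits["CTCF"] = None
    for kind in ELEMENT_PRECEDENCE[:-1]:
        if kind in hits:
            return kind, hits[kind]
    return "intergenic", None


class TestPrecedence:
    @pytest.fixture
    def overlapping_model(self):
        # every element covers position 50
        m = GeneModel(
            "g1", "c", "+", 40, 200,
            exons=[(40, 80), (120, 200)],
            utr5=[(40, 60)],
            utr3=[(190, 200)],
            promoter=(0, 40),
        )
        return m

    def test_utr5_beats_exon(self, overlapping_model):
        idx = AnnotationIndex([overlapping_model])
        assert idx.classify("c", 50) == ("UTR5", "g1")

    def test_exon_beats_intron_neighbours(self, overlapping_model):
        idx = AnnotationIndex([overlapping_model])
        assert idx.classify("c", 70) == ("exon", "g1")
        assert idx.classify("c", 100) == ("intron", "g1")

    def test_promoter_beats_ctcf(self, overlapping_model):
        idx = AnnotationIndex([overlapping_model], ctcf={"c": [(0, 40)]})
        assert idx.classify("c", 10) == ("promoter", "g1")

    def test_ctcf_beats_intergenic(self):
        idx = AnnotationIndex([], ctcf={"c": [(100, 200)]})
        assert idx.classify("c", 150) == ("CTCF", None)
        assert idx.classify("c", 99) == ("intergenic", None)

    def test_unknown_chromosome_is_intergenic(self, overlapping_model):
        idx = AnnotationIndex([overlapping_model])
        assert idx.classify("nope", 50) == ("intergenic", None)

    def test_interval_bounds_half_open(self):
        m = GeneModel("g", "c", "+", 10, 20, exons=[(10, 20)])
        idx = AnnotationIndex([m])
        assert idx.classify("c", 10)[0] == "exon"
        assert idx.classify("c", 19)[0] == "exon"
        assert idx.classify("c", 20)[0] == "intron" or idx.classify("c", 20)[0] == "intergenic"

    def test_tie_between_genes_is_lexically_smallest(self):
        a = GeneModel("gB", "c", "+", 0, 100, exons=[(0, 100)])
        b = GeneModel("gA", "c", "+", 0, 100, exons=[(0, 100)])
        idx = AnnotationIndex([a, b])
        assert idx.classify("c", 50) == ("exon", "gA")


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_random_models_match_linear_scan(self, seed):
        rng = np.random.default_rng(seed)
        models = []
        for g in range(8):
            ts = int(rng.integers(0, 8000))
            te = ts + int(rng.integers(500, 3000))
            n_ex = int(rng.integers(1, 4))
            bounds = np.sort(rng.integers(ts, te, size=2 * n_ex))
            exons = [
                (int(bounds[2 * i]), int(bounds[2 * i + 1]))
                for i in range(n_ex)
                if bounds[2 * i + 1] > bounds[2 * i]
            ]
            strand = "+" if rng.random() < 0.5 else "-"
            prom = (max(0, ts - 500), ts) if strand == "+" else (te, te + 500)
            models.append(
                GeneModel(
                    f"g{g:02d}", "c", strand, ts, te,
                    exons=exons,
                    utr5=exons[:1] if rng.random() < 0.5 else [],
                    utr3=exons[-1:] if rng.random() < 0.5 else [],
                    promoter=prom,
                )
            )
        ctcf = {"c": [(2000, 2500), (9000, 9400)]}
        idx = AnnotationIndex(models, ctcf)
        for pos in rng.integers(0, 12000, size=200):
            pos = int(pos)
            assert idx.classify("c", pos) == naive_classify(models, ctcf, "c", pos)

    def test_model_order_invariance(self):
        rng = np.random.default_rng(9)
        models = [
            GeneModel(f"g{i}", "c", "+", i * 100, i * 100 + 250,
                      exons=[(i * 100, i * 100 + 250)], promoter=(max(0, i * 100 - 50), i * 100))
            for i in range(10)
        ]
        shuffled = list(models)
        rng.shuffle(shuffled)
        a, b = AnnotationIndex(models), AnnotationIndex(shuffled)
        for pos in range(0, 1100, 7):
            assert a.classify("c", pos) == b.classify("c", pos)


class TestGeneratorRoundTrip:
    def test_planted_elements_recovered(self, standard_sim):
        """Annotating the digested genome reproduces the generator's labels."""
        paths = standard_sim["paths"]
        catalog = build_catalog(paths["genome"])
        models = load_annotation(paths["gff"])
        ctcf = load_ctcf_bed(paths["ctcf"])
        anns = annotate_catalog(catalog, models, ctcf)
        truth = standard_sim["truth"].sites.set_index("site_id")
        assert set(anns) == set(truth.index)
        for sid, ann in anns.items():
            assert ann.element == truth.loc[sid, "element"], sid
            want_gene = truth.loc[sid, "gene_id"]
            if ann.element in ("intergenic", "CTCF"):
                assert ann.gene_id is None
            else:
                assert ann.gene_id == want_gene, sid

    def test_intergenic_and_intron_dominate(self, standard_sim):
        truth = standard_sim["truth"].sites
        frac = truth["element"].isin(["intergenic", "intron"]).mean()
        assert frac > 0.5


class TestElementDistribution:
    def test_hand_example(self):
        from methylrad.annotate import SiteAnnotation

        anns = {
            "s1": SiteAnnotation("s1", "exon", "g1"),
            "s2": SiteAnnotation("s2", "exon", "g1"),
            "s3": SiteAnnotation("s3", "intergenic", None),
        }
        authentic = pd.DataFrame(
            {"A": [True, False, True], "B": [True, True, False]},
            index=["s1", "s2", "s3"],
        )
        dist = element_distribution(anns, authentic)
        assert dist.loc["exon", "A"] == 1
        assert dist.loc["exon", "B"] == 2
        assert dist.loc["intergenic", "A"] == 1
        assert dist["A"].sum() == 2 and dist["B"].sum() == 2

    def test_column_sums_equal_authentic_sites(self, standard_run):
        dist = standard_run["element_distribution"]
        authentic = standard_run["authentic"]
        assert list(dist.sum(axis=0)) == list(authentic.sum(axis=0))
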