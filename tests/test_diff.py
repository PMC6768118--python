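"""Differential methylation: exact-test oracles, dispersion, calls, power."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from methylrad.annotate import SiteAnnotation
from methylrad.diff import (
    aggregate_to_gene,
    call_differential,
    differential_test,
    estimate_dispersion,
    exact_nb_test,
    log2_fold_change,
    scale_to_common_library,
)

from conftest import nb_counts


class TestAggregateToGene:
    def test_groupby_sum_over_genic_sites_only(self):
        counts = pd.DataFrame(
            {"T1": [5, 7, 100, 9]},
            index=["s1", "s2", "s3", "s4"],
        )
        anns = {
            "s1": SiteAnnotation("s1", "promoter", "gA"),
            "s2": SiteAnnotation("s2", "exon", "gA"),
            "s3": SiteAnnotation("s3", "intergenic", None),
            "s4": SiteAnnotation("s4", "UTR3", "gB"),
        }
        out = aggregate_to_gene(counts, anns)
        assert out.loc["gA", "T1"] == 12
        assert out.loc["gB", "T1"] == 9
        assert "s3" not in out.index and len(out) == 2

    def test_empty_when_no_genic_sites(self):
        counts = pd.DataFrame({"T1": [5]}, index=["s1"])
        anns = {"s1": SiteAnnotation("s1", "intergenic", None)}
        assert aggregate_to_gene(counts, anns).empty

    def test_total_conservation(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(30, 2)),
            index=[f"s{i}" for i in range(30)],
            columns=["T1", "C1"],
        )
        anns = {
            f"s{i}": SiteAnnotation(f"s{i}", "exon", f"g{i % 5}")
            for i in range(30)
        }
        out = aggregate_to_gene(counts, anns)
        assert (out.sum(axis=0) == counts.sum(axis=0)).all()


class TestScaling:
    def test_equal_libraries_unchanged(self):
        counts = pd.DataFrame({"a": [10, 20], "b": [20, 10]})
        assert scale_to_common_library(counts).equals(counts.astype(np.int64))

    def test_geometric_mean_target(self):
        counts = pd.DataFrame({"a": [100], "b": [400]})
        scaled = scale_to_common_library(counts)
        # geometric mean of 100 and 400 is 200
        assert list(scaled.sum(axis=0)) == [200, 200]

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"a": [0], "b": [5]})
        with pytest.raises(ValueError, match="a"):
            scale_to_common_library(counts)


class TestDispersion:
    def test_requires_replication(self, groups6):
        counts = pd.DataFrame({"T1": [5], "C1": [5]})
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersion(
                counts, pd.Series({"T1": "treated", "C1": "control"})
            )

    def test_poisson_data_near_zero(self, groups6):
        rng = np.random.default_rng(0)
        mu = rng.uniform(20, 200, size=3000)
        counts = pd.DataFrame(
            nb_counts(rng, mu, 0.0, 6), columns=groups6.index
        )
        assert estimate_dispersion(counts, groups6) < 0.05

    def test_recovers_planted_dispersion(self, groups6):
        rng = np.random.default_rng(1)
        mu = rng.uniform(20, 200, size=3000)
        counts = pd.DataFrame(
            nb_counts(rng, mu, 0.4, 6), columns=groups6.index
        )
        assert 0.2 <= estimate_dispersion(counts, groups6) <= 0.6

    def test_all_zero_counts_give_zero(self, groups6):
        counts = pd.DataFrame(0, index=range(5), columns=groups6.index)
        assert estimate_dispersion(counts, groups6) == 0.0


def binomial_conditional_p(counts_a, counts_b):
    """Exact-rational oracle for the phi=0 conditional (binomial) test."""
    counts_a = [int(x) for x in counts_a]
    counts_b = [int(x) for x in counts_b]
    ya, yb = sum(counts_a), sum(counts_b)
    na, nb_ = len(counts_a), len(counts_b)
    total = ya + yb
    if total == 0:
        return Fraction(1)
    denom = Fraction(na + nb_) ** total
    probs = [
        Fraction(comb(total, y) * na**y * nb_ ** (total - y), 1) / denom
        for y in range(total + 1)
    ]
    obs = probs[ya]
    return sum(p for p in probs if p <= obs)


class TestExactNbTest:
    def test_worked_example_poisson(self):
        p = exact_nb_test([12, 8, 10], [2, 1, 3], 0.0)
        oracle = float(binomial_conditional_p([12, 8, 10], [2, 1, 3]))
        assert p == pytest.approx(oracle, abs=1e-9)
        assert p == pytest.approx(6.96e-05, rel=0.01)

    def test_symmetric_counts_give_p_one(self):
        assert exact_nb_test([5, 5, 5], [5, 5, 5], 0.0) == pytest.approx(1.0)
        assert exact_nb_test([5, 5, 5], [5, 5, 5], 0.3) == pytest.approx(1.0)

    def test_zero_total_is_one(self):
        assert exact_nb_test([0, 0], [0, 0], 0.2) == 1.0

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = list(rng.integers(0, 30, size=3))
            b = list(rng.integers(0, 30, size=3))
            for phi in (0.0, 0.25):
                assert exact_nb_test(a, b, phi) == pytest.approx(
                    exact_nb_test(b, a, phi), rel=1e-9
                )

    @pytest.mark.parametrize("seed", range(10))
    def test_phi_zero_matches_rational_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = list(rng.integers(0, 25, size=int(rng.integers(2, 5))))
        b = list(rng.integers(0, 25, size=int(rng.integers(2, 5))))
        assert exact_nb_test(a, b, 0.0) == pytest.approx(
            float(binomial_conditional_p(a, b)), abs=1e-9
        )

    def test_reduction_law_small_phi_exhaustive(self):
        """As phi -> 0 the NB conditional law converges to the binomial one,
        uniformly over all splits of every total up to 60."""
        worst = 0.0
        for total in range(1, 61):
            for ya in range(total + 1):
                a = [ya, 0, 0]
                b = [total - ya, 0, 0]
                p_nb = exact_nb_test(a, b, 1e-8)
                p_bin = exact_nb_test(a, b, 0.0)
                worst = max(worst, abs(p_nb - p_bin))
        assert worst < 1e-5

    def test_larger_phi_is_more_conservative(self):
        a, b = [40, 35, 45], [10, 12, 8]
        p0 = exact_nb_test(a, b, 0.0)
        p3 = exact_nb_test(a, b, 0.3)
        assert p3 > p0

    def test_monotone_in_imbalance(self):
        # holding the total fixed, a more extreme split is never less significant
        total = 40
        ps = [exact_nb_test([y, 0, 0], [total - y, 0, 0], 0.1)
              for y in range(total // 2, total + 1)]
        for earlier, later in zip(ps, ps[1:]):
            assert later <= earlier + 1e-12


class TestLog2FoldChange:
    def test_examples(self):
        assert log2_fold_change(31.5, 7.5) == pytest.approx(2.0)
        assert log2_fold_change(7.5, 31.5) == pytest.approx(-2.0)
        assert log2_fold_change(0.0, 0.0) == 0.0

    def test_pseudocount_bounds_extremes(self):
        assert np.isfinite(log2_fold_change(1000.0, 0.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change(-1.0, 5.0)


class TestCallDifferential:
    def test_boundary_values_not_significant(self):
        df = pd.DataFrame(
            {
                "p_value": [0.05, 0.01, 0.01, 0.049],
                "log2fc": [2.0, 1.0, -1.0, 1.01],
            }
        )
        out = call_differential(df)
        assert list(out["significant"]) == [False, False, False, True]
        assert list(out["direction"]) == ["none", "none", "none", "hyper"]

    def test_hypo_direction(self):
        df = pd.DataFrame({"p_value": [0.001], "log2fc": [-1.5]})
        assert call_differential(df)["direction"].iloc[0] == "hypo"


def planted_counts(rng, n_features, n_planted, lfc, depth, phi, groups):
    """Balanced hyper/hypo planting (half up, half down)."""
    mu_c = rng.uniform(depth * 0.5, depth * 1.5, size=n_features)
    true = np.zeros(n_features)
    up = rng.choice(n_features, size=n_planted, replace=False)
    half = n_planted // 2
    true[up[:half]] = lfc
    true[up[half:]] = -lfc
    mu_t = mu_c * 2.0**true
    treated = [c for c in groups.index if groups[c] == "treated"]
    control = [c for c in groups.index if groups[c] == "control"]
    counts = pd.DataFrame(index=range(n_features))
    for c in treated:
        counts[c] = nb_counts(rng, mu_t, phi, 1)[:, 0]
    for c in control:
        counts[c] = nb_counts(rng, mu_c, phi, 1)[:, 0]
    return counts[list(groups.index)], true


class TestDifferentialTest:
    def test_table_shape_and_sorting(self, groups6):
        rng = np.random.default_rng(0)
        counts, _ = planted_counts(rng, 50, 10, 2.0, 50, 0.1, groups6)
        out = differential_test(counts, groups6)
        assert set(out.columns) >= {
            "mean_rpm_treated", "mean_rpm_control", "log2fc",
            "p_value", "q_value", "significant", "direction",
        }
        assert out["p_value"].is_monotonic_increasing
        assert len(out) == 50
        assert out.attrs["dispersion"] >= 0

    def test_group_label_swap_flips_sign(self, groups6):
        rng = np.random.default_rng(1)
        counts, _ = planted_counts(rng, 40, 8, 2.0, 50, 0.1, groups6)
        swapped = groups6.map({"treated": "control", "control": "treated"})
        a = differential_test(counts, groups6, phi=0.1).sort_index()
        b = differential_test(counts, swapped, phi=0.1).sort_index()
        assert np.allclose(a["p_value"], b["p_value"])
        assert np.allclose(a["log2fc"], -b["log2fc"])

    def test_type_one_error_near_nominal(self, groups6):
        """Null data at phi=0.3: fraction with p<0.05 in [0.025, 0.075]."""
        rng = np.random.default_rng(3)
        mu = rng.uniform(25, 100, size=2000)
        counts = pd.DataFrame(
            nb_counts(rng, mu, 0.3, 6), columns=groups6.index
        )
        out = differential_test(counts, groups6, phi=0.3)
        frac = float((out["p_value"] < 0.05).mean())
        assert 0.025 <= frac <= 0.075

    def test_power_and_precision_at_study_scale(self, groups6):
        """300 genes, 30 planted at |log2FC|=2, depth 50, phi=0.3, 3v3:
        >=80% of planted genes flagged and >=95% of BH-corrected calls are
        planted."""
        rng = np.random.default_rng(4)
        hits = tot = 0
        q_true = q_all = 0
        for _ in range(5):
            counts, true = planted_counts(rng, 300, 30, 2.0, 50, 0.3, groups6)
            out = differential_test(counts, groups6).sort_index()
            planted = true != 0
            flagged = out["significant"].to_numpy()
            hits += int((flagged & planted).sum())
            tot += int(planted.sum())
            q_call = (out["q_value"] < 0.05).to_numpy() & (
                out["log2fc"].abs() > 1
            ).to_numpy()
            q_all += int(q_call.sum())
            q_true += int((q_call & planted).sum())
        assert hits / tot >= 0.80
        assert q_true / q_all >= 0.95

    def test_recovered_lfc_close_to_planted(self, groups6):
        rng = np.random.default_rng(5)
        errs = []
        for _ in range(3):
            counts, true = planted_counts(rng, 300, 30, 2.0, 50, 0.1, groups6)
            out = differential_test(counts, groups6).sort_index()
            planted = true != 0
            errs.append(
                float(np.mean(np.abs(out["log2fc"][planted]) )) - 2.0
            )
        assert abs(float(np.mean(errs))) < 0.5
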