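from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddpp.core import (
    build_feature_matrix,
    compute_feature,
    pearson_with_p,
    rank_genes,
    stepin_select,
    summate,
)
from ddpp.datamodel import (
    Channel,
    Cohort,
    DegenerateDataError,
    FeatureMode,
    GenePanel,
    SummationMethod,
    ValidationError,
)
from ddpp.panels import get_panel, published_model
from ddpp.synthetic import GeneratorConfig, generate_cohort
from conftest import EVEROLIMUS_PRINTED, IO_PRINTED, make_patient
from oracles import brute_feature, brute_pearson_p, t_tail


class TestComputeFeature:
    def test_equal_intensities_zero(self):
        assert compute_feature(100.0, 100.0, 57.3) == 0.0

    def test_unit_cell(self):
        # log2(220/110) = 1 and log1.1(1.1) = 1
        assert compute_feature(220.0, 110.0, 1.1) == pytest.approx(1.0, abs=1e-12)

    def test_reference_value(self):
        expected = brute_feature(150.0, 100.0, 150.0)
        got = compute_feature(150.0, 100.0, 150.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(30.753, abs=5e-4)

    def test_tumor_only(self):
        assert compute_feature(
            1.1, 999.0, 5.0, FeatureMode.TUMOR_ONLY
        ) == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_raises(self):
        with pytest.raises(ValidationError):
            compute_feature(0.0, 1.0, 1.0)
        with pytest.raises(ValidationError):
            compute_feature(1.0, -2.0, 1.0)

    @given(
        tumor=st.floats(0.01, 1e6),
        normal=st.floats(0.01, 1e6),
        intensity=st.floats(0.01, 1e6),
    )
    def test_antisymmetry_in_fold(self, tumor, normal, intensity):
        f = compute_feature(tumor, normal, intensity)
        g = compute_feature(normal, tumor, intensity)
        assert f == pytest.approx(-g, rel=1e-9, abs=1e-9)

    @given(
        tumor=st.floats(0.01, 1e6),
        normal=st.floats(0.01, 1e6),
        intensity=st.floats(0.01, 1e6),
    )
    def test_matches_brute_force(self, tumor, normal, intensity):
        assert compute_feature(tumor, normal, intensity) == pytest.approx(
            brute_feature(tumor, normal, intensity), rel=1e-10, abs=1e-10
        )


class TestFeatureMatrix:
    def test_single_cell_composition(self):
        cohort = Cohort(
            drug="d",
            patients=[
                make_patient("P1", 2.0, {"G1": (120.0, 80.0)}),
                make_patient("P2", 3.0, {"G1": (90.0, 70.0)}),
                make_patient("P3", 4.0, {"G1": (60.0, 50.0)}),
            ],
        )
        fm = build_feature_matrix(cohort, ["G1"], Channel.TUMOR)
        assert fm.values[0, 0] == pytest.approx(
            compute_feature(120.0, 80.0, 120.0), rel=1e-12
        )

    def test_identical_channels_all_zero(self):
        patients = [
            make_patient(f"P{i}", float(i + 1), {"G1": (v, v), "G2": (2 * v, 2 * v)})
            for i, v in enumerate([10.0, 20.0, 30.0])
        ]
        fm = build_feature_matrix(Cohort(drug="d", patients=patients),
                                  ["G1", "G2"], Channel.NORMAL)
        assert np.allclose(fm.values, 0.0)

    def test_matches_elementwise_brute_force(self, tiny_cohort):
        for channel in (Channel.TUMOR, Channel.NORMAL):
            fm = build_feature_matrix(tiny_cohort, ["G1", "G2", "G3"], channel)
            for i, patient in enumerate(tiny_cohort.patients):
                for j, gene in enumerate(fm.gene_order):
                    pe = patient.expression[gene]
                    intensity = (
                        pe.tumor_intensity if channel is Channel.TUMOR
                        else pe.normal_intensity
                    )
                    assert fm.values[i, j] == pytest.approx(
                        brute_feature(pe.tumor_intensity, pe.normal_intensity,
                                      intensity),
                        rel=1e-10,
                    )

    def test_missing_gene_lists_symbols(self, tiny_cohort):
        with pytest.raises(ValidationError, match="MISSING"):
            build_feature_matrix(tiny_cohort, ["G1", "MISSING"], Channel.TUMOR)


class TestPearson:
    def test_perfect_positive(self):
        r, p = pearson_with_p([1, 2, 3], [2, 4, 6])
        assert r == 1.0 and p == 0.0

    def test_perfect_negative(self):
        r, p = pearson_with_p([1, 2, 3], [6, 4, 2])
        assert r == -1.0

    def test_df2_closed_form(self):
        # r = 0.8; for df=2 the two-sided p is 1 - t/sqrt(2 + t^2) = 0.2
        r, p = pearson_with_p([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-12)
        assert p == pytest.approx(0.2, abs=1e-10)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateDataError):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(
        data=st.data(),
        n=st.integers(3, 10),
    )
    @settings(max_examples=200)
    def test_affine_invariance(self, data, n):
        xs = [
            float(v) for v in data.draw(
                st.lists(st.integers(-1000, 1000), min_size=n, max_size=n,
                         unique=True)
            )
        ]
        ys = [
            float(v) for v in data.draw(
                st.lists(st.integers(-1000, 1000), min_size=n, max_size=n,
                         unique=True)
            )
        ]
        r0, _ = pearson_with_p(xs, ys)
        r1, _ = pearson_with_p([3.5 * x + 11 for x in xs], ys)
        assert abs(r0) <= 1.0
        assert r1 == pytest.approx(r0, rel=1e-8, abs=1e-8)

    def test_brute_force_agreement_small_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(3, 11))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r, p = pearson_with_p(x, y)
            rb, pb = brute_pearson_p(list(x), list(y))
            assert r == pytest.approx(rb, abs=1e-10)
            assert p == pytest.approx(pb, abs=1e-10)

    def test_printed_r_p_pairs_consistent_with_two_sided_t(self):
        # the printed per-gene (r, p) pairs must match our p-value convention;
        # tolerance reflects the precision each value was printed with (both
        # r and p are rounded in the source)
        def p_of(r, df):
            t = abs(r) * math.sqrt(df / (1 - r * r))
            return 2 * t_tail(t, df)

        def check(rows, df):
            for gene, r, p in rows:
                if abs(r) >= 0.995:
                    continue
                # r itself is rounded to two decimals: the printed p must be
                # attainable for some r within +-0.005 of the printed r
                p_tol = 0.5 * 10 ** -len(str(p).split(".")[1]) + 1e-9
                lo = p_of(abs(r) + 0.005, df) - p_tol
                hi = p_of(abs(r) - 0.005, df) + p_tol
                assert lo <= p <= hi, (gene, p, lo, hi)

        check(EVEROLIMUS_PRINTED, 4)
        check(IO_PRINTED, 1)


class TestSummate:
    def test_single_value(self):
        for method in (SummationMethod.SUM, SummationMethod.MEAN,
                       SummationMethod.MEDIAN, SummationMethod.FOLD):
            assert summate([-3.5], method) == -3.5
        assert summate([-3.5], SummationMethod.FOLD_ABS) == 3.5

    def test_two_values(self):
        v = [1.0, 3.0]
        assert summate(v, SummationMethod.SUM) == 4.0
        assert summate(v, SummationMethod.MEAN) == 2.0
        assert summate(v, SummationMethod.MEDIAN) == 2.0
        assert summate(v, SummationMethod.FOLD) == 3.0
        assert summate(v, SummationMethod.FOLD_ABS) == 3.0

    def test_sign_algebra(self):
        assert summate([-2.0, 3.0, -4.0], SummationMethod.FOLD) == 24.0
        assert summate([-2.0, 3.0, -4.0], SummationMethod.FOLD_ABS) == 24.0
        assert summate([-2.0, 3.0, 4.0], SummationMethod.FOLD) == -24.0
        assert summate([-2.0, 3.0, 4.0], SummationMethod.FOLD_ABS) == 24.0

    def test_median_even_length(self):
        assert summate([1.0, 2.0, 10.0, 20.0], SummationMethod.MEDIAN) == 6.0

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            summate([], SummationMethod.SUM)

    def test_overflow_raises(self):
        with pytest.raises(ValidationError, match="overflow"):
            summate([1e300, 1e300], SummationMethod.FOLD)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=8))
    def test_numpy_reference(self, values):
        assert summate(values, SummationMethod.SUM) == pytest.approx(
            float(np.sum(values)), rel=1e-12, abs=1e-12
        )
        assert summate(values, SummationMethod.MEDIAN) == pytest.approx(
            float(np.median(values)), rel=1e-12, abs=1e-12
        )


class TestRankGenes:
    def test_printed_ranking_order_everolimus(self):
        # sorting the printed per-gene correlations with our ranking key must
        # reproduce the printed order, whose first eight genes form the
        # published predictor
        key = lambda row: (-abs(row[1]), row[2], row[0])
        assert sorted(EVEROLIMUS_PRINTED, key=key) == EVEROLIMUS_PRINTED
        panel = get_panel("everolimus")
        top8 = [panel.resolve(g) for g, _, _ in EVEROLIMUS_PRINTED[:8]]
        assert top8 == list(published_model("everolimus").genes)

    def test_printed_ranking_order_io(self):
        key = lambda row: (-abs(row[1]), row[2], row[0])
        assert sorted(IO_PRINTED, key=key) == IO_PRINTED
        panel = get_panel("anti-pd1")
        top6 = [panel.resolve(g) for g, _, _ in IO_PRINTED[:6]]
        assert top6 == list(published_model("anti-pd1").genes)

    def test_perfectly_linear_gene_ranks_first(self):
        rng = np.random.default_rng(0)
        patients = []
        for i, pfs in enumerate([2.0, 5.0, 9.0, 14.0]):
            expr = {"LIN": (100.0 * 2.0 ** pfs, 100.0)}
            for g in ("N1", "N2"):
                expr[g] = (float(rng.uniform(50, 150)), float(rng.uniform(50, 150)))
            patients.append(make_patient(f"P{i}", pfs, expr))
        cohort = Cohort(drug="d", patients=patients)
        # LIN's log2 fold change is exactly PFS; use the normal channel so the
        # constant intensity multiplier keeps the feature linear in PFS
        channel, ranking = rank_genes(
            cohort, GenePanel(drug="d", genes=["N1", "LIN", "N2"])
        )
        assert ranking[0].gene == "LIN"
        assert abs(ranking[0].r) == pytest.approx(1.0, abs=1e-12)
        assert channel is Channel.NORMAL

    def test_degenerate_gene_ranked_last(self, tiny_cohort):
        from ddpp.datamodel import PairedExpression

        for p in tiny_cohort.patients:
            p.add_expression(
                PairedExpression(
                    gene="FLAT", tumor_intensity=100.0, normal_intensity=100.0
                )
            )
        _, ranking = rank_genes(
            tiny_cohort, GenePanel(drug="toy", genes=["G1", "FLAT", "G2", "G3"])
        )
        assert ranking[-1].gene == "FLAT"
        assert ranking[-1].degenerate and ranking[-1].r == 0.0

    def test_ranking_matches_brute_force(self, tiny_cohort, tiny_panel):
        channel, ranking = rank_genes(tiny_cohort, tiny_panel)
        fm = build_feature_matrix(tiny_cohort, tiny_panel.genes, channel)
        pfs = list(tiny_cohort.pfs)
        brute = []
        for j, gene in enumerate(fm.gene_order):
            r, p = brute_pearson_p(list(fm.values[:, j]), pfs)
            brute.append((gene, r, p))
        brute.sort(key=lambda row: (-abs(row[1]), row[2], row[0]))
        assert [c.gene for c in ranking] == [g for g, _, _ in brute]
        for c, (g, r, p) in zip(ranking, brute):
            assert c.r == pytest.approx(r, abs=1e-10)
            assert c.p == pytest.approx(p, abs=1e-10)


class TestStepinSelect:
    def test_single_gene_panel_reduction(self, tiny_cohort):
        panel = GenePanel(drug="toy", genes=["G1"])
        sel = stepin_select(tiny_cohort, panel)
        assert sel.best_k == 1
        _, ranking = rank_genes(tiny_cohort, panel)
        assert abs(sel.best_r) == pytest.approx(abs(ranking[0].r), abs=1e-12)

    def test_k1_methods_equal_univariate(self, tiny_cohort, tiny_panel):
        sel = stepin_select(tiny_cohort, tiny_panel)
        top = sel.ranking[0]
        for method in SummationMethod:
            cell = sel.cell(1, method)
            assert abs(cell.r) == pytest.approx(abs(top.r), abs=1e-12)

    def test_table_shape(self, tiny_cohort, tiny_panel):
        sel = stepin_select(tiny_cohort, tiny_panel)
        assert len(sel.cells) == len(tiny_panel) * len(SummationMethod)
        ks = {c.k for c in sel.cells}
        assert ks == {1, 2, 3}

    def test_best_cell_attains_max_abs_r(self, tiny_cohort, tiny_panel):
        sel = stepin_select(tiny_cohort, tiny_panel)
        max_abs = max(abs(c.r) for c in sel.cells if not c.degenerate)
        assert abs(sel.best_r) == pytest.approx(max_abs, abs=0.0)
        assert sel.best_k <= len(tiny_panel)

    def test_patient_and_gene_order_invariance(self, tiny_cohort, tiny_panel):
        sel = stepin_select(tiny_cohort, tiny_panel)
        shuffled_cohort = Cohort(
            drug="toy", patients=list(reversed(tiny_cohort.patients))
        )
        shuffled_panel = GenePanel(drug="toy", genes=["G3", "G1", "G2"])
        sel2 = stepin_select(shuffled_cohort, shuffled_panel)
        assert sel2.best_k == sel.best_k
        assert sel2.best_method == sel.best_method
        assert sel2.best_r == pytest.approx(sel.best_r, rel=1e-12)
        assert sel2.best_genes == sel.best_genes

    def test_constant_pfs_raises(self, tiny_panel, tiny_cohort):
        for p in tiny_cohort.patients:
            p.pfs_months = 5.0
        with pytest.raises(DegenerateDataError):
            stepin_select(tiny_cohort, tiny_panel)

    def test_planted_signature_noise_free(self, planted_cohort):
        cohort, truth, panel = planted_cohort
        sel = stepin_select(cohort, panel)
        assert set(sel.best_genes) == set(truth.genes)
        assert abs(sel.best_r) == pytest.approx(1.0, abs=1e-9)
        assert sel.channel == truth.channel
        # all planted features are positive, so fold and fold_abs coincide
        assert sel.best_method in (SummationMethod.FOLD, SummationMethod.FOLD_ABS)
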