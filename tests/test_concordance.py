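import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from scnalnc import concordance as cc
from scnalnc import synthetic as syn
from scnalnc.classify import ClassifiedSCNA, GenomeAnnotation, LNCRNA_ONLY
from scnalnc.models import (
    AMPLIFICATION,
    DELETION,
    GeneModel,
    Peak,
    PlantedAlteration,
    SegmentSet,
)
from tests.conftest import flat_segments


def welch_oracle(x, y):
    """Textbook Welch formulas, independent of the implementation path."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestWelchT:
    def test_identical_samples(self):
        t, df, p = cc.welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == 1

    def test_hand_computed_example(self):
        t, df, p = cc.welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742346, abs=1e-6)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert p == pytest.approx(0.021312, abs=1e-5)

    def test_shift_invariance(self):
        x, y = [1.0, 2.5, 3.1, 0.4], [2.2, 5.0, 4.4]
        a = cc.welch_t(x, y)
        b = cc.welch_t([v + 7.3 for v in x], [v + 7.3 for v in y])
        assert a == pytest.approx(b, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(cc.DegenerateDataError):
            cc.welch_t([1.0], [2.0, 3.0])
        with pytest.raises(cc.DegenerateDataError):
            cc.welch_t([1.0, 1.0], [2.0, 2.0])

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=20),
        st.lists(st.floats(-50, 50), min_size=3, max_size=20),
    )
    def test_agrees_with_textbook_oracle(self, x, y):
        x = [round(v, 3) for v in x]
        y = [round(v, 3) for v in y]
        if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
            return
        t, df, p = cc.welch_t(x, y)
        to, dfo, po = welch_oracle(x, y)
        assert t == pytest.approx(to, abs=1e-10)
        assert df == pytest.approx(dfo, abs=1e-10)
        assert p == pytest.approx(po, abs=1e-10)


def scna_for_gene(gene, direction=AMPLIFICATION, pad=20_000):
    peak = Peak(
        direction,
        gene.chromosome,
        (gene.start - pad, gene.end + pad),
        (gene.start - pad, gene.end + pad),
        (gene.start - pad, gene.end + pad),
        1.0,
        0.01,
    )
    return ClassifiedSCNA(peak, [gene.gene_id], LNCRNA_ONLY)


class TestConcordanceFilter:
    @pytest.fixture()
    def setup(self):
        gene = GeneModel("LNC1", "chr1", 400_000, 440_000, "+", "lncRNA")
        annotation = GenomeAnnotation([gene])
        rng = np.random.default_rng(0)
        tumors = {f"T{i}": 1 for i in range(30)}
        normals = {f"N{i}": 1 for i in range(30)}
        labels = {**{s: "tumor" for s in tumors}, **{s: "normal" for s in normals}}
        return gene, annotation, labels

    def _expr(self, labels, tumor_mean, normal_mean, sd=0.3, seed=0):
        rng = np.random.default_rng(seed)
        vals = {
            s: 2 ** (tumor_mean if l == "tumor" else normal_mean) + rng.normal(0, sd)
            for s, l in labels.items()
        }
        return pd.DataFrame([vals], index=["LNC1"]).clip(lower=0)

    def test_concordant_amplification_survives(self, setup):
        gene, annotation, labels = setup
        expr = self._expr(labels, tumor_mean=4.0, normal_mean=3.0)
        scna = scna_for_gene(gene, AMPLIFICATION)
        verdicts, survivors = cc.concordance_filter([scna], expr, labels, annotation)
        assert survivors == [scna]
        assert verdicts[0].direction_match and verdicts[0].putative_functional

    def test_discordant_direction_never_functional(self, setup):
        """An amplified region whose lncRNA is LOWER in tumor fails the
        direction rule even at tiny p."""
        gene, annotation, labels = setup
        expr = self._expr(labels, tumor_mean=2.0, normal_mean=4.0)
        scna = scna_for_gene(gene, AMPLIFICATION)
        verdicts, survivors = cc.concordance_filter([scna], expr, labels, annotation)
        assert verdicts[0].p_value < 0.05
        assert not verdicts[0].direction_match
        assert survivors == []
        # the same expression pattern is concordant for a deletion
        _, del_surv = cc.concordance_filter(
            [scna_for_gene(gene, DELETION)], expr, labels, annotation
        )
        assert len(del_surv) == 1

    def test_missing_normals_is_an_error(self, setup):
        gene, annotation, labels = setup
        tumor_only = {s: l for s, l in labels.items() if l == "tumor"}
        expr = self._expr(labels, 4.0, 3.0)[list(tumor_only)]
        with pytest.raises(cc.ValidationError, match="normal"):
            cc.concordance_filter([scna_for_gene(gene)], expr, tumor_only, annotation)

    def test_survivors_are_subset_of_input(self, genome, planted_lnc):
        alt, gene = planted_lnc
        strong = PlantedAlteration(alt.chromosome, alt.start, alt.end, AMPLIFICATION, 0.5, 1.5, 0.1)
        segs, _ = syn.simulate_cohort(genome, [strong], n_tumor=50, n_normal=30, seed=71)
        expr, labels = syn.simulate_expression(genome, segs, seed=72)
        annotation = GenomeAnnotation(genome.genes)
        scnas = [scna_for_gene(g) for g in genome.genes if g.biotype == "lncRNA"]
        _, survivors = cc.concordance_filter(scnas, expr, labels, annotation)
        assert set(map(id, survivors)) <= set(map(id, scnas))


class TestAmplificationGroupTest:
    def test_all_amplified_is_degenerate(self):
        row = pd.Series([1.0, 2.0, 3.0], index=["T1", "T2", "T3"])
        with pytest.raises(cc.DegenerateDataError):
            cc.amplification_group_test(row, ["T1", "T2", "T3"])

    def test_planted_amplification_raises_group_mean(self, genome, planted_lnc):
        alt, gene = planted_lnc
        strong = PlantedAlteration(alt.chromosome, alt.start, alt.end, AMPLIFICATION, 0.3, 1.5, 0.1)
        segs, carriers = syn.simulate_cohort(genome, [strong], n_tumor=100, n_normal=0, seed=81)
        expr, _ = syn.simulate_expression(genome, segs, seed=82)
        res = cc.amplification_group_test(expr.loc[gene.gene_id, segs.tumor_samples], carriers[0])
        assert res["amplified_mean"] > res["other_mean"]
        assert res["p_value"] < 0.05

    def test_label_shuffle_p_is_uniform(self):
        """Under random group labels the Welch p is U(0,1): KS not rejecting."""
        rng = np.random.default_rng(5)
        values = pd.Series(rng.normal(0, 1, 60), index=[f"T{i}" for i in range(60)])
        ps = []
        for _ in range(200):
            amp = list(rng.choice(values.index, size=20, replace=False))
            ps.append(cc.amplification_group_test(2**values, amp)["p_value"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestCohortSummary:
    def _cohort(self, n_amp, n_tot, gene):
        vals = {f"T{i}": (1.0 if i < n_amp else 0.0) for i in range(n_tot)}
        segs = flat_segments(vals, chrom=gene.chromosome, length=1_000_000)
        return segs

    def test_paper_style_percentage(self):
        """43 amplified of 493 tumors is reported as 8.72%."""
        gene = GeneModel("LNC1", "chr1", 400_000, 440_000, "+", "lncRNA")
        segs = self._cohort(43, 493, gene)
        scna = scna_for_gene(gene)
        expr = pd.DataFrame(
            [np.ones(493)], index=["LNC1"], columns=segs.tumor_samples
        )
        out = cc.cohort_summary(scna, segs, expr, "LNC1")
        assert round(out["percent_amplified"], 2) == 8.72
        assert out["percent_expressed"] == 100.0

    def test_all_zero_expression(self):
        gene = GeneModel("LNC1", "chr1", 400_000, 440_000, "+", "lncRNA")
        segs = self._cohort(2, 4, gene)
        expr = pd.DataFrame([np.zeros(4)], index=["LNC1"], columns=segs.tumor_samples)
        out = cc.cohort_summary(scna_for_gene(gene), segs, expr, "LNC1")
        assert out["percent_expressed"] == 0.0
        assert out["percent_amplified_and_expressed"] == 0.0

    def test_full_carrier_frequency_is_100_percent(self):
        gene = GeneModel("LNC1", "chr1", 400_000, 440_000, "+", "lncRNA")
        segs = self._cohort(4, 4, gene)
        expr = pd.DataFrame([np.ones(4)], index=["LNC1"], columns=segs.tumor_samples)
        out = cc.cohort_summary(scna_for_gene(gene), segs, expr, "LNC1")
        assert out["percent_amplified"] == 100.0


class TestDifferentialMethylation:
    def test_planted_hypomethylated_cpg(self, genome):
        target = genome.genes[0].gene_id
        beta, cpg_map, labels = syn.simulate_methylation(genome, {target}, seed=91)
        res = cc.differential_methylation(beta, labels)
        for cpg in cpg_map.index[cpg_map["gene_id"] == target]:
            assert res.loc[cpg, "p_value"] < 0.001
            assert res.loc[cpg, "hypomethylated_in_tumor"]

    def test_constant_cpg_survives_as_nan(self):
        beta = pd.DataFrame(
            {"T1": [0.5, 0.4], "T2": [0.5, 0.45], "N1": [0.5, 0.7], "N2": [0.5, 0.72]},
            index=["cg_const", "cg_real"],
        )
        labels = {"T1": "tumor", "T2": "tumor", "N1": "normal", "N2": "normal"}
        res = cc.differential_methylation(beta, labels)
        assert np.isnan(res.loc["cg_const", "p_value"])
        assert res.loc["cg_real", "p_value"] < 0.05
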