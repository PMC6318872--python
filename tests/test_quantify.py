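"""Bootstrap RPKM quantification, significance calls, quantile normalization."""

import math

import numpy as np
import pandas as pd
import pytest

from mhbcircuit.io import AlignmentTable, GeneCatalog, IntegrityError
from mhbcircuit.quantify import (
    BootstrapExpression,
    bootstrap_rpkm,
    expression_significance,
    mean_rpkm_matrix,
    normalize_matrix,
    quantify_samples,
    quantile_normalize,
)
from mhbcircuit.synthetic import generate_experiment

from test_synthetic import tiny_config


def make_catalog(lengths):
    frame = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(lengths))],
            "organism": "host",
            "length_bp": lengths,
        }
    )
    return GeneCatalog.from_frame(frame)


def make_alignment(pairs, sample_id="s1"):
    frame = pd.DataFrame(pairs, columns=["read_id", "gene_id"])
    return AlignmentTable(sample_id, frame)


class TestBootstrapRpkm:
    def test_unique_reads_give_closed_form_rpkm_with_zero_sd(self):
        catalog = make_catalog([1000])
        aln = make_alignment([(f"r{i}", "g0") for i in range(10)])
        expr = bootstrap_rpkm(aln, catalog, iterations=50, seed=0)
        row = expr.frame.loc["g0"]
        # RPKM = 10 / (1 kb * 10/1e6 M reads) = 1,000,000 exactly
        assert row["mean_rpkm"] == 1_000_000.0
        assert row["sd_rpkm"] == 0.0
        assert row["unique_rpkm"] == 1_000_000.0

    def test_gene_with_no_reads_is_exactly_zero(self):
        catalog = make_catalog([1000, 500])
        aln = make_alignment([("r0", "g0")])
        expr = bootstrap_rpkm(aln, catalog, iterations=20, seed=0)
        assert expr.frame.loc["g1", "mean_rpkm"] == 0.0
        assert expr.frame.loc["g1", "sd_rpkm"] == 0.0

    def test_ambiguous_read_splits_binomially(self):
        # one read aligning to two equal-length genes: across B(10000, 1/2)
        # assignments each gene's mean count is 0.5 +- 3 binomial SEs
        catalog = make_catalog([1000, 1000])
        aln = make_alignment([("r0", "g0"), ("r0", "g1")])
        iters = 10_000
        expr = bootstrap_rpkm(aln, catalog, iterations=iters, seed=1)
        scale = 1e9 / (1000.0 * 1)  # per-count RPKM for 1 aligned read
        se3 = 3 * math.sqrt(0.25 / iters)
        for gene in ("g0", "g1"):
            mean_count = expr.frame.loc[gene, "mean_rpkm"] / scale
            assert abs(mean_count - 0.5) < se3
        assert expr.frame["unique_rpkm"].sum() == 0.0

    def test_reads_are_conserved_across_iterations(self, small_experiment):
        exp = small_experiment
        sid = exp.design.sample_ids[0]
        expr = bootstrap_rpkm(exp.alignments[sid], exp.catalog, iterations=25, seed=3)
        lengths = exp.catalog.lengths.to_numpy(dtype=float)
        mean_counts = (
            expr.frame["mean_rpkm"].to_numpy() * lengths * expr.n_reads / 1e9
        )
        assert mean_counts.sum() == pytest.approx(expr.n_reads, rel=1e-9)

    def test_without_multimapping_bootstrap_equals_closed_form_exactly(self):
        exp = generate_experiment(tiny_config(multimap_fraction=0.0))
        sid = exp.design.sample_ids[3]
        expr = bootstrap_rpkm(exp.alignments[sid], exp.catalog, iterations=30, seed=2)
        counts = exp.truth.true_counts[sid].to_numpy(dtype=float)
        lengths = exp.catalog.lengths.to_numpy(dtype=float)
        total = counts.sum()
        expected = counts * (1e9 / (lengths * total))
        assert (expr.frame["sd_rpkm"].to_numpy() == 0.0).all()
        assert (expr.frame["mean_rpkm"].to_numpy() == expected).all()

    def test_monte_carlo_error_shrinks_with_iterations(self):
        # 20 reads ambiguous between two genes: mean count estimate of 10
        # should tighten ~ 1/sqrt(iterations)
        catalog = make_catalog([1000, 1000])
        pairs = []
        for i in range(20):
            pairs += [(f"r{i}", "g0"), (f"r{i}", "g1")]
        aln = make_alignment(pairs)
        scale = 1e9 / (1000.0 * 20)

        def errors(iters):
            out = []
            for seed in range(12):
                e = bootstrap_rpkm(aln, catalog, iterations=iters, seed=seed)
                out.append(e.frame.loc["g0", "mean_rpkm"] / scale - 10.0)
            return np.sqrt(np.mean(np.square(out)))

        ratio = errors(100) / errors(10_000)
        assert 3.0 < ratio < 33.0  # ideal ratio is 10

    def test_parameter_and_integrity_errors(self):
        catalog = make_catalog([1000])
        aln = make_alignment([("r0", "g0")])
        with pytest.raises(ValueError, match="iterations"):
            bootstrap_rpkm(aln, catalog, iterations=0)
        with pytest.raises(IntegrityError, match="absent from catalog"):
            bootstrap_rpkm(make_alignment([("r0", "gX")]), catalog, iterations=5)


class TestExpressionSignificance:
    def make_expr(self, means, sds):
        frame = pd.DataFrame(
            {
                "unique_rpkm": means,
                "mean_rpkm": means,
                "sd_rpkm": sds,
            },
            index=[f"g{i}" for i in range(len(means))],
        )
        return BootstrapExpression("s", frame, n_reads=100, iterations=10)

    def test_probability_of_nonexpression(self):
        expr = expression_significance(self.make_expr([0.0, 2.0], [1.0, 1.0]))
        p = expr.frame["p_expressed"]
        assert p["g0"] == pytest.approx(0.5)
        # independent oracle for Phi(-2)
        assert p["g1"] == pytest.approx(math.erfc(2 / math.sqrt(2)) / 2, rel=1e-12)

    def test_degenerate_zero_sd(self):
        expr = expression_significance(self.make_expr([5.0, 0.0], [0.0, 0.0]))
        assert expr.frame["p_expressed"].tolist() == [0.0, 1.0]

    def test_expressed_flag_needs_both_significance_and_level(self):
        # q ~ 0 for both genes; only the one above 2 RPKM is called expressed
        expr = expression_significance(self.make_expr([2.5, 1.9], [1e-12, 1e-12]))
        assert expr.frame["expressed_flag"].tolist() == [True, False]

    def test_q_values_are_bh_adjusted_within_sample(self):
        expr = expression_significance(
            self.make_expr([1.0, 2.0, 3.0, 0.5], [1.0, 1.0, 1.0, 1.0])
        )
        from mhbcircuit.stats import bh_fdr

        np.testing.assert_allclose(
            expr.frame["q_expressed"], bh_fdr(expr.frame["p_expressed"].to_numpy())
        )


class TestQuantileNormalization:
    def test_hand_computed_two_column_example(self):
        mat = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]})
        out = quantile_normalize(mat)
        assert out["a"].tolist() == [1.5, 3.5]
        assert out["b"].tolist() == [1.5, 3.5]

    def test_identical_columns_are_a_fixed_point(self):
        mat = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(mat), mat)

    def test_idempotent_and_identical_order_statistics(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        once = quantile_normalize(mat)
        twice = quantile_normalize(once)
        pd.testing.assert_frame_equal(once, twice)
        ref = np.sort(once["a"].to_numpy())
        for col in "bcd":
            np.testing.assert_array_equal(np.sort(once[col].to_numpy()), ref)

    def test_tied_values_stay_tied_with_average_ties(self):
        mat = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [1.0, 2.0, 3.0]})
        out = quantile_normalize(mat, ties="average")
        assert out.loc[0, "a"] == out.loc[1, "a"]

    def test_normalize_matrix_logs_then_normalizes(self):
        mat = pd.DataFrame({"a": [0.0, 3.0], "b": [1.0, 7.0]})
        out = normalize_matrix(mat, pseudocount=1.0)
        # log2(x+1) columns: (0,2) and (1,3) -> both become (0.5, 2.5)
        assert out["a"].tolist() == [0.5, 2.5]
        assert out["b"].tolist() == [0.5, 2.5]


def test_quantify_samples_is_deterministic(small_experiment):
    exp = small_experiment
    sub = {s: exp.alignments[s] for s in exp.design.sample_ids[:2]}
    a = quantify_samples(sub, exp.catalog, iterations=30, seed=9)
    b = quantify_samples(sub, exp.catalog, iterations=30, seed=9)
    for sid in sub:
        pd.testing.assert_frame_equal(a[sid].frame, b[sid].frame)


def test_mean_rpkm_matrix_requires_consistent_gene_sets():
    f1 = pd.DataFrame({"unique_rpkm": [1.0], "mean_rpkm": [1.0], "sd_rpkm": [0.0]}, index=["g0"])
    f2 = f1.copy()
    f2.index = ["g1"]
    exprs = {
        "a": BootstrapExpression("a", f1, 1, 1),
        "b": BootstrapExpression("b", f2, 1, 1),
    }
    with pytest.raises(IntegrityError):
        mean_rpkm_matrix(exprs)
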