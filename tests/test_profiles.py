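"""Region-fraction QC and nucleus-vs-cell expression concordance."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from droncqc.profiles import (
    align_means,
    deviating_genes,
    mean_log_expression,
    pearson_concordance,
    region_fractions,
)
from droncqc.quantify import ExpressionMatrix
from droncqc.readio import tagged_reads_from_records

LN2 = 0.6931471805599453
PEARSON_1234_1235 = 0.9827076298239908  # r of (1,2,3,4) vs (1,2,3,5)


def region_reads(counts):
    rows = []
    for region, n in counts.items():
        rows += [("A" * 12, "C" * 8, "g1", "human", region)] * n
    return tagged_reads_from_records(rows)


class TestRegionFractions:
    def test_degenerate_all_exonic(self):
        summary = region_fractions(region_reads({"exonic": 7}))
        assert summary.fractions == {
            "exonic": 1.0, "intronic": 0.0, "intergenic": 0.0, "mitochondrial": 0.0
        }

    def test_simple_arithmetic(self):
        summary = region_fractions(
            region_reads(
                {"exonic": 3, "intronic": 3, "intergenic": 3, "mitochondrial": 1}
            )
        )
        assert summary.n_mapped == 10
        assert summary.fractions["exonic"] == pytest.approx(0.3)
        assert summary.fractions["mitochondrial"] == pytest.approx(0.1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            region_fractions(region_reads({}))

    def test_fractions_sum_to_one_and_counts_conserve(self, small_run):
        _, reads = small_run
        summary = region_fractions(reads)
        assert summary.n_mapped == len(reads)
        assert sum(summary.fractions.values()) == pytest.approx(1.0, abs=1e-9)


def matrix_from_columns(columns, genes=None):
    data = np.asarray(columns).T  # columns: per-barcode gene count vectors
    genes = genes or [f"g{i}" for i in range(data.shape[0])]
    return ExpressionMatrix(
        genes=genes,
        barcodes=[f"b{j}" for j in range(data.shape[1])],
        counts=sp.csr_matrix(data),
    )


class TestMeanLogExpression:
    def test_zero_count_gives_zero(self):
        means = mean_log_expression(matrix_from_columns([[0]]))
        assert means.iloc[0] == 0.0

    def test_two_barcodes_count_one_each(self):
        means = mean_log_expression(matrix_from_columns([[1], [1]]))
        assert means.iloc[0] == pytest.approx(LN2)

    def test_duplicating_barcodes_leaves_means_unchanged(self):
        base = [[0, 1, 5], [3, 2, 0]]
        means_once = mean_log_expression(matrix_from_columns(base))
        means_twice = mean_log_expression(matrix_from_columns(base + base))
        assert np.allclose(means_once, means_twice)

    def test_no_barcodes_rejected(self):
        matrix = ExpressionMatrix(genes=["g"], barcodes=[],
                                  counts=sp.csr_matrix((1, 0)))
        with pytest.raises(ValueError):
            mean_log_expression(matrix)


def series(values, prefix="g"):
    return pd.Series(
        np.asarray(values, dtype=float),
        index=[f"{prefix}{i}" for i in range(len(values))],
    )


class TestPearsonConcordance:
    def test_identical_vectors_are_perfectly_concordant(self):
        result = pearson_concordance(series([1, 2, 3, 4]), series([1, 2, 3, 4]))
        assert result.r == pytest.approx(1.0)

    def test_reversed_vector_anticorrelates(self):
        result = pearson_concordance(series([0, 1, 2]), series([2, 1, 0]))
        assert result.r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        result = pearson_concordance(series([1, 2, 3, 4]), series([1, 2, 3, 5]))
        assert result.r == pytest.approx(PEARSON_1234_1235, abs=1e-12)
        assert 0 < result.p_value <= 1

    def test_agrees_with_covariance_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            result = pearson_concordance(series(x), series(y))
            xc, yc = x - x.mean(), y - y.mean()
            oracle = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
            assert result.r == pytest.approx(oracle, abs=1e-12)

    def test_union_pairing_fills_absent_genes_with_zero(self):
        a = pd.Series([1.0, 2.0], index=["g1", "g2"])
        b = pd.Series([2.0, 3.0, 1.0], index=["g2", "g3", "g4"])
        xa, xb = align_means(a, b)
        assert len(xa) == 4
        assert xa["g3"] == 0.0 and xb["g1"] == 0.0
        xi, yi = align_means(a, b, genes="intersection")
        assert list(xi.index) == ["g2"]

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_concordance(series([1, 1, 1]), series([1, 2, 3]))

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            pearson_concordance(series([1, 2]), series([2, 1]))

    def test_tiny_p_reported_in_r_style(self):
        x = np.linspace(0, 5, 200)
        result = pearson_concordance(series(x), series(x + 1e-6))
        assert result.p_report == "< 2.2e-16"


class TestDeviatingGenes:
    def test_zero_threshold_returns_all(self):
        table = deviating_genes(series([1, 2]), series([2, 1]), 0.0)
        assert len(table) == 2

    def test_identical_vectors_have_no_deviators(self):
        assert len(deviating_genes(series([1, 2]), series([1, 2]), 0.5)) == 0

    def test_selection_and_ordering(self):
        a = series([0.0, 2.0, 0.5])
        b = series([0.0, 0.0, 2.0])
        table = deviating_genes(a, b, 1.0)
        assert table["gene"].tolist() == ["g1", "g2"]  # |2.0| then |-1.5|
        assert table["diff"].tolist() == [2.0, -1.5]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            deviating_genes(series([1, 2]), series([1, 2]), -0.1)


def test_concordance_rises_as_compartment_effect_shrinks():
    # two preparations share an expression program; one compartment
    # up-scales a gene subset by exp(effect). r must grow towards 1 as the
    # effect vanishes, exactly 1 at zero effect.
    rng = np.random.default_rng(17)
    n_genes, n_barcodes = 300, 40
    rates = rng.lognormal(1.0, 1.0, size=n_genes)
    base = rng.poisson(rates[:, None], size=(n_genes, n_barcodes))
    compartment = rng.choice(n_genes, size=60, replace=False)
    correlations = []
    for effect in (2.0, 1.0, 0.5, 0.0):
        scaled = base.copy().astype(float)
        scaled[compartment] = np.round(scaled[compartment] * math.exp(effect))
        matrix_a = matrix_from_columns(base.T.tolist())
        matrix_b = matrix_from_columns(scaled.T.tolist())
        result = pearson_concordance(
            mean_log_expression(matrix_a), mean_log_expression(matrix_b)
        )
        correlations.append(result.r)
    assert correlations == sorted(correlations)
    assert correlations[-1] == pytest.approx(1.0)


def test_region_recovery_from_simulation(small_run, small_params):
    _, reads = small_run
    summary = region_fractions(reads)
    for p, region in zip(
        small_params.region_probs,
        ("exonic", "intronic", "intergenic", "mitochondrial"),
    ):
        se = math.sqrt(p * (1 - p) / summary.n_mapped)
        assert abs(summary.fractions[region] - p) < 3 * se
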