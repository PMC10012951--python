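"""Read-region QC fractions and nucleus-vs-cell expression concordance.

Nuclear RNA has a characteristic genomic footprint: compared with whole
cells, a much larger share of reads falls in introns (unspliced nuclear
transcripts) and a near-zero share on the mitochondrial genome, which is
physically absent from isolated nuclei.  :func:`region_fractions`
summarises that footprint.  Concordance between two preparations (e.g.
nuclei vs cells of the same line) is measured on per-gene average
log-transformed counts with a Pearson correlation; genes whose averages
diverge beyond a threshold are flagged as deviating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .quantify import ExpressionMatrix
from .readio import REGIONS

#: p-values below R's double-precision reporting floor print as "< 2.2e-16"
P_REPORT_FLOOR = 2.2e-16


@dataclass
class RegionSummary:
    """Fractions of mapped reads per genomic region category."""

    n_mapped: int
    fractions: dict[str, float]

    def to_dict(self) -> dict:
        return {"n_mapped": self.n_mapped, "fractions": dict(self.fractions)}


def region_fractions(reads: pd.DataFrame) -> RegionSummary:
    """Fraction of reads in each region category, out of all mapped reads.

    The four categories (exonic, intronic, intergenic, mitochondrial) are
    exclusive — each read is counted exactly once — so the fractions sum
    to 1.
    """
    if len(reads) == 0:
        raise ValueError("cannot compute region fractions of an empty read table")
    counts = reads["region"].value_counts()
    total = int(counts.sum())
    fractions = {region: float(counts.get(region, 0)) / total for region in REGIONS}
    return RegionSummary(n_mapped=total, fractions=fractions)


def mean_log_expression(matrix: ExpressionMatrix) -> pd.Series:
    """Per-gene mean of ln(count + 1) over all barcodes (zeros included).

    The natural log is used; the base is immaterial for any downstream
    Pearson correlation (affine invariance) but fixes the scale of the
    reported means.
    """
    n_barcodes = len(matrix.barcodes)
    if n_barcodes == 0:
        raise ValueError("matrix has no barcodes")
    logged = matrix.counts.astype(float)
    logged.data = np.log1p(logged.data)  # log1p(0) = 0, so sparsity is preserved
    means = np.asarray(logged.sum(axis=1)).ravel() / n_barcodes
    return pd.Series(means, index=pd.Index(matrix.genes, name="gene"))


def align_means(
    means_a: pd.Series, means_b: pd.Series, genes: str = "union"
) -> tuple[pd.Series, pd.Series]:
    """Pair two per-gene mean vectors on a shared gene set.

    ``genes='union'`` (default) treats a gene absent from one side as mean
    0 — consistent with retaining all-zero gene rows; ``'intersection'``
    keeps only genes present in both.
    """
    if genes == "union":
        index = means_a.index.union(means_b.index, sort=True)
        return (
            means_a.reindex(index, fill_value=0.0),
            means_b.reindex(index, fill_value=0.0),
        )
    if genes == "intersection":
        index = means_a.index.intersection(means_b.index).sort_values()
        return means_a.reindex(index), means_b.reindex(index)
    raise ValueError(f"genes must be 'union' or 'intersection', got {genes!r}")


@dataclass
class ConcordanceResult:
    """Pearson concordance between two per-gene mean-log-expression vectors."""

    n_genes: int
    r: float
    p_value: float
    means_a: pd.Series
    means_b: pd.Series

    @property
    def p_report(self) -> str:
        """p-value in reporting style: '< 2.2e-16' below the floor."""
        if self.p_value < P_REPORT_FLOOR:
            return "< 2.2e-16"
        return f"{self.p_value:.4g}"

    def deviating(self, min_abs_diff: float) -> pd.DataFrame:
        return deviating_genes(self.means_a, self.means_b, min_abs_diff)

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "r": self.r,
            "p_value": self.p_value,
            "p_report": self.p_report,
        }


def pearson_concordance(
    means_a: pd.Series, means_b: pd.Series, genes: str = "union"
) -> ConcordanceResult:
    """Pearson correlation between paired per-gene means.

    Vectors are aligned per :func:`align_means`; at least 3 genes are
    required and neither vector may be constant.  The two-sided p-value
    follows the exact t distribution with n - 2 degrees of freedom.
    """
    a, b = align_means(means_a, means_b, genes=genes)
    n = len(a)
    if n < 3:
        raise ValueError(f"need >= 3 paired genes for a correlation, got {n}")
    x = a.to_numpy(dtype=float)
    y = b.to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    result = stats.pearsonr(x, y)
    return ConcordanceResult(
        n_genes=n,
        r=float(result.statistic),
        p_value=float(max(result.pvalue, np.finfo(float).tiny)),
        means_a=a,
        means_b=b,
    )


def deviating_genes(
    means_a: pd.Series, means_b: pd.Series, min_abs_diff: float
) -> pd.DataFrame:
    """Genes whose mean log expression differs by >= ``min_abs_diff``.

    Returns columns gene, mean_a, mean_b, diff (a - b), abs_diff, sorted
    by absolute difference descending (ties by gene name for determinism).
    This is a declared stand-in for a per-gene differential expression
    test: it flags genes highly expressed in one preparation but not the
    other, without any significance calibration.
    """
    if min_abs_diff < 0:
        raise ValueError("min_abs_diff must be non-negative")
    a, b = align_means(means_a, means_b, genes="union")
    diff = a - b
    table = pd.DataFrame(
        {
            "gene": a.index,
            "mean_a": a.to_numpy(),
            "mean_b": b.to_numpy(),
            "diff": diff.to_numpy(),
            "abs_diff": np.abs(diff.to_numpy()),
        }
    )
    table = table[table["abs_diff"] >= min_abs_diff]
    return table.sort_values(
        ["abs_diff", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
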