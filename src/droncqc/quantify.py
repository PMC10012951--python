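"""UMI-collapsed expression quantification for whitelisted barcodes.

After barcode repair, every read carries an accepted bead barcode (or is
dropped as unassignable).  Molecules are counted per (gene, barcode) as
the number of distinct UMI sequences among the supporting reads — exact
sequence identity, no UMI error correction — alongside the raw read
support.  The per-barcode filters mirror the barnyard figure cut-offs:
a gene counts as expressed when its read support reaches
``min_reads_per_gene`` (default 1), and barcodes expressing fewer than
``min_genes_per_barcode`` genes (default 200) are removed.  Gene rows are
always retained, even when all-zero, so matrices built on the same panel
stay alignable by gene set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .barcodes import Whitelist


@dataclass
class ExpressionMatrix:
    """Sparse gene x barcode UMI counts with optional raw read support.

    ``counts[g, b]`` is the number of distinct UMIs observed for gene g
    under barcode b; ``per_gene_reads[g, b]`` (when present) the number of
    supporting reads, so ``counts <= per_gene_reads`` elementwise.
    """

    genes: list[str]
    barcodes: list[str]
    counts: sp.csr_matrix
    per_gene_reads: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if self.per_gene_reads is not None:
            self.per_gene_reads = sp.csr_matrix(self.per_gene_reads)
            if self.per_gene_reads.shape != self.counts.shape:
                raise ValueError("per_gene_reads shape differs from counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def total_umis(self) -> int:
        return int(self.counts.sum())

    def umis_per_barcode(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_per_barcode(
        self, min_reads_per_gene: int = 1, support: str = "reads"
    ) -> np.ndarray:
        """Expressed-gene count per barcode under the chosen support rule."""
        matrix = self._support_matrix(support)
        if min_reads_per_gene == 1:
            return np.diff(sp.csc_matrix(matrix).indptr)
        return np.asarray((matrix >= min_reads_per_gene).sum(axis=0)).ravel()

    def _support_matrix(self, support: str) -> sp.spmatrix:
        if support == "reads":
            if self.per_gene_reads is None:
                raise ValueError("read support requested but per_gene_reads is absent")
            return self.per_gene_reads
        if support == "transcripts":
            return self.counts
        raise ValueError(f"support must be 'reads' or 'transcripts', got {support!r}")

    def subset_barcodes(self, keep: Sequence[str]) -> "ExpressionMatrix":
        """Column subset in the given barcode order (all must be present)."""
        index = {b: i for i, b in enumerate(self.barcodes)}
        cols = np.array([index[b] for b in keep], dtype=int)
        return ExpressionMatrix(
            genes=list(self.genes),
            barcodes=list(keep),
            counts=self.counts[:, cols],
            per_gene_reads=(
                None if self.per_gene_reads is None else self.per_gene_reads[:, cols]
            ),
        )

    def to_anndata(self):
        """Barcode x gene AnnData view (scanpy orientation)."""
        import anndata

        return anndata.AnnData(
            X=self.counts.T.tocsr(),
            obs=pd.DataFrame(index=pd.Index(self.barcodes, name="barcode")),
            var=pd.DataFrame(index=pd.Index(self.genes, name="gene")),
        )

    def save_mtx(self, out_dir: str | Path) -> None:
        """MatrixMarket triplet: matrix.mtx + features.tsv + barcodes.tsv."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(out_dir / "matrix.mtx", self.counts.tocoo())
        if self.per_gene_reads is not None:
            scipy.io.mmwrite(out_dir / "reads.mtx", self.per_gene_reads.tocoo())
        (out_dir / "features.tsv").write_text("".join(f"{g}\n" for g in self.genes))
        (out_dir / "barcodes.tsv").write_text("".join(f"{b}\n" for b in self.barcodes))

    @classmethod
    def load_mtx(cls, out_dir: str | Path) -> "ExpressionMatrix":
        out_dir = Path(out_dir)
        counts = sp.csr_matrix(scipy.io.mmread(out_dir / "matrix.mtx"))
        reads_path = out_dir / "reads.mtx"
        per_gene_reads = (
            sp.csr_matrix(scipy.io.mmread(reads_path)) if reads_path.exists() else None
        )
        genes = (out_dir / "features.tsv").read_text().splitlines()
        barcodes = (out_dir / "barcodes.tsv").read_text().splitlines()
        return cls(
            genes=genes, barcodes=barcodes, counts=counts, per_gene_reads=per_gene_reads
        )


def count_molecules(
    reads: pd.DataFrame,
    whitelist: Whitelist,
    genes: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """UMI-collapsed counts per whitelisted barcode after repair.

    Each read's barcode is replaced through the whitelist's repair map;
    unassignable reads are dropped.  ``counts`` collapses reads to
    distinct (barcode, gene, UMI) molecules, ``per_gene_reads`` keeps the
    raw read support.  Matrix columns are the whitelist entries in rank
    order (including entries with no reads); rows are ``genes`` when
    given, else the genes observed, sorted.
    """
    entries = whitelist.entries
    col_index = {b: i for i, b in enumerate(entries)}

    raw = reads["barcode"]
    raw_cat = raw if isinstance(raw.dtype, pd.CategoricalDtype) else raw.astype(
        "category"
    )
    categories = raw_cat.cat.categories
    mapped = np.full(len(categories), -1, dtype=np.int64)
    for i, raw_barcode in enumerate(categories):
        assigned = whitelist.repair_map.get(raw_barcode, None)
        if assigned is not None:
            mapped[i] = col_index[assigned]
    col_of_read = mapped[raw_cat.cat.codes.to_numpy()]
    kept = col_of_read >= 0

    gene_series = reads["gene"]
    if not isinstance(gene_series.dtype, pd.CategoricalDtype):
        gene_series = gene_series.astype("category")
    if genes is None:
        observed = gene_series.cat.categories[
            np.unique(gene_series.cat.codes.to_numpy()[kept])
        ]
        genes = sorted(map(str, observed))
    gene_index = {g: i for i, g in enumerate(genes)}
    gene_mapped = np.array(
        [gene_index.get(g, -1) for g in gene_series.cat.categories], dtype=np.int64
    )
    row_of_read = gene_mapped[gene_series.cat.codes.to_numpy()]
    kept &= row_of_read >= 0

    shape = (len(genes), len(entries))
    if not kept.any():
        zero = sp.csr_matrix(shape, dtype=np.int64)
        return ExpressionMatrix(
            genes=list(genes), barcodes=list(entries), counts=zero.copy(),
            per_gene_reads=zero.copy(),
        )

    umi_series = reads["umi"]
    if isinstance(umi_series.dtype, pd.CategoricalDtype):
        umi_codes = umi_series.cat.codes.to_numpy()[kept]
    else:
        umi_codes = pd.factorize(umi_series.to_numpy()[kept])[0]
    table = pd.DataFrame(
        {"g": row_of_read[kept], "b": col_of_read[kept], "u": umi_codes}
    )
    read_support = table.groupby(["g", "b"], sort=False).size()
    molecule_support = (
        table.drop_duplicates().groupby(["g", "b"], sort=False).size()
    )

    def to_csr(series: pd.Series) -> sp.csr_matrix:
        g = series.index.get_level_values("g").to_numpy()
        b = series.index.get_level_values("b").to_numpy()
        return sp.coo_matrix(
            (series.to_numpy(dtype=np.int64), (g, b)), shape=shape
        ).tocsr()

    return ExpressionMatrix(
        genes=list(genes),
        barcodes=list(entries),
        counts=to_csr(molecule_support),
        per_gene_reads=to_csr(read_support),
    )


def apply_barcode_filters(
    matrix: ExpressionMatrix,
    min_reads_per_gene: int = 1,
    min_genes_per_barcode: int = 200,
    support: str = "reads",
) -> ExpressionMatrix:
    """Remove barcodes expressing fewer than ``min_genes_per_barcode`` genes.

    A gene is "expressed" in a barcode when its support (raw reads by
    default, UMIs with ``support='transcripts'``) reaches
    ``min_reads_per_gene``.  Gene rows are retained even if all-zero after
    filtering; the operation is idempotent.
    """
    if min_reads_per_gene < 0 or min_genes_per_barcode < 0:
        raise ValueError("filter thresholds must be non-negative")
    if min_reads_per_gene == 1 and matrix.per_gene_reads is None and support == "reads":
        # nonzero UMIs iff nonzero reads, so transcript support is equivalent
        support = "transcripts"
    n_genes = matrix.genes_per_barcode(
        min_reads_per_gene=max(min_reads_per_gene, 1), support=support
    )
    keep = n_genes >= min_genes_per_barcode
    cols = [b for b, flag in zip(matrix.barcodes, keep) if flag]
    return matrix.subset_barcodes(cols)
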