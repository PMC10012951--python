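"""Read-1 structure validation and tagged-read table IO.

DroNc-seq read 1 is sequenced for 26 cycles and carries, in order, a 12 nt
bead (nucleus) barcode, an 8 nt unique molecular identifier, a single
anchor base that must be A, C or G (the "V" base preceding the capture
oligo's poly-T), and then the poly-T stretch itself.  A read pair is kept
only when this structure is intact; everything downstream (whitelisting,
repair, quantification) consumes only structurally valid reads.

The tagged-read table is the post-alignment representation this package
works from: one row per sequenced read with its barcode, UMI, gene,
genome of origin and genomic region.  It is either produced by the
synthetic generator (:mod:`droncqc.simdrops`) or derived by the user from
an aligned, annotated BAM upstream.
"""

from __future__ import annotations

import enum
import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

BARCODE_LENGTH = 12
UMI_LENGTH = 8
ANCHOR_BASES = frozenset("ACG")
#: number of poly-T cycles observable in a 26-cycle read 1
POLYT_WINDOW = 5
#: minimum T count inside the window for the poly-T check to pass
POLYT_MIN_T = 4

REGIONS = ("exonic", "intronic", "intergenic", "mitochondrial")
GENOMES = ("human", "murine")

TAGGED_READ_COLUMNS = ("barcode", "umi", "gene", "genome", "region")


class RejectReason(enum.Enum):
    """Why a read-1 sequence failed the structural check."""

    TOO_SHORT = "TOO_SHORT"
    BAD_ANCHOR = "BAD_ANCHOR"
    BAD_POLYT = "BAD_POLYT"
    AMBIGUOUS_BASE = "AMBIGUOUS_BASE"


class FormatError(ValueError):
    """A file violated the format contract (missing column, bad label, ...)."""


@dataclass(frozen=True)
class Read1Parse:
    """Result of parsing one read-1 sequence.

    ``valid`` and ``reject_reason`` are mutually exclusive: exactly one of
    ``valid is True`` / ``reject_reason is not None`` holds.
    """

    barcode: str
    umi: str
    anchor: str
    valid: bool
    reject_reason: RejectReason | None = None


def parse_read1(
    sequence: str,
    *,
    barcode_length: int = BARCODE_LENGTH,
    umi_length: int = UMI_LENGTH,
    polyt_window: int = POLYT_WINDOW,
    polyt_min_t: int = POLYT_MIN_T,
) -> Read1Parse:
    """Parse a read-1 sequence into barcode / UMI / anchor and validate it.

    Positions (1-based): 1-12 barcode, 13-20 UMI, 21 anchor, 22-26 poly-T
    window.  A read is valid iff it is long enough, barcode and UMI are
    unambiguous (no N), the anchor is one of A/C/G, and at least
    ``polyt_min_t`` of the ``polyt_window`` bases after the anchor are T.

    This function is total: it never raises on sequence content, it
    returns ``valid=False`` with a :class:`RejectReason` instead.
    """
    seq = sequence.upper()
    min_length = barcode_length + umi_length + 1 + polyt_window
    barcode = seq[:barcode_length]
    umi = seq[barcode_length : barcode_length + umi_length]
    anchor = seq[barcode_length + umi_length : barcode_length + umi_length + 1]

    def reject(reason: RejectReason) -> Read1Parse:
        return Read1Parse(barcode, umi, anchor, valid=False, reject_reason=reason)

    if len(seq) < min_length:
        return reject(RejectReason.TOO_SHORT)
    if any(base not in "ACGT" for base in barcode + umi):
        return reject(RejectReason.AMBIGUOUS_BASE)
    if anchor not in ANCHOR_BASES:
        return reject(RejectReason.BAD_ANCHOR)
    tail = seq[barcode_length + umi_length + 1 : min_length]
    if tail.count("T") < polyt_min_t:
        return reject(RejectReason.BAD_POLYT)
    return Read1Parse(barcode, umi, anchor, valid=True)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class FilterResult:
    """Outcome of structural filtering of a FASTQ pair."""

    kept: int
    rejected: dict[RejectReason, int]

    @property
    def total(self) -> int:
        return self.kept + sum(self.rejected.values())

    def to_dict(self) -> dict:
        return {
            "kept": self.kept,
            "rejected": {reason.value: n for reason, n in self.rejected.items()},
            "total": self.total,
        }


def filter_fastq(
    fastq1: str | Path,
    fastq2: str | Path,
    out1: str | Path,
    out2: str | Path,
    **parse_kwargs,
) -> FilterResult:
    """Keep read pairs whose read 1 has a correctly formed barcode structure.

    Pairs are streamed; a pair is written to ``out1``/``out2`` iff
    :func:`parse_read1` accepts read 1.  Counts conserve:
    ``kept + sum(rejected.values()) == input pairs``.

    Raises :class:`FormatError` if the two files hold unequal numbers of
    records.
    """
    rejected = {reason: 0 for reason in RejectReason}
    kept = 0
    _SENTINEL = object()
    with _open_text(fastq1) as handle1, _open_text(fastq2) as handle2, _open_text(
        out1, "wt"
    ) as keep1, _open_text(out2, "wt") as keep2:
        iter1 = FastqGeneralIterator(handle1)
        iter2 = FastqGeneralIterator(handle2)
        while True:
            rec1 = next(iter1, _SENTINEL)
            rec2 = next(iter2, _SENTINEL)
            if rec1 is _SENTINEL and rec2 is _SENTINEL:
                break
            if rec1 is _SENTINEL or rec2 is _SENTINEL:
                raise FormatError("paired FASTQ files hold unequal record counts")
            title1, seq1, qual1 = rec1
            title2, seq2, qual2 = rec2
            parse = parse_read1(seq1, **parse_kwargs)
            if parse.valid:
                kept += 1
                keep1.write(f"@{title1}\n{seq1}\n+\n{qual1}\n")
                keep2.write(f"@{title2}\n{seq2}\n+\n{qual2}\n")
            else:
                rejected[parse.reject_reason] += 1
    return FilterResult(kept=kept, rejected=rejected)


def load_tagged_reads(path: str | Path) -> pd.DataFrame:
    """Load a tagged-read TSV into a DataFrame.

    The file must carry a header with columns ``barcode``, ``umi``,
    ``gene``, ``genome`` (``species`` is accepted as an alias) and
    ``region``; extra columns are ignored and row order is preserved.
    Unknown region labels raise :class:`FormatError` naming the first
    offending row (1-based, excluding the header).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "genome" not in df.columns and "species" in df.columns:
        df = df.rename(columns={"species": "genome"})
    for column in TAGGED_READ_COLUMNS:
        if column not in df.columns:
            raise FormatError(f"tagged-read table is missing required column {column!r}")
    df = df.loc[:, list(TAGGED_READ_COLUMNS)].reset_index(drop=True)
    bad = ~df["region"].isin(REGIONS)
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise FormatError(
            f"unknown region label {df['region'][row - 1]!r} at row {row}; "
            f"expected one of {REGIONS}"
        )
    for column in ("gene", "genome", "region"):
        df[column] = df[column].astype("category")
    return df


def write_tagged_reads(reads: pd.DataFrame, path: str | Path) -> None:
    """Write a tagged-read table as TSV (columns per :data:`TAGGED_READ_COLUMNS`)."""
    reads.loc[:, list(TAGGED_READ_COLUMNS)].to_csv(path, sep="\t", index=False)


def tagged_reads_from_records(records: Iterable[tuple]) -> pd.DataFrame:
    """Build a tagged-read DataFrame from (barcode, umi, gene, genome, region) tuples."""
    return pd.DataFrame.from_records(list(records), columns=list(TAGGED_READ_COLUMNS))
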