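"""Candidate selection, whitelist construction and Hamming barcode repair.

Bead barcodes observed in the reads are a mix of real bead sequences and
their sequencing-error satellites.  The whitelist is built from barcodes
that look like real nuclei (at least 150 genes detected), ranked either
by genes detected or by total reads, and truncated to the theoretical
number of nuclei expected from the loading.  Every other observed barcode
is then repaired to the nearest whitelist entry within a maximum Hamming
distance (default 2, the "H2" setting); a barcode equidistant from two or
more entries at the minimal qualifying distance is left unassigned rather
than arbitrarily reassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: sentinel for a raw barcode that could not be assigned to the whitelist
UNASSIGNED = None

RANKING_MODES = ("by_genes", "by_reads")


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(
            f"hamming_distance requires equal lengths, got {len(a)} and {len(b)}"
        )
    return sum(x != y for x, y in zip(a, b))


def barcode_stats(
    reads: pd.DataFrame,
    min_reads_per_gene: int = 1,
    barcode_column: str = "barcode",
) -> pd.DataFrame:
    """Per-barcode read and gene tallies from a tagged-read table.

    ``n_genes`` counts genes with at least ``min_reads_per_gene`` reads for
    the barcode.  Returns columns ``barcode``, ``n_reads``, ``n_genes``.
    """
    if min_reads_per_gene < 1:
        raise ValueError("min_reads_per_gene must be >= 1")
    per_gene = (
        reads.groupby([barcode_column, "gene"], observed=True, sort=False)
        .size()
        .rename("reads")
        .reset_index()
    )
    n_reads = per_gene.groupby(barcode_column, observed=True, sort=False)["reads"].sum()
    expressed = per_gene[per_gene["reads"] >= min_reads_per_gene]
    n_genes = (
        expressed.groupby(barcode_column, observed=True, sort=False)
        .size()
        .reindex(n_reads.index, fill_value=0)
    )
    stats = pd.DataFrame({"n_reads": n_reads, "n_genes": n_genes})
    stats.index.name = "barcode"
    return stats.reset_index()


def candidate_barcodes(
    stats: pd.DataFrame, min_genes: int = 150, mode: str = "by_genes"
) -> pd.DataFrame:
    """Barcodes with >= ``min_genes`` genes detected, ranked for whitelisting.

    Sorted descending by the mode's key (genes detected or total reads);
    ties are broken by the other key descending, then lexicographically by
    barcode so the ranking is total and deterministic.
    """
    if mode not in RANKING_MODES:
        raise ValueError(f"mode must be one of {RANKING_MODES}, got {mode!r}")
    kept = stats[stats["n_genes"] >= min_genes]
    primary, secondary = (
        ("n_genes", "n_reads") if mode == "by_genes" else ("n_reads", "n_genes")
    )
    return kept.sort_values(
        [primary, secondary, "barcode"], ascending=[False, False, True]
    ).reset_index(drop=True)


@dataclass
class Whitelist:
    """Ranked accepted barcodes plus the raw -> accepted repair map.

    ``repair_map`` maps every raw barcode seen so far to a whitelist entry
    or to :data:`UNASSIGNED` (``None``).  Entries always map to
    themselves; assigned pairs satisfy ``hamming <= max_distance``.
    """

    entries: list[str]
    ranking_mode: str = "by_genes"
    max_distance: int = 2
    repair_map: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("whitelist entries must be unique")
        for entry in self.entries:
            self.repair_map.setdefault(entry, entry)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._entry_set

    @property
    def _entry_set(self) -> frozenset:
        return frozenset(self.entries)

    def write(self, path: str | Path) -> None:
        """One accepted barcode per line, rank order."""
        Path(path).write_text("".join(f"{b}\n" for b in self.entries))

    def write_repair_map(self, path: str | Path) -> None:
        """Two-column TSV raw -> assigned, '-' for unassigned."""
        with open(path, "w") as handle:
            handle.write("raw\tassigned\n")
            for raw, assigned in self.repair_map.items():
                handle.write(f"{raw}\t{assigned if assigned is not None else '-'}\n")


def build_whitelist(
    candidates: pd.DataFrame, n_expected: int, mode: str = "by_genes"
) -> Whitelist:
    """Truncate ranked candidates to the expected number of nuclei.

    ``n_expected`` is the theoretical number of single nuclei expected
    from the loading (e.g. droplets x occupancy); the whitelist keeps the
    top ``min(n_expected, candidates)`` barcodes and starts from an
    identity repair map.
    """
    if n_expected <= 0:
        raise ValueError(f"n_expected must be positive, got {n_expected}")
    entries = candidates["barcode"].head(n_expected).tolist()
    return Whitelist(entries=entries, ranking_mode=mode)


def _encode(barcodes: Sequence[str], length: int) -> np.ndarray:
    """Barcodes -> (n, length) uint8 base codes (A,C,G,T -> 0..3)."""
    as_bytes = np.asarray(list(barcodes), dtype=f"S{length}")
    flat = as_bytes.view(np.uint8).reshape(len(barcodes), length)
    codes = np.zeros_like(flat)
    for value, base in enumerate(b"ACGT"):
        codes[flat == base] = value
    return codes


def _pack(codes: np.ndarray) -> np.ndarray:
    """(n, L) 2-bit base codes -> packed uint64, one word per barcode."""
    n, length = codes.shape
    if length > 32:
        raise ValueError("packed representation supports length <= 32")
    packed = np.zeros(n, dtype=np.uint64)
    for position in range(length):
        packed = (packed << np.uint64(2)) | codes[:, position].astype(np.uint64)
    return packed


@dataclass
class RepairSummary:
    """Counts from one repair pass over raw barcodes."""

    n_raw: int
    n_exact: int
    n_repaired: int
    n_ambiguous: int
    n_unassigned: int

    def to_dict(self) -> dict:
        return {
            "n_raw": self.n_raw,
            "n_exact": self.n_exact,
            "n_repaired": self.n_repaired,
            "n_ambiguous": self.n_ambiguous,
            "n_unassigned": self.n_unassigned,
        }


def repair_barcodes(
    raw_barcodes: Iterable[str],
    whitelist: Whitelist,
    max_distance: int = 2,
) -> tuple[Whitelist, RepairSummary]:
    """Complete the whitelist's repair map over the observed raw barcodes.

    A whitelisted barcode maps to itself.  A non-whitelisted barcode maps
    to the unique nearest whitelist entry at Hamming distance <=
    ``max_distance``; if two or more entries tie at the minimal qualifying
    distance the barcode is left :data:`UNASSIGNED` (ties are counted in
    the summary), as is any barcode farther than ``max_distance`` from
    every entry.

    Distances are computed exactly for all (raw, entry) pairs using a
    packed 2-bit representation; the result is identical to a brute-force
    all-pairs Hamming scan.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be non-negative")
    unique_raw = pd.unique(np.asarray(list(raw_barcodes), dtype=object))
    if len(whitelist.entries) == 0:
        for raw in unique_raw:
            whitelist.repair_map.setdefault(raw, UNASSIGNED)
        n_exact = 0
        summary = RepairSummary(
            n_raw=len(unique_raw),
            n_exact=0,
            n_repaired=0,
            n_ambiguous=0,
            n_unassigned=len(unique_raw),
        )
        whitelist.max_distance = max_distance
        return whitelist, summary

    length = len(whitelist.entries[0])
    for raw in unique_raw:
        if len(raw) != length:
            raise ValueError(
                f"raw barcode {raw!r} length {len(raw)} != whitelist length {length}"
            )

    entry_set = whitelist._entry_set
    exact = [raw for raw in unique_raw if raw in entry_set]
    todo = [raw for raw in unique_raw if raw not in entry_set]
    for raw in exact:
        whitelist.repair_map[raw] = raw

    n_repaired = n_ambiguous = n_unassigned = 0
    if todo:
        wl_packed = _pack(_encode(whitelist.entries, length))
        raw_packed = _pack(_encode(todo, length))
        entries_arr = np.asarray(whitelist.entries, dtype=object)
        chunk = max(1, 2_000_000 // max(1, len(wl_packed)))
        for start in range(0, len(todo), chunk):
            block = raw_packed[start : start + chunk]
            diff = block[:, None] ^ wl_packed[None, :]
            # one mismatched base -> one or two set bits in its 2-bit field
            mism = (diff | (diff >> np.uint64(1))) & np.uint64(
                0x5555555555555555
            )
            dist = np.bitwise_count(mism)
            best = dist.min(axis=1)
            n_best = (dist == best[:, None]).sum(axis=1)
            nearest = dist.argmin(axis=1)
            for offset in range(len(block)):
                raw = todo[start + offset]
                if best[offset] > max_distance:
                    whitelist.repair_map[raw] = UNASSIGNED
                    n_unassigned += 1
                elif n_best[offset] > 1:
                    whitelist.repair_map[raw] = UNASSIGNED
                    n_ambiguous += 1
                    n_unassigned += 1
                else:
                    whitelist.repair_map[raw] = entries_arr[nearest[offset]]
                    n_repaired += 1

    whitelist.max_distance = max_distance
    summary = RepairSummary(
        n_raw=len(unique_raw),
        n_exact=len(exact),
        n_repaired=n_repaired,
        n_ambiguous=n_ambiguous,
        n_unassigned=n_unassigned,
    )
    return whitelist, summary
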