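"""Barnyard (two-species mixing) analysis and Poisson loading arithmetic.

In a barnyard experiment, nuclei from two species (here human T24 and
murine NIH-3T3 cultures, mixed 1:1) are run through the droplet device
together.  A barcode whose transcripts come overwhelmingly (>95%) from one
genome is called a singlet of that species; a barcode below the threshold
for both genomes is "mixed" and betrays a droplet that captured nuclei
from both species.  Same-species doublets are invisible to this readout:
under independent loading with species proportions p and q, only a
fraction 2pq of doublets is cross-species, so the total doublet rate is
estimated as ``mixed / (2 p q) / classified`` — a factor of exactly 2 at a
1:1 mix.

The module also houses the Poisson loading arithmetic: diluting nuclei so
that a fraction ``occupancy`` of droplets contains at least one nucleus
corresponds to a per-droplet Poisson mean λ = −ln(1 − occupancy), and the
fraction of occupied droplets holding two or more nuclei follows in
closed form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .quantify import ExpressionMatrix

SPECIES_LABELS = ("human", "murine", "mixed")


def occupancy_to_lambda(occupancy: float) -> float:
    """Poisson mean per droplet from the fraction of occupied droplets.

    Solves ``1 - exp(-lam) = occupancy`` for ``lam``; occupancy must lie in
    [0, 1).
    """
    if not 0.0 <= occupancy < 1.0:
        raise ValueError(f"occupancy must be in [0, 1), got {occupancy}")
    return -math.log1p(-occupancy)


def doublet_fraction_among_occupied(lam: float) -> float:
    """Fraction of occupied droplets that contain >= 2 nuclei, Poisson(λ) loading.

    ``(1 - e^{-λ} - λ e^{-λ}) / (1 - e^{-λ})``; defined as 0 at λ = 0.
    """
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    if lam == 0:
        return 0.0
    p_occupied = -math.expm1(-lam)
    p_multi = p_occupied - lam * math.exp(-lam)
    return p_multi / p_occupied


def expected_stamps(n_beads: int, capture_rate: float = 0.05) -> float:
    """Expected STAMPs (bead-attached transcriptomes) from an aliquot of beads.

    DroNc-seq captures a nucleus on ~5% of beads, so an aliquot of 5000
    beads yields ~250 STAMPs.
    """
    if not 0.0 <= capture_rate <= 1.0:
        raise ValueError(f"capture_rate must be in [0, 1], got {capture_rate}")
    if n_beads <= 0:
        raise ValueError(f"n_beads must be positive, got {n_beads}")
    return n_beads * capture_rate


@dataclass
class SpeciesCallSet:
    """Per-barcode species assignment from a barnyard experiment.

    ``calls`` holds one row per classified barcode with columns
    ``barcode``, ``n_human``, ``n_murine``, ``fraction_max`` and ``label``
    (human / murine / mixed).  ``n_excluded_zero`` counts barcodes dropped
    because both genome totals were zero.
    """

    calls: pd.DataFrame
    threshold: float = 0.95
    unit: str = "transcripts"
    n_excluded_zero: int = 0

    def __len__(self) -> int:
        return len(self.calls)

    def label_counts(self) -> dict[str, int]:
        counts = self.calls["label"].value_counts()
        return {label: int(counts.get(label, 0)) for label in SPECIES_LABELS}

    @classmethod
    def from_counts(
        cls, n_human: int, n_murine: int, n_mixed: int, threshold: float = 0.95
    ) -> "SpeciesCallSet":
        """Build a call set from aggregate counts (e.g. numbers read off a figure).

        Per-barcode transcript counts are placeholders consistent with each
        label; only the labels matter for doublet estimation.
        """
        rows = []
        for i in range(n_human):
            rows.append((f"human_{i}", 100, 0, 1.0, "human"))
        for i in range(n_murine):
            rows.append((f"murine_{i}", 0, 100, 1.0, "murine"))
        for i in range(n_mixed):
            rows.append((f"mixed_{i}", 50, 50, 0.5, "mixed"))
        calls = pd.DataFrame(
            rows, columns=["barcode", "n_human", "n_murine", "fraction_max", "label"]
        )
        return cls(calls=calls, threshold=threshold)


def classify_species(
    matrix_human: "ExpressionMatrix",
    matrix_murine: "ExpressionMatrix",
    threshold: float = 0.95,
    unit: str = "transcripts",
) -> SpeciesCallSet:
    """Classify barcodes as human, murine or mixed by genome transcript share.

    For each barcode in the union of the two matrices' barcode sets, the
    totals aligned to each genome are compared: the barcode is labelled
    ``human`` iff strictly more than ``threshold`` of its transcripts map
    to the human genome (symmetrically ``murine``), else ``mixed``.  A
    barcode at exactly the threshold is mixed.  ``unit`` selects UMI
    counts (``"transcripts"``) or raw read support (``"reads"``).

    Barcodes with zero total in both matrices are excluded and counted in
    ``n_excluded_zero``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if unit not in ("transcripts", "reads"):
        raise ValueError(f"unit must be 'transcripts' or 'reads', got {unit!r}")

    def totals(matrix: "ExpressionMatrix") -> pd.Series:
        if unit == "transcripts":
            data = matrix.counts
        else:
            if matrix.per_gene_reads is None:
                raise ValueError("unit='reads' requires per_gene_reads")
            data = matrix.per_gene_reads
        return pd.Series(
            np.asarray(data.sum(axis=0)).ravel(), index=matrix.barcodes
        )

    human = totals(matrix_human)
    murine = totals(matrix_murine)
    barcodes = human.index.union(murine.index, sort=True)
    n_human = human.reindex(barcodes, fill_value=0).to_numpy(dtype=float)
    n_murine = murine.reindex(barcodes, fill_value=0).to_numpy(dtype=float)

    total = n_human + n_murine
    nonzero = total > 0
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} barcode(s) had zero total in both matrices and were excluded",
            stacklevel=2,
        )
    n_human, n_murine, total = n_human[nonzero], n_murine[nonzero], total[nonzero]
    frac_human = n_human / total
    frac_murine = n_murine / total
    label = np.where(
        frac_human > threshold,
        "human",
        np.where(frac_murine > threshold, "murine", "mixed"),
    )
    calls = pd.DataFrame(
        {
            "barcode": np.asarray(barcodes)[nonzero],
            "n_human": n_human.astype(int),
            "n_murine": n_murine.astype(int),
            "fraction_max": np.maximum(frac_human, frac_murine),
            "label": label,
        }
    )
    return SpeciesCallSet(
        calls=calls, threshold=threshold, unit=unit, n_excluded_zero=n_excluded
    )


@dataclass
class DoubletEstimate:
    """Cross-species-corrected doublet rate estimate.

    ``doublet_rate`` is a fraction in [0, 1]; :attr:`percent` reports it as
    a percentage rounded to two decimals, the convention used in summaries.
    """

    n_total: int
    n_mixed: int
    species_proportions: tuple[float, float]
    correction_factor: float
    doublet_rate: float
    capped: bool = False

    @property
    def percent(self) -> float:
        return round(self.doublet_rate * 100.0, 2)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_mixed": self.n_mixed,
            "species_proportions": list(self.species_proportions),
            "correction_factor": self.correction_factor,
            "doublet_rate": self.doublet_rate,
            "doublet_rate_percent": self.percent,
            "capped": self.capped,
        }


def estimate_doublet_rate(
    calls: SpeciesCallSet,
    species_proportions: tuple[float, float] = (0.5, 0.5),
) -> DoubletEstimate:
    """Estimate the total doublet rate from mixed-barcode counts.

    Only cross-species doublets are observable; with loading proportions
    (p, q) they are a fraction 2pq of all doublets, so

        doublet_rate = n_mixed / (2 p q) / n_classified

    (exactly twice the mixed fraction at a 1:1 mix).  The rate is capped at
    1 with a warning if the correction overshoots.
    """
    p, q = species_proportions
    if p < 0 or q < 0 or p * q == 0:
        raise ValueError(
            f"species proportions must be positive, got {species_proportions}"
        )
    n_total = len(calls)
    if n_total == 0:
        raise ValueError("cannot estimate a doublet rate from zero classified barcodes")
    n_mixed = calls.label_counts()["mixed"]
    correction = 1.0 / (2.0 * p * q)
    rate = n_mixed * correction / n_total
    capped = rate > 1.0
    if capped:
        warnings.warn(
            f"corrected doublet rate {rate:.3f} exceeds 1; capping at 1", stacklevel=2
        )
        rate = 1.0
    return DoubletEstimate(
        n_total=n_total,
        n_mixed=n_mixed,
        species_proportions=(p, q),
        correction_factor=correction,
        doublet_rate=rate,
        capped=capped,
    )


def write_species_calls(calls: SpeciesCallSet, path) -> None:
    """Species calls as TSV: barcode, n_human, n_murine, fraction_max, label."""
    calls.calls.to_csv(path, sep="\t", index=False)
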