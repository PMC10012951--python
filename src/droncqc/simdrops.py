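"""Synthetic droplet encapsulation, transcript sampling and read synthesis.

Emulates a DroNc-seq barnyard run: droplets load nuclei from two species
(default 1:1 human/murine) under Poisson-limiting dilution so that a
target fraction of droplets (default 5%) is occupied; each nucleus
contributes a log-normal number of polyadenylated molecules sampled
uniformly from its species' gene panel; each molecule is sequenced as one
or more reads carrying the droplet's bead barcode (with i.i.d. per-base
substitution errors), the molecule's UMI, the A/C/G anchor base and a
poly-T tail, 26 cycles in total.

Outputs are a droplet truth table (who was encapsulated where), a
tagged-read table with both the true and the observed barcode, and
optionally a gzip FASTQ pair.  Ambient RNA, bead-quality effects and
sequence-level cDNA errors in read 2 are deliberately not modelled.
"""

from __future__ import annotations

import gzip
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .barnyard import occupancy_to_lambda
from .readio import GENOMES, REGIONS

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ANCHORS = np.frombuffer(b"ACG", dtype=np.uint8)

#: default per-read region label probabilities for nuclei, in REGIONS order
#: (exonic, intronic, intergenic, mitochondrial)
DEFAULT_REGION_PROBS = (0.34, 0.37, 0.28, 0.01)


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one synthetic run.

    Defaults are the barnyard conditions this package simulates: 2x10^5
    droplets at 5% occupancy, a 1:1 human/murine nucleus mix, 12 nt
    barcodes and 8 nt UMIs, and a modest per-nucleus molecular complexity
    typical of droplet snRNA-seq nuclei.
    """

    n_droplets: int = 200_000
    occupancy: float = 0.05
    species_proportions: tuple[float, float] = (0.5, 0.5)
    n_genes_per_species: int = 1500
    molecules_per_nucleus_mean: float = 400.0
    molecules_per_nucleus_sigma: float = 0.3
    reads_per_molecule_mean: float = 1.2
    barcode_length: int = 12
    umi_length: int = 8
    barcode_error_rate: float = 0.005
    region_probs: tuple[float, float, float, float] = DEFAULT_REGION_PROBS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        if not 0.0 <= self.occupancy < 1.0:
            raise ValueError(
                f"occupancy must be in [0, 1), got {self.occupancy}"
            )
        p, q = self.species_proportions
        if p < 0 or q < 0 or abs(p + q - 1.0) > 1e-12:
            raise ValueError(
                f"species_proportions must be non-negative and sum to 1, got {(p, q)}"
            )
        if self.n_genes_per_species <= 0:
            raise ValueError("gene panel must be non-empty (n_genes_per_species >= 1)")
        if self.molecules_per_nucleus_mean <= 0:
            raise ValueError("molecules_per_nucleus_mean must be positive")
        if self.molecules_per_nucleus_sigma < 0:
            raise ValueError("molecules_per_nucleus_sigma must be non-negative")
        if self.reads_per_molecule_mean <= 0:
            raise ValueError("reads_per_molecule_mean must be positive")
        if self.barcode_length <= 0 or self.umi_length <= 0:
            raise ValueError("barcode_length and umi_length must be positive")
        if not 0.0 <= self.barcode_error_rate <= 1.0:
            raise ValueError("barcode_error_rate must be in [0, 1]")
        if len(self.region_probs) != len(REGIONS) or any(
            p < 0 for p in self.region_probs
        ) or abs(sum(self.region_probs) - 1.0) > 1e-9:
            raise ValueError(
                f"region_probs must be {len(REGIONS)} non-negative values summing to 1"
            )

    @property
    def poisson_lambda(self) -> float:
        """Per-droplet Poisson loading mean implied by the target occupancy."""
        return occupancy_to_lambda(self.occupancy)

    def to_yaml(self, path: str | Path) -> None:
        """Echo the parameters as a key-value config file."""
        payload = asdict(self)
        payload["species_proportions"] = list(self.species_proportions)
        payload["region_probs"] = list(self.region_probs)
        with open(path, "w") as handle:
            yaml.safe_dump(payload, handle, sort_keys=True)


def gene_panels(params: SimulationParams) -> tuple[list[str], list[str]]:
    """Disjoint gene identifier panels for the two species (human, murine)."""
    n = params.n_genes_per_species
    return (
        [f"HSA_G{i:05d}" for i in range(n)],
        [f"MMU_G{i:05d}" for i in range(n)],
    )


def _codes_to_strings(codes: np.ndarray) -> np.ndarray:
    """(n, L) base-code array (0..3) -> array of L-mer strings."""
    n, length = codes.shape
    as_bytes = _BASES[codes].view(f"S{length}").ravel()
    return as_bytes.astype(str)


def _unique_barcode_codes(
    rng: np.random.Generator, n: int, length: int
) -> np.ndarray:
    """Draw n distinct barcodes as (n, length) base-code rows."""
    space = 4**length
    if n > space:
        raise ValueError(f"cannot draw {n} unique barcodes of length {length}")
    picked = np.empty(0, dtype=np.int64)
    while picked.size < n:
        extra = rng.integers(0, space, size=int((n - picked.size) * 1.2) + 16)
        picked = np.unique(np.concatenate([picked, extra]))
    picked = rng.permutation(picked)[:n]
    codes = np.empty((n, length), dtype=np.uint8)
    for position in range(length - 1, -1, -1):
        codes[:, position] = picked % 4
        picked //= 4
    return codes


def simulate_encapsulation(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Load nuclei into droplets under Poisson(λ) with λ = −ln(1 − occupancy).

    Returns the droplet truth table: one row per droplet with its unique
    bead barcode, nucleus count, per-species nucleus counts (each nucleus'
    species drawn independently from ``species_proportions``), and the
    derived ``is_doublet`` (>= 2 nuclei) and ``is_cross_species`` (both
    species present) flags.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    lam = params.poisson_lambda
    counts = rng.poisson(lam, size=params.n_droplets)
    n_human = rng.binomial(counts, params.species_proportions[0])
    n_murine = counts - n_human
    barcodes = _codes_to_strings(
        _unique_barcode_codes(rng, params.n_droplets, params.barcode_length)
    )
    return pd.DataFrame(
        {
            "droplet_id": np.arange(params.n_droplets, dtype=np.int64),
            "barcode": barcodes,
            "nucleus_count": counts,
            "n_human": n_human,
            "n_murine": n_murine,
            "is_doublet": counts >= 2,
            "is_cross_species": (n_human >= 1) & (n_murine >= 1),
        }
    )


def synthesize_reads(
    droplets: pd.DataFrame,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
    fastq_prefix: str | Path | None = None,
) -> tuple[pd.DataFrame, tuple[Path, Path] | None]:
    """Sample molecules and reads for encapsulated nuclei.

    Per nucleus the molecule count is log-normal (location
    ``ln(molecules_per_nucleus_mean)``, scale
    ``molecules_per_nucleus_sigma``) rounded up to at least 1; each
    molecule draws a gene uniformly from its species' panel and a random
    UMI, and is sequenced ``max(1, Poisson(reads_per_molecule_mean))``
    times.  Substitution errors at ``barcode_error_rate`` per base are
    applied to the barcode segment of each read only.

    Returns the tagged-read table (columns ``droplet_id``, ``barcode`` =
    observed, ``true_barcode``, ``umi``, ``gene``, ``genome``, ``region``,
    ``anchor``) and, when ``fastq_prefix`` is given, the paths of the gzip
    FASTQ pair written via :func:`write_fastq`.
    """
    if len(droplets) == 0:
        raise ValueError("droplets table is empty")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))

    panels = gene_panels(params)
    all_genes = panels[0] + panels[1]
    n_genes = params.n_genes_per_species

    occupied = droplets[droplets["nucleus_count"] > 0]
    # one nucleus row per encapsulated nucleus, species code 0=human 1=murine
    droplet_idx = np.concatenate(
        [
            np.repeat(occupied.index.to_numpy(), occupied["n_human"].to_numpy()),
            np.repeat(occupied.index.to_numpy(), occupied["n_murine"].to_numpy()),
        ]
    )
    species_nuc = np.concatenate(
        [
            np.zeros(int(occupied["n_human"].sum()), dtype=np.int8),
            np.ones(int(occupied["n_murine"].sum()), dtype=np.int8),
        ]
    )
    order = rng.permutation(droplet_idx.size)  # decouple row order from species
    droplet_idx, species_nuc = droplet_idx[order], species_nuc[order]
    n_nuclei = droplet_idx.size

    empty = pd.DataFrame(
        {
            "droplet_id": pd.Series(dtype=np.int64),
            "barcode": pd.Series(dtype=str),
            "true_barcode": pd.Series(dtype=str),
            "umi": pd.Series(dtype=str),
            "gene": pd.Series(dtype="category"),
            "genome": pd.Series(dtype="category"),
            "region": pd.Series(dtype="category"),
            "anchor": pd.Series(dtype=str),
        }
    )
    if n_nuclei == 0:
        return (empty, None)

    mu = np.log(params.molecules_per_nucleus_mean)
    molecules = np.ceil(
        rng.lognormal(mu, params.molecules_per_nucleus_sigma, size=n_nuclei)
    ).astype(np.int64)
    molecules = np.maximum(molecules, 1)
    n_molecules = int(molecules.sum())

    nucleus_of_mol = np.repeat(np.arange(n_nuclei), molecules)
    gene_code = rng.integers(0, n_genes, size=n_molecules)
    gene_code = gene_code + species_nuc[nucleus_of_mol].astype(np.int64) * n_genes
    umi_codes = rng.integers(
        0, 4, size=(n_molecules, params.umi_length), dtype=np.uint8
    )

    reads_per_mol = np.maximum(
        1, rng.poisson(params.reads_per_molecule_mean, size=n_molecules)
    )
    mol_of_read = np.repeat(np.arange(n_molecules), reads_per_mol)
    n_reads = mol_of_read.size

    region_code = np.searchsorted(
        np.cumsum(params.region_probs), rng.random(n_reads), side="right"
    ).astype(np.int8)
    anchor_code = rng.integers(0, 3, size=n_reads, dtype=np.uint8)

    # observed barcodes: copy the true code rows, then substitute at error sites
    droplet_barcodes = droplets["barcode"].to_numpy()
    barcode_codes = _unique_barcode_codes_from_strings(
        droplet_barcodes, params.barcode_length
    )
    read_droplet = droplet_idx[nucleus_of_mol[mol_of_read]]
    obs_codes = barcode_codes[read_droplet].copy()
    if params.barcode_error_rate > 0:
        mask = (
            rng.random(obs_codes.shape, dtype=np.float32)
            < params.barcode_error_rate
        )
        n_errors = int(mask.sum())
        if n_errors:
            shift = rng.integers(1, 4, size=n_errors, dtype=np.uint8)
            obs_codes[mask] = (obs_codes[mask] + shift) % 4

    gene_cat = pd.Categorical.from_codes(gene_code[mol_of_read], categories=all_genes)
    genome_cat = pd.Categorical.from_codes(
        species_nuc[nucleus_of_mol[mol_of_read]], categories=list(GENOMES)
    )
    region_cat = pd.Categorical.from_codes(region_code, categories=list(REGIONS))
    # categorical storage: observed barcodes repeat heavily, UMIs live in a
    # 4^umi_length space, anchors in {A,C,G} — interning keeps memory flat
    obs_factor_codes, obs_uniques = pd.factorize(_codes_to_strings(obs_codes))
    umi_factor_codes, umi_uniques = pd.factorize(_codes_to_strings(umi_codes))
    reads = pd.DataFrame(
        {
            "droplet_id": droplets["droplet_id"].to_numpy()[read_droplet],
            "barcode": pd.Categorical.from_codes(
                obs_factor_codes, categories=obs_uniques
            ),
            "true_barcode": pd.Categorical.from_codes(
                read_droplet.astype(np.int64), categories=droplet_barcodes
            ),
            "umi": pd.Categorical.from_codes(
                umi_factor_codes[mol_of_read], categories=umi_uniques
            ),
            "gene": gene_cat,
            "genome": genome_cat,
            "region": region_cat,
            "anchor": pd.Categorical.from_codes(
                anchor_code.astype(np.int64), categories=["A", "C", "G"]
            ),
        }
    )

    fastq_paths = None
    if fastq_prefix is not None:
        fastq_paths = write_fastq(reads, fastq_prefix, read1_length=26)
    return reads, fastq_paths


def _unique_barcode_codes_from_strings(barcodes: np.ndarray, length: int) -> np.ndarray:
    """Inverse of :func:`_codes_to_strings` for fixed-length barcodes."""
    as_bytes = np.asarray(barcodes, dtype=f"S{length}")
    flat = as_bytes.view(np.uint8).reshape(len(barcodes), length)
    codes = np.empty_like(flat)
    for value, base in enumerate(b"ACGT"):
        codes[flat == base] = value
    return codes


def write_fastq(
    reads: pd.DataFrame, prefix: str | Path, read1_length: int = 26
) -> tuple[Path, Path]:
    """Write the tagged reads as a gzip FASTQ pair.

    Read 1 is ``observed barcode + UMI + anchor`` padded with poly-T to
    ``read1_length``; read 2 carries the gene identifier as a synthetic
    pre-aligned payload, with genome and region echoed in the title.
    Qualities are a constant Phred+33 'I' string.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    r1_path = prefix.with_name(prefix.name + "_R1.fastq.gz")
    r2_path = prefix.with_name(prefix.name + "_R2.fastq.gz")
    qual1 = "I" * read1_length
    with gzip.open(r1_path, "wt") as r1, gzip.open(r2_path, "wt") as r2:
        for i, row in enumerate(reads.itertuples(index=False)):
            stub = row.barcode + row.umi + row.anchor
            seq1 = stub + "T" * (read1_length - len(stub))
            gene = str(row.gene)
            r1.write(f"@r{i}/1\n{seq1}\n+\n{qual1}\n")
            r2.write(
                f"@r{i}/2 gene={gene} genome={row.genome} region={row.region}\n"
                f"{gene}\n+\n{'I' * len(gene)}\n"
            )
    return r1_path, r2_path


def write_truth(reads: pd.DataFrame, path: str | Path) -> None:
    """Write the error-free truth table as TSV.

    Columns: droplet_id, barcode (true bead barcode), umi, gene, species,
    region.
    """
    truth = pd.DataFrame(
        {
            "droplet_id": reads["droplet_id"],
            "barcode": reads["true_barcode"],
            "umi": reads["umi"],
            "gene": reads["gene"],
            "species": reads["genome"],
            "region": reads["region"],
        }
    )
    truth.to_csv(path, sep="\t", index=False)
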