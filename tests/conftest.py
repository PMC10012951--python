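import numpy as np
import pytest

from droncqc.simdrops import SimulationParams, simulate_encapsulation, synthesize_reads


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """A small barnyard run: ~200 occupied droplets, ~60k reads."""
    return SimulationParams(
        n_droplets=4000,
        occupancy=0.05,
        n_genes_per_species=400,
        molecules_per_nucleus_mean=300.0,
        molecules_per_nucleus_sigma=0.2,
        reads_per_molecule_mean=1.2,
        barcode_error_rate=0.005,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_run(small_params):
    """(droplets, reads) for the small barnyard run."""
    droplets = simulate_encapsulation(small_params)
    reads, _ = synthesize_reads(droplets, small_params)
    return droplets, reads


@pytest.fixture
def write_fastq_file(tmp_path):
    """Write 4-line FASTQ records [(title, seq), ...] to a file; returns the path."""

    def _write(name, records, gz=False):
        import gzip

        path = tmp_path / name
        opener = gzip.open if gz else open
        with opener(path, "wt") as handle:
            for title, seq in records:
                handle.write(f"@{title}\n{seq}\n+\n{'I' * len(seq)}\n")
        return path

    return _write


@pytest.fixture(scope="session")
def bruteforce_repair():
    """Independent all-pairs Hamming repair oracle (character-matrix scan).

    Returns raw -> entry or None, with the same nearest-unique-within-d
    rule as the library: whitelisted barcodes map to themselves, ties at
    the minimal qualifying distance are unassigned.
    """

    def _oracle(raw_barcodes, entries, max_distance):
        length = len(entries[0])
        raw_mat = np.array([list(b) for b in raw_barcodes])
        wl_mat = np.array([list(b) for b in entries])
        dist = (raw_mat[:, None, :] != wl_mat[None, :, :]).sum(axis=2)
        entry_set = set(entries)
        out = {}
        for i, raw in enumerate(raw_barcodes):
            if raw in entry_set:
                out[raw] = raw
                continue
            row = dist[i]
            best = row.min()
            if best > max_distance or (row == best).sum() > 1:
                out[raw] = None
            else:
                out[raw] = entries[int(row.argmin())]
        return out

    return _oracle


@pytest.fixture(scope="session")
def random_barcodes():
    """Factory: n distinct random DNA strings of the given length."""

    def _make(rng: np.random.Generator, n: int, length: int = 12):
        seen = set()
        while len(seen) < n:
            codes = rng.integers(0, 4, size=(n - len(seen), length))
            for row in codes:
                seen.add("".join("ACGT"[c] for c in row))
        return sorted(seen)[:n]

    return _make
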