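"""Candidate selection, whitelisting and Hamming barcode repair."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from droncqc.barcodes import (
    Whitelist,
    barcode_stats,
    build_whitelist,
    candidate_barcodes,
    hamming_distance,
    repair_barcodes,
)
from droncqc.simdrops import SimulationParams, simulate_encapsulation, synthesize_reads


@pytest.mark.parametrize(
    "a, b, expected",
    [("AAAA", "AAAA", 0), ("AAAA", "AAAT", 1), ("ACGT", "TGCA", 4)],
)
def test_hamming_examples(a, b, expected):
    assert hamming_distance(a, b) == expected


def test_hamming_rejects_unequal_lengths():
    with pytest.raises(ValueError):
        hamming_distance("AAA", "AAAA")


@settings(max_examples=100, derandomize=True)
@given(
    st.integers(1, 16).flatmap(
        lambda n: st.tuples(
            st.text("ACGT", min_size=n, max_size=n),
            st.text("ACGT", min_size=n, max_size=n),
        )
    )
)
def test_hamming_symmetry_and_identity(pair):
    a, b = pair
    assert hamming_distance(a, b) == hamming_distance(b, a)
    assert hamming_distance(a, a) == 0
    assert (hamming_distance(a, b) == 0) == (a == b)
    assert 0 <= hamming_distance(a, b) <= len(a)


def test_barcode_stats_tallies_reads_and_genes():
    reads = pd.DataFrame(
        {
            "barcode": ["b1"] * 4 + ["b2"] * 2,
            "gene": ["g1", "g1", "g2", "g3", "g1", "g1"],
        }
    )
    stats = barcode_stats(reads).set_index("barcode")
    assert stats.loc["b1", "n_reads"] == 4 and stats.loc["b1", "n_genes"] == 3
    assert stats.loc["b2", "n_reads"] == 2 and stats.loc["b2", "n_genes"] == 1
    # at min_reads_per_gene=2 only genes with 2+ reads count as detected
    stats2 = barcode_stats(reads, min_reads_per_gene=2).set_index("barcode")
    assert stats2.loc["b1", "n_genes"] == 1
    assert stats2.loc["b2", "n_genes"] == 1


def _stats(rows):
    return pd.DataFrame(rows, columns=["barcode", "n_reads", "n_genes"])


def test_candidate_floor_is_150_genes():
    stats = _stats([("bc_low", 999, 149), ("bc_at", 10, 150), ("bc_hi", 5, 151)])
    kept = candidate_barcodes(stats)["barcode"].tolist()
    assert "bc_low" not in kept  # 149 genes is below the floor
    assert kept == ["bc_hi", "bc_at"]


def test_candidate_ranking_modes_and_tiebreaks():
    stats = _stats(
        [("a", 10, 300), ("b", 99, 200), ("c", 50, 300), ("d", 50, 300)]
    )
    by_genes = candidate_barcodes(stats, mode="by_genes")["barcode"].tolist()
    assert by_genes == ["c", "d", "a", "b"]  # genes desc, reads desc, lexicographic
    by_reads = candidate_barcodes(stats, mode="by_reads")["barcode"].tolist()
    assert by_reads == ["b", "c", "d", "a"]
    with pytest.raises(ValueError):
        candidate_barcodes(stats, mode="by_vibes")


def test_whitelist_truncates_to_expected_nuclei(random_barcodes):
    rng = np.random.default_rng(0)
    barcodes = random_barcodes(rng, 500)
    stats = _stats([(b, 10, 200 + i) for i, b in enumerate(barcodes)])
    candidates = candidate_barcodes(stats)
    wl = build_whitelist(candidates, n_expected=250)
    assert len(wl) == 250
    assert wl.entries == candidates["barcode"].head(250).tolist()
    assert all(wl.repair_map[b] == b for b in wl.entries)

    short = build_whitelist(candidates.head(100), n_expected=250)
    assert len(short) == 100
    with pytest.raises(ValueError):
        build_whitelist(candidates, n_expected=0)


class TestRepair:
    def make_whitelist(self, entries):
        return Whitelist(entries=list(entries))

    def test_whitelisted_barcode_maps_to_itself(self):
        wl = self.make_whitelist(["AAAAAAAAAAAA", "CCCCCCCCCCCC"])
        wl, summary = repair_barcodes(["AAAAAAAAAAAA"], wl)
        assert wl.repair_map["AAAAAAAAAAAA"] == "AAAAAAAAAAAA"
        assert summary.n_exact == 1

    def test_unique_neighbour_within_two_is_assigned(self):
        wl = self.make_whitelist(["AAAAAAAAAAAA", "CCCCCCCCCCCC"])
        raw = "AAAAAAAAAAGG"  # distance 2 from the A entry, 12 from the C entry
        wl, summary = repair_barcodes([raw], wl)
        assert wl.repair_map[raw] == "AAAAAAAAAAAA"
        assert summary.n_repaired == 1

    def test_tie_at_minimal_distance_is_unassigned(self):
        wl = self.make_whitelist(["AAAAAAAAAAAA", "AAAAAAAAAAGG"])
        raw = "AAAAAAAAAAAG"  # distance 1 from both entries
        wl, summary = repair_barcodes([raw], wl)
        assert wl.repair_map[raw] is None
        assert summary.n_ambiguous == 1 and summary.n_unassigned == 1

    def test_beyond_max_distance_is_unassigned(self):
        wl = self.make_whitelist(["AAAAAAAAAAAA"])
        raw = "AAAAAAAAAGGG"  # distance 3
        wl, summary = repair_barcodes([raw], wl, max_distance=2)
        assert wl.repair_map[raw] is None
        wl2, _ = repair_barcodes([raw], self.make_whitelist(["AAAAAAAAAAAA"]),
                                 max_distance=3)
        assert wl2.repair_map[raw] == "AAAAAAAAAAAA"

    def test_h0_mode_keeps_only_exact_matches(self):
        wl = self.make_whitelist(["AAAAAAAAAAAA"])
        wl, summary = repair_barcodes(
            ["AAAAAAAAAAAA", "AAAAAAAAAAAT"], wl, max_distance=0
        )
        assert wl.repair_map["AAAAAAAAAAAT"] is None
        assert summary.n_exact == 1 and summary.n_unassigned == 1

    def test_length_mismatch_rejected(self):
        wl = self.make_whitelist(["AAAAAAAAAAAA"])
        with pytest.raises(ValueError):
            repair_barcodes(["AAAA"], wl)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle(self, seed, bruteforce_repair, random_barcodes):
        rng = np.random.default_rng(seed)
        n_wl = int(rng.integers(5, 120))
        n_raw = int(rng.integers(50, 600))
        pool = random_barcodes(rng, n_wl + n_raw, length=12)
        entries = pool[:n_wl]
        # raw mix: mutated entries (0-3 substitutions) and unrelated barcodes
        raw = []
        for _ in range(n_raw):
            if rng.random() < 0.7:
                base = list(entries[rng.integers(0, n_wl)])
                for pos in rng.choice(12, size=rng.integers(0, 4), replace=False):
                    base[pos] = "ACGT"[rng.integers(0, 4)]
                raw.append("".join(base))
            else:
                raw.append(pool[n_wl + rng.integers(0, n_raw)])
        expected = bruteforce_repair(raw, entries, max_distance=2)
        wl, _ = repair_barcodes(raw, Whitelist(entries=list(entries)), max_distance=2)
        assert {r: wl.repair_map[r] for r in raw} == expected

    def test_never_reassigns_whitelisted_and_respects_distance(
        self, bruteforce_repair, random_barcodes
    ):
        rng = np.random.default_rng(42)
        entries = random_barcodes(rng, 80)
        raw = entries[:10] + [
            "".join(rng.choice(list("ACGT"), 12)) for _ in range(200)
        ]
        wl, _ = repair_barcodes(raw, Whitelist(entries=entries), max_distance=2)
        for barcode in entries[:10]:
            assert wl.repair_map[barcode] == barcode
        for barcode in raw:
            assigned = wl.repair_map[barcode]
            if assigned is not None:
                assert hamming_distance(barcode, assigned) <= 2


def test_error_reads_repair_back_to_truth_for_separated_beads():
    # a bead barcode at distance >= 5 from every other whitelist entry is
    # the unique nearest entry for any of its reads with <= 2 substitutions
    params = SimulationParams(
        n_droplets=500,
        occupancy=0.15,
        n_genes_per_species=100,
        molecules_per_nucleus_mean=80.0,
        molecules_per_nucleus_sigma=0.2,
        reads_per_molecule_mean=1.2,
        barcode_error_rate=0.02,
        seed=13,
    )
    droplets = simulate_encapsulation(params)
    reads, _ = synthesize_reads(droplets, params)
    truth_barcodes = sorted(set(reads["true_barcode"].astype(str)))
    separated = {
        barcode
        for barcode in truth_barcodes
        if min(
            hamming_distance(barcode, other)
            for other in truth_barcodes
            if other != barcode
        )
        >= 5
    }
    assert len(separated) >= len(truth_barcodes) // 2  # random 12-mers: most qualify

    wl, _ = repair_barcodes(
        reads["barcode"].astype(str), Whitelist(entries=truth_barcodes)
    )
    obs = reads["barcode"].astype(str).to_numpy()
    true = reads["true_barcode"].astype(str).to_numpy()
    n_errors = np.array([hamming_distance(o, t) for o, t in zip(obs, true)])
    check = (n_errors <= 2) & np.isin(true, sorted(separated))
    assigned = np.array([wl.repair_map[o] for o in obs], dtype=object)
    assert check.any() and (n_errors[check] > 0).any()
    assert (assigned[check] == true[check]).all()
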