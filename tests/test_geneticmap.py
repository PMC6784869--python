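import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grasskit.geneticmap import (
    ContigConflictError,
    SnpBin,
    UndefinedRecombinationError,
    build_pseudomolecules,
    correct_crossovers,
    count_crossovers,
    estimate_rf,
    filter_snps,
    group_markers,
    kosambi,
    make_bins,
    merge_bins,
    order_markers,
    rf_matrix,
)

A, H, B, M = 0, 1, 2, -1


def _bin(bin_id, genotypes, contig="c1", start=0, end=0, n_snps=1):
    return SnpBin(bin_id, contig, start, end, n_snps, np.array(genotypes, dtype=np.int8))


class TestFilterSnps:
    @pytest.mark.parametrize(
        "depth, maf, kept",
        [(1, 0.3, False), (10, 0.05, False), (2, 0.1, True), (5, 0.4, True)],
    )
    def test_depth_and_maf_thresholds_inclusive(self, depth, maf, kept):
        calls = pd.DataFrame({"depth": [depth], "maf": [maf]})
        assert (len(filter_snps(calls)) == 1) is kept


class TestMakeBins:
    def _markers(self, n, contig="c1"):
        return pd.DataFrame(
            {"marker": [f"m{i}" for i in range(n)], "contig": contig,
             "pos": np.arange(1, n + 1) * 100}
        )

    def test_120_snps_give_bins_of_50_50_20(self):
        geno = np.zeros((120, 4), dtype=np.int8)
        bins = make_bins(self._markers(120), geno)
        assert [b.n_snps for b in bins] == [50, 50, 20]

    def test_50_snps_one_bin(self):
        geno = np.zeros((50, 4), dtype=np.int8)
        assert len(make_bins(self._markers(50), geno)) == 1

    def test_consensus_majority_and_tie_rules(self):
        # 30 A + 20 B = 60% agreement -> A; 25 A + 25 B -> tie -> missing
        geno = np.zeros((50, 2), dtype=np.int8)
        geno[30:, 0] = B
        geno[:25, 1] = A
        geno[25:, 1] = B
        bins = make_bins(self._markers(50), geno)
        assert bins[0].genotypes[0] == A
        assert bins[0].genotypes[1] == M

    def test_unsorted_positions_rejected(self):
        markers = self._markers(10)
        markers.loc[5, "pos"] = 1
        with pytest.raises(ValueError):
            make_bins(markers, np.zeros((10, 2), dtype=np.int8))


def brute_force_rf(g_i, g_j):
    """Oracle: explicit loop over individuals with per-pair event counting."""
    events = informative = 0
    for a, b in zip(g_i, g_j):
        if a < 0 or b < 0:
            continue
        informative += 1
        if {a, b} == {A, B}:
            events += 2
        elif a != b:
            events += 1
    return min(events / (2 * informative), 0.499)


class TestEstimateRf:
    def test_no_transitions_zero(self):
        g = np.array([A] * 50 + [B] * 50, dtype=np.int8)
        assert estimate_rf(g, g) == 0.0

    def test_single_a_to_h_event(self):
        g1 = np.array([A] * 10, dtype=np.int8)
        g2 = g1.copy()
        g2[0] = H
        assert estimate_rf(g1, g2) == pytest.approx(0.05)

    def test_a_to_b_counts_two_events(self):
        g1 = np.array([A] * 10, dtype=np.int8)
        g2 = g1.copy()
        g2[0] = B
        assert estimate_rf(g1, g2) == pytest.approx(0.10)

    def test_all_missing_raises(self):
        g = np.full(5, M, dtype=np.int8)
        with pytest.raises(UndefinedRecombinationError):
            estimate_rf(g, g)

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        g1 = rng.choice([A, H, B, M], size=30, p=[0.3, 0.35, 0.3, 0.05]).astype(np.int8)
        g2 = rng.choice([A, H, B, M], size=30, p=[0.3, 0.35, 0.3, 0.05]).astype(np.int8)
        if np.all((g1 < 0) | (g2 < 0)):
            return
        assert estimate_rf(g1, g2) == pytest.approx(brute_force_rf(g1, g2))

    def test_rf_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(4)
        bins = [
            _bin(f"b{i}", rng.choice([A, H, B, M], size=40, p=[0.3, 0.3, 0.3, 0.1]))
            for i in range(6)
        ]
        mat = rf_matrix(bins)
        for i in range(6):
            for j in range(i + 1, 6):
                assert mat[i, j] == pytest.approx(
                    brute_force_rf(bins[i].genotypes, bins[j].genotypes)
                )


class TestGrouping:
    def test_two_distant_clusters_two_groups(self):
        rf = np.full((6, 6), 0.47)
        rf[:3, :3] = 0.05
        rf[3:, 3:] = 0.05
        np.fill_diagonal(rf, 0.0)
        assert len(group_markers(rf)) == 2

    def test_tightly_linked_single_group(self):
        rf = np.full((5, 5), 0.1)
        np.fill_diagonal(rf, 0.0)
        assert len(group_markers(rf)) == 1


class TestOrdering:
    def test_three_bins_additive_order(self):
        rf = np.array([[0.0, 0.05, 0.10], [0.05, 0.0, 0.05], [0.10, 0.05, 0.0]])
        order = order_markers([0, 1, 2], rf)
        assert order in ([0, 1, 2], [2, 1, 0])

    def test_two_bins_deterministic(self):
        rf = np.array([[0.0, 0.2], [0.2, 0.0]])
        assert order_markers([0, 1], rf) in ([0, 1], [1, 0])


class TestCorrectCrossovers:
    def test_short_double_crossover_set_missing(self):
        geno = np.array([[A], [A], [B], [A], [A]], dtype=np.int8)
        pos = [0.0, 1e6, 2e6, 3e6, 4e6]  # B segment crossovers 1 Mb apart < min? no
        corrected, log = correct_crossovers(geno, pos, min_cross_distance=2.5e6)
        assert corrected[2, 0] == M
        assert count_crossovers(corrected)[0] == 0
        assert len(log) == 1

    def test_single_clean_crossover_untouched(self):
        geno = np.array([[A], [A], [B], [B], [B]], dtype=np.int8)
        pos = [0.0, 2e6, 4e6, 6e6, 8e6]
        corrected, log = correct_crossovers(geno, pos)
        assert np.array_equal(corrected, geno)
        assert len(log) == 0

    def test_event_cap_enforced(self):
        codes = [A, B] * 6  # 12 alternating single-bin segments, 11 crossovers
        geno = np.array(codes, dtype=np.int8).reshape(-1, 1)
        pos = list(np.arange(12) * 5e6)
        corrected, _ = correct_crossovers(geno, pos, min_cross_distance=1e6,
                                          max_events=10)
        assert count_crossovers(corrected)[0] <= 10

    @given(st.integers(0, 5000))
    @settings(max_examples=60, deadline=None)
    def test_never_adds_crossovers_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        geno = rng.choice([A, H, B, M], size=(20, 3), p=[0.3, 0.3, 0.3, 0.1]).astype(np.int8)
        pos = np.sort(rng.uniform(0, 4e7, size=20))
        before = count_crossovers(geno)
        once, _ = correct_crossovers(geno, pos)
        twice, log2 = correct_crossovers(once, pos)
        assert np.all(count_crossovers(once) <= before)
        assert np.array_equal(once, twice)
        assert len(log2) == 0


class TestMergeBins:
    def _pair(self, gap, g1, g2):
        b1 = _bin("b1", g1, start=1_000, end=2_000)
        b2 = _bin("b2", g2, start=2_000 + gap, end=3_000 + gap)
        return [b1, b2]

    def test_identical_within_gap_merged(self):
        out = merge_bins(self._pair(50_000, [A, H], [A, H]))
        assert len(out) == 1 and out[0].n_snps == 2

    def test_identical_beyond_gap_not_merged(self):
        out = merge_bins(self._pair(150_000, [A, H], [A, H]))
        assert len(out) == 2

    def test_conflicting_genotype_not_merged(self):
        out = merge_bins(self._pair(50_000, [A, H], [B, H]))
        assert len(out) == 2

    def test_missing_matches_anything_and_fills(self):
        out = merge_bins(self._pair(50_000, [A, M], [M, H]))
        assert len(out) == 1
        assert list(out[0].genotypes) == [A, H]


class TestKosambi:
    @pytest.mark.parametrize("r, cm", [(0.0, 0.0), (0.1, 10.14), (0.4, 54.93)])
    def test_closed_form_values(self, r, cm):
        assert kosambi(r) == pytest.approx(cm, abs=0.005)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            kosambi(0.5)

    @given(st.floats(min_value=0.0, max_value=0.499))
    @settings(max_examples=200)
    def test_map_expansion_bound(self, r):
        assert kosambi(r) >= 100 * r - 1e-9

    @given(st.floats(0.0, 0.498), st.floats(1e-4, 1e-3))
    @settings(max_examples=200)
    def test_strictly_increasing(self, r, dr):
        assert kosambi(min(r + dr, 0.499)) > kosambi(r)


class TestPseudomolecules:
    def _anchored(self, rows):
        return pd.DataFrame(rows, columns=["contig", "group", "pos", "cM"])

    def test_three_contigs_ordered_with_100n_gaps(self):
        contigs = {"c1": "AAAA", "c2": "CCCC", "c3": "GGGG"}
        anchored = self._anchored(
            [("c2", "LG1", 1, 0.0), ("c1", "LG1", 1, 10.0), ("c3", "LG1", 1, 20.0)]
        )
        builds = build_pseudomolecules(contigs, anchored)
        assert len(builds) == 1
        seq = builds[0].sequence
        assert seq == "CCCC" + "N" * 100 + "AAAA" + "N" * 100 + "GGGG"
        assert len(seq) == 12 + 200  # length identity

    def test_single_contig_no_gap(self):
        builds = build_pseudomolecules(
            {"c1": "ACGT"}, self._anchored([("c1", "LG1", 1, 0.0)])
        )
        assert builds[0].sequence == "ACGT"

    def test_orientation_from_cm_position_correlation(self):
        anchored = self._anchored(
            [("c1", "LG1", 100, 30.0), ("c1", "LG1", 200, 20.0), ("c1", "LG1", 300, 10.0)]
        )
        builds = build_pseudomolecules({"c1": "AACG"}, anchored)
        assert builds[0].placements.iloc[0]["strand"] == "-"
        assert builds[0].sequence == "CGTT"  # reverse complement

    def test_conflicting_groups_raise(self):
        anchored = self._anchored(
            [("c1", "LG1", 1, 0.0), ("c1", "LG2", 1, 0.0)]
        )
        with pytest.raises(ContigConflictError):
            build_pseudomolecules({"c1": "ACGT"}, anchored)

    def test_unanchored_reported(self):
        builds = build_pseudomolecules(
            {"c1": "ACGT", "orphan": "TTTT"},
            self._anchored([("c1", "LG1", 1, 0.0)]),
        )
        assert builds[0].unanchored == ["orphan"]
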