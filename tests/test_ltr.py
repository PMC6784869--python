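import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grasskit.ltr import (
    LTRElement,
    SaturationError,
    age_histogram,
    date_elements,
    find_intact_ltr,
    find_solo_ltr,
    insertion_age,
    k2p_distance,
    k2p_from_counts,
    solo_intact_ratio,
)
from grasskit.simulate import (
    LtrFamilySpec,
    SimConfig,
    SsrSpec,
    codes_to_str,
    k2p_mutate,
    simulate_genome,
)


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestK2P:
    def test_identical_sequences_zero(self):
        est = k2p_distance("ACGTACGT", "ACGTACGT", aligned=True)
        assert est.p == est.q == est.k == 0.0

    @pytest.mark.parametrize(
        "ts, tv, expected",
        [(10, 5, 0.1702), (0, 5, 0.0520)],
    )
    def test_closed_form_100_sites(self, ts, tv, expected):
        assert k2p_from_counts(100, ts, tv) == pytest.approx(expected, abs=5e-5)

    def test_transitions_and_transversions_separated(self):
        # A->G transition, A->T transversion
        est = k2p_distance("AAAAAAAAAA", "GAAAAAAAAT", aligned=True)
        assert est.p == pytest.approx(0.1)
        assert est.q == pytest.approx(0.1)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_from_counts(100, 50, 10)

    @given(st.integers(0, 30), st.integers(0, 20))
    @settings(max_examples=200)
    def test_k2p_at_least_p_distance(self, ts, tv):
        # multiple-hit correction can only inflate the observed distance
        n = 100
        try:
            k = k2p_from_counts(n, ts, tv)
        except SaturationError:
            return
        assert k >= (ts + tv) / n - 1e-12
        if ts + tv == 0:
            assert k == 0.0

    def test_round_trip_bias_small(self):
        # simulate pairs at known K over 1 kb; estimator bias < 2%
        rng = np.random.default_rng(42)
        for k_true in (0.05, 0.2):
            est = []
            for _ in range(500):
                anc = rng.integers(0, 4, 1000).astype(np.int8)
                a = k2p_mutate(anc, k_true / 2, rng)
                b = k2p_mutate(anc, k_true / 2, rng)
                est.append(
                    k2p_distance(codes_to_str(a), codes_to_str(b), aligned=True).k
                )
            assert abs(np.mean(est) - k_true) / k_true < 0.02


class TestAgeArithmetic:
    @pytest.mark.parametrize(
        "k, years", [(0.0, 0.0), (0.026, 1.0e6), (0.0052, 2.0e5)]
    )
    def test_insertion_age(self, k, years):
        assert insertion_age(k) == pytest.approx(years, rel=1e-9)

    @pytest.mark.parametrize(
        "solo, intact, ratio",
        [(121792, 48370, 2.5), (44349, 35559, 1.2), (0, 10, 0.0)],
    )
    def test_solo_intact_ratio(self, solo, intact, ratio):
        assert solo_intact_ratio(solo, intact) == ratio

    def test_zero_intact_raises(self):
        with pytest.raises(ZeroDivisionError):
            solo_intact_ratio(5, 0)


class TestAgeHistogram:
    def test_family_burst_modes_separate(self):
        rng = np.random.default_rng(0)
        from grasskit.ltr import DivergenceEstimate

        ests = []
        for fam, mean in (("Gypsy", 1.2e6), ("Copia", 0.6e6)):
            for age in rng.normal(mean, 2e5, 500):
                ests.append(
                    DivergenceEstimate("x", 400, 0, 0, 0, max(age, 0.0), 1.3e-8, fam)
                )
        hist = age_histogram(ests)
        gypsy_mode = hist[(hist["family"] == "Gypsy") & hist["is_mode"]].iloc[0]
        copia_mode = hist[(hist["family"] == "Copia") & hist["is_mode"]].iloc[0]
        assert gypsy_mode["bin_start_years"] >= 1.0e6
        assert copia_mode["bin_end_years"] <= 1.0e6

    def test_empty_input(self):
        assert len(age_histogram([])) == 0

    def test_all_equal_ages_single_bin(self):
        from grasskit.ltr import DivergenceEstimate

        ests = [DivergenceEstimate("x", 1, 0, 0, 0, 1.1e6, 1.3e-8, "Gypsy")] * 7
        hist = age_histogram(ests)
        assert (hist["count"] > 0).sum() == 1
        assert hist.loc[hist["count"] > 0, "count"].iloc[0] == 7


class TestIntactDetection:
    def test_zero_mutation_elements_recovered_exactly(self):
        cfg = SimConfig(
            seed=1, genome_length=400_000, n_chromosomes=2, n_genes=10,
            ltr_spec=[LtrFamilySpec("Gypsy", 10, 0, age_mean_years=0.0,
                                    age_sd_years=0.0)],
        )
        g = simulate_genome(cfg)
        els = find_intact_ltr(g.sequences, family_library=g.truth.ltr_library)
        truth = {
            (e["chrom"], tuple(e["ltr5"]), tuple(e["ltr3"]))
            for e in g.truth.elements
            if e["kind"] == "intact"
        }
        found = {(e.chrom, e.ltr5, e.ltr3) for e in els}
        assert found == truth  # 10/10 with exact coordinates
        assert all(e.family == "Gypsy" for e in els)

    def test_repeat_free_genome_empty(self):
        rng = np.random.default_rng(3)
        assert find_intact_ltr({"chr1": _random_seq(rng, 40_000)}) == []

    def test_highly_diverged_copies_not_reported(self):
        # copies at 20% divergence fall below the 85% identity floor
        rng = np.random.default_rng(4)
        ltr = list(_random_seq(rng, 400))
        other = list(ltr)
        for i in range(0, 400, 5):  # every 5th base differs: identity 0.80
            other[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[i]]
        genome = {
            "chr1": _random_seq(rng, 5000)
            + "".join(ltr)
            + _random_seq(rng, 3000)
            + "".join(other)
            + _random_seq(rng, 5000)
        }
        assert find_intact_ltr(genome) == []


class TestSoloDetection:
    def _library(self, rng):
        return {"Gypsy_1": _random_seq(rng, 400)}

    def test_planted_solo_at_90_percent_identity_reported(self):
        rng = np.random.default_rng(5)
        lib = self._library(rng)
        solo = list(lib["Gypsy_1"])
        for i in rng.choice(400, size=40, replace=False):  # 10% divergence
            solo[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[solo[i]]
        genome = {"chr1": _random_seq(rng, 3000) + "".join(solo) + _random_seq(rng, 3000)}
        out = find_solo_ltr(genome, lib, [])
        assert len(out) == 1
        assert out[0].family == "Gypsy"
        assert abs(out[0].ltr5[0] - 3000) < 10

    def test_identity_exactly_85_percent_excluded(self):
        # the threshold is strict: similar means identity > 85%, not >=
        rng = np.random.default_rng(6)
        lib = self._library(rng)
        solo = list(lib["Gypsy_1"])
        # 60 well-spaced substitutions of 400 -> edit distance exactly 60,
        # identity exactly 0.85
        for i in np.arange(60) * 6 + rng.integers(0, 3, size=60):
            solo[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[solo[i]]
        genome = {"chr1": _random_seq(rng, 3000) + "".join(solo) + _random_seq(rng, 3000)}
        assert find_solo_ltr(genome, lib, []) == []

    def test_ltr_of_intact_element_excluded(self):
        rng = np.random.default_rng(7)
        lib = self._library(rng)
        ltr = lib["Gypsy_1"]
        genome = {
            "chr1": _random_seq(rng, 2000) + ltr + _random_seq(rng, 3000) + ltr
            + _random_seq(rng, 2000)
        }
        intact = [
            LTRElement("i1", "Gypsy", "intact", "chr1", (2000, 2400),
                       (5400, 5800), (2400, 5400))
        ]
        assert find_solo_ltr(genome, lib, intact) == []
        # without the exclusion the same copies ARE matched
        assert len(find_solo_ltr(genome, lib, [])) == 2

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            find_solo_ltr({"chr1": "ACGT"}, {}, [])


class TestMixedGenomeRecovery:
    def test_disjointness_and_recovery(self, default_genome):
        cfg, g = default_genome
        intact = find_intact_ltr(g.sequences, family_library=g.truth.ltr_library,
                                 require_tsd=True)
        solos = find_solo_ltr(g.sequences, g.truth.ltr_library, intact)
        # solo output never overlaps intact output
        for s in solos:
            for e in intact:
                if s.chrom != e.chrom:
                    continue
                assert not (s.ltr5[0] < e.span[1] and e.span[0] < s.ltr5[1])
        # recovery of the planted complement
        tr_intact = [e for e in g.truth.elements if e["kind"] == "intact"]
        hit = sum(
            1 for e in tr_intact
            if any(x.chrom == e["chrom"] and abs(x.ltr5[0] - e["ltr5"][0]) < 30
                   for x in intact)
        )
        assert hit >= 0.9 * len(tr_intact)
        tr_solo = [e for e in g.truth.elements if e["kind"] == "solo"]
        hit_solo = sum(
            1 for e in tr_solo
            if any(x.chrom == e["chrom"] and abs(x.ltr5[0] - e["start"]) < 30
                   for x in solos)
        )
        assert hit_solo >= 0.8 * len(tr_solo)


class TestDating:
    def test_dating_planted_elements_from_truth_coordinates(self):
        cfg = SimConfig(
            seed=50, genome_length=1_500_000, n_chromosomes=1, n_genes=0,
            ssr_spec=SsrSpec(counts={}),
            ltr_spec=[LtrFamilySpec("Gypsy", 40, 0, 1.0e6, 0.0,
                                    ltr_length=1000, internal_length=2500)],
        )
        g = simulate_genome(cfg)
        els = [
            LTRElement(e["id"], e["family"], "intact", e["chrom"],
                       tuple(e["ltr5"]), tuple(e["ltr3"]))
            for e in g.truth.elements
        ]
        ests = date_elements(g.sequences, els)
        assert len(ests) == 40
        mean_age = np.mean([e.age_years for e in ests])
        assert mean_age == pytest.approx(1.0e6, rel=0.1)
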