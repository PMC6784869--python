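import numpy as np
import pytest
from scipy.stats import chisquare

from grasskit.ltr import k2p_distance
from grasskit.simulate import (
    BacSpec,
    F2Spec,
    LtrFamilySpec,
    OrthoSpec,
    PlacementError,
    SimConfig,
    SsrSpec,
    codes_to_str,
    simulate_bac_pools,
    simulate_f2,
    simulate_genome,
    simulate_ortholog_tables,
    simulate_population,
)


class TestGenomeGenerator:
    def test_seed_determinism_byte_identical(self):
        cfg = SimConfig(seed=99, genome_length=400_000, n_chromosomes=2, n_genes=5)
        a = simulate_genome(cfg)
        b = simulate_genome(cfg)
        assert a.sequences == b.sequences
        assert a.annotation.equals(b.annotation)

    def test_empty_feature_config_gives_plain_background(self):
        cfg = SimConfig(
            seed=1, genome_length=50_000, n_chromosomes=1, n_genes=0,
            ltr_spec=[], ssr_spec=SsrSpec(counts={}),
        )
        g = simulate_genome(cfg)
        assert len(g.annotation) == 0
        assert g.truth.elements == [] and g.truth.genes == [] and g.truth.ssrs == []
        assert len(g.sequences["chr1"]) == 50_000

    def test_infeasible_packing_raises(self):
        cfg = SimConfig(
            seed=1, genome_length=20_000, n_chromosomes=1, n_genes=0,
            ltr_spec=[LtrFamilySpec("Gypsy", 10, 0, 1e6, 0.0)],
            ssr_spec=SsrSpec(counts={}),
        )
        with pytest.raises(PlacementError):
            simulate_genome(cfg)

    def test_ltr_divergence_matches_molecular_clock(self):
        # 10 intact elements at exactly 1 Myr and rate 1.3e-8 diverge by
        # K = 2 r T = 0.026 in expectation; check within 3 SE of the
        # per-site binomial sampling error
        cfg = SimConfig(
            seed=7, genome_length=300_000, n_chromosomes=1, n_genes=0,
            ssr_spec=SsrSpec(counts={}),
            ltr_spec=[LtrFamilySpec("Gypsy", 10, 0, 1.0e6, 0.0, ltr_length=400)],
        )
        g = simulate_genome(cfg)
        ks = []
        length = 400
        for el in g.truth.elements:
            seq = g.sequences[el["chrom"]]
            a = seq[el["ltr5"][0] : el["ltr5"][1]]
            b = seq[el["ltr3"][0] : el["ltr3"][1]]
            ks.append(k2p_distance(a, b, aligned=True).k)
        expected = 2 * 1.3e-8 * 1.0e6
        se = np.sqrt(expected * (1 - expected) / length / len(ks))
        assert abs(np.mean(ks) - expected) < 3 * se

    def test_annotation_matches_truth_coordinates(self):
        cfg = SimConfig(seed=5, genome_length=200_000, n_chromosomes=1, n_genes=10)
        g = simulate_genome(cfg)
        intact = [e for e in g.truth.elements if e["kind"] == "intact"]
        ann = g.annotation[g.annotation["type"] == "LTR_retrotransposon"]
        assert len(ann) == len(intact)
        for e in intact:
            row = ann[ann["id"] == e["id"]].iloc[0]
            assert row["start"] == e["ltr5"][0] + 1  # GFF-style 1-based
            assert row["end"] == e["ltr3"][1]


class TestBacPools:
    def test_reads_in_exactly_one_row_and_column_pool(self, repeat_free_config):
        cfg = repeat_free_config(2)
        cfg.bac_spec = BacSpec(n_bacs=4, pool_rows=2, pool_cols=2,
                               insert_length=(15_000, 20_000), reads_per_bac=10)
        sim = simulate_bac_pools(cfg, simulate_genome(cfg))
        rows, cols = set(sim.layout.rows), set(sim.layout.cols)
        for rid in sim.reads:
            in_rows = [p for p in rows if rid in sim.pool_reads[p]]
            in_cols = [p for p in cols if rid in sim.pool_reads[p]]
            assert len(in_rows) == 1 and len(in_cols) == 1

    def test_error_free_reads_are_exact_substrings(self, repeat_free_config):
        cfg = repeat_free_config(3)
        cfg.bac_spec = BacSpec(n_bacs=4, pool_rows=2, pool_cols=2,
                               insert_length=(15_000, 20_000), reads_per_bac=10,
                               read_error_rate=0.0)
        sim = simulate_bac_pools(cfg, simulate_genome(cfg))
        contigs = {}
        for pool in sim.pool_contigs.values():
            contigs.update(pool)
        for rid, read in sim.reads.items():
            bac = sim.truth.read_to_bac[rid]
            assert read in contigs[f"{bac}_ctg"]

    def test_shared_segment_reads_recorded_ambiguous(self, repeat_free_config):
        cfg = repeat_free_config(4)
        cfg.bac_spec = BacSpec(n_bacs=6, pool_rows=2, pool_cols=3,
                               insert_length=(15_000, 20_000), reads_per_bac=40,
                               shared_segment_bp=5_000)
        sim = simulate_bac_pools(cfg, simulate_genome(cfg))
        assert sim.truth.shared_segment is not None
        assert len(sim.truth.ambiguous_reads) > 0
        donors = {sim.truth.shared_segment["donor"], sim.truth.shared_segment["acceptor"]}
        for rid in sim.truth.ambiguous_reads:
            assert sim.truth.read_to_bac[rid] in donors

    def test_grid_too_small_raises(self, repeat_free_config):
        cfg = repeat_free_config(5)
        cfg.bac_spec = BacSpec(n_bacs=5, pool_rows=2, pool_cols=2)
        with pytest.raises(ValueError):
            simulate_bac_pools(cfg, simulate_genome(cfg))


class TestF2:
    def test_seed_determinism(self):
        cfg = SimConfig(seed=8, genome_length=10_000_000, n_chromosomes=2,
                        emit_sequence=False,
                        f2_spec=F2Spec(n_individuals=20, n_markers=40))
        g = simulate_genome(cfg)
        a = simulate_f2(cfg, g)
        b = simulate_f2(cfg, g)
        assert np.array_equal(a.genotypes, b.genotypes)

    def test_clean_genotypes_reconstruct_from_crossover_truth(self):
        # independent reconstruction: genotype = sum over the two gametes of
        # (start phase + crossovers left of the marker) mod 2
        cfg = SimConfig(seed=9, genome_length=50_000_000, n_chromosomes=2,
                        emit_sequence=False,
                        f2_spec=F2Spec(n_individuals=30, n_markers=60,
                                       genotype_error_rate=0.0, missing_rate=0.0))
        g = simulate_genome(cfg)
        sim = simulate_f2(cfg, g)
        markers = sim.truth.markers
        for i, ind in enumerate(sim.individuals):
            expected = []
            for _, m in markers.iterrows():
                total = 0
                for gamete in range(2):
                    breaks = sim.truth.crossovers[ind][m["chrom"]][gamete]
                    phase = sim.truth.phases[ind][m["chrom"]][gamete]
                    n_left = sum(1 for b in breaks if b <= m["pos"])
                    total += (phase + n_left) % 2
                expected.append(total)
            assert np.array_equal(sim.genotypes[:, i], np.array(expected))

    def test_mendelian_segregation_1_2_1(self):
        cfg = SimConfig(seed=10, genome_length=10_000_000, n_chromosomes=1,
                        emit_sequence=False,
                        f2_spec=F2Spec(n_individuals=2000, n_markers=20,
                                       genotype_error_rate=0.0, missing_rate=0.0))
        g = simulate_genome(cfg)
        sim = simulate_f2(cfg, g)
        for r in range(sim.genotypes.shape[0]):
            counts = np.bincount(sim.genotypes[r], minlength=3)
            p = chisquare(counts, f_exp=np.array([0.25, 0.5, 0.25]) * 2000).pvalue
            assert p > 0.001


class TestPopulation:
    def test_study_group_sizes_give_147_accessions(self):
        sim = simulate_population(SimConfig(seed=1))
        assert len(sim.accessions) == 147
        assert [sim.groups.count(g) for g in (0, 1, 2)] == [30, 64, 53]

    def test_no_sweep_gives_ratio_near_one(self):
        from grasskit.popgen import window_stats

        cfg = SimConfig(seed=6)
        cfg.pop_spec.sweep_reduction = 1.0
        sim = simulate_population(cfg)
        stats = window_stats(sim.genotypes, sim.positions, sim.groups,
                             cfg.pop_spec.chrom_length)
        pivot = stats.pivot_table(index="start", columns="group", values="pi")
        ratios = pivot[0] / pivot[1]
        assert 0.8 < ratios.median() < 1.25

    def test_sweep_window_diversity_reduced(self):
        cfg = SimConfig(seed=2)
        sim = simulate_population(cfg)
        lo, hi = sim.truth.sweep_window
        inside = (sim.positions >= lo) & (sim.positions < hi)
        freqs = sim.truth.group_freqs
        het = 2 * freqs * (1 - freqs)
        reduction = het[1, ~inside].mean() / max(het[1, inside].mean(), 1e-12)
        assert reduction > 5  # configured 10x, within sampling wobble

    def test_invalid_window_raises(self):
        cfg = SimConfig(seed=1)
        cfg.pop_spec.sweep_window = (9_000_000, 11_000_000)
        with pytest.raises(ValueError):
            simulate_population(cfg)


class TestOrthologTables:
    def test_seed_determinism(self):
        a = simulate_ortholog_tables(SimConfig(seed=12))
        b = simulate_ortholog_tables(SimConfig(seed=12))
        assert a.pairs.equals(b.pairs)
        for sp in a.orders:
            assert a.orders[sp].equals(b.orders[sp])

    def test_planted_events_recorded_in_truth(self):
        cfg = SimConfig(seed=13, ortho_spec=OrthoSpec(n_insertions=4, n_deletions=6))
        sim = simulate_ortholog_tables(cfg)
        focal_genes = set(sim.orders[sim.truth.focal]["gene"])
        other_genes = set(sim.orders[sim.truth.other]["gene"])
        assert len(sim.truth.deleted_core) == 6
        assert len(sim.truth.inserted_genes) == 4
        for core in sim.truth.deleted_core:
            assert f"{sim.truth.focal}_g{core:04d}" not in focal_genes
            assert f"{sim.truth.other}_g{core:04d}" in other_genes
        for gene in sim.truth.inserted_genes:
            assert gene in focal_genes
        # inserted genes appear in no homology pair
        assert not (
            set(sim.pairs["gene_a"]) | set(sim.pairs["gene_b"])
        ) & set(sim.truth.inserted_genes)

    def test_needs_three_outgroups(self):
        cfg = SimConfig(seed=1, ortho_spec=OrthoSpec(species=("A", "B", "Bd")))
        with pytest.raises(ValueError):
            simulate_ortholog_tables(cfg)
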