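"""Synthetic-input generators: determinism, planted effects, file formats."""

import math

import networkx as nx
import numpy as np
import obonet
import pytest

from degchar import (
    ConfigurationError,
    SimulationConfig,
    generate_deg_lists,
    generate_disorder_tracks,
    generate_go,
    generate_ppi,
    generate_profiles,
    generate_proteome,
    merge_gene_lists,
    protein_conservation,
)
from degchar.synthetic_data import write_fasta


class TestConfigValidation:
    def test_negative_count_rejected_naming_field(self):
        with pytest.raises(ConfigurationError, match="n_proteome"):
            SimulationConfig(n_proteome=-5)

    def test_flip_rate_at_chance_rejected(self):
        with pytest.raises(ConfigurationError, match="predictor_flip_rates"):
            SimulationConfig(predictor_flip_rates=(0.5, 0.1, 0.1, 0.1, 0.1))

    def test_overlap_larger_than_lists_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(deg_list_sizes=(5, 5, 6, 0))

    def test_infeasible_focal_coverage_rejected(self):
        with pytest.raises(ConfigurationError, match="n_focal"):
            SimulationConfig(n_focal=10, deg_list_sizes=(55, 55, 6, 5))


class TestProteome:
    def test_same_seed_byte_identical_fasta(self, tiny_config, tmp_path):
        for name in ("a.fasta", "b.fasta"):
            write_fasta(tmp_path / name, generate_proteome(tiny_config))
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()

    def test_zero_sd_gives_constant_lengths(self):
        cfg = SimulationConfig(seed=1, n_proteome=50, n_focal=103,
                               length_log_sd=0.0)
        lengths = {r.length for r in generate_proteome(cfg)}
        assert lengths == {round(math.exp(cfg.length_log_mean))}

    def test_sample_median_near_412_at_n10000(self):
        cfg = SimulationConfig(seed=2, n_proteome=9897, n_focal=103)
        lengths = [r.length for r in generate_proteome(cfg)]
        # oracle: the median of the target log-normal itself
        oracle = math.exp(cfg.length_log_mean)
        assert abs(np.median(lengths) - oracle) / oracle < 0.05

    def test_lengths_at_least_30_and_accessions_unique(self, tiny_config):
        records = generate_proteome(tiny_config)
        assert min(r.length for r in records) >= 30
        assert len({r.accession for r in records}) == len(records)

    def test_central_band_lengths_shared_by_at_least_20(self):
        cfg = SimulationConfig(seed=5, n_proteome=5000, n_focal=103)
        lengths = np.array([r.length for r in generate_proteome(cfg)])
        lo, hi = np.percentile(lengths, [5, 95])
        values, counts = np.unique(lengths, return_counts=True)
        in_band = (values >= lo) & (values <= hi)
        assert counts[in_band].min() >= 20

    def test_sequences_use_standard_alphabet(self, tiny_config):
        records = generate_proteome(tiny_config)
        assert set(records[0].sequence) <= set("ACDEFGHIKLMNPQRSTVWY")


class TestProfiles:
    def test_uniform_flag_gives_zero_conservation(self, tiny_config):
        import dataclasses

        cfg = dataclasses.replace(tiny_config, conservation_uniform=True)
        records = generate_proteome(cfg)[:3]
        profiles = generate_profiles(records, cfg)
        for profile in profiles.values():
            assert np.allclose(profile.matrix, 1 / 20)
            assert protein_conservation(profile) == pytest.approx(0.0, abs=1e-12)

    def test_rows_normalized_within_1e9(self, tiny_config):
        records = generate_proteome(tiny_config)[:5]
        profiles = generate_profiles(records, tiny_config)
        for profile in profiles.values():
            assert np.abs(profile.matrix.sum(axis=1) - 1).max() < 1e-9

    def test_mean_relative_entropy_decreases_with_concentration(self):
        import dataclasses

        base = SimulationConfig(seed=7, n_proteome=103, n_focal=103)
        records = generate_proteome(base)[:40]
        means = []
        for alpha in (0.1, 1.0, 10.0):
            cfg = dataclasses.replace(
                base,
                conservation_alpha_focal=alpha,
                conservation_alpha_background=alpha,
            )
            profiles = generate_profiles(records, cfg)
            means.append(
                np.mean([protein_conservation(p) for p in profiles.values()])
            )
        # oracle: Monte-Carlo E[RE] under the same Dirichlet laws
        rng = np.random.default_rng(99)
        mc = []
        for alpha in (0.1, 1.0, 10.0):
            rows = rng.dirichlet(np.full(20, alpha), size=4000)
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(rows > 0, rows * np.log(rows * 20), 0.0)
            mc.append(terms.sum(axis=1).mean())
        assert means[0] > means[1] > means[2]
        assert mc[0] > mc[1] > mc[2]
        for observed, expected in zip(means, mc):
            assert observed == pytest.approx(expected, rel=0.1)

    def test_subset_generation_matches_full_run(self, tiny_config):
        records = generate_proteome(tiny_config)
        full = generate_profiles(records[:10], tiny_config)
        subset = generate_profiles(records[4:6], tiny_config)
        for acc, prof in subset.items():
            assert np.array_equal(prof.matrix, full[acc].matrix)


class TestDisorderTracks:
    def test_zero_flip_rates_reproduce_truth_exactly(self):
        cfg = SimulationConfig(seed=8, n_proteome=103, n_focal=103,
                               predictor_flip_rates=(0.0,) * 5)
        records = generate_proteome(cfg)[:10]
        tracks = generate_disorder_tracks(records, cfg)
        for ts in tracks.values():
            assert np.all(ts.tracks == ts.tracks[0])
            assert np.array_equal(ts.consensus, ts.tracks[0])

    def test_zero_target_content_gives_all_ordered(self):
        cfg = SimulationConfig(seed=8, n_proteome=103, n_focal=103,
                               disorder_content_focal=0.0,
                               disorder_content_background=0.0,
                               predictor_flip_rates=(0.0,) * 5)
        records = generate_proteome(cfg)[:10]
        tracks = generate_disorder_tracks(records, cfg)
        assert all(ts.content == 0.0 for ts in tracks.values())

    def test_consensus_content_near_target(self):
        # oracle: with 5 voters at flip rate 0.05, majority-vote accuracy is
        # so high that consensus content tracks the stationary fraction
        cfg = SimulationConfig(
            seed=9, n_proteome=200, n_focal=103,
            disorder_content_background=0.18,
            predictor_flip_rates=(0.05,) * 5,
        )
        records = [r for r in generate_proteome(cfg)
                   if r.regulation == "background"]
        tracks = generate_disorder_tracks(records, cfg)
        mean_content = np.mean([ts.content for ts in tracks.values()])
        assert abs(mean_content - 0.18) < 0.02

    def test_track_lengths_equal_sequence_lengths(self, tiny_config):
        records = generate_proteome(tiny_config)[:5]
        tracks = generate_disorder_tracks(records, tiny_config)
        for rec in records:
            assert tracks[rec.accession].length == rec.length


class TestPPI:
    def test_realized_mean_degree_near_target(self):
        cfg = SimulationConfig(seed=10, n_proteome=1897, n_focal=103,
                               ppi_absent_fraction=0.0, mean_degree=6.0)
        net = generate_ppi(generate_proteome(cfg), cfg)
        mean_degree = 2 * net.n_edges / net.n_nodes
        assert 5.4 <= mean_degree <= 6.6

    def test_edge_list_has_no_self_loops(self, tiny_config, tmp_path):
        records = generate_proteome(tiny_config)
        generate_ppi(records, tiny_config, tmp_path / "edges.tsv")
        for line in (tmp_path / "edges.tsv").read_text().splitlines():
            a, b = line.split("\t")
            assert a != b

    def test_same_seed_identical_edge_list(self, tiny_config, tmp_path):
        records = generate_proteome(tiny_config)
        generate_ppi(records, tiny_config, tmp_path / "a.tsv")
        generate_ppi(records, tiny_config, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_absent_fraction_removes_proteins(self):
        import dataclasses

        cfg = SimulationConfig(seed=10, n_proteome=897, n_focal=103)
        records = generate_proteome(cfg)
        net = generate_ppi(records, dataclasses.replace(cfg, ppi_absent_fraction=0.3))
        assert net.n_nodes < len(records)

    def test_mean_degree_at_least_n_rejected(self):
        cfg = SimulationConfig(seed=1, n_proteome=103, n_focal=103,
                               mean_degree=4.0)
        records = generate_proteome(cfg)[:12]
        import dataclasses

        with pytest.raises(ConfigurationError, match="mean_degree"):
            generate_ppi(records, dataclasses.replace(cfg, mean_degree=50.0,
                                                      ppi_absent_fraction=0.0))


class TestGO:
    def test_obo_round_trip_is_acyclic_dag(self, tiny_config, tmp_path):
        records = generate_proteome(tiny_config)
        generate_go(records, tiny_config, obo_path=tmp_path / "go.obo")
        graph = obonet.read_obo(str(tmp_path / "go.obo"))
        assert nx.is_directed_acyclic_graph(graph)
        assert len(graph) == tiny_config.go_n_terms

    def test_gaf_references_existing_accessions(self, tiny_config, tmp_path):
        records = generate_proteome(tiny_config)
        accessions = {r.accession for r in records}
        generate_go(records, tiny_config, gaf_path=tmp_path / "anno.gaf")
        for line in (tmp_path / "anno.gaf").read_text().splitlines():
            if line.startswith("!"):
                continue
            assert line.split("\t")[1] in accessions

    def test_planted_focal_annotations_match_binomial_mean(self):
        # oracle: direct focal annotations of the planted term ~ Binomial(n, p)
        plant_rate = 0.06
        counts = []
        for seed in range(100):
            cfg = SimulationConfig(
                seed=seed, n_proteome=103, n_focal=103, go_n_terms=30,
                planted_terms=(("GO:0000010", plant_rate, 0.02),),
            )
            records = generate_proteome(cfg)
            go = generate_go(records, cfg)
            focal = {r.accession for r in records if r.regulation != "background"}
            counts.append(
                sum(1 for acc in focal
                    if "GO:0000010" in go.direct_annotations[acc])
            )
        expected = 103 * plant_rate
        sd = math.sqrt(103 * plant_rate * (1 - plant_rate) / 100)
        assert abs(np.mean(counts) - expected) < 4 * sd

    def test_depth_bounded(self, tiny_config):
        records = generate_proteome(tiny_config)
        go = generate_go(records, tiny_config)
        rev = go.graph.reverse()  # parent -> child
        for root in go.roots():
            depths = nx.single_source_shortest_path_length(rev, root)
            assert max(depths.values()) <= tiny_config.go_depth

    def test_unknown_planted_term_rejected(self):
        with pytest.raises(ConfigurationError, match="planted_terms"):
            cfg = SimulationConfig(n_proteome=200, n_focal=103, go_n_terms=30,
                                   planted_terms=(("GO:9999999", 0.2, 0.05),))
            generate_go(generate_proteome(cfg), cfg)


class TestDEGLists:
    def test_paper_scale_cardinalities(self, tiny_config):
        records = generate_proteome(tiny_config)
        deg = generate_deg_lists(records, tiny_config)
        assert len(deg.list_a) == 55 and len(deg.list_b) == 55
        ids_a = {g.gene_id for g in deg.list_a}
        ids_b = {g.gene_id for g in deg.list_b}
        assert len(ids_a & ids_b) == 6
        assert len(ids_a | ids_b) == 104
        mapped_genes = {g for g, _, _ in deg.mapping_table}
        assert len((ids_a | ids_b) & mapped_genes) == 99
        merged = merge_gene_lists(deg.list_a, deg.list_b)
        assert len(merged.genes) == 104 and not merged.conflicts

    def test_full_overlap_gives_one_list(self):
        cfg = SimulationConfig(seed=3, n_proteome=103, n_focal=103,
                               deg_list_sizes=(5, 5, 5, 0),
                               go_n_terms=30)
        records = generate_proteome(cfg)
        deg = generate_deg_lists(records, cfg)
        assert {g.gene_id for g in deg.list_a} == {g.gene_id for g in deg.list_b}

    def test_disjoint_lists_all_mapped(self):
        cfg = SimulationConfig(seed=3, n_proteome=103, n_focal=103,
                               deg_list_sizes=(4, 3, 0, 0), go_n_terms=30)
        records = generate_proteome(cfg)
        deg = generate_deg_lists(records, cfg)
        ids = {g.gene_id for g in deg.list_a} | {g.gene_id for g in deg.list_b}
        assert len(ids) == 7
        assert ids <= {g for g, _, _ in deg.mapping_table}

    def test_directions_consistent_across_lists(self, tiny_config):
        records = generate_proteome(tiny_config)
        deg = generate_deg_lists(records, tiny_config)
        directions = {}
        for entry in deg.list_a + deg.list_b:
            assert directions.setdefault(entry.gene_id, entry.direction) == entry.direction
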