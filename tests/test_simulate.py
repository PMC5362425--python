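"""Synthetic bundle generator: determinism, config contracts, oracle recounts."""

import dataclasses
import filecmp
import json

import pytest

from netpharm import (
    SyntheticConfig,
    bipartite_stats,
    build_bipartite,
    merge_disease_targets,
    overlap_targets,
    recount_oracle,
    screen_compounds,
    simulate_bundle,
)


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SyntheticConfig(seed=7)
        paths_a = simulate_bundle(cfg).write(tmp_path / "a")
        paths_b = simulate_bundle(cfg).write(tmp_path / "b")
        assert paths_a.keys() == paths_b.keys()
        for key in paths_a:
            assert filecmp.cmp(paths_a[key], paths_b[key], shallow=False), key

    def test_different_seeds_differ(self):
        a = simulate_bundle(SyntheticConfig(seed=1))
        b = simulate_bundle(SyntheticConfig(seed=2))
        assert a.ppi.edges != b.ppi.edges


class TestConfigContracts:
    def test_missing_dl_fraction_zero_means_no_absent_dl(self):
        bundle = simulate_bundle(SyntheticConfig(seed=3, missing_dl_fraction=0.0))
        assert all(r.dl is not None for r in bundle.compounds)

    def test_infeasible_module_rejected_before_generation(self):
        with pytest.raises(ValueError, match="module"):
            simulate_bundle(SyntheticConfig(ppi_n_nodes=10, planted_module_size=20,
                                            n_targets=5))

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError, match="probabilities"):
            SyntheticConfig(herb_sharing_prob=1.5).validate()

    def test_manifest_sets_within_generated_entities(self, default_bundle):
        m = default_bundle.manifest
        ids = {r.compound_id for r in default_bundle.compounds}
        assert m.true_threshold_survivors <= ids
        assert m.planted_module <= default_bundle.ppi.nodes
        assert m.planted_terms <= set(default_bundle.gene_sets.terms)

    def test_ppi_is_simple(self, default_bundle):
        for u, v in default_bundle.ppi.edges:
            assert u != v

    def test_rescued_compounds_carry_notes_and_whitelist(self, default_bundle):
        rescued = [r for r in default_bundle.compounds if r.rescued]
        assert {r.compound_id for r in rescued} == set(default_bundle.whitelist)
        assert all(r.rescue_note for r in rescued)

    def test_manifest_json_round_trips(self, tmp_path, default_bundle):
        paths = default_bundle.write(tmp_path)
        data = json.loads(paths["manifest"].read_text())
        assert sorted(default_bundle.manifest.planted_module) == data["planted_module"]
        assert data["params"]["seed"] == default_bundle.config.seed


class TestOracleRecounts:
    """Pipeline computations must equal the naive recount on any bundle."""

    @pytest.mark.parametrize("seed", [42, 7, 99])
    def test_pipeline_counts_equal_oracle(self, seed):
        bundle = simulate_bundle(SyntheticConfig(seed=seed))
        oracle = recount_oracle(bundle)

        screen = screen_compounds(bundle.compounds, whitelist=bundle.whitelist)
        assert len(screen.kept) == oracle["n_kept"]
        assert sorted(screen.kept_ids) == oracle["kept_ids"]
        assert screen.per_herb_counts == oracle["per_herb_counts"]

        build = build_bipartite(screen.kept_records, bundle.ct_map)
        stats = bipartite_stats(build.network)
        assert stats["n_compounds"] == oracle["n_mapped_compounds"]
        assert stats["n_targets"] == oracle["n_putative_targets"]
        assert stats["n_edges"] == oracle["n_ct_edges"]
        assert len(build.unmapped) == oracle["n_unmapped_kept"]

        disease = merge_disease_targets(bundle.disease_lists)
        assert len(disease.merged) == oracle["n_merged_disease"]
        shared = overlap_targets(build.network.target_nodes, disease)
        assert len(shared) == oracle["n_overlap"]

    def test_all_compounds_above_thresholds_keeps_all(self):
        cfg = SyntheticConfig(
            seed=5,
            ob_distribution=("constant", (60.0,)),
            dl_distribution=("constant", (0.5,)),
            missing_dl_fraction=0.0,
            n_rescued=0,
        )
        bundle = simulate_bundle(cfg)
        oracle = recount_oracle(bundle)
        assert oracle["n_kept"] == oracle["n_compounds"]

    def test_zero_compounds_all_zero(self):
        cfg = SyntheticConfig(seed=5, n_herbs=0, compounds_per_herb=0, n_rescued=0)
        oracle = recount_oracle(simulate_bundle(cfg))
        assert oracle["n_compounds"] == 0 and oracle["n_kept"] == 0
        assert oracle["n_ct_edges"] == 0 and oracle["n_putative_targets"] == 0
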