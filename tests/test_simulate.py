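import numpy as np
import pandas as pd
import pytest

from circanet.simulate import (
    SimulationConfig,
    SimulationTruth,
    make_pwm_library,
    read_promoters_fasta,
    simulate_atlas,
    simulate_expression,
    simulate_promoters,
    write_atlas,
    write_promoters_fasta,
)


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(class_fractions={"null": 0.5, "core": 0.4})

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"timepoints": ()},
            {"timepoints": (0.0, 4.0, 4.0)},
            {"noise_sd": -1},
            {"dd_amplitude_ratio": 0.0},
            {"motif_length": 2000},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestExpression:
    def test_noiseless_core_genes_are_exact_cosines(self):
        config = SimulationConfig(
            n_genes=50,
            class_fractions={"null": 0.0, "core": 1.0},
            noise_sd=0.0,
            n_tfs=2,
            targets_per_tf=5,
            seed=3,
        )
        ld, dd, truth = simulate_expression(config)
        t = ld.condition("LD").timepoints()
        for gene in truth.genes.index[:10]:
            row = truth.genes.loc[gene]
            expected = row["baseline"] + row["amplitude"] * np.cos(2 * np.pi * (t - row["phase"]) / 24)
            np.testing.assert_allclose(ld.values.loc[gene], expected, atol=1e-10)
            expected_dd = row["baseline"] + 0.7 * row["amplitude"] * np.cos(2 * np.pi * (t - row["phase"]) / 24)
            np.testing.assert_allclose(dd.values.loc[gene], expected_dd, atol=1e-10)

    def test_single_seed_drives_everything(self):
        a = simulate_expression(SimulationConfig(n_genes=600, seed=5))
        b = simulate_expression(SimulationConfig(n_genes=600, seed=5))
        c = simulate_expression(SimulationConfig(n_genes=600, seed=6))
        assert a[0].values.equals(b[0].values) and a[1].values.equals(b[1].values)
        assert a[2].genes.equals(b[2].genes)
        assert not a[0].values.equals(c[0].values)

    def test_class_proportions_exact(self):
        config = SimulationConfig(n_genes=1000, seed=1)
        _, _, truth = simulate_expression(config)
        counts = truth.genes["class"].value_counts()
        assert counts["null"] == 700 and counts["core"] == 200
        assert counts["fast_light"] == 40 and counts["slow_light"] == 40
        assert counts["dark_induced"] == 20

    def test_truth_phases_inside_class_windows(self, sim_study):
        _, _, _, truth = sim_study
        g = truth.genes
        fast = g.loc[g["class"] == "fast_light", "phase"]
        slow = g.loc[g["class"] == "slow_light", "phase"]
        dark = g.loc[g["class"] == "dark_induced", "phase"]
        assert ((fast >= 2) & (fast < 8)).all()
        assert ((slow >= 8) & (slow < 16)).all()
        assert (((dark >= 16) & (dark < 24)) | (dark < 2)).all()

    def test_light_classes_flat_in_dd_dark_elevated(self):
        config = SimulationConfig(n_genes=1000, noise_sd=0.0, seed=8)
        ld, dd, truth = simulate_expression(config)
        g = truth.genes
        for cls in ("fast_light", "slow_light"):
            idx = g.index[g["class"] == cls]
            dev = dd.values.loc[idx].to_numpy() - g.loc[idx, "baseline"].to_numpy()[:, None]
            np.testing.assert_allclose(dev, 0, atol=1e-10)
        dark = g.index[g["class"] == "dark_induced"]
        dd_dev = dd.values.loc[dark].to_numpy() - g.loc[dark, "baseline"].to_numpy()[:, None]
        assert (dd_dev > 0).all()  # elevated constant
        assert (dd_dev.std(axis=1) < 1e-10).all()

    def test_tf_target_phase_concentration(self, sim_study):
        config, _, _, truth = sim_study
        from circanet.phase import circular_distance, circular_mean

        for tf, grp in truth.tf_edges.groupby("tf"):
            tf_phase = truth.genes.loc[tf, "phase"]
            center = circular_mean(truth.genes.loc[grp["target"], "phase"])
            assert circular_distance(center, (tf_phase + config.target_phase_lag) % 24) < 4.0


@pytest.fixture(scope="module")
def small_sim():
    config = SimulationConfig(
        n_genes=120,
        class_fractions={"null": 0.4, "core": 0.6},
        n_tfs=2,
        targets_per_tf=5,
        mutation_rate=0.0,
        seed=9,
    )
    _, _, truth = simulate_expression(config)
    pwms, _ = make_pwm_library(truth.tf_edges["tf"].unique(), config.motif_length, seed=9)
    promoters, orthologs = simulate_promoters(truth, pwms, config)
    return config, truth, pwms, promoters, orthologs


class TestPromoters:
    def test_zero_mutation_consensus_present_in_all_species(self, small_sim):
        config, truth, pwms, promoters, _ = small_sim
        pwm_by_tf = {p.id.removeprefix("M_"): p for p in pwms}
        for row in truth.tf_edges.itertuples():
            consensus = pwm_by_tf[row.tf].consensus
            from circanet.motifs import reverse_complement

            for species in config.species:
                seq = promoters[species][row.target]
                assert consensus in seq or reverse_complement(consensus) in seq

    def test_planted_positions_match_string_search(self, small_sim):
        config, truth, pwms, promoters, _ = small_sim
        pwm_by_id = {p.id: p for p in pwms}
        from circanet.motifs import reverse_complement

        for row in truth.planted_motifs.itertuples():
            consensus = pwm_by_id[row.motif].consensus
            site = consensus if row.strand == "+" else reverse_complement(consensus)
            seq = promoters[row.species][row.gene]
            assert seq[row.offset : row.offset + len(site)] == site
            assert 0 <= row.offset <= config.promoter_length - len(site)

    def test_background_gc_content(self, small_sim):
        config, truth, _, promoters, _ = small_sim
        non_targets = set(truth.genes.index) - set(truth.tf_edges["target"])
        pooled = "".join(promoters["zebrafish"][g] for g in sorted(non_targets)[:50])
        gc = (pooled.count("G") + pooled.count("C")) / len(pooled)
        assert gc == pytest.approx(0.40, abs=0.02)

    def test_fasta_roundtrip(self, small_sim, tmp_path):
        _, _, _, promoters, _ = small_sim
        paths = write_promoters_fasta(promoters, tmp_path)
        back = read_promoters_fasta(paths)
        assert back == promoters

    def test_ortholog_map_covers_all_species(self, small_sim):
        config, truth, _, _, orthologs = small_sim
        assert set(orthologs["species"]) == set(config.species)
        assert len(orthologs) == len(truth.genes) * config.n_species

    def test_empty_library_rejected(self, small_sim):
        config, truth, _, _, _ = small_sim
        with pytest.raises(ValueError):
            simulate_promoters(truth, [], config)


class TestAtlas:
    def test_tf_shares_tissue_with_all_targets_at_full_share(self):
        config = SimulationConfig(
            n_genes=200,
            class_fractions={"null": 0.2, "core": 0.8},
            n_tfs=3,
            targets_per_tf=10,
            tissue_share=1.0,
            seed=10,
        )
        _, _, truth = simulate_expression(config)
        atlas = simulate_atlas(truth)
        for tf, grp in truth.tf_edges.groupby("tf"):
            assert (atlas[grp["target"]] == atlas[tf]).all()

    def test_uniform_assignment_balanced(self):
        config = SimulationConfig(
            n_genes=1000,
            class_fractions={"null": 1.0},
            n_tfs=0,
            n_tissues=5,
            seed=12,
        )
        _, _, truth = simulate_expression(config)
        counts = simulate_atlas(truth).value_counts()
        se = np.sqrt(1000 * 0.2 * 0.8)
        assert np.all(np.abs(counts.to_numpy() - 200) <= 3 * se)

    def test_atlas_roundtrip(self, tmp_path):
        config = SimulationConfig(n_genes=600, seed=13)
        _, _, truth = simulate_expression(config)
        atlas = simulate_atlas(truth)
        write_atlas(atlas, tmp_path / "atlas.tsv")
        back = pd.read_csv(tmp_path / "atlas.tsv", sep="\t", header=None, names=["gene", "tissue"])
        back = back.set_index("gene")["tissue"]
        assert back.to_dict() == atlas.to_dict()


def test_truth_json_roundtrip(tmp_path):
    config = SimulationConfig(n_genes=600, seed=14)
    _, _, truth = simulate_expression(config)
    truth.to_json(tmp_path / "truth.json")
    back = SimulationTruth.from_json(tmp_path / "truth.json")
    assert list(back.genes.index) == list(truth.genes.index)
    assert back.genes["class"].tolist() == truth.genes["class"].tolist()
    np.testing.assert_allclose(
        back.genes["phase"].to_numpy(dtype=float), truth.genes["phase"].to_numpy(), equal_nan=True
    )
    assert back.tf_edges.equals(truth.tf_edges)
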