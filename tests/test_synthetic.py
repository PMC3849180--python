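"""The synthetic-data generator and its planted ground truth."""

import hashlib
from pathlib import Path

import pytest

from mirconsensus.diffexp import down_votes
from mirconsensus.sites import scan_seed_sites
from mirconsensus.synthetic import (
    MIR100,
    GeneratorConfig,
    generate_dataset,
    plant_seed_site,
    write_dataset,
)


def _tree_hash(directory: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(Path(directory).iterdir()):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()


class TestDeterminism:
    def test_fixed_seed_gives_byte_identical_files(self, tmp_path):
        config = GeneratorConfig(n_genes=200)
        a, b = tmp_path / "a", tmp_path / "b"
        write_dataset(generate_dataset(config, seed=7), a)
        write_dataset(generate_dataset(config, seed=7), b)
        assert _tree_hash(a) == _tree_hash(b)

    def test_different_seeds_differ(self, tmp_path):
        config = GeneratorConfig(n_genes=200)
        a, b = tmp_path / "a", tmp_path / "b"
        write_dataset(generate_dataset(config, seed=7), a)
        write_dataset(generate_dataset(config, seed=8), b)
        assert _tree_hash(a) != _tree_hash(b)

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            generate_dataset(GeneratorConfig())


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 10},
            {"effect_fc": 0.0},
            {"effect_fc": 1.2},
            {"effect_fc": 0.7},  # does not undercut the 0.67 calibrator
            {"noise_sd": -0.1},
            {"n_down_experiments": 6},
            {"tissue_panel_r": -1.0},
        ],
    )
    def test_bad_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_dataset(GeneratorConfig(**kwargs), seed=1)


class TestStudyDesignShape:
    def test_five_experiments_three_calibrated_one_mouse(self, default_dataset):
        exps = default_dataset.experiments
        assert len(exps) == 5
        fc_exps = [e for e in exps if e.mode.value == "fold_change"]
        assert len(fc_exps) == 3
        for e, expected_fc in zip(fc_exps, (0.88, 0.67, 0.67)):
            assert e.calibrator in e.fc
            assert e.fc[e.calibrator] == pytest.approx(expected_fc)
        assert sum(e.species == "mouse" for e in exps) == 1

    def test_prediction_matrix_has_twelve_tools(self, default_dataset):
        assert len(default_dataset.prediction_matrix.tools) == 12

    def test_truth_partitions_the_gene_universe(self, default_dataset):
        truth = default_dataset.truth
        assert not truth.true_targets & truth.decoy_genes
        universe = {g for e in default_dataset.experiments if e.mode.value == "fold_change" for g in e.fc}
        assert truth.true_targets | truth.decoy_genes == universe

    def test_panels_cover_all_samples_with_references(self, default_dataset):
        for panel in default_dataset.panels.values():
            wide = panel.ct.pivot(index="assay", columns="sample", values="ct")
            assert not wide.isna().any().any()
            for assay in (panel.mirna_assay, panel.mirna_reference, panel.gene_reference):
                assert assay in wide.index
        assert len(default_dataset.panels["tissue"].ct["sample"].unique()) == 7
        assert len(default_dataset.panels["cell"].ct["sample"].unique()) == 10


class TestPlantedDownRecovery:
    def test_noise_free_votes_match_planting_exactly(self, noise_free_dataset):
        table = down_votes(noise_free_dataset.experiments)
        planted = noise_free_dataset.planted_down
        for gene, exps in planted.items():
            assert table.D[gene] == len(exps), gene
            down_in = set(table.flags.columns[table.flags.loc[gene]])
            assert down_in == set(exps), gene

    def test_all_true_targets_reach_top_set_when_planted_in_three(self, noise_free_dataset):
        table = down_votes(noise_free_dataset.experiments)
        for gene in noise_free_dataset.truth.true_targets:
            assert table.D[gene] >= 3

    def test_lower_effect_fc_never_decreases_top_set_recall(self):
        recalls = []
        for effect_fc in (0.65, 0.5, 0.35, 0.2):
            config = GeneratorConfig(effect_fc=effect_fc, noise_sd=0.4)
            ds = generate_dataset(config, seed=21)
            table = down_votes(ds.experiments)
            true = ds.truth.true_targets
            recalls.append(len(table.top_set & true) / len(true))
        assert recalls == sorted(recalls)


class TestPlantSeedSite:
    def test_planting_log_recovered_exactly_by_scanner(self):
        config = GeneratorConfig(n_random_sites=28)  # 30 sites incl. the 2 fixed
        ds = generate_dataset(config, seed=19)
        assert len(ds.planting_log) == 30
        found = sorted(
            (tx.id, s.seed_match_start, s.region_label)
            for tx in ds.transcripts
            for s in scan_seed_sites(tx, MIR100)
        )
        assert found == sorted(ds.planting_log)

    def test_dual_site_architecture_on_first_transcript(self, default_dataset):
        tx = default_dataset.transcripts[0]
        sites = {s.seed_match_start: s.region_label for s in scan_seed_sites(tx, MIR100)}
        assert sites[409] == "CDS"
        assert sites[2155] == "3UTR"

    def test_planting_preserves_all_other_bases(self, toy_transcript, mir100):
        planted = plant_seed_site(toy_transcript, mir100, 31)
        assert len(planted.sequence) == len(toy_transcript.sequence)
        diffs = [
            i + 1
            for i, (a, b) in enumerate(zip(toy_transcript.sequence, planted.sequence))
            if a != b
        ]
        assert all(31 <= p <= 37 for p in diffs)

    def test_region_mismatch_rejected(self, toy_transcript, mir100):
        with pytest.raises(ValueError, match="region"):
            plant_seed_site(toy_transcript, mir100, 5, region="CDS")

    def test_overflowing_position_rejected(self, toy_transcript, mir100):
        with pytest.raises(ValueError):
            plant_seed_site(toy_transcript, mir100, 95)


class TestMouseHarmonizationPath:
    def test_mouse_list_symbols_are_title_case_on_disk(self, tmp_path, default_dataset):
        write_dataset(default_dataset, tmp_path)
        mouse = next(e for e in default_dataset.experiments if e.species == "mouse")
        raw = (tmp_path / f"{mouse.id}.down.tsv").read_text().splitlines()
        assert raw, "mouse down-list must not be empty"
        assert all(line != line.upper() for line in raw)  # e.g. Gene0123
        # but the in-memory experiment is already harmonized
        assert all(g == g.upper() for g in mouse.down_list)
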