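"""Synthetic scene generator: sampling laws, rendering, determinism."""

import numpy as np
import pandas as pd
import pytest

from tsquant.geometry import CellGeometry, default_geometry
from tsquant.simulate import (
    ConditionPreset,
    GroundTruth,
    NoiseModel,
    PRESETS,
    PSFModel,
    generate_experiment,
    render_stack,
    sample_ground_truth,
)


class TestPresets:
    def test_condition_table(self):
        """The four drug conditions carry their reported translating fractions."""
        assert PRESETS["untreated"].p_translating == 0.63
        assert PRESETS["puromycin"].p_translating == 0.03
        assert PRESETS["emetine_puromycin"].p_translating == 0.05
        assert PRESETS["anisomycin"].p_translating == 0.50

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            ConditionPreset("bad", 1.5)


class TestSampleGroundTruth:
    def test_zero_probability_gives_no_nascent_chains(self, small_geometry):
        gt = sample_ground_truth(ConditionPreset("p0", 0.0), small_geometry, 50, seed=0)
        assert len(gt.mrna) == 50
        assert (gt.mrna["k"] == 0).all()
        assert (~gt.mrna["translating"]).all()

    def test_certain_translation_gives_k_at_least_one(self, small_geometry):
        gt = sample_ground_truth(ConditionPreset("p1", 1.0), small_geometry, 50, seed=0)
        assert gt.mrna["translating"].all()
        assert (gt.mrna["k"] >= 1).all()

    def test_translating_fraction_follows_binomial_law(self, small_geometry):
        """At n=5000 the realized fraction sits within 3 binomial SEs of p."""
        p = 0.63
        gt = sample_ground_truth(
            ConditionPreset("untreated", p), small_geometry, 5000, seed=11, min_spacing_px=0.0
        )
        se = np.sqrt(p * (1 - p) / 5000)
        assert abs(gt.mrna["translating"].mean() - p) < 3 * se

    def test_positions_inside_cytoplasm_with_min_spacing(self, small_geometry):
        gt = sample_ground_truth(PRESETS["untreated"], small_geometry, 20, seed=2)
        iy = gt.mrna["y"].round().astype(int)
        ix = gt.mrna["x"].round().astype(int)
        assert small_geometry.cyto_mask[iy, ix].all()
        pos = gt.mrna[["y", "x"]].to_numpy()
        d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 5.0

    def test_empty_cytoplasm_is_an_error(self):
        geo = CellGeometry(
            shape=(5, 16, 16),
            cyto_mask=np.zeros((16, 16), bool),
            nucleus_mask=np.zeros((16, 16), bool),
        )
        with pytest.raises(ValueError, match="cytoplasm"):
            sample_ground_truth(PRESETS["untreated"], geo, 5, seed=0)

    def test_reproducible_for_fixed_seed(self, small_geometry):
        a = sample_ground_truth(PRESETS["untreated"], small_geometry, 30, seed=5)
        b = sample_ground_truth(PRESETS["untreated"], small_geometry, 30, seed=5)
        pd.testing.assert_frame_equal(a.mrna, b.mrna)
        pd.testing.assert_frame_equal(a.free_peptides, b.free_peptides)

    def test_roundtrip_through_csv(self, small_geometry, tmp_path):
        gt = sample_ground_truth(PRESETS["untreated"], small_geometry, 12, seed=4)
        gt.to_csv(tmp_path / "m.csv", tmp_path / "f.csv")
        back = GroundTruth.from_csv(tmp_path / "m.csv", tmp_path / "f.csv")
        pd.testing.assert_frame_equal(gt.mrna, back.mrna)
        pd.testing.assert_frame_equal(gt.free_peptides, back.free_peptides)


class TestRenderStack:
    def test_empty_scene_is_flat_background(self, small_geometry, psf, noise_off):
        empty = ConditionPreset("empty", 0.0, free_peptide_density=0.0)
        gt = sample_ground_truth(empty, small_geometry, 0, seed=0)
        m, p = render_stack(gt, small_geometry, psf, noise_off, 1200.0, seed=0)
        assert np.all(m.data == noise_off.background)
        assert np.all(p.data == noise_off.background)

    def test_single_free_peptide_integral_conserved(self, small_geometry, psf, noise_off):
        """The protein-channel total above background equals i_single_true."""
        gt0 = sample_ground_truth(
            ConditionPreset("p0", 0.0, free_peptide_density=0.0), small_geometry, 0, seed=3
        )
        free = pd.DataFrame(
            {"peptide_id": [0], "z": [5.0], "y": [48.0], "x": [48.0], "intensity_units": [1.0]}
        )
        gt = GroundTruth(mrna=gt0.mrna, free_peptides=free)
        _, p = render_stack(gt, small_geometry, psf, noise_off, 1200.0, seed=0)
        total = p.data.sum() - noise_off.background * p.data.size
        assert total == pytest.approx(1200.0, rel=0.01)

    def test_protein_intensity_scales_with_nascent_count(self, small_geometry, psf, noise_off):
        mrna = pd.DataFrame(
            {
                "mrna_id": [0],
                "z": [5.0],
                "y": [48.0],
                "x": [48.0],
                "translating": [True],
                "k": [7],
                "intensity": [2000.0],
            }
        )
        gt = GroundTruth(mrna=mrna, free_peptides=pd.DataFrame(
            columns=["peptide_id", "z", "y", "x", "intensity_units"]))
        _, p = render_stack(gt, small_geometry, psf, noise_off, 1200.0, seed=0)
        total = p.data.sum() - noise_off.background * p.data.size
        assert total == pytest.approx(7 * 1200.0, rel=0.01)

    def test_bit_identical_for_fixed_seed(self, small_geometry, psf):
        noise = NoiseModel()
        gt = sample_ground_truth(PRESETS["untreated"], small_geometry, 10, seed=1)
        m1, p1 = render_stack(gt, small_geometry, psf, noise, 1200.0, seed=9)
        m2, p2 = render_stack(gt, small_geometry, psf, noise, 1200.0, seed=9)
        assert np.array_equal(m1.data, m2.data)
        assert np.array_equal(p1.data, p2.data)

    def test_noise_disabled_sum_decomposes(self, small_geometry, psf, noise_off):
        """Stack total = background*voxels + sum of spot integrals, within 1%."""
        gt = sample_ground_truth(PRESETS["untreated"], small_geometry, 8, seed=6)
        m, p = render_stack(gt, small_geometry, psf, noise_off, 1200.0, seed=0)
        m_total = m.data.sum() - noise_off.background * m.data.size
        assert m_total == pytest.approx(gt.mrna["intensity"].sum(), rel=0.01)
        expected_p = 1200.0 * (gt.mrna["k"].sum() + gt.free_peptides["intensity_units"].sum())
        p_total = p.data.sum() - noise_off.background * p.data.size
        assert p_total == pytest.approx(expected_p, rel=0.01)


class TestGenerateExperiment:
    def test_files_manifest_and_determinism(self, tmp_path):
        presets = [PRESETS["untreated"], PRESETS["puromycin"]]
        geo = default_geometry((11, 96, 96))
        m1 = generate_experiment(presets, 1, seed=0, out_dir=tmp_path / "a", geometry=geo)
        assert len(m1) == 2
        for row in m1.itertuples(index=False):
            for col in ("mrna_tiff", "protein_tiff", "mrna_truth_csv", "free_truth_csv"):
                assert (tmp_path / "a" / getattr(row, col)).exists()
        assert (tmp_path / "a" / "manifest.csv").exists()
        assert (tmp_path / "a" / "params.json").exists()
        assert m1["n_mrna"].between(8, 30).all()
        m2 = generate_experiment(presets, 1, seed=0, out_dir=tmp_path / "b", geometry=geo)
        pd.testing.assert_frame_equal(m1, m2)
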