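"""Synthetic scene generator: counts, containment, clustering, rendering."""

import numpy as np
import pytest

from fpfseg.data import (
    PackingError,
    SceneConfig,
    _four_adjacent,
    generate_dataset,
    micro_scene_config,
    render_channels,
    sample_geometry,
    simulate_scene,
    write_dataset,
)
from fpfseg.io import read_image_pair, read_label_map


class TestGeometry:
    def test_empty_scene(self):
        s = sample_geometry(SceneConfig(n_cells=0))
        assert len(s.cell_truth) == 0 and len(s.nucleus_truth) == 0
        assert s.nucleus_to_cell == {}

    def test_counts_and_bijection_without_multinucleates(self):
        s = sample_geometry(SceneConfig(n_cells=5, multinucleate_rate=0.0, seed=3))
        assert len(s.cell_truth) == 5
        assert len(s.nucleus_truth) == 5
        assert sorted(s.nucleus_to_cell.values()) == [1, 2, 3, 4, 5]

    def test_full_clustering_adjacency(self):
        s = sample_geometry(SceneConfig(n_cells=4, cluster_fraction=1.0, seed=2))
        masks = s.cell_truth.masks
        for i in range(4):
            assert any(_four_adjacent(masks[i], masks[j]) for j in range(4) if j != i)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_nucleus_inside_exactly_one_cell(self, seed):
        s = sample_geometry(micro_scene_config(seed=seed, multinucleate_rate=0.3))
        for nmask, nlab in zip(s.nucleus_truth.masks, s.nucleus_truth.labels):
            owner = s.nucleus_to_cell[int(nlab)]
            inside = [int(clab) for cmask, clab in zip(s.cell_truth.masks, s.cell_truth.labels)
                      if (nmask & cmask).sum() == nmask.sum()]
            assert inside == [owner]

    def test_every_cell_has_a_nucleus(self):
        s = sample_geometry(micro_scene_config(seed=9, multinucleate_rate=0.5))
        assert set(s.nucleus_to_cell.values()) == set(int(v) for v in s.cell_truth.labels)

    def test_multinucleate_rate_converges(self):
        # pool ~1000 cells; 2-nucleus fraction within binomial 4-sigma of r
        r = 0.2
        two = total = 0
        for seed in range(250):
            s = sample_geometry(micro_scene_config(seed=seed, multinucleate_rate=r))
            counts = {}
            for c in s.nucleus_to_cell.values():
                counts[c] = counts.get(c, 0) + 1
            total += len(s.cell_truth)
            two += sum(1 for v in counts.values() if v == 2)
        frac = two / total
        sigma = np.sqrt(r * (1 - r) / total)
        # second-nucleus placement can fail in crowded cells, so only a
        # one-sided slack below r plus sampling noise is allowed
        assert r - 6 * sigma - 0.03 < frac < r + 4 * sigma

    def test_deterministic_given_seed(self):
        a = sample_geometry(micro_scene_config(seed=21))
        b = sample_geometry(micro_scene_config(seed=21))
        assert np.array_equal(a.cell_truth.label_map(), b.cell_truth.label_map())
        assert np.array_equal(a.nucleus_truth.label_map(), b.nucleus_truth.label_map())

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            sample_geometry(SceneConfig(image_height=96, image_width=96, n_cells=40,
                                        cell_radius_range=(18.0, 35.0)))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(nucleus_radius_range=(10.0, 20.0), cell_radius_range=(18.0, 35.0))
        with pytest.raises(ValueError):
            SceneConfig(cluster_fraction=1.5)


class TestRendering:
    def test_noiseless_isolated_cell_is_piecewise_constant(self):
        cfg = micro_scene_config(seed=4, n_cells=1, cluster_fraction=0.0,
                                 noise_sd=0.0, contact_attenuation=0.0)
        s = sample_geometry(cfg)
        pair = render_channels(s, cfg)
        inside = s.cell_truth.masks[0]
        assert np.all(pair.cell[inside] == cfg.cell_level)
        assert np.all(pair.cell[~inside] == cfg.background_level)
        nuc = s.nucleus_truth.masks[0]
        assert np.all(pair.nucleus[nuc] == cfg.nucleus_level)

    def test_contact_band_attenuation(self):
        cfg = SceneConfig(image_height=160, image_width=160, n_cells=2,
                          cluster_fraction=1.0, noise_sd=0.0, contact_attenuation=0.5,
                          cell_radius_range=(18.0, 24.0), nucleus_radius_range=(6.0, 9.0),
                          seed=8)
        s = sample_geometry(cfg)
        pair = render_channels(s, cfg)
        from fpfseg.data import _contact_band

        band = _contact_band(s.cell_truth.label_map(np.int32))
        assert band.any()
        assert pair.cell[band].mean() == pytest.approx(0.5 * cfg.cell_level, rel=1e-6)

    def test_rendering_deterministic(self):
        cfg = micro_scene_config(seed=6)
        a = simulate_scene(cfg)
        b = simulate_scene(cfg)
        assert np.array_equal(a.image_pair.nucleus, b.image_pair.nucleus)
        assert np.array_equal(a.image_pair.cell, b.image_pair.cell)


class TestDatasetIO:
    def test_write_read_round_trip(self, tmp_path):
        samples = generate_dataset(micro_scene_config(), 3, seed=5)
        manifest = write_dataset(samples, tmp_path)
        assert len(manifest["samples"]) == 3
        entry = manifest["samples"][0]
        cells = read_label_map(tmp_path / entry["paths"]["cell_masks"])
        assert np.array_equal(cells.label_map(), samples[0].cell_truth.label_map())
        pair = read_image_pair((tmp_path / entry["paths"]["nucleus"],
                                tmp_path / entry["paths"]["cell"]))
        assert pair.shape == samples[0].image_pair.shape

    def test_split_honors_requested_counts(self, tmp_path):
        # emulated benchmark proportion: 64 train / 18 test of 82
        samples = generate_dataset(micro_scene_config(n_cells=2, cluster_fraction=0.0), 6, seed=1)
        manifest = write_dataset(samples, tmp_path, n_train=4, n_test=2)
        splits = [e["split"] for e in manifest["samples"]]
        assert splits.count("train") == 4 and splits.count("test") == 2
        default = write_dataset(samples, tmp_path / "d")
        assert default["n_train"] == round(6 * 64 / 82)
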