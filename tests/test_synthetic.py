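"""Simulator: geometry, determinism, pathology and dataset generation."""

import dataclasses

import numpy as np
import pytest

from octseg.errors import ParameterError
from octseg.preprocess import boundaries_to_mask
from octseg.scheme import BACKGROUND, COLLAPSED, CYST, PRERETINAL
from octseg.synthetic import (
    SimulationParams,
    make_benchmark_dataset,
    make_dataset,
    simulate_bscan,
)


def flood_fill_components(binary: np.ndarray) -> int:
    """Reference 4-connected component count by BFS flood fill."""
    visited = np.zeros_like(binary, dtype=bool)
    h, w = binary.shape
    count = 0
    for i in range(h):
        for j in range(w):
            if binary[i, j] and not visited[i, j]:
                count += 1
                stack = [(i, j)]
                visited[i, j] = True
                while stack:
                    r, c = stack.pop()
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] \
                                and not visited[rr, cc]:
                            visited[rr, cc] = True
                            stack.append((rr, cc))
    return count


class TestSimulateBscan:
    def test_determinism_bit_identical(self, default_params):
        a = simulate_bscan(default_params, seed=11, diseased=True)
        b = simulate_bscan(default_params, seed=11, diseased=True)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask.labels, b.mask.labels)
        assert np.array_equal(a.boundaries.depths, b.boundaries.depths)

    def test_degenerate_geometry_gives_flat_bands(self, default_params):
        p = dataclasses.replace(
            default_params, speckle=0.0, fovea_depth=0.0,
            boundary_smoothness=0.0, thickness_jitter=0.0,
        )
        s = simulate_bscan(p, seed=0, diseased=False)
        # per-row class constant across columns
        assert (s.mask.labels == s.mask.labels[:, :1]).all()
        assert (s.image == s.image[:, :1]).all()

    def test_boundaries_non_crossing_and_intensities_bounded(self, default_params):
        for seed in range(5):
            s = simulate_bscan(default_params, seed=seed, diseased=True)
            d = s.boundaries.depths
            assert (np.diff(d, axis=0) >= 0).all()
            assert s.image.min() >= 0.0 and s.image.max() <= 1.0

    def test_nondiseased_mask_matches_boundaries_exactly(self, default_params):
        for seed in range(5):
            s = simulate_bscan(default_params, seed=seed, diseased=False)
            rebuilt = boundaries_to_mask(s.boundaries, default_params.height)
            assert np.array_equal(rebuilt.labels, s.mask.labels)
            assert not np.isin(s.mask.labels, (COLLAPSED, CYST)).any()

    def test_diseased_flag_controls_pathology(self, default_params):
        healthy = simulate_bscan(default_params, seed=3, diseased=False)
        assert not np.isin(healthy.mask.labels, (COLLAPSED, CYST)).any()
        diseased = simulate_bscan(default_params, seed=3, diseased=True)
        assert np.isin(diseased.mask.labels, (COLLAPSED, CYST)).any()

    def test_cyst_count_matches_connected_components(self, default_params):
        p = dataclasses.replace(
            default_params, cyst_count_range=(2, 2), collapse_prob=0.0
        )
        for seed in (0, 5, 9):
            s = simulate_bscan(p, seed=seed, diseased=True)
            cysts = s.mask.labels == CYST
            assert flood_fill_components(cysts) == 2

    def test_class_completeness_over_diseased_samples(self, default_params):
        seen = set()
        for seed in range(50):
            s = simulate_bscan(default_params, seed=seed, diseased=True)
            seen.update(np.unique(s.mask.labels).tolist())
        assert seen == set(range(14))

    def test_learned_mask_has_no_cysts(self, default_params):
        s = simulate_bscan(
            dataclasses.replace(default_params, cyst_count_range=(2, 3)),
            seed=2, diseased=True,
        )
        learned = s.learned_mask()
        assert not (learned.labels == CYST).any()
        # only former cyst pixels changed
        changed = learned.labels != s.mask.labels
        assert (s.mask.labels[changed] == CYST).all()

    @pytest.mark.parametrize(
        "field,value",
        [
            ("layer_thickness", (0, 5, 6, 5, 5, 4, 2, 3, 3, 4)),
            ("speckle", -0.1),
            ("disease_prevalence", 1.5),
            ("top_margin", 60.0),
            ("cyst_count_range", (3, 1)),
        ],
    )
    def test_invalid_params_rejected(self, default_params, field, value):
        p = dataclasses.replace(default_params, **{field: value})
        with pytest.raises(ParameterError):
            p.validate()


class TestMakeDataset:
    def test_split_sizes_and_leakage(self, small_params, tmp_path):
        man = make_dataset(small_params, n_patients=10, scans_per_patient=2,
                           labeled_fraction=1.0, seed=0, out_dir=tmp_path)
        by_split = {s: set(man.patients(s)) for s in ("train", "val", "test")}
        assert (len(by_split["train"]), len(by_split["val"]), len(by_split["test"])) \
            == (8, 1, 1)
        assert not (by_split["train"] & by_split["val"])
        assert not (by_split["train"] & by_split["test"])
        assert not (by_split["val"] & by_split["test"])
        man.validate()

    def test_record_count_matches_files_on_disk(self, small_params, tmp_path):
        man = make_dataset(small_params, n_patients=20, scans_per_patient=3,
                           labeled_fraction=0.5, seed=1, out_dir=tmp_path)
        assert len(man.records) == 60
        assert len(list((tmp_path / "images").glob("*.png"))) == 60
        n_labeled = sum(r.labeled for r in man.records)
        assert len(list((tmp_path / "masks").glob("*.png"))) == n_labeled

    def test_full_labeled_fraction(self, small_params, tmp_path):
        man = make_dataset(small_params, n_patients=10, scans_per_patient=1,
                           labeled_fraction=1.0, seed=2, out_dir=tmp_path)
        assert all(r.labeled for r in man.select(split="train"))

    def test_unlabeled_records_carry_no_annotations(self, small_params, tmp_path):
        man = make_dataset(small_params, n_patients=12, scans_per_patient=2,
                           labeled_fraction=0.5, seed=3, out_dir=tmp_path)
        unl = man.select(split="train", labeled=False)
        assert unl and all(
            r.mask_path is None and r.boundaries_path is None for r in unl
        )

    def test_zero_labeled_patients_rejected(self, small_params, tmp_path):
        with pytest.raises(ParameterError):
            make_dataset(small_params, n_patients=10, scans_per_patient=1,
                         labeled_fraction=0.01, seed=0, out_dir=tmp_path)

    def test_test_split_mixes_disease(self, small_params, tmp_path):
        man = make_dataset(small_params, n_patients=10, scans_per_patient=4,
                           labeled_fraction=1.0, seed=4, out_dir=tmp_path)
        flags = {r.diseased for r in man.select(split="test")}
        assert flags == {True, False}

    def test_benchmark_dataset_counts(self, small_params, tmp_path):
        man = make_benchmark_dataset(small_params, seed=0, out_dir=tmp_path)
        assert len(man.select(split="train", labeled=True)) == 8
        assert len(man.select(split="train", labeled=False)) == 200
        assert len(man.select(split="test")) == 30
        man.validate()

    def test_roundtrip_manifest_io(self, small_params, tmp_path):
        from octseg.dataio import DatasetManifest

        man = make_dataset(small_params, n_patients=10, scans_per_patient=1,
                           labeled_fraction=1.0, seed=5, out_dir=tmp_path)
        reloaded = DatasetManifest.load(tmp_path / "manifest.jsonl")
        assert [r.scan_id for r in reloaded.records] == \
            [r.scan_id for r in man.records]
        rec = reloaded.select(split="train", labeled=True)[0]
        img = reloaded.load_image(rec)
        assert img.shape == (16, 16) and 0.0 <= img.min() and img.max() <= 1.0
        assert rec.scan_id in reloaded.access_log
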