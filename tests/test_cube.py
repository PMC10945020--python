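"""Hypercube calibration, segmentation, partitioning, extraction, RGB, ENVI I/O."""

import numpy as np
import pandas as pd
import pytest

from hsiatp.cube import (
    CalibrationError,
    Hypercube,
    ReferenceFrames,
    calibrate,
    extract_mean_spectra,
    partition_segments,
    read_envi,
    reconstruct_rgb,
    segment_foreground,
    spectra_matrix,
    write_envi,
)

WL5 = np.array([400.0, 500.0, 600.0, 700.0, 800.0])


def _cube(data, wl=WL5, kind="reflectance"):
    return Hypercube(np.asarray(data, dtype=float), wl, kind=kind)


class TestHypercube:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            Hypercube(np.zeros((4, 4, 3)), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            Hypercube(np.zeros((4, 4, 3)), np.array([3.0, 2.0, 1.0]))
        with pytest.raises(ValueError):
            Hypercube(np.zeros((4, 4, 3)), np.arange(3.0), kind="banana")

    def test_nearest_band_lookup_and_range_guard(self):
        c = _cube(np.zeros((2, 2, 5)))
        assert c.band_index(695) == 3  # 700 nm is nearest
        assert c.band_index(400) == 0
        with pytest.raises(ValueError):
            c.band_index(399)
        with pytest.raises(ValueError):
            c.band_index(900)


class TestCalibrate:
    def test_known_ratios(self, rng):
        dark = rng.uniform(50, 100, size=(4, 6, 5))
        white = dark + rng.uniform(500, 1000, size=(4, 6, 5))
        refs = ReferenceFrames(dark=dark, white=white)
        assert np.allclose(calibrate(_cube(white, kind="raw"), refs).data, 1.0)
        assert np.allclose(calibrate(_cube(dark, kind="raw"), refs).data, 0.0)
        mid = calibrate(_cube((dark + white) / 2, kind="raw"), refs)
        assert np.allclose(mid.data, 0.5)
        assert mid.kind == "reflectance"

    def test_affine_in_raw_signal(self, rng):
        """calibrate(a*r1 + (1-a)*white) == a*calibrate(r1) + (1-a)."""
        dark = np.full((3, 4, 5), 100.0)
        white = np.full((3, 4, 5), 4000.0)
        refs = ReferenceFrames(dark=dark, white=white)
        r1 = rng.uniform(200, 3000, size=(3, 4, 5))
        a = 0.37
        lhs = calibrate(_cube(a * r1 + (1 - a) * white, kind="raw"), refs).data
        rhs = a * calibrate(_cube(r1, kind="raw"), refs).data + (1 - a)
        assert np.allclose(lhs, rhs)

    def test_white_equals_dark_names_band(self):
        dark = np.zeros((2, 2, 5))
        white = np.ones((2, 2, 5))
        white[:, :, 2] = 0.0
        with pytest.raises(CalibrationError, match="600"):
            calibrate(_cube(np.ones((2, 2, 5)), kind="raw"),
                      ReferenceFrames(dark=dark, white=white))

    def test_reference_broadcasting_spectrum_vs_cube(self, rng):
        raw = rng.uniform(100, 4000, size=(3, 4, 5))
        dark_s, white_s = np.full(5, 100.0), np.full(5, 4000.0)
        full = calibrate(
            _cube(raw, kind="raw"),
            ReferenceFrames(dark=np.broadcast_to(dark_s, raw.shape),
                            white=np.broadcast_to(white_s, raw.shape)),
        )
        spec = calibrate(_cube(raw, kind="raw"), ReferenceFrames(dark=dark_s, white=white_s))
        assert np.allclose(full.data, spec.data)


class TestSegmentForeground:
    def test_strict_threshold(self):
        data = np.zeros((1, 3, 5))
        data[0, 0, 3] = 0.075   # exactly at threshold -> background
        data[0, 1, 3] = 0.076
        data[0, 2, 3] = 0.074
        mask = segment_foreground(_cube(data), 695.0, 0.075)
        assert mask.tolist() == [[False, True, False]]

    def test_requires_reflectance_kind(self):
        with pytest.raises(ValueError):
            segment_foreground(_cube(np.zeros((2, 2, 5)), kind="raw"))


class TestPartitionSegments:
    def test_horizontal_rectangle_equal_column_slices(self):
        mask = np.zeros((30, 160), dtype=bool)
        mask[10:20, 5:155] = True  # 10 rows x 150 cols
        labels = partition_segments(mask, 15)
        counts = np.bincount(labels.labels.ravel(), minlength=16)[1:]
        assert np.all(counts == 100)
        for seg in range(1, 16):  # each slice spans exactly 10 consecutive columns
            cols = np.unique(np.nonzero(labels.labels == seg)[1])
            assert len(cols) == 10 and cols.max() - cols.min() == 9

    def test_rotation_equivariance(self):
        mask = np.zeros((30, 160), dtype=bool)
        mask[10:20, 5:155] = True
        labels = partition_segments(mask, 15)
        labels_t = partition_segments(mask.T, 15)
        assert np.array_equal(labels_t.labels, labels.labels.T)

    def test_blob_segments_balanced_and_exhaustive(self, rng):
        # irregular blob: union of random disks along a line
        mask = np.zeros((60, 120), dtype=bool)
        rr, cc = np.mgrid[0:60, 0:120]
        for k in range(12):
            cy = 30 + rng.integers(-8, 9)
            cx = 10 + k * 9
            r = rng.integers(5, 12)
            mask |= (rr - cy) ** 2 + (cc - cx) ** 2 <= r**2
        labels = partition_segments(mask, 15)
        counts = np.bincount(labels.labels[mask], minlength=16)[1:]
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == mask.sum()           # no pixel lost
        assert np.all(labels.labels[~mask] == 0)    # none invented

    def test_two_components_partitioned_independently(self):
        mask = np.zeros((40, 100), dtype=bool)
        mask[5:15, 10:90] = True
        mask[25:35, 10:90] = True
        labels = partition_segments(mask, 15)
        assert labels.sausages() == [1, 2]
        for sid in (1, 2):
            counts = np.bincount(labels.labels[labels.sausage_ids == sid], minlength=16)[1:]
            assert counts.max() - counts.min() <= 1

    def test_too_small_component_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4, 2:7] = True  # 5 px < 15 segments
        with pytest.raises(ValueError, match="cannot form"):
            partition_segments(mask, 15)


class TestExtractMeanSpectra:
    def test_constant_cube_and_two_pixel_mean(self):
        data = np.zeros((2, 30, 5))
        spectrum_a = np.array([1.0, 2, 3, 4, 5])
        spectrum_b = np.array([3.0, 4, 5, 6, 7])
        data[0], data[1] = spectrum_a, spectrum_b
        mask = np.ones((2, 30), dtype=bool)
        labels = partition_segments(mask, 15)
        table = extract_mean_spectra(_cube(data), labels, reference={1: -6.0})
        X, wl = spectra_matrix(table)
        assert np.allclose(X, (spectrum_a + spectrum_b) / 2)  # each slice has one px per row
        assert np.array_equal(wl, WL5)
        assert np.all(table["atp_log10_molL"] == -6.0)
        assert list(table["segment_id"]) == list(range(1, 16))

    def test_missing_reference_id_rejected(self):
        mask = np.ones((2, 30), dtype=bool)
        labels = partition_segments(mask, 15)
        with pytest.raises(KeyError, match=r"\[1\]"):
            extract_mean_spectra(_cube(np.ones((2, 30, 5))), labels, reference={2: -5.0})

    def test_zero_noise_segments_equal_mixture_spectra(self, noise_free_run):
        """Generator oracle: every segment mean equals its sausage's mixture."""
        truth = noise_free_run["truth"]
        table = noise_free_run["table"]
        X, _ = spectra_matrix(table)
        lo, hi = -10.0, -4.0
        for sid, atp in truth.atp_values.items():
            t = (atp - lo) / (hi - lo)
            expected = (1 - t) * truth.endmembers["low"] + t * truth.endmembers["high"]
            rows = X[table["sausage_id"].to_numpy() == sid]
            assert np.max(np.abs(rows - expected)) < 1e-9


class TestReconstructRGB:
    def test_constant_cube_uniform_grey(self):
        img = reconstruct_rgb(_cube(np.full((4, 4, 5), 0.5)))
        assert np.allclose(img, 0.5)

    def test_red_channel_is_600nm_plane(self, rng):
        data = rng.uniform(0.1, 0.9, size=(5, 5, 5))
        img = reconstruct_rgb(_cube(data))
        plane = data[:, :, 2]  # 600 nm
        expected = (plane - plane.min()) / (plane.max() - plane.min())
        assert np.allclose(img[:, :, 0], expected)

    def test_high_atp_sausage_brighter_in_red(self, noise_free_run):
        truth = noise_free_run["truth"]
        img = reconstruct_rgb(noise_free_run["reflectance"], noise_free_run["mask"])
        red = img[:, :, 0]
        low_id = min(truth.atp_values, key=truth.atp_values.get)
        high_id = max(truth.atp_values, key=truth.atp_values.get)
        assert red[truth.sausage_mask(high_id)].mean() > red[truth.sausage_mask(low_id)].mean()


def test_envi_roundtrip(tmp_path, rng):
    data = rng.uniform(0, 1, size=(6, 7, 5))
    cube = _cube(data)
    write_envi(cube, tmp_path / "scene", dtype=np.float64)
    back = read_envi(tmp_path / "scene")
    assert np.array_equal(back.data, data)
    assert np.array_equal(back.wavelengths, WL5)
    assert back.kind == "reflectance"
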