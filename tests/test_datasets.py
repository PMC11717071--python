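import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hypercal.datasets import (
    DEFAULT_BRAND_PROTEIN,
    SpectralDataset,
    SyntheticSpec,
    ValidationError,
    generate_sparse_regression,
    generate_synthetic,
    read_spectra,
    train_test_split,
    write_spectra,
)


class TestRoundTrip:
    def test_toy_file_dimensions(self, toy_dataset, tmp_path):
        path = tmp_path / "toy.csv"
        write_spectra(toy_dataset, path)
        ds = read_spectra(path)
        assert (ds.n, ds.p) == (3, 5)
        np.testing.assert_array_equal(ds.ids, toy_dataset.ids)

    def test_write_read_identity(self, small_dataset, tmp_path):
        path = tmp_path / "ds.csv"
        write_spectra(small_dataset, path)
        ds = read_spectra(path)
        np.testing.assert_allclose(ds.reflectance, small_dataset.reflectance, atol=1e-12)
        np.testing.assert_allclose(ds.analyte, small_dataset.analyte, atol=1e-12)
        np.testing.assert_allclose(ds.wavelengths, small_dataset.wavelengths, atol=0)

    def test_full_size_round_trip(self, default_dataset, tmp_path):
        path = tmp_path / "full.csv"
        write_spectra(default_dataset, path)
        ds = read_spectra(path)
        assert (ds.n, ds.p) == (800, 125)
        np.testing.assert_array_equal(ds.reflectance, default_dataset.reflectance)

    def test_blank_analyte_cell_names_row(self, toy_dataset, tmp_path):
        path = tmp_path / "bad.csv"
        write_spectra(toy_dataset, path)
        lines = path.read_text().splitlines()
        parts = lines[2].split(",")
        parts[2] = ""  # blank the analyte of the second data row
        lines[2] = ",".join(parts)
        path.write_text("\n".join(lines))
        with pytest.raises(ValidationError, match="row 1"):
            read_spectra(path)

    def test_empty_dataset_writes_header_only(self, tmp_path):
        ds = SpectralDataset(
            wavelengths=np.array([400.0, 500.0]),
            reflectance=np.empty((0, 2)),
            analyte=np.empty(0),
            brand=np.empty(0, dtype=str),
            ids=np.empty(0, dtype=str),
        )
        path = tmp_path / "empty.csv"
        write_spectra(ds, path)
        lines = [ln for ln in path.read_text().splitlines() if ln]
        assert len(lines) == 1
        assert lines[0].startswith("id,brand,protein_g_per_100g")

    def test_wavelength_headers_keep_six_significant_digits(self, tmp_path):
        wl = np.linspace(400.123456, 999.987654, 4)
        ds = SpectralDataset(wl, np.ones((2, 4)), [1.0, 2.0], ["a", "b"], ["x", "y"])
        path = tmp_path / "wl.csv"
        write_spectra(ds, path)
        back = read_spectra(path)
        np.testing.assert_allclose(back.wavelengths, wl, rtol=1e-12)


class TestValidation:
    def test_non_monotone_wavelengths_rejected(self):
        with pytest.raises(ValidationError, match="increasing"):
            SpectralDataset([500.0, 400.0], np.ones((1, 2)), [1.0], ["a"], ["x"])

    def test_nonpositive_analyte_rejected(self):
        with pytest.raises(ValidationError, match="analyte"):
            SpectralDataset([400.0, 500.0], np.ones((1, 2)), [0.0], ["a"], ["x"])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="unique"):
            SpectralDataset([400.0, 500.0], np.ones((2, 2)), [1.0, 2.0], ["a", "a"], ["x", "x"])


class TestGenerator:
    def test_default_design_is_800_by_125(self, default_dataset):
        assert (default_dataset.n, default_dataset.p) == (800, 125)
        assert default_dataset.wavelengths[0] == 400.0
        assert default_dataset.wavelengths[-1] == 1000.0
        # brand-level analyte means sit at the reference protein values
        means = [default_dataset.analyte[default_dataset.brand == f"brand{i+1}"].mean()
                 for i in range(5)]
        np.testing.assert_allclose(means, DEFAULT_BRAND_PROTEIN, atol=0.2)

    def test_zero_noise_spectra_identical_within_brand(self):
        spec = SyntheticSpec(
            rois_per_sample=1, baseline_drift_sd=0, roi_noise_sd=0,
            sample_scale_sd=0, analyte_jitter_sd=0, pigment_depth_sd=0, seed=5,
        )
        ds = generate_synthetic(spec)
        for b in np.unique(ds.brand):
            block = ds.reflectance[ds.brand == b]
            assert np.ptp(block, axis=0).max() == 0.0

    def test_seed_determinism(self):
        spec = SyntheticSpec(samples_per_brand=3, rois_per_sample=2, seed=9)
        a = generate_synthetic(spec)
        b = generate_synthetic(spec)
        np.testing.assert_array_equal(a.reflectance, b.reflectance)
        c = generate_synthetic(SyntheticSpec(samples_per_brand=3, rois_per_sample=2, seed=10))
        assert not np.array_equal(a.reflectance, c.reflectance)

    def test_band_depth_affine_in_analyte(self):
        """With noise off, absorption depth at a band center is affine in analyte."""
        spec = SyntheticSpec(
            rois_per_sample=1, samples_per_brand=1, baseline_drift_sd=0,
            roi_noise_sd=0, sample_scale_sd=0, analyte_jitter_sd=0,
            pigment_depth_sd=0, seed=0,
        )
        ds = generate_synthetic(spec)
        center_idx = int(np.argmin(np.abs(ds.wavelengths - 962.0)))
        depth = -ds.reflectance[:, center_idx]
        A = np.c_[ds.analyte, np.ones(ds.n)]
        resid = depth - A @ np.linalg.lstsq(A, depth, rcond=None)[0]
        assert np.abs(resid).max() < 1e-8

    def test_sparse_regression_snr(self):
        X, y = generate_sparse_regression(5000, 20, [1, 5], snr=20.0, seed=0)
        signal = X[:, [1, 5]].sum(axis=1)
        noise = y - signal
        assert signal.var() / noise.var() == pytest.approx(20.0, rel=0.1)


class TestSplit:
    def test_seven_three_split_sizes(self, default_dataset):
        train, test = train_test_split(default_dataset, ratio=0.7, seed=0)
        assert (train.n, test.n) == (560, 240)
        for b in np.unique(default_dataset.brand):
            assert (train.brand == b).sum() == 112
            assert (test.brand == b).sum() == 48

    def test_half_split_is_disjoint(self):
        ds = SpectralDataset(
            wavelengths=[400.0, 500.0],
            reflectance=np.arange(20.0).reshape(10, 2),
            analyte=np.arange(1.0, 11.0),
            brand=np.array(["a"] * 10),
            ids=np.array([f"s{i}" for i in range(10)]),
        )
        train, test = train_test_split(ds, ratio=0.5, seed=1, stratify=False)
        assert (train.n, test.n) == (5, 5)
        assert not set(train.ids) & set(test.ids)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), ratio=st.floats(0.1, 0.9))
    def test_split_partitions_ids(self, seed, ratio):
        ds = generate_synthetic(
            SyntheticSpec(samples_per_brand=4, rois_per_sample=2, n_bands=10, seed=3))
        train, test = train_test_split(ds, ratio=ratio, seed=seed)
        assert set(train.ids) | set(test.ids) == set(ds.ids)
        assert not set(train.ids) & set(test.ids)

    def test_tiny_brand_rejected_under_stratification(self):
        ds = SpectralDataset(
            wavelengths=[400.0, 500.0],
            reflectance=np.ones((3, 2)),
            analyte=[1.0, 2.0, 3.0],
            brand=np.array(["a", "a", "b"]),
            ids=np.array(["x", "y", "z"]),
        )
        with pytest.raises(ValueError, match="brand 'b'"):
            train_test_split(ds, ratio=0.5, seed=0, stratify=True)

    def test_bad_ratio_rejected(self, toy_dataset):
        with pytest.raises(ValueError, match="ratio"):
            train_test_split(toy_dataset, ratio=1.5)
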