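"""Handcrafted feature registry, extraction, and Z-score scaling."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import oodhar as oh
from oodhar.features import CHANNEL_NAMES, RepresentationMatrix
from oodhar.harmonize import WINDOW_SAMPLES, WindowSet
from oodhar.synthgen import ConfigurationError


def _windowset_from_values(values):
    n = len(values)
    return WindowSet(values, np.full(n, "walk", dtype=object),
                     np.full(n, "s", dtype=object), np.full(n, "D", dtype=object),
                     np.array([f"D/s/{i}" for i in range(n)], dtype=object))


def _window_with_channels(x=None, y=None, z=None):
    vals = np.zeros((1, WINDOW_SAMPLES, 4))
    for c, sig in enumerate((x, y, z)):
        if sig is not None:
            vals[0, :, c] = sig
    vals[0, :, 3] = np.linalg.norm(vals[0, :, :3], axis=1)
    return _windowset_from_values(vals)


class TestRegistry:
    def test_default_has_48_entries_and_192_total(self):
        reg = oh.build_registry()
        assert len(reg.entries) == 48
        assert oh.N_FEATURES == 48 * 4 == 192

    def test_family_exclusion_breaks_contract(self):
        with pytest.raises(ConfigurationError):
            oh.build_registry({"families": ("statistical", "temporal")})
        with pytest.raises(ConfigurationError):
            oh.build_registry({"families": ("statistical", "wavelet")})

    def test_order_is_stable(self, windowset):
        a = oh.extract_features(windowset.select(np.arange(3)))
        b = oh.extract_features(windowset.select(np.arange(3)))
        assert a.dim_names == b.dim_names
        names = oh.build_registry().names
        assert a.dim_names[:48] == tuple(f"x__{n}" for n in names)

    def test_no_per_coefficient_or_wavelet_features(self):
        names = " ".join(oh.build_registry().names).lower()
        for banned in ("mfcc", "lpcc", "wavelet", "ecdf", "histogram"):
            assert banned not in names


class TestExtraction:
    def test_output_width_is_192(self, windowset):
        rep = oh.extract_features(windowset.select(np.arange(5)))
        assert rep.values.shape == (5, 192)
        assert rep.source == "handcrafted"

    def test_all_zero_window_degenerate_values(self):
        rep = oh.extract_features(_windowset_from_values(np.zeros((1, 250, 4))))
        assert np.all(np.isfinite(rep.values))
        by_name = dict(zip(rep.dim_names, rep.values[0]))
        assert by_name["x__mean"] == 0.0
        assert by_name["x__variance"] == 0.0
        assert by_name["x__zero_crossing_rate"] == 0.0
        assert by_name["x__spectral_entropy"] == 0.0
        assert by_name["x__dominant_frequency"] == 0.0

    def test_sine_dominant_frequency(self):
        t = np.arange(WINDOW_SAMPLES) / 50.0
        ws = _window_with_channels(x=np.sin(2 * np.pi * 2.0 * t))
        rep = oh.extract_features(ws)
        by_name = dict(zip(rep.dim_names, rep.values[0]))
        assert by_name["x__dominant_frequency"] == pytest.approx(2.0, abs=0.1)

    def test_constant_offset_has_zero_dominant_frequency(self):
        ws = _window_with_channels(z=np.full(WINDOW_SAMPLES, 9.81))
        rep = oh.extract_features(ws)
        by_name = dict(zip(rep.dim_names, rep.values[0]))
        assert by_name["z__dominant_frequency"] == 0.0
        assert by_name["z__mean"] == pytest.approx(9.81)

    def test_extraction_is_pure(self, windowset):
        sub = windowset.select(np.arange(4))
        a = oh.extract_features(sub).values
        b = oh.extract_features(sub).values
        assert np.array_equal(a, b)

    def test_magnitude_features_rotation_invariant(self, rng):
        raw = rng.normal(size=(3, 250, 3)) + [0.0, 0.0, 9.81]
        R = Rotation.from_rotvec([0.9, 0.2, -0.5]).as_matrix()

        def with_mag(x):
            mag = np.linalg.norm(x, axis=2, keepdims=True)
            return np.concatenate([x, mag], axis=2)

        f1 = oh.extract_features(_windowset_from_values(with_mag(raw)))
        f2 = oh.extract_features(_windowset_from_values(with_mag(raw @ R.T)))
        mag_cols = [i for i, n in enumerate(f1.dim_names) if n.startswith("mag__")]
        assert len(mag_cols) == 48
        assert np.allclose(f1.values[:, mag_cols], f2.values[:, mag_cols],
                           atol=1e-6)
        # axis-channel features do change under rotation
        assert not np.allclose(f1.values[:, :48], f2.values[:, :48], atol=1e-3)

    def test_malformed_window_shape_rejected(self, windowset):
        ws = windowset.select(np.arange(2))
        ws.values = ws.values[:, :100, :]
        with pytest.raises(ValueError):
            oh.extract_features(ws)


class TestScaler:
    def _rep(self, cols):
        cols = np.asarray(cols, dtype=float)
        names = tuple(f"f{i}" for i in range(cols.shape[1]))
        return RepresentationMatrix(cols, names, "embedding")

    def test_unit_column_example(self):
        rep = self._rep([[1.0], [2.0], [3.0]])
        scaled = oh.apply_scaler(oh.fit_scaler(rep), rep)
        assert np.allclose(scaled.values[:, 0], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_column_maps_to_zero(self):
        rep = self._rep([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        scaled = oh.apply_scaler(oh.fit_scaler(rep), rep)
        assert np.all(scaled.values[:, 0] == 0.0)

    def test_train_columns_centered(self, handcrafted):
        scaler = oh.fit_scaler(handcrafted)
        scaled = oh.apply_scaler(scaler, handcrafted)
        assert np.all(np.abs(scaled.values.mean(axis=0)) < 1e-9)
        sds = scaled.values.std(axis=0)
        assert np.all((np.abs(sds - 1) < 1e-6) | (sds == 0.0))

    def test_inverse_recovers_non_constant_columns(self, rng):
        rep = self._rep(rng.normal(size=(20, 6)))
        scaler = oh.fit_scaler(rep)
        back = oh.inverse_scale(scaler, oh.apply_scaler(scaler, rep))
        assert np.allclose(back.values, rep.values, atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        scaler = oh.fit_scaler(self._rep([[1.0], [2.0]]))
        with pytest.raises(ValueError):
            oh.apply_scaler(scaler, self._rep([[1.0, 2.0]]))


class TestRepresentationIO:
    def test_round_trip(self, tmp_path, handcrafted):
        sub = RepresentationMatrix(handcrafted.values[:5], handcrafted.dim_names,
                                   "handcrafted")
        path = tmp_path / "rep.tsv"
        oh.write_representation(sub, path)
        back = oh.read_representation(path)
        assert back.source == "handcrafted"
        assert back.dim_names == sub.dim_names
        assert np.allclose(back.values, sub.values, atol=1e-12)

    def test_scaler_round_trip(self, tmp_path, handcrafted):
        scaler = oh.fit_scaler(handcrafted)
        oh.write_scaler(scaler, tmp_path / "scaler.tsv")
        back = oh.read_scaler(tmp_path / "scaler.tsv")
        assert np.allclose(back.mean, scaler.mean)
        assert np.allclose(back.sd, scaler.sd)
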