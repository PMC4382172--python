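"""Spectral I/O, replicate averaging, regridding and smoothing."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ovicolor import (
    Spectrum,
    SpectrumError,
    WavelengthGrid,
    average_replicates,
    pad_sensitivity,
    read_spectra,
    regrid,
    triangular_smooth,
    write_spectra,
)


def make_spec(values, wl=None, kind="reflectance", **meta):
    wl = np.arange(300.0, 701.0) if wl is None else np.asarray(wl, float)
    v = np.full(wl.size, values, float) if np.isscalar(values) else np.asarray(values, float)
    return Spectrum(wl, v, kind=kind, meta=meta)


class TestSpectrumValidation:
    def test_rejects_descending_wavelengths(self):
        with pytest.raises(SpectrumError, match="strictly increasing"):
            Spectrum(np.array([700.0, 500.0, 300.0]), np.ones(3))

    def test_rejects_out_of_band_wavelengths(self):
        with pytest.raises(SpectrumError, match="within"):
            Spectrum(np.array([100.0, 400.0]), np.ones(2))

    def test_rejects_negative_reflectance_and_nonfinite(self):
        wl = np.array([400.0, 500.0])
        with pytest.raises(SpectrumError):
            Spectrum(wl, np.array([0.5, -0.1]))
        with pytest.raises(SpectrumError):
            Spectrum(wl, np.array([0.5, np.nan]))


class TestReadSpectra:
    def test_wide_dialect_parses_header_metadata(self):
        text = "wl\te1_c1_blunt_1\te1_c1_blunt_2\n400\t0.1\t0.2\n500\t0.3\t0.4\n"
        specs = read_spectra(io.StringIO(text), dialect="wide")
        assert len(specs) == 2
        assert specs[0].meta["egg_id"] == "e1"
        assert specs[0].meta["clutch_id"] == "c1"
        assert specs[1].meta["replicate"] == "2"
        assert np.array_equal(specs[0].wavelengths, [400.0, 500.0])

    def test_long_dialect(self):
        text = "id,wavelength,value\na,400,0.1\na,500,0.2\nb,400,0.3\nb,500,0.4\n"
        specs = read_spectra(io.StringIO(text), dialect="long")
        assert [s.meta["egg_id"] for s in specs] == ["a", "b"]
        assert specs[1].values[1] == pytest.approx(0.4)

    def test_descending_wavelengths_rejected(self):
        text = "wl\ta\n700\t0.1\n300\t0.2\n"
        with pytest.raises(SpectrumError, match="increasing"):
            read_spectra(io.StringIO(text), dialect="wide")

    def test_percent_values_rescaled_to_proportion(self):
        text = "wl\ta\n400\t5\n500\t95\n"
        (s,) = read_spectra(io.StringIO(text), dialect="wide")
        assert np.allclose(s.values, [0.05, 0.95])

    def test_percent_override(self):
        text = "wl\ta\n400\t0.5\n500\t1.5\n"
        (s,) = read_spectra(io.StringIO(text), dialect="wide", percent=True)
        assert np.allclose(s.values, [0.005, 0.015])

    def test_non_numeric_cell_names_location(self):
        text = "wl\ta\n400\t0.1\n500\tbogus\n"
        with pytest.raises(SpectrumError, match="'a'"):
            read_spectra(io.StringIO(text), dialect="wide")

    def test_write_read_roundtrip(self, tmp_path):
        specs = [make_spec(0.3, wl=[400, 500, 600], egg_id="e1", clutch_id="c1"),
                 make_spec(0.6, wl=[400, 500, 600], egg_id="e2", clutch_id="c1")]
        path = tmp_path / "w.tsv"
        write_spectra(specs, path)
        back = read_spectra(path, dialect="wide")
        assert len(back) == 2
        assert np.allclose(back[0].values, 0.3)
        assert back[1].meta["clutch_id"] == "c1"


class TestAverageReplicates:
    def test_mean_of_identical_spectra_is_identity(self):
        specs = [make_spec(0.3, egg_id="e", clutch_id="c", replicate=i) for i in range(9)]
        (out,) = average_replicates(specs)
        assert np.allclose(out.values, 0.3)
        assert out.meta["n_averaged"] == 9
        assert "replicate" not in out.meta

    def test_pointwise_mean(self):
        specs = [make_spec(0.2, egg_id="e", clutch_id="c"),
                 make_spec(0.4, egg_id="e", clutch_id="c")]
        (out,) = average_replicates(specs)
        assert np.allclose(out.values, 0.3)

    def test_noise_averages_toward_truth(self, rng):
        n = 400
        specs = [make_spec(np.clip(0.3 + rng.normal(0, 0.05, 401), 0, None),
                           egg_id="e", clutch_id="c") for _ in range(n)]
        (out,) = average_replicates(specs)
        se = 0.05 / np.sqrt(n)
        assert np.all(np.abs(out.values - 0.3) < 6 * se)

    def test_permutation_invariance(self, rng):
        specs = [make_spec(rng.uniform(0, 1, 401), egg_id="e", clutch_id="c")
                 for _ in range(5)]
        (a,) = average_replicates(specs)
        (b,) = average_replicates(specs[::-1])
        # identical up to float summation order
        assert np.allclose(a.values, b.values, rtol=0, atol=1e-12)

    def test_mixed_grids_rejected(self):
        specs = [make_spec(0.3, wl=[400, 500], egg_id="e", clutch_id="c"),
                 make_spec(0.3, wl=[400, 600], egg_id="e", clutch_id="c")]
        with pytest.raises(SpectrumError, match="regrid"):
            average_replicates(specs)


class TestRegrid:
    def test_identity_on_target_grid(self):
        s = make_spec(0.5)
        out = regrid(s, WavelengthGrid())
        assert np.array_equal(out.values, s.values)

    def test_linear_midpoint(self):
        s = Spectrum(np.array([400.0, 500.0]), np.array([0.0, 1.0]))
        out = regrid(s, WavelengthGrid(450, 460, 10))
        assert out.values[0] == pytest.approx(0.5)

    def test_roundtrip_at_original_knots(self, rng):
        wl = np.arange(300.0, 701.0, 5.0)
        s = Spectrum(wl, rng.uniform(0, 1, wl.size))
        fine = regrid(s, WavelengthGrid(300, 700, 1))
        back = regrid(fine, WavelengthGrid(300, 700, 5))
        assert np.allclose(back.values, s.values)

    def test_idempotent(self, rng):
        s = make_spec(rng.uniform(0, 1, 401))
        g = WavelengthGrid(350, 650, 2)
        once = regrid(s, g)
        twice = regrid(once, g)
        assert np.array_equal(once.values, twice.values)

    def test_no_extrapolation(self):
        s = Spectrum(np.array([400.0, 500.0]), np.array([0.0, 1.0]))
        with pytest.raises(SpectrumError, match="outside"):
            regrid(s, WavelengthGrid(300, 700, 1))


class TestPadSensitivity:
    def test_pad_uv_region_with_zero(self):
        wl = np.arange(330.0, 701.0)
        s = Spectrum(wl, np.ones(wl.size), kind="sensitivity")
        out = pad_sensitivity(s, (300.0, 330.0), 0.0)
        assert out.wavelengths[0] == 300.0
        below = out.values[out.wavelengths < 330.0]
        assert np.all(below == 0.0)
        assert np.trapezoid(below, out.wavelengths[out.wavelengths < 330]) == 0.0

    def test_overlap_without_overwrite_rejected(self):
        s = make_spec(1.0, kind="sensitivity")
        with pytest.raises(SpectrumError, match="overwrite"):
            pad_sensitivity(s, (400.0, 450.0), 0.0)

    def test_overwrite_zeroes_region(self):
        s = make_spec(1.0, kind="sensitivity")
        out = pad_sensitivity(s, (300.0, 330.0), 0.0, overwrite=True)
        assert np.all(out.values[out.wavelengths <= 330.0] == 0.0)
        assert np.all(out.values[out.wavelengths > 330.0] == 1.0)

    def test_reflectance_rejected(self):
        with pytest.raises(SpectrumError, match="sensitivity"):
            pad_sensitivity(make_spec(1.0), (300, 330))


class TestTriangularSmooth:
    def test_constant_unchanged(self):
        s = make_spec(0.7)
        out = triangular_smooth(s, 30.0)
        assert np.allclose(out.values, 0.7, atol=1e-12)

    def test_delta_becomes_triangle_with_unit_mass(self):
        v = np.zeros(401)
        v[200] = 1.0
        out = triangular_smooth(make_spec(v), 30.0)
        support = np.nonzero(out.values)[0]
        # base ~30 nm: nonzero within +-14 of the spike on a 1-nm grid
        assert support.min() >= 200 - 15 and support.max() <= 200 + 15
        assert out.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.argmax(out.values) == 200

    def test_affine_preserved_in_interior(self):
        wl = np.arange(300.0, 701.0)
        ramp = (wl - 300.0) / 400.0
        out = triangular_smooth(Spectrum(wl, ramp), 30.0)
        interior = slice(20, -20)
        assert np.allclose(out.values[interior], ramp[interior], atol=1e-9)

    def test_integral_conserved_for_interior_support(self, rng):
        v = np.zeros(401)
        v[100:300] = rng.uniform(0, 1, 200)
        out = triangular_smooth(make_spec(v), 30.0)
        assert out.values.sum() == pytest.approx(v.sum(), abs=1e-9)

    def test_width_below_two_steps_warns_and_returns_input(self):
        s = make_spec(0.5)
        with pytest.warns(UserWarning, match="unchanged"):
            out = triangular_smooth(s, 1.5)
        assert out is s

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=30, max_size=80),
           st.floats(4.0, 60.0))
    def test_output_within_input_range(self, values, width):
        wl = 300.0 + np.arange(len(values))
        out = triangular_smooth(Spectrum(wl, np.array(values)), width)
        assert out.values.min() >= min(values) - 1e-12
        assert out.values.max() <= max(values) + 1e-12
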