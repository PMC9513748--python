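"""Band intensities, heat maps, hotspot localization, co-localization."""

import numpy as np
import pytest

from sersev.core import SpectralGrid
from sersev.errors import DegenerateSpectrumError
from sersev.raman_map import (
    IntensityMap,
    MapScan,
    band_intensity,
    build_intensity_map,
    colocalization,
    locate_hotspot,
    read_map_scan,
    write_map_scan,
)
from sersev.synthetic import Peak, SubtypeTemplate, generate_map_scan

GRID = SpectralGrid(553.0, 1581.0, 1023)


def lorentzian(wn, center, height, width):
    return height * width**2 / ((wn - center) ** 2 + width**2)


class TestBandIntensity:
    def test_zero_spectrum_gives_zero(self):
        assert band_intensity(np.zeros(GRID.n_points), GRID, 1123.0, 8.0, subtract_baseline=False) == 0.0

    def test_unit_rectangle_integrates_to_window_width(self):
        grid = SpectralGrid(600.0, 855.0, 256)  # spacing exactly 1 cm^-1
        y = np.zeros(256)
        center, hw = 700.0, 8.0
        wn = grid.wavenumbers
        y[(wn >= center - hw) & (wn <= center + hw)] = 1.0
        out = band_intensity(y, grid, center, hw, subtract_baseline=False)
        assert out == pytest.approx(2 * hw)

    def test_lorentzian_matches_dense_quadrature(self):
        y = lorentzian(GRID.wavenumbers, 1270.0, 2.0, 7.0)
        out = band_intensity(y, GRID, 1270.0, 8.0, subtract_baseline=False)
        dense = np.linspace(1270.0 - 8, 1270.0 + 8, 200001)
        ref = np.trapezoid(lorentzian(dense, 1270.0, 2.0, 7.0), dense)
        assert out == pytest.approx(ref, rel=5e-3)

    def test_baseline_subtraction_removes_broad_background(self):
        wn = GRID.wavenumbers
        y = lorentzian(wn, 1341.0, 1.5, 6.0) + 2.0 + 0.001 * (wn - wn[0])
        with_bg = band_intensity(y, GRID, 1341.0, 8.0, subtract_baseline=True)
        clean = band_intensity(
            lorentzian(wn, 1341.0, 1.5, 6.0), GRID, 1341.0, 8.0, subtract_baseline=False
        )
        assert with_bg == pytest.approx(clean, rel=0.1)

    def test_window_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            band_intensity(np.zeros(GRID.n_points), GRID, 560.0, 20.0)


def template():
    return SubtypeTemplate(
        "em",
        peaks=(
            Peak(1123.0, 1.0, 7.0),
            Peak(1270.0, 0.7, 6.0),
            Peak(1341.0, 0.8, 6.0),
        ),
    )


class TestBuildIntensityMap:
    def test_identical_spectra_give_constant_map(self):
        base = lorentzian(GRID.wavenumbers, 1123.0, 1.0, 7.0)
        data = np.tile(base, (4, 5, 1))
        scan = MapScan(np.arange(5) * 0.1, np.arange(4) * 0.1, 0.1, GRID, data)
        imap = build_intensity_map(scan, 1123.0, 8.0, subtract_baseline=False)
        assert np.ptp(imap.values) == pytest.approx(0.0, abs=1e-12)

    def test_single_bright_spectrum_is_map_maximum(self):
        base = lorentzian(GRID.wavenumbers, 1123.0, 1.0, 7.0)
        data = np.tile(base, (6, 6, 1))
        data[2, 4] *= 10.0
        scan = MapScan(np.arange(6) * 0.1, np.arange(6) * 0.1, 0.1, GRID, data)
        imap = build_intensity_map(scan, 1123.0, 8.0, subtract_baseline=False)
        assert np.unravel_index(np.argmax(imap.values), imap.values.shape) == (2, 4)

    def test_noise_free_emitter_map_decreases_radially(self):
        scan = generate_map_scan([(1.0, 1.0, 1.0)], template(), beam_sigma=0.5, step=0.1, extent=(0, 2, 0, 2))
        imap = build_intensity_map(scan, 1123.0, 8.0, subtract_baseline=False)
        cy, cx = 10, 10
        r = np.hypot(*np.meshgrid(np.arange(21) - cx, np.arange(21) - cy))
        order = np.argsort(r.ravel())
        v = imap.values.ravel()[order]
        # intensity never increases with radius beyond sampling tolerance
        assert np.all(np.diff(v) <= 1e-6 * v.max() + np.where(np.diff(r.ravel()[order]) > 0, v.max(), 0))
        assert np.unravel_index(np.argmax(imap.values), imap.values.shape) == (cy, cx)

    def test_transposition_commutes(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0.5, 1.5, size=(4, 4, 1))[:, :, [0] * GRID.n_points] * lorentzian(
            GRID.wavenumbers, 1123.0, 1.0, 7.0
        )
        xs = np.arange(4) * 0.1
        scan = MapScan(xs, xs, 0.1, GRID, data)
        scan_t = MapScan(xs, xs, 0.1, GRID, np.transpose(data, (1, 0, 2)))
        a = build_intensity_map(scan, 1123.0, 8.0, subtract_baseline=False).values
        b = build_intensity_map(scan_t, 1123.0, 8.0, subtract_baseline=False).values
        np.testing.assert_allclose(a.T, b, atol=1e-12)


class TestLocateHotspot:
    def test_delta_map_located_exactly(self):
        values = np.zeros((9, 9))
        values[6, 2] = 1.0
        imap = IntensityMap(values, 1123.0, 8.0, np.arange(9) * 0.1, np.arange(9) * 0.1, 0.1)
        assert locate_hotspot(imap) == (pytest.approx(0.2), pytest.approx(0.6))

    def test_two_equal_maxima_tie_breaks_lexicographically(self):
        values = np.zeros((7, 7))
        values[1, 4] = values[4, 1] = 1.0  # far enough apart that no 3x3 window sees both
        imap = IntensityMap(values, 1123.0, 8.0, np.arange(7) * 0.1, np.arange(7) * 0.1, 0.1)
        x, y = locate_hotspot(imap)
        assert (y, x) == (pytest.approx(0.1), pytest.approx(0.4))

    def test_constant_map_rejected(self):
        imap = IntensityMap(np.ones((4, 4)), 1123.0, 8.0, np.arange(4) * 0.1, np.arange(4) * 0.1, 0.1)
        with pytest.raises(DegenerateSpectrumError):
            locate_hotspot(imap)

    def test_randomized_scenes_located_within_one_step(self):
        """Blurred emitter at random positions, band-level SNR 10."""
        tpl = template()
        rng = np.random.default_rng(5)
        hits = 0
        n_scenes = 20
        for s in range(n_scenes):
            x0, y0 = rng.uniform(0.5, 1.5, size=2)
            scan = generate_map_scan(
                [(float(x0), float(y0), 1.0)], tpl, beam_sigma=0.5, step=0.1,
                extent=(0, 2, 0, 2), noise_sigma=0.1, seed=2000 + s,
            )
            imap = build_intensity_map(scan, 1123.0, 8.0, subtract_baseline=False)
            hx, hy = locate_hotspot(imap)
            hits += abs(hx - x0) <= 0.1 + 1e-9 and abs(hy - y0) <= 0.1 + 1e-9
        assert hits >= 0.95 * n_scenes


class TestColocalization:
    def test_identical_maps_correlate_perfectly(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(6, 6))
        m = IntensityMap(v, 1123.0, 8.0, np.arange(6), np.arange(6), 1.0)
        m2 = IntensityMap(v.copy(), 1270.0, 8.0, np.arange(6), np.arange(6), 1.0)
        assert colocalization([m, m2])["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_negated_map_anticorrelates(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(6, 6))
        m = IntensityMap(v, 1123.0, 8.0, np.arange(6), np.arange(6), 1.0)
        m2 = IntensityMap(-v, 1270.0, 8.0, np.arange(6), np.arange(6), 1.0)
        assert colocalization([m, m2])["pearson_r"].iloc[0] == pytest.approx(-1.0)

    def test_same_emitter_bands_cocorrelate_under_noise(self):
        scan = generate_map_scan(
            [(1.0, 1.0, 1.0)], template(), beam_sigma=0.5, step=0.1,
            extent=(0, 2, 0, 2), noise_sigma=0.07, seed=99,
        )
        maps = [
            build_intensity_map(scan, c, 8.0, subtract_baseline=False)
            for c in (1123.0, 1270.0, 1341.0)
        ]
        assert (colocalization(maps)["pearson_r"] >= 0.7).all()


class TestMapScanIO:
    def test_round_trip(self, tmp_path):
        scan = generate_map_scan(
            [(0.5, 0.5, 1.0)], template(), beam_sigma=0.4, step=0.25,
            extent=(0, 1, 0, 1), noise_sigma=0.01, seed=7,
            grid=SpectralGrid(600, 855, 256),
        )
        path = tmp_path / "scan.csv"
        write_map_scan(scan, path)
        back = read_map_scan(path)
        assert back.step_width == scan.step_width
        np.testing.assert_array_equal(back.data, scan.data)
        np.testing.assert_allclose(back.x, scan.x)
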