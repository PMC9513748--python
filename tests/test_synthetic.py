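"""Synthetic cohort generator: determinism, structure, ground truth."""

import numpy as np
import pytest

from sersev.core import DEFAULT_GRID
from sersev.errors import ConfigError
from sersev.preprocess import preprocess_cohort
from sersev.synthetic import (
    DEFAULT_PEAK_LIBRARY,
    SimConfig,
    generate_cohort,
    generate_map_scan,
    make_subtype_template,
    sample_vesicle_spectrum,
)


class TestMakeSubtypeTemplate:
    def test_deterministic_under_seed(self):
        a = make_subtype_template("t", 7)
        b = make_subtype_template("t", 7)
        assert a == b

    def test_n_peaks_equal_to_library_uses_all(self):
        k = len(DEFAULT_PEAK_LIBRARY)
        tpl = make_subtype_template("t", 0, n_peaks=(k, k))
        assert {p.center for p in tpl.peaks} == set(DEFAULT_PEAK_LIBRARY)

    def test_n_peaks_beyond_library_rejected(self):
        k = len(DEFAULT_PEAK_LIBRARY)
        with pytest.raises(ConfigError):
            make_subtype_template("t", 0, n_peaks=(k + 1, k + 1))

    def test_templates_render_pairwise_distinct(self):
        rng = np.random.default_rng(0)
        rendered = np.vstack(
            [make_subtype_template(f"t{i}", rng).render() for i in range(100)]
        )
        d = np.linalg.norm(rendered[:, None, :] - rendered[None, :, :], axis=2)
        off_diag = d[~np.eye(100, dtype=bool)]
        assert off_diag.min() > 0.0


class TestSampleVesicleSpectrum:
    def test_noise_free_limit_renders_template_exactly(self):
        tpl = make_subtype_template("t", 1)
        rng = np.random.default_rng(0)
        spec = sample_vesicle_spectrum(
            tpl, rng, amp_sigma=0, height_sigma=0, shift_sd=0, baseline_amp=0, noise_sigma=0
        )
        np.testing.assert_array_equal(spec, tpl.render())

    def test_within_type_variation_below_between_type_distance(self):
        """Two draws of one type are closer (preprocessed) than draws of
        different types at default jitter."""
        rng = np.random.default_rng(1)
        tpl_a = make_subtype_template("a", 10)
        tpl_b = make_subtype_template("b", 11)
        cfg = SimConfig()
        kw = dict(
            amp_sigma=cfg.amp_sigma,
            height_sigma=cfg.height_sigma,
            shift_sd=cfg.shift_sd,
            baseline_amp=cfg.baseline_amp,
            noise_sigma=cfg.noise_sigma,
        )
        from sersev.preprocess import PreprocessConfig, preprocess_spectrum

        pc = PreprocessConfig()
        a1 = preprocess_spectrum(sample_vesicle_spectrum(tpl_a, rng, **kw), pc)
        a2 = preprocess_spectrum(sample_vesicle_spectrum(tpl_a, rng, **kw), pc)
        b1 = preprocess_spectrum(sample_vesicle_spectrum(tpl_b, rng, **kw), pc)
        assert np.linalg.norm(a1 - a2) < np.linalg.norm(a1 - b1)


class TestGenerateCohort:
    def test_structure_matches_configuration(self, small_default):
        cohorts, truth = small_default
        for fluid, cohort in cohorts.items():
            assert len(cohort.donors("GC")) == 15
            assert len(cohort.donors("control")) == 15
            counts = cohort.meta.groupby("donor_id").size()
            assert counts.between(20, 28).all()

    def test_ground_truth_covers_every_spectrum_exactly_once(self, small_default):
        cohorts, truth = small_default
        # fixtures are preprocessed but nothing was dropped, so ids match
        all_ids = sorted(sid for c in cohorts.values() for sid in c.spectrum_ids)
        table_ids = sorted(truth.table["spectrum_id"])
        assert table_ids == all_ids
        assert truth.table["spectrum_id"].is_unique

    def test_realized_unique_fraction_tracks_configuration(self):
        cohorts, truth = generate_cohort(SimConfig(spectra_per_sample=(20, 28)))
        cfg = SimConfig(spectra_per_sample=(20, 28))
        t = truth.table
        for fluid, frac in cfg.unique_fraction.items():
            gc = t[(t["fluid"] == fluid) & (t["group"] == "GC")]
            realized = (gc["uniqueness"] == "GC-unique").mean()
            n = len(gc)
            se = np.sqrt(frac * (1 - frac) / n)
            assert abs(realized - frac) <= 3 * se

    def test_null_configuration_mixes_groups(self):
        """unique_fraction 0 everywhere: both groups draw only shared
        types, so group labels carry no information."""
        cfg = SimConfig(
            spectra_per_sample=(8, 10),
            donors_per_group=6,
            unique_fraction={"tissue": 0.0, "blood": 0.0, "saliva": 0.0},
            control_unique_prob=0.0,
        )
        _, truth = generate_cohort(cfg)
        assert (truth.table["uniqueness"] == "shared").all()

    def test_byte_identical_rerun_under_master_seed(self):
        a_cohorts, a_truth = generate_cohort(SimConfig(spectra_per_sample=(8, 10), donors_per_group=4))
        b_cohorts, b_truth = generate_cohort(SimConfig(spectra_per_sample=(8, 10), donors_per_group=4))
        for fluid in a_cohorts:
            np.testing.assert_array_equal(
                a_cohorts[fluid].intensities, b_cohorts[fluid].intensities
            )
            assert a_cohorts[fluid].meta.equals(b_cohorts[fluid].meta)
        assert a_truth.table.equals(b_truth.table)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(unique_fraction={"tissue": 1.4, "blood": 0.4, "saliva": 0.1})

    def test_noise_dial_degrades_accuracy_in_expectation(self):
        """More additive noise -> lower end-to-end CV accuracy (averaged
        over seeds)."""
        from sersev.classify import cross_validate

        means = []
        for noise in (0.02, 0.6):
            accs = []
            for seed in (1, 2, 3):
                cfg = SimConfig(
                    spectra_per_sample=(8, 10),
                    donors_per_group=6,
                    noise_sigma=noise,
                    seed=seed,
                )
                cohorts, _ = generate_cohort(cfg)
                pp, _ = preprocess_cohort(cohorts["tissue"])
                y = (pp.meta["group"] == "GC").to_numpy(dtype=int)
                accs.append(cross_validate(pp.intensities, y, rounds=3, seed=seed).mean_accuracy)
            means.append(np.mean(accs))
        assert means[1] < means[0]


class TestGenerateMapScan:
    def test_single_central_emitter_peaks_at_center(self):
        tpl = make_subtype_template("t", 2)
        scan = generate_map_scan([(1.0, 1.0, 1.0)], tpl, beam_sigma=0.5, step=0.1, extent=(0, 2, 0, 2))
        total = scan.data.sum(axis=2)
        assert np.unravel_index(np.argmax(total), total.shape) == (10, 10)

    def test_vanishing_beam_sigma_confines_emitter_to_its_lattice_point(self):
        tpl = make_subtype_template("t", 2)
        scan = generate_map_scan(
            [(0.5, 0.5, 1.0)], tpl, beam_sigma=1e-4, step=0.1, extent=(0, 1, 0, 1)
        )
        total = scan.data.sum(axis=2)
        nz = np.argwhere(total > 1e-6 * total.max())
        assert nz.tolist() == [[5, 5]]

    def test_total_intensity_matches_gaussian_beam_normalization(self):
        """Summed beam weight over the lattice ~ 2*pi*sigma^2/step^2 per
        unit emitter amplitude (analytic Gaussian integral)."""
        tpl = make_subtype_template("t", 2)
        sigma, step = 0.3, 0.05
        scan = generate_map_scan(
            [(2.0, 2.0, 1.0), (1.0, 3.0, 2.0)], tpl, beam_sigma=sigma, step=step,
            extent=(0, 4, 0, 4),
        )
        base_sum = tpl.render().sum()
        expected = (1.0 + 2.0) * 2 * np.pi * sigma**2 / step**2 * base_sum
        assert scan.data.sum() == pytest.approx(expected, rel=0.01)

    def test_emitter_outside_extent_rejected(self):
        tpl = make_subtype_template("t", 2)
        with pytest.raises(ConfigError):
            generate_map_scan([(5.0, 0.5, 1.0)], tpl, extent=(0, 1, 0, 1))
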