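"""Phantom construction, one-tissue kinetics, rendering, cohort generation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from dualphase_pet.imaging_core import parse_frame_spec
from dualphase_pet.phantom_sim import (
    CohortConfig,
    KineticParams,
    LesionSpec,
    PhantomSpec,
    RegionDef,
    build_phantom,
    cortex_labels,
    default_phantom_spec,
    generate_cohort,
    mirror_labels,
    parametric_input_function,
    reference_region,
    render_dynamic_image,
    render_static,
    simulate_tac,
)
from dualphase_pet.tac_analysis import tac_peak, window_mean
from tests.conftest import COARSE_GRID


class TestBuildPhantom:
    def test_flip_and_label_swap_is_identity(self, coarse_spec, coarse_labels):
        assert np.array_equal(mirror_labels(coarse_labels, coarse_spec), coarse_labels)

    def test_midline_sphere_alone_is_flip_invariant(self):
        spec = PhantomSpec(
            (20, 20, 20),
            (4, 4, 4),
            (RegionDef(1, "pons", "midline", "sphere", ((0.0, 0.0, 0.0), 20.0)),),
        )
        labels = build_phantom(spec)
        assert labels.any()
        assert np.array_equal(np.flip(labels, axis=0), labels)

    def test_left_right_voxel_counts_equal(self, coarse_spec, coarse_labels):
        for r in coarse_spec.regions:
            if r.side != "left":
                continue
            partner = coarse_spec.label_by_name[
                r.name.replace("_left", "_right").replace("_L", "_R")
            ]
            assert (coarse_labels == r.label).sum() == (coarse_labels == partner).sum()

    def test_atlas_emulation_has_at_least_20_cortical_labels(self, coarse_labels, coarse_spec):
        census = set(np.unique(coarse_labels)) - {0}
        cx = cortex_labels(coarse_spec)
        cortical_present = (cx["left"] | cx["right"]) & census
        assert len(cortical_present) >= 20

    def test_overlapping_regions_raise_with_both_names(self):
        spec = PhantomSpec(
            (20, 20, 20),
            (4, 4, 4),
            (
                RegionDef(1, "a", "midline", "sphere", ((0.0, 0.0, 0.0), 20.0)),
                RegionDef(2, "b", "midline", "sphere", ((4.0, 0.0, 0.0), 20.0)),
            ),
        )
        with pytest.raises(ValueError, match="'b'.*'a'|'a'.*'b'"):
            build_phantom(spec)

    def test_reference_regions_resolve(self, coarse_spec):
        for name in ("cerebellum", "centrum_semiovale", "pons", "whole_brain_global_mean"):
            ref = reference_region(coarse_spec, name)
            assert ref.labels
        with pytest.raises(ValueError):
            reference_region(coarse_spec, "amygdala")


class TestInputFunction:
    def test_shape_constraints(self, fine_input_function):
        cp = fine_input_function
        assert cp.values[0] == 0.0
        assert np.all(cp.values >= 0)
        i = int(np.argmax(cp.values))
        assert cp.t_s[i] < 120.0  # early bolus peak
        d = np.diff(cp.values)
        assert np.all(d[:i] >= 0)
        assert np.all(d[i:] <= 1e-9)  # monotone-decaying tail


class TestSimulateTac:
    def test_zero_influx_gives_all_zero_tac(self, fine_input_function, paper_schedule):
        tac = simulate_tac(KineticParams(0.0, 0.05), fine_input_function, paper_schedule)
        assert np.allclose(tac.values, 0.0)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(-0.1, 0.05)
        with pytest.raises(ValueError):
            KineticParams(0.1, -0.05)

    def test_coarse_input_sampling_rejected(self, paper_schedule):
        cp = parametric_input_function(duration_s=3700.0, dt_s=2.0)
        with pytest.raises(ValueError, match="5x finer"):
            simulate_tac(KineticParams(0.2, 0.05), cp, paper_schedule)

    def test_convolution_matches_riemann_oracle(self, fine_input_function, paper_schedule):
        """Frame averages agree within 0.5% with a brute-force discrete
        convolution (rectangle rule on the 0.1-s grid)."""
        K1, k2 = 0.25, 0.05
        cp = fine_input_function
        dt_min = cp.dt_s / 60.0
        kernel = np.exp(-k2 * np.arange(cp.t_s.size) * dt_min)
        ct_oracle = K1 * signal.fftconvolve(cp.values, kernel)[: cp.t_s.size] * dt_min
        # rectangle-rule frame averages
        oracle = np.array(
            [
                ct_oracle[(cp.t_s >= s) & (cp.t_s < s + d)].mean()
                for s, d in paper_schedule.frames
            ]
        )
        tac = simulate_tac(KineticParams(K1, k2), cp, paper_schedule)
        scale = np.abs(oracle).max()
        assert np.all(np.abs(tac.values - oracle) <= 0.005 * scale)

    def test_blockade_lowers_late_window_but_not_first_frame(
        self, fine_input_function, paper_schedule
    ):
        base = simulate_tac(
            KineticParams(0.25, 0.05, 0.9, 0.0), fine_input_function, paper_schedule
        )
        blocked = simulate_tac(
            KineticParams(0.25, 0.05, 0.9, 0.5), fine_input_function, paper_schedule
        )
        assert window_mean(blocked, 1800, 3600) < window_mean(base, 1800, 3600)
        assert blocked.values[0] == pytest.approx(base.values[0], rel=0.01)

    def test_late_signal_decreases_monotonically_with_occupancy(
        self, fine_input_function, paper_schedule
    ):
        lates = [
            window_mean(
                simulate_tac(
                    KineticParams(0.25, 0.05, 0.9, o), fine_input_function, paper_schedule
                ),
                1800,
                3600,
            )
            for o in (0.0, 0.2, 0.4, 0.6, 0.8)
        ]
        assert np.all(np.diff(lates) < 0)

    def test_first_pass_nearly_occupancy_invariant(
        self, fine_input_function, paper_schedule
    ):
        def first_pass(o):
            tac = simulate_tac(
                KineticParams(0.25, 0.05, 0.9, o), fine_input_function, paper_schedule
            )
            return window_mean(tac, 0, 60)

        base = first_pass(0.0)
        for o in (0.2, 0.4, 0.6):
            assert abs(first_pass(o) - base) / base < 0.02
        assert abs(first_pass(0.8) - base) / base < 0.04

    def test_faster_washout_peaks_earlier(self, fine_input_function, paper_schedule):
        slow = simulate_tac(KineticParams(0.25, 0.05), fine_input_function, paper_schedule)
        fast = simulate_tac(KineticParams(0.25, 0.10), fine_input_function, paper_schedule)
        assert tac_peak(fast)[0] < tac_peak(slow)[0]


class TestRendering:
    def _tacs(self, labels, schedule, cp):
        present = sorted(set(np.unique(labels)) - {0})
        return {
            lab: simulate_tac(KineticParams(0.1 + 0.02 * i, 0.05), cp, schedule)
            for i, lab in enumerate(present)
        }

    def test_noise_free_unblurred_render_paints_exact_tac_values(
        self, coarse_labels, paper_schedule
    ):
        cp = parametric_input_function(duration_s=3700.0, dt_s=1.0)
        short = parse_frame_spec("2x300")
        tacs = self._tacs(coarse_labels, short, cp)
        img = render_dynamic_image(
            coarse_labels, tacs, 0.0, 0.0, 0, COARSE_GRID["voxel_size_mm"]
        )
        for lab, tac in tacs.items():
            region = img.voxels[coarse_labels == lab]
            assert np.allclose(region, tac.values[None, :])

    def test_same_seed_renders_identical_volumes(self, coarse_labels):
        kwargs = dict(
            psf_fwhm_mm=(6.6, 6.6, 5.1),
            noise_scale=2.0,
            voxel_size_mm=COARSE_GRID["voxel_size_mm"],
            duration_s=600.0,
        )
        uptake = {int(lab): 5.0 for lab in np.unique(coarse_labels) if lab > 0}
        a = render_static(coarse_labels, uptake, seed=17, **kwargs)
        b = render_static(coarse_labels, uptake, seed=17, **kwargs)
        assert np.array_equal(a.voxels, b.voxels)

    def test_noise_sd_scales_inversely_with_sqrt_frame_duration(self, coarse_labels):
        uptake = {int(lab): 8.0 for lab in np.unique(coarse_labels) if lab > 0}
        interior = coarse_labels == 7  # centrum semiovale: compact, interior
        sds = {}
        for dur in (5.0, 600.0):
            img = render_static(
                coarse_labels,
                uptake,
                psf_fwhm_mm=0.0,
                noise_scale=2.0,
                seed=3,
                voxel_size_mm=COARSE_GRID["voxel_size_mm"],
                duration_s=dur,
            )
            sds[dur] = np.std(img.voxels[interior])
        assert sds[5.0] / sds[600.0] == pytest.approx(np.sqrt(600.0 / 5.0), rel=0.1)

    def test_missing_label_tac_raises_with_label(self, coarse_labels, paper_schedule):
        cp = parametric_input_function(duration_s=3700.0, dt_s=1.0)
        short = parse_frame_spec("1x300")
        tacs = self._tacs(coarse_labels, short, cp)
        tacs.pop(11)  # drop the pons
        with pytest.raises(ValueError, match="11"):
            render_dynamic_image(
                coarse_labels, tacs, 0.0, 0.0, 0, COARSE_GRID["voxel_size_mm"]
            )

    def test_interior_regional_mean_survives_psf_blur(self):
        """PSF blurring conserves interior values: a compact region eroded
        by ~2 FWHM recovers its painted value within 1%. Uses the 2-mm
        grid so the erosion leaves an interior core."""
        from scipy import ndimage

        spec = default_phantom_spec()
        labels = build_phantom(spec)
        cereb = spec.label_by_name["cerebellum_left"]
        uptake = {int(lab): 5.0 for lab in np.unique(labels) if lab > 0}
        uptake[cereb] = 10.0
        img = render_static(
            labels,
            uptake,
            psf_fwhm_mm=(6.6, 6.6, 5.1),
            noise_scale=0.0,
            seed=0,
            voxel_size_mm=(2.0, 2.0, 2.0),
            duration_s=600.0,
        )
        core = ndimage.binary_erosion(labels == cereb, iterations=6)  # 12 mm
        assert core.any()
        assert img.voxels[core].mean() == pytest.approx(10.0, rel=0.01)


class TestLesionSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            LesionSpec(101, "up", 10.0, 0.2)
        with pytest.raises(ValueError):
            LesionSpec(101, "left", 10.0, 1.5)
        with pytest.raises(ValueError):
            LesionSpec(101, "left", -1.0, 0.2)

    def test_default_broad_radius_doubles_core(self):
        spec = LesionSpec(101, "left", 12.0, 0.2)
        assert spec.broad_radius == 24.0


class TestGenerateCohort:
    def test_default_cohort_has_29_truth_records_8_blocked(self, default_cohort):
        assert len(default_cohort.truth) == 29
        assert int(default_cohort.truth["blocked"].sum()) == 8

    def test_unblocked_only_cohort_has_no_occupancy(self):
        cohort = generate_cohort(
            CohortConfig(n_unblocked=3, n_blocked=0, **COARSE_GRID), seed=2
        )
        assert (cohort.truth["occupancy"] == 0).all()

    def test_same_seed_reproduces_truth_table(self):
        config = CohortConfig(n_unblocked=2, n_blocked=1, **COARSE_GRID)
        a = generate_cohort(config, seed=5)
        b = generate_cohort(config, seed=5)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(a.tac_table_suv, b.tac_table_suv)

    def test_subject_streams_stable_under_cohort_growth(self):
        small = generate_cohort(CohortConfig(n_unblocked=2, n_blocked=0, **COARSE_GRID), seed=5)
        big = generate_cohort(CohortConfig(n_unblocked=4, n_blocked=0, **COARSE_GRID), seed=5)
        pd.testing.assert_frame_equal(
            small.truth, big.truth.iloc[: len(small.truth)].reset_index(drop=True)
        )

    def test_unblocked_cortical_peaks_near_study_conditions(self, default_cohort):
        """Per-subject cortical peak times average ~4 min unblocked and
        come earlier in the blocked arm."""
        from dualphase_pet.tac_analysis import TimeActivityCurve

        peaks = {True: [], False: []}
        table = default_cohort.tac_table_suv
        for sid, g in table[table.region == "cerebral_cortex"].groupby("subject"):
            g = g.sort_values("frame_index")
            tac = TimeActivityCurve(default_cohort.schedule, g["value"].to_numpy())
            peaks[bool(g["blocked"].iloc[0])].append(tac_peak(tac)[0])
        assert np.mean(peaks[False]) == pytest.approx(4.0, abs=0.8)
        assert np.mean(peaks[True]) < np.mean(peaks[False])

    def test_lesion_core_late_reduction_matches_drawn_severity(self, default_cohort):
        """The constructed noise-free late-window reduction in the lesion
        core equals the drawn severity fraction (calibration property)."""
        s = default_cohort.subjects[0]
        lab = s.lesion.center_region
        normal = window_mean(s.tacs_true[lab], 1800, 3600)
        core = window_mean(s.tacs_lesion_core[lab], 1800, 3600)
        assert 1.0 - core / normal == pytest.approx(s.truth["severity_frac"], abs=0.01)

    def test_written_cohort_files(self, tmp_path):
        config = CohortConfig(n_unblocked=1, n_blocked=0, **COARSE_GRID)
        cohort = generate_cohort(config, seed=3, out_dir=tmp_path, render=True)
        assert (tmp_path / "truth.csv").exists()
        assert (tmp_path / "atlas_labels.nii.gz").exists()
        assert (tmp_path / "sub-001_ucbh_dynamic.nii.gz").exists()
        assert (tmp_path / "sub-001_fdg.nii.gz").exists()
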