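import numpy as np
import pytest

from mpcasl import kinetic, phantom, pipeline
from mpcasl.phantom import (
    REGIONS,
    AcquisitionConfig,
    RespirationConfig,
    add_tumour,
    make_mouse_phantom,
    simulate_multi_pld,
    simulate_multiphase,
)


class TestMakeMousePhantom:
    def test_same_seed_is_bit_identical(self):
        a = make_mouse_phantom(seed=7)
        b = make_mouse_phantom(seed=7)
        assert np.array_equal(a.region_map, b.region_map)
        assert np.array_equal(a.f, b.f)
        assert np.array_equal(a.delta_t, b.delta_t)
        assert np.array_equal(a.phase_offset, b.phase_offset)

    def test_regions_partition_brain(self, small_phantom):
        region_sum = sum(
            small_phantom.region_mask(n).sum()
            for n in ("cortex", "striatum", "corpus_callosum", "ventricle")
        )
        assert region_sum == small_phantom.mask.sum()

    def test_default_regional_means_are_reference_values(self, small_phantom):
        assert small_phantom.region_mean("cortex") == pytest.approx(103.0)
        assert small_phantom.region_mean("striatum") == pytest.approx(90.0)
        assert small_phantom.region_mean("corpus_callosum") == pytest.approx(77.0)

    def test_most_voxels_arrive_by_04s(self, small_phantom):
        frac = kinetic.arrival_fraction(
            small_phantom.delta_t, small_phantom.mask, 0.4
        )
        assert frac >= 0.95

    def test_phase_field_bandlimited(self, small_phantom):
        ph = small_phantom.phase_offset
        for axis in (0, 1):
            jumps = np.abs(np.diff(ph, axis=axis))
            assert jumps.max() <= 45.0

    def test_phase_amplitude_bound(self):
        ph = make_mouse_phantom(seed=2, phase_amplitude=60.0)
        assert np.abs(ph.phase_offset).max() <= 60.0 + 1e-9

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValueError):
            make_mouse_phantom(shape=(8, 8, 1))


class TestAddTumour:
    def test_rim_only_when_core_zero(self, small_phantom):
        t = add_tumour(small_phantom, radius_core=0.0, radius_rim=3.0)
        assert (t.region_map == REGIONS["tumour_rim"]).sum() > 0
        assert (t.region_map == REGIONS["tumour_core"]).sum() == 0

    def test_everything_outside_lesion_unchanged(self, small_phantom):
        t = add_tumour(small_phantom, radius_core=1.5, radius_rim=3.0)
        outside = ~(
            (t.region_map == REGIONS["tumour_rim"])
            | (t.region_map == REGIONS["tumour_core"])
        )
        assert np.array_equal(t.f[outside], small_phantom.f[outside])
        assert np.array_equal(t.region_map[outside], small_phantom.region_map[outside])
        # and the lesion is confined to the left hemisphere's striatum side
        nx = t.region_map.shape[1]
        lesion = ~outside
        assert lesion[:, : nx // 2 + 2, :].sum() == lesion.sum()

    def test_default_core_rim_flow_levels(self, small_phantom):
        t = add_tumour(small_phantom, radius_core=2.0, radius_rim=4.0)
        core = t.region_map == REGIONS["tumour_core"]
        rim = t.region_map == REGIONS["tumour_rim"]
        assert t.f[core].mean() == pytest.approx(69.0, abs=8.0)
        assert t.f[rim].mean() == pytest.approx(83.0, abs=5.0)

    def test_ventricle_overlap_rejected(self, small_phantom):
        centre = np.array(np.nonzero(small_phantom.region_mask("ventricle"))).mean(axis=1)
        with pytest.raises(ValueError, match="ventricle"):
            add_tumour(small_phantom, centre=centre, radius_core=1.0, radius_rim=2.0)

    def test_invalid_radii_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            add_tumour(small_phantom, radius_core=5.0, radius_rim=3.0)

    def test_core_variance_detected_by_f_test(self):
        # power check: inflated core variance flagged at alpha = 0.05
        from mpcasl.densitometry import roi_stats

        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            ph = make_mouse_phantom(seed=seed, shape=(32, 32, 4), f_jitter_sd=4.0)
            t = add_tumour(ph, radius_core=2.5, radius_rim=4.5, seed=seed + 1000)
            core = t.region_map == REGIONS["tumour_core"]
            contra = t.region_map == REGIONS["striatum"]
            nx = t.region_map.shape[1]
            contra[:, : nx // 2, :] = False
            n = int(min(core.sum(), contra.sum()))
            a = t.f[core][:n]
            b = t.f[contra][:n]
            df = roi_stats(a, b, {"roi": np.ones(n, bool)})
            row = df.iloc[0]
            # directional check: core variance larger and F-test significant
            if row.f > 1 and row.f_p < 0.05:
                hits += 1
        assert hits >= 90


class TestSimulateMultiphase:
    def test_noiseless_pipeline_recovers_flow(self):
        # flat phase field: the chain is exact up to numerical tolerance
        ph = make_mouse_phantom(seed=4, shape=(32, 32, 2), phase_amplitude=0.0)
        acq = AcquisitionConfig(noise_sigma=0.0)
        series, truth = simulate_multiphase(ph, acq)
        cfg = pipeline.PipelineConfig(n_supervoxels=20)
        res = pipeline.run_pipeline(
            series, truth["baseline"], truth["mask"], cfg, bat_map=truth["delta_t"]
        )
        sel = truth["mask"] & (ph.f > 0)
        rel = np.abs(res["cbf"][sel] - ph.f[sel]) / ph.f[sel]
        assert np.nanmax(rel) < 1e-3

    def test_triggered_untriggered_differ_only_by_fluctuation(self):
        ph = make_mouse_phantom(seed=5, shape=(32, 32, 4))
        base = dict(noise_sigma=1.0, seed=9)
        s_trig, _ = simulate_multiphase(
            ph, AcquisitionConfig(respiration=RespirationConfig(triggered=True), **base)
        )
        s_untrig, truth = simulate_multiphase(
            ph, AcquisitionConfig(respiration=RespirationConfig(triggered=False), **base)
        )
        # same seed, same noise: difference is the multiplicative term on
        # the clean signal only
        clean = truth["baseline"][..., None] - truth["delta_m"][..., None] * (
            pipeline.fermi_response(
                pipeline.wrap_angle(
                    pipeline.PHASE_ANGLES[None, None, None, :]
                    - ph.phase_offset[..., None]
                )
            )
        )
        diff = s_untrig.signal - s_trig.signal
        # superior slices are barely affected, inferior carry the flutter
        assert np.abs(diff[:, :, -1]).max() < np.abs(diff[:, :, 0]).max()
        # reconstruct flutter and check it is bounded by the amplitude
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = diff / clean
        assert np.nanmax(np.abs(ratio[np.isfinite(ratio)])) <= 0.05 + 1e-9

    def test_measured_snr_near_target(self):
        snrs = []
        for seed in range(10):
            ph = make_mouse_phantom(seed=seed)
            series, truth = simulate_multiphase(
                ph, AcquisitionConfig(target_snr=15.0, seed=seed)
            )
            noise_roi = ~truth["mask"]
            noise_roi[8:, :, :] = False  # corner background region
            snrs.append(pipeline.series_snr(series, truth["mask"], noise_roi))
        assert np.mean(snrs) == pytest.approx(15.0, rel=0.15)

    def test_untriggered_defaults_lower_snr(self):
        acq_t = AcquisitionConfig(respiration=RespirationConfig(triggered=True))
        acq_u = AcquisitionConfig(respiration=RespirationConfig(triggered=False))
        assert acq_t.resolved_snr() == 15.1
        assert acq_u.resolved_snr() == 6.5

    def test_rician_noise_supported(self, small_phantom):
        acq = AcquisitionConfig(target_snr=10.0, noise="rician", seed=3)
        series, _ = simulate_multiphase(small_phantom, acq)
        assert np.all(series.signal >= 0.0)


class TestSimulateMultiPld:
    def test_zero_before_arrival(self):
        # delta_t beyond tau + max(PLD): no signal anywhere, noiselessly
        ph = make_mouse_phantom(
            seed=6,
            shape=(32, 32, 2),
            delta_t_defaults={
                "cortex": 2.2, "striatum": 2.2, "corpus_callosum": 2.2, "ventricle": 2.2
            },
            delta_t_jitter_sd=0.0,
        )
        sched = kinetic.PLDSchedule(np.linspace(0.01, 1.0, 12))
        sig, _ = simulate_multi_pld(ph, sched, AcquisitionConfig(noise_sigma=0.0))
        assert np.allclose(sig, 0.0)

    def test_noiseless_bat_recovery(self):
        ph = make_mouse_phantom(seed=8, shape=(32, 32, 2))
        sched = kinetic.PLDSchedule(np.linspace(0.01, 1.0, 12))
        sig, truth = simulate_multi_pld(ph, sched, AcquisitionConfig(noise_sigma=0.0))
        sel = truth["mask"] & (ph.f > 0)
        yn = sig[sel] / truth["m0_blood"][sel][:, None]
        _, dt_fit, _ = kinetic.fit_bat_map(yn, sched, truth["kinetic_params"])
        assert np.nanmax(np.abs(dt_fit - ph.delta_t[sel])) < 1e-3

    def test_arrival_fraction_recovered_at_snr15(self):
        ph = make_mouse_phantom(
            seed=9,
            shape=(32, 32, 4),
            delta_t_defaults={"corpus_callosum": 0.32},
            delta_t_jitter_sd=0.05,
        )
        sched = kinetic.PLDSchedule(np.linspace(0.01, 1.0, 12))
        sig, truth = simulate_multi_pld(ph, sched, AcquisitionConfig(target_snr=15.0, seed=9))
        sel = truth["mask"] & (ph.f > 0)
        yn = sig[sel] / truth["m0_blood"][sel][:, None]
        _, dt_fit, _ = kinetic.fit_bat_map(yn, sched, truth["kinetic_params"])
        bat = np.full(sel.shape, np.nan)
        bat[sel] = dt_fit
        truth_frac = kinetic.arrival_fraction(ph.delta_t, sel, 0.4)
        fit_frac = kinetic.arrival_fraction(bat, sel, 0.4)
        assert abs(truth_frac - fit_frac) < 0.02


class TestSingleSourceOfTruth:
    def test_forward_model_shared_with_analysis_modules(self):
        # the generator must use the analysis code's response functions
        assert phantom.kinetic is kinetic
        assert phantom.fermi_response is pipeline.fermi_response
        assert phantom.wrap_angle is pipeline.wrap_angle
        assert phantom.MultiphaseSeries is pipeline.MultiphaseSeries

    def test_truth_bundle_sufficient(self, small_phantom):
        series, truth = simulate_multiphase(small_phantom, AcquisitionConfig(seed=1))
        for key in ("delta_m", "baseline", "f", "delta_t", "phase_offset",
                    "m0_blood", "mask", "region_map", "noise_sigma", "kinetic_params"):
            assert key in truth
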