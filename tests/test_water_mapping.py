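"""Correction chain i-v: estimator oracles, recovery bounds and invariances."""

import numpy as np
import pytest

from hydromap.mr_forward import ScanSpec, spgr_signal
from hydromap.phantom import DEFAULT_T1, DEFAULT_WATER
from hydromap.water_mapping import (ALL_STEPS, correct_pd, estimate_b1t,
                                    estimate_receive_field, estimate_t1,
                                    estimate_t2star, map_water,
                                    normalize_to_csf, remove_residual_bias,
                                    t1_signal_ratio)


def _tissue_error(phantom, res, tissue):
    m = phantom.tissue_mask(tissue) & res.valid_mask
    return res.water_map[m].mean() - DEFAULT_WATER[tissue]


# ---------------------------------------------------------------------------
# step i — transmit field

def test_b1t_fit_recovers_the_worked_example_scaling():
    # signals proportional to sin(1.1 * alpha) -> b = 1.100
    angles = [30.0, 60.0, 90.0, 120.0]
    vols = [np.full((4, 4, 4), 50.0 * np.sin(np.deg2rad(1.1 * a)))
            for a in angles]
    b1t, flags = estimate_b1t(vols, angles_deg=angles, smooth_fwhm_mm=0.0)
    assert np.allclose(b1t, 1.1, atol=1e-3)
    assert not flags.any()


def test_b1t_fit_is_exact_identity_for_nominal_field():
    angles = [30.0, 60.0, 90.0, 120.0]
    vols = [np.full((3, 3, 3), 80.0 * np.sin(np.deg2rad(a))) for a in angles]
    b1t, _ = estimate_b1t(vols, angles_deg=angles, smooth_fwhm_mm=0.0)
    assert np.allclose(b1t, 1.0, atol=1e-6)


def test_b1t_fit_needs_at_least_three_angles():
    vols = [np.ones((2, 2, 2))] * 2
    with pytest.raises(ValueError):
        estimate_b1t(vols, angles_deg=[30.0, 60.0])


def test_b1t_dead_voxels_are_flagged_and_defaulted():
    angles = [30.0, 60.0, 90.0, 120.0]
    vols = [np.zeros((2, 2, 2)) for _ in angles]
    b1t, flags = estimate_b1t(vols, angles_deg=angles, smooth_fwhm_mm=0.0)
    assert flags.all()
    assert np.allclose(b1t, 1.0)


# ---------------------------------------------------------------------------
# step ii — T2*

def test_t2star_fit_is_exact_on_noiseless_decay():
    te = 2.3 + 2.27 * np.arange(8)
    truth = np.array([30.0, 50.0, 60.0, 200.0])
    s0 = np.array([40.0, 55.0, 70.0, 90.0])
    vols = [ (s0 * np.exp(-t / truth)).reshape(2, 2) for t in te]
    t2s, s0_hat, flags = estimate_t2star(vols, te)
    assert np.allclose(t2s.ravel(), truth, rtol=1e-9)
    assert np.allclose(s0_hat.ravel(), s0, rtol=1e-9)
    assert not flags.any()


def test_t2star_fit_flags_nondecaying_voxels():
    te = 2.3 + 2.27 * np.arange(8)
    vols = [np.full((2, 2), 10.0 * np.exp(+t / 100.0)) for t in te]
    t2s, _, flags = estimate_t2star(vols, te)
    assert flags.all()


# ---------------------------------------------------------------------------
# step iii — T1

def test_t1_signal_ratio_matches_the_closed_form_oracle():
    # R(1000) = 0.61435 / 0.39347 at nominal flip angles
    assert t1_signal_ratio(1000.0) == pytest.approx(0.61435 / 0.39347,
                                                    abs=2e-4)


def test_t1_inversion_recovers_the_worked_example():
    pd = np.full((3, 3, 3), 1.5614)
    t1s = np.ones((3, 3, 3))
    b1t = np.ones((3, 3, 3))
    t1, flags = estimate_t1(pd, t1s, b1t)
    assert np.allclose(t1, 1000.0, atol=1.0)
    assert not flags.any()


def test_t1_inversion_is_self_consistent_under_transmit_error():
    rng = np.random.default_rng(0)
    truth = rng.uniform(400.0, 3000.0, size=(5, 5, 5))
    b1t = rng.uniform(0.85, 1.15, size=truth.shape)
    ratio = t1_signal_ratio(truth, b1t)
    t1, flags = estimate_t1(ratio, np.ones_like(ratio), b1t)
    assert np.allclose(t1, truth, atol=0.2)
    assert not flags.any()


def test_t1_out_of_range_ratio_is_clamped_and_flagged():
    pd = np.full((2, 2, 2), 100.0)        # far above any attainable ratio
    t1, flags = estimate_t1(pd, np.ones_like(pd), np.ones_like(pd))
    assert flags.all()
    assert np.allclose(t1, 6000.0)


# ---------------------------------------------------------------------------
# receive field and combined correction

def test_receive_field_is_mean_normalized(phantom48, acq48_noiseless):
    b1r, flags = estimate_receive_field(acq48_noiseless.recv_array,
                                        acq48_noiseless.recv_body,
                                        mask=phantom48.brain_mask)
    assert b1r[phantom48.brain_mask].mean() == pytest.approx(1.0, abs=1e-12)


def test_corrected_pd_is_proportional_to_water_in_the_noiseless_limit():
    scan = ScanSpec()
    water = np.array([[70.0, 83.0], [100.0, 75.0]])
    t1 = np.array([[900.0, 1400.0], [4000.0, 1000.0]])
    t2s = np.array([[50.0, 60.0], [200.0, 55.0]])
    b1t = np.array([[0.9, 1.1], [1.0, 1.05]])
    b1r = np.array([[1.1, 0.95], [1.0, 0.9]])
    pd = spgr_signal(water, t1, t2s, b1t, b1r, scan)
    out, valid = correct_pd(pd, t2s, t1, b1t, b1r)
    assert valid.all()
    assert np.allclose(out, water, rtol=1e-12)


def test_residual_bias_removal_is_near_identity_on_bias_free_input(phantom48):
    # bias-free anatomy: exact class constants plus 1 percent voxel texture
    m = phantom48.brain_mask
    clean = np.where(m, phantom48.truth_water, 0.0)
    out, bias = remove_residual_bias(clean, m, voxel_size_mm=3.0)
    assert np.all(np.abs(out[m] / clean[m] - 1.0) < 0.002)
    rng = np.random.default_rng(5)
    tex = clean * np.exp(rng.normal(0.0, 0.01, clean.shape))
    out_t, _ = remove_residual_bias(np.where(m, tex, 0.0), m,
                                    voxel_size_mm=3.0)
    assert np.all(np.abs(out_t[m] / tex[m] - 1.0) < 0.002)


def test_residual_bias_removal_recovers_a_smooth_multiplicative_field(
        phantom48):
    # a corrupting field much smoother than the 60 mm estimation kernel
    # (the estimator's stated domain) is removed to within 1 percent
    from hydromap.phantom import make_fields
    m = phantom48.brain_mask
    clean = np.where(m, phantom48.truth_water, 0.0)
    smooth = make_fields(phantom48.shape, amplitude=0.1, smoothness_mm=100.0,
                         seed=33, voxel_size_mm=3.0, brain_mask=m).b1t
    corrupted = clean * smooth
    out_c, _ = remove_residual_bias(corrupted, m, voxel_size_mm=3.0)
    out_0, _ = remove_residual_bias(clean, m, voxel_size_mm=3.0)
    assert np.all(np.abs(out_c[m] / out_0[m] - 1.0) < 0.01)


def test_residual_bias_removal_preserves_the_brain_mean(result48_noisy):
    m = result48_noisy.valid_mask
    vol = np.where(m, result48_noisy.pd_corrected, 0.0)
    out, _ = remove_residual_bias(vol, m, voxel_size_mm=3.0)
    assert out[m].mean() == pytest.approx(vol[m].mean(), rel=1e-9)


# ---------------------------------------------------------------------------
# step v — CSF normalization

def test_csf_normalization_sets_reference_mean_to_one_hundred(result48_noisy):
    w = result48_noisy.water_map
    assert w[result48_noisy.csf_mask_eroded].mean() \
        == pytest.approx(100.0, abs=1e-9)


def test_csf_normalization_rejects_a_tiny_reference_region():
    vol = np.ones((20, 20, 20))
    vent = np.zeros_like(vol, bool)
    vent[10, 10, 10] = True
    with pytest.raises(ValueError, match="ventricle_mask"):
        normalize_to_csf(vol, vent)


# ---------------------------------------------------------------------------
# full chain

def test_noiseless_chain_recovers_tissue_water_within_point_two(
        phantom48, result48_noiseless):
    for tissue in ("wm", "gm", "csf"):
        assert abs(_tissue_error(phantom48, result48_noiseless, tissue)) < 0.2


def test_noisy_chain_keeps_pure_tissue_rmse_below_two_points(
        phantom48, result48_noisy):
    from hydromap.tissue_histogram import pure_tissue_mask
    pure = pure_tissue_mask({t: phantom48.prob_maps[t] for t in ("wm", "gm")})
    m = pure & result48_noisy.valid_mask
    err = result48_noisy.water_map[m] - phantom48.truth_water[m]
    assert np.sqrt((err ** 2).mean()) < 2.0


def test_skipping_t2star_correction_depresses_the_water_map(
        phantom48, acq48_noiseless, result48_noiseless):
    steps = tuple(s for s in ALL_STEPS if s != "t2star")
    res = map_water(acq48_noiseless, phantom48.ventricle_mask,
                    phantom48.brain_mask, steps=steps, voxel_size_mm=3.0)
    # uncompensated exp(-TE/T2*) decays tissue faster than the CSF
    # reference, so normalized tissue water drops below truth
    assert _tissue_error(phantom48, res, "wm") < -1.0
    assert abs(_tissue_error(phantom48, result48_noiseless, "wm")) < 0.2


def test_skipping_t1_correction_shrinks_tissue_contrast(
        phantom48, acq48_noiseless, result48_noiseless):
    steps = tuple(s for s in ALL_STEPS if s != "t1_saturation")
    res = map_water(acq48_noiseless, phantom48.ventricle_mask,
                    phantom48.brain_mask, steps=steps, voxel_size_mm=3.0)

    def contrast(r):
        return (r.water_map[phantom48.tissue_mask("gm") & r.valid_mask].mean()
                - r.water_map[phantom48.tissue_mask("wm") & r.valid_mask].mean())

    # saturation suppresses long-T1 GM more than WM; without the correction
    # the recovered GM-WM contrast falls short of the true 11.47 points
    assert contrast(res) < contrast(result48_noiseless) - 1.0


def test_unknown_correction_step_is_rejected(phantom48, acq48_noiseless):
    with pytest.raises(ValueError, match="unknown"):
        map_water(acq48_noiseless, phantom48.ventricle_mask,
                  phantom48.brain_mask, steps=("b1_transmit", "despike"))


def test_water_map_is_invariant_to_a_global_gain(phantom48, acq48_noiseless,
                                                 result48_noiseless):
    res = map_water(acq48_noiseless.scaled(1.7), phantom48.ventricle_mask,
                    phantom48.brain_mask, voxel_size_mm=3.0)
    m = result48_noiseless.valid_mask
    assert np.allclose(res.water_map[m], result48_noiseless.water_map[m],
                       rtol=1e-10)


def test_qc_summary_reports_flag_counts(result48_noisy):
    qc = result48_noisy.qc_summary()
    assert set(qc) >= {"applied_steps", "flag_counts", "n_csf_reference"}
    assert qc["applied_steps"] == list(ALL_STEPS)
    assert qc["n_csf_reference"] >= 20
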