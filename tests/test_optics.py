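import math

import numpy as np
import pytest
from scipy import ndimage

from deepmarrow import optics, phantom
from deepmarrow.core_io import AcquisitionParams, ImageStack
from deepmarrow.optics import TissueLayer, TissueModel, ZAdaptation


# ---------------------------------------------------------------------------
# pulse-train arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("e_nj,rate_hz,mw", [
    (39.8, 3.0e6, 119.4),
    (0.0, 5.0e6, 0.0),
    (495.0, 1.01e6, 499.95),
])
def test_average_power_is_exact_product(e_nj, rate_hz, mw):
    assert optics.average_power(e_nj, rate_hz) == pytest.approx(mw, abs=1e-9)


def test_average_power_rejects_negative():
    with pytest.raises(ValueError):
        optics.average_power(-1.0, 1e6)


@pytest.mark.parametrize("dwell,rate,n", [
    (1.98, 3.0e6, 5.94), (1.98, 4.0e6, 7.92), (4.0, 1.0e6, 4.0),
])
def test_pulses_per_pixel(dwell, rate, n):
    assert optics.pulses_per_pixel(dwell, rate) == pytest.approx(n)


# ---------------------------------------------------------------------------
# z-adaptation and effective pulse energy
# ---------------------------------------------------------------------------

def test_z_adaptation_passes_through_anchors():
    law = optics.z_adaptation([(50.0, 2.76), (488.0, 108.64)])
    assert law(50.0) == pytest.approx(2.76)
    assert law(488.0) == pytest.approx(108.64)
    # closed form for the two-point exponential
    assert law.l_adapt == pytest.approx(438.0 / math.log(108.64 / 2.76), rel=1e-12)


def test_z_adaptation_flat_and_degenerate():
    flat = optics.z_adaptation([(0.0, 5.0), (100.0, 5.0)])
    assert math.isinf(flat.l_adapt) and flat(77.0) == 5.0
    with pytest.raises(ValueError):
        optics.z_adaptation([(10.0, 1.0), (10.0, 2.0)])


def test_effective_pulse_energy_cortex_attenuation():
    tissue = TissueModel([TissueLayer("cortex", 130.0, 113.0)])
    law = ZAdaptation.flat(1.0)
    assert optics.effective_pulse_energy(law, tissue, 0.0) == pytest.approx(1.0)
    assert optics.effective_pulse_energy(law, tissue, 130.0) == pytest.approx(
        math.exp(-130.0 / 113.0), rel=1e-12)
    lossless = TissueModel([TissueLayer("x", 500.0, math.inf)])
    assert optics.effective_pulse_energy(law, lossless, 400.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        optics.effective_pulse_energy(law, tissue, 131.0)


def test_effective_energy_nonincreasing_under_flat_law():
    tissue = TissueModel.tibia()
    law = ZAdaptation.flat(10.0)
    z = np.linspace(0.0, tissue.total_depth, 200)
    e = np.asarray(optics.effective_pulse_energy(law, tissue, z))
    assert np.all(np.diff(e) <= 1e-12)


def test_saturation_depth_constructed_crossing():
    # lossless tissue, E(z) = exp(z/100): crosses e at exactly z = 100
    tissue = TissueModel([TissueLayer("x", 500.0, math.inf)])
    law = ZAdaptation(z_ref=0.0, e_ref=1.0, l_adapt=100.0)
    z = optics.saturation_depth(law, tissue, math.e)
    assert z == pytest.approx(100.0, abs=0.1)
    assert optics.saturation_depth(law, tissue, 0.0) == 0.0
    flat = ZAdaptation.flat(1.0)
    assert optics.saturation_depth(flat, tissue, 2.0) is None


# ---------------------------------------------------------------------------
# attenuation-length regression
# ---------------------------------------------------------------------------

def _noise_free_slab(l_e, n_planes=25, dz=5.0, order=3):
    tissue = TissueModel([TissueLayer("slab", n_planes * dz + dz, l_e)])
    acq = AcquisitionParams(excitation_order=order)
    return phantom.attenuation_slab(
        tissue, acq, n_planes=n_planes, dz=dz,
        noise=phantom.NoiseModel(offset=0.0, read_sd=0.0, shot_noise=False)), acq


def test_noise_free_single_layer_recovers_l_e_exactly():
    (stack, mask, _), acq = _noise_free_slab(113.0)
    fit = optics.fit_attenuation_length(stack, acq, mask=mask)
    assert fit.l_e == pytest.approx(113.0, rel=1e-6)  # float32 voxel storage


def test_lossless_slab_reports_infinite_l_e():
    (stack, mask, _), acq = _noise_free_slab(math.inf)
    fit = optics.fit_attenuation_length(stack, acq, mask=mask)
    assert math.isinf(fit.l_e)


def test_power_corrected_fit_undoes_z_adaptation():
    # with energy adaptation exactly compensating attenuation the raw signal is
    # flat, but dividing by E(z) must still recover the true l_e
    l_e = 150.0
    tissue = TissueModel([TissueLayer("slab", 200.0, l_e)])
    law = phantom.matched_z_adaptation(tissue)
    acq = AcquisitionParams(excitation_order=3)
    stack, mask, _ = phantom.attenuation_slab(
        tissue, acq, applied_energy=law, n_planes=20, dz=8.0,
        noise=phantom.NoiseModel(offset=0.0, read_sd=0.0, shot_noise=False))
    fit = optics.fit_attenuation_length(stack, acq, mask=mask, applied_energy=law)
    assert fit.l_e == pytest.approx(l_e, rel=1e-6)


def test_insufficient_planes_raises():
    (stack, mask, _), acq = _noise_free_slab(113.0, n_planes=4)
    with pytest.raises(ValueError):
        optics.fit_attenuation_length(stack, acq, mask=mask)


def test_poisson_noise_bias_below_two_percent():
    acq = AcquisitionParams(excitation_order=3)
    tissue = TissueModel([TissueLayer("slab", 130.0, 113.0)])
    vals = []
    for s in range(50):
        stack, mask, bg_mask = phantom.attenuation_slab(
            tissue, acq, n_planes=20, dz=6.0, seed=s)
        bg = float(stack.voxels[0, 0][:, bg_mask].mean())
        vals.append(optics.fit_attenuation_length(
            stack, acq, mask=mask, background=bg).l_e)
    assert abs(np.mean(vals) - 113.0) / 113.0 < 0.02


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------

def _snr_stack(signal, bg_mean, bg_sd, seed=0):
    rng = np.random.default_rng(seed)
    vol = np.zeros((4, 16, 32), dtype=np.float32)
    vol[:, :, 16:] = rng.normal(bg_mean, bg_sd, (4, 16, 16))
    vol[:, :, :16] = signal
    vol = np.clip(vol, 0, None)
    stack = ImageStack(vol, (5.0, 1.0, 1.0), ["c"])
    smask = np.zeros((16, 32), bool); smask[:, :16] = True
    bmask = np.zeros((16, 32), bool); bmask[:, 16:] = True
    return stack, smask, bmask


def test_snr_formula():
    stack, smask, bmask = _snr_stack(16.0, 10.0, 2.0)
    prof = optics.snr_profile(stack, smask, bmask)
    expected = (16.0 - prof.background_mean) / prof.background_sd
    assert np.allclose(prof.snr, expected, rtol=1e-6)


def test_snr_zero_for_null_signal():
    stack, smask, bmask = _snr_stack(10.0, 10.0, 2.0)
    prof = optics.snr_profile(stack, smask, bmask)
    assert np.allclose(prof.snr, 0.0, atol=0.5)


def test_snr_offset_invariance():
    stack, smask, bmask = _snr_stack(60.0, 10.0, 2.0)
    p0 = optics.snr_profile(stack, smask, bmask)
    shifted = stack.with_voxels(stack.voxels + 500.0)
    p1 = optics.snr_profile(shifted, smask, bmask)
    assert np.allclose(p0.snr, p1.snr, rtol=1e-5)


def test_snr_scales_linearly_with_rep_rate():
    """Doubling/tripling the repetition rate scales signal, hence SNR, linearly."""
    tissue = TissueModel([TissueLayer("slab", 200.0, 150.0)])
    noise = phantom.NoiseModel(offset=100.0, read_sd=2.0, shot_noise=True)
    profs = {}
    for rate in (1.0e6, 3.0e6):
        acq = AcquisitionParams(rep_rate=rate, excitation_order=3)
        stack, smask, bmask = phantom.attenuation_slab(
            tissue, acq, n_planes=15, dz=10.0, brightness=300.0,
            noise=noise, seed=5)
        profs[rate] = optics.snr_profile(stack, smask, bmask)
    ratio = profs[3.0e6].snr / profs[1.0e6].snr
    assert np.median(ratio) == pytest.approx(3.0, rel=0.15)


def test_snr_degenerate_background_raises():
    stack, smask, bmask = _snr_stack(16.0, 10.0, 0.0)
    stack.voxels[0, 0][:, :, 16:] = 10.0
    with pytest.raises(ValueError):
        optics.snr_profile(stack, smask, bmask)


def test_snr_crossing_depths_interpolated():
    vol = np.zeros((5, 8, 32), dtype=np.float32)
    rng = np.random.default_rng(1)
    vol[:, :, 16:] = np.clip(rng.normal(10, 2, (5, 8, 16)), 0, None)
    for k, s in enumerate([30, 20, 12, 8, 10.5]):
        vol[k, :, :16] = s
    stack = ImageStack(vol, (10.0, 1.0, 1.0), ["c"])
    smask = np.zeros((8, 32), bool); smask[:, :16] = True
    bmask = np.zeros((8, 32), bool); bmask[:, 16:] = True
    prof = optics.snr_profile(stack, smask, bmask)
    assert prof.segmentation_limit_depth is not None
    assert 0 < prof.segmentation_limit_depth < 40.0


# ---------------------------------------------------------------------------
# resolution
# ---------------------------------------------------------------------------

BEADS = [(16, 32, 32), (16, 20, 40), (10, 40, 20), (16, 10, 10), (20, 50, 50),
         (12, 25, 45)]


def test_gaussian_spot_fwhm_closed_form():
    stack = phantom.bead_stack(BEADS, (0.9, 0.3))
    est = optics.resolution_from_structures(stack, BEADS, axis="lateral")
    assert est.fwhm == pytest.approx(2.3548 * 0.3, rel=0.02)
    est_ax = optics.resolution_from_structures(stack, BEADS, axis="axial",
                                               half_window=10)
    assert est_ax.fwhm == pytest.approx(2.3548 * 0.9, rel=0.03)


def test_edge_derivative_recovers_blur_kernel():
    edge = np.zeros((9, 64, 64), dtype=np.float32)
    edge[:, :, 32:] = 1000.0
    edge = ndimage.gaussian_filter(edge, (0.0, 0.0, 3.0))  # sigma 3 px = 0.3 μm
    stack = ImageStack(edge, (0.5, 0.1, 0.1), ["c"])
    pts = [(4, y, 32) for y in (10, 20, 30, 40, 50)]
    est = optics.resolution_from_structures(stack, pts, axis="lateral",
                                            method="edge_derivative")
    assert est.fwhm == pytest.approx(2.3548 * 0.3, rel=0.02)


def test_fwhm_monotone_with_depth_blur():
    fwhms = []
    for sigma in (0.25, 0.35, 0.5):
        stack = phantom.bead_stack(BEADS, (0.9, sigma))
        fwhms.append(optics.resolution_from_structures(stack, BEADS,
                                                       axis="lateral").fwhm)
    assert fwhms == sorted(fwhms)


def test_resolution_needs_five_structures():
    stack = phantom.bead_stack(BEADS[:3], (0.9, 0.3))
    with pytest.raises(ValueError):
        optics.resolution_from_structures(stack, BEADS[:3], axis="lateral")


def test_diffraction_limit_scalings():
    lat1, ax1 = optics.diffraction_limit(1650.0, 1.05, n_photon=1)
    lat3, ax3 = optics.diffraction_limit(1650.0, 1.05, n_photon=3)
    assert lat3 == pytest.approx(lat1 / math.sqrt(3), rel=1e-12)
    lat_2x, ax_2x = optics.diffraction_limit(3300.0, 1.05, n_photon=3)
    assert lat_2x == pytest.approx(2 * lat3, rel=1e-12)
    assert ax_2x == pytest.approx(2 * ax3, rel=1e-12)
    # frozen regression values for the instrument configuration
    assert lat3 == pytest.approx(0.6441, abs=2e-4)
    assert ax3 == pytest.approx(2.2984, abs=2e-4)


# ---------------------------------------------------------------------------
# photobleaching
# ---------------------------------------------------------------------------

def test_photobleach_constant_trace_gives_zero():
    t = np.arange(0.0, 60.0, 5.0)
    fit = optics.fit_photobleaching(t, np.full_like(t, 400.0))
    assert fit.k == pytest.approx(0.0, abs=1e-12)


def test_photobleach_halving_closed_form():
    t = np.arange(0.0, 60.0, 10.0)
    fit = optics.fit_photobleaching(t, 100.0 * 0.5 ** (t / 10.0))
    assert fit.k == pytest.approx(math.log(2) / 10.0, rel=1e-9)


def test_photobleach_recovers_generative_rate():
    t = np.arange(0.0, 120.0, 0.5)
    fit = optics.fit_photobleaching(t, 500.0 * np.exp(-1.3e-3 * t))
    assert fit.k == pytest.approx(1.3e-3, rel=0.01)


def test_photobleach_requires_positive_points():
    with pytest.raises(ValueError):
        optics.fit_photobleaching(np.arange(6.0), np.zeros(6))
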