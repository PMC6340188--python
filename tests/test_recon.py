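"""Reconstruction chain: conversion, background, unwrapping, merging."""

import numpy as np
import pytest

from fetalflow.core import PhaseStack, VelocityField, polynomial_basis, voxel_centers, wrap_phase
from fetalflow.phantom import AcquisitionSpec, build_phantom, encode
from fetalflow.recon import (
    StaticMask,
    compute_angiogram,
    correct_background,
    detect_static,
    merge_dual_venc,
    phase_to_velocity,
    reconstruct_dual_venc,
    unwrap_high,
)

from conftest import straight_tube_network, two_channel_phantom


def _uniform_field(value, shape=(8, 8, 8), nt=2, spacing=1.0, venc=None):
    v = np.broadcast_to(np.asarray(value, float), shape + (nt, 3)).copy()
    prov = {} if venc is None else {"venc": venc}
    return VelocityField(spacing=np.full(3, spacing), frame_times=np.arange(nt) * 100.0,
                         period=nt * 100.0, v=v, provenance=prov)


def _stack_from_phase(phase, venc, mag=None, spacing=1.0):
    nt = phase.shape[3]
    if mag is None:
        mag = np.ones(phase.shape[:4])
    return PhaseStack(spacing=np.full(3, spacing), frame_times=np.arange(nt) * 100.0,
                      period=nt * 100.0, magnitude=mag, phase=phase, venc=venc)


# --- phase -> velocity -----------------------------------------------------


@pytest.mark.parametrize("phi,venc,expected", [(0.4 * np.pi, 50.0, 20.0), (0.0, 75.0, 0.0),
                                               (np.pi, 150.0, 150.0)])
def test_phase_to_velocity_linear_map(phi, venc, expected):
    phase = np.full((4, 4, 4, 2, 3), phi)
    field = phase_to_velocity(_stack_from_phase(phase, venc))
    assert np.allclose(field.v, expected)
    assert field.provenance["venc"] == venc


# --- static-tissue detection -----------------------------------------------


def test_static_mask_noise_free(pulse_tube):
    """Noise-free pulsatile phantom: the mask covers all tissue, no air,
    and any extra voxels are slow near-wall lumen voxels whose temporal
    velocity variation sits below the threshold-equivalent velocity."""
    net, acq, ph = pulse_tube
    stacks = encode(ph.truth, acq, phantom=ph)
    mask = detect_static(stacks[0], phase_std_max=0.1, mag_min=0.3).mask
    assert np.all(mask[ph.tissue_mask])
    air = ~ph.tissue_mask & ~ph.lumen_mask
    assert not np.any(mask[air])
    extra = mask & ph.lumen_mask
    assert extra.sum() < 0.2 * ph.lumen_mask.sum()
    if extra.any():
        v_equiv = stacks[0].venc * 0.1 / np.pi  # velocity std at the phase threshold
        assert ph.truth.v[extra].std(axis=1).max() <= v_equiv + 1e-9


def test_static_mask_recall_under_noise():
    net = straight_tube_network(kind="arterial", peak_cm_s=60.0)
    acq = AcquisitionSpec(grid_shape=(48, 48, 48), spacing=1.0, n_frames=8,
                          vencs=(50.0, 150.0), snr=20.0, seed=3)
    ph = build_phantom(net, acq)
    stacks = encode(ph.truth, acq, phantom=ph)
    mask = detect_static(stacks[0]).mask
    recall = (mask & ph.tissue_mask).sum() / ph.tissue_mask.sum()
    assert recall >= 0.9


def test_static_mask_all_lumen_is_empty(caplog):
    """A volume with pulsatile flow everywhere yields an empty mask."""
    rng = np.random.default_rng(0)
    phase = wrap_phase(rng.uniform(-3, 3, size=(6, 6, 6, 4, 3)))
    with caplog.at_level("WARNING"):
        mask = detect_static(_stack_from_phase(phase, 150.0))
    assert mask.count == 0
    assert any("empty" in r.message for r in caplog.records)


def test_static_detection_threshold_validation(tube):
    net, acq, ph = tube
    stacks = encode(ph.truth, acq, phantom=ph)
    with pytest.raises(ValueError):
        detect_static(stacks[0], phase_std_max=0.0)
    with pytest.raises(ValueError):
        detect_static(stacks[0], mag_min=-0.1)


# --- background correction -------------------------------------------------


def _contaminated_field(coeffs, order, shape=(16, 16, 16), nt=3):
    """Zero flow plus a known polynomial offset; full static mask."""
    spacing = np.full(3, 2.0)
    x, y, z = voxel_centers(shape, spacing)
    coords = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    extent = spacing * np.asarray(shape)
    basis = polynomial_basis(coords, order, extent / 2, extent / 2)
    bg = (basis @ np.asarray(coeffs).T).reshape(shape + (3,))
    v = np.repeat(bg[:, :, :, None, :], nt, axis=3)
    return VelocityField(spacing=spacing, frame_times=np.arange(nt) * 100.0,
                         period=nt * 100.0, v=v, provenance={})


def test_linear_offset_removed_to_machine_precision():
    coeffs = np.array([[1.0, 2.0, -1.5, 0.5], [0.3, -0.2, 0.1, 0.9], [0.0, 1.1, 0.0, -0.4]])
    field = _contaminated_field(coeffs, order=1)
    mask = StaticMask(np.ones(field.grid_shape, dtype=bool))
    out = correct_background(field, mask, order=1)
    assert np.max(np.abs(out.v)) < 1e-10


def test_zero_offset_is_identity():
    field = _uniform_field(0.0)
    out = correct_background(field, StaticMask(np.ones(field.grid_shape, bool)), order=1)
    assert np.allclose(out.v, 0.0)


def test_background_correction_idempotent():
    coeffs = np.array([[0.5, 1.0, -0.5, 0.2], [0.1, 0.4, 0.3, -0.2], [0.2, -0.3, 0.6, 0.1]])
    field = _contaminated_field(coeffs, order=1)
    mask = StaticMask(np.ones(field.grid_shape, dtype=bool))
    once = correct_background(field, mask, order=1)
    twice = correct_background(once, mask, order=1)
    assert np.max(np.abs(twice.v - once.v)) < 1e-9


def test_quadratic_contamination_order1_leaves_best_linear_residual():
    """Correcting quadratic contamination at order 1 leaves exactly the
    independent least-squares linear-fit residual."""
    n_q = 10  # order-2 monomial count
    rng = np.random.default_rng(1)
    coeffs = rng.normal(size=(3, n_q))
    field = _contaminated_field(coeffs, order=2)
    mask = StaticMask(np.ones(field.grid_shape, dtype=bool))
    out = correct_background(field, mask, order=1)
    # independent reference: direct lstsq of the contamination on a linear basis
    x, y, z = voxel_centers(field.grid_shape, field.spacing)
    coords = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    basis = polynomial_basis(coords, 1, field.extent / 2, field.extent / 2)
    vmean = field.v.mean(axis=3).reshape(-1, 3)
    fit = basis @ np.linalg.lstsq(basis, vmean, rcond=None)[0]
    expected = (vmean - fit).reshape(field.grid_shape + (3,))
    assert np.allclose(out.v[:, :, :, 0, :], expected, atol=1e-9)


def test_background_correction_needs_enough_voxels():
    field = _uniform_field(1.0)
    tiny = np.zeros(field.grid_shape, bool)
    tiny[0, 0, 0] = True
    with pytest.raises(ValueError, match="static"):
        correct_background(field, StaticMask(tiny), order=1)
    with pytest.raises(ValueError):
        correct_background(field, StaticMask(np.zeros(field.grid_shape, bool)), order=1)


# --- unwrapping ------------------------------------------------------------


def test_unwrap_is_identity_on_unaliased_data():
    field = _uniform_field([30.0, -40.0, 10.0], venc=150.0)
    out = unwrap_high(field)
    assert np.array_equal(out.v, field.v)


def test_unwrap_restores_single_aliased_voxel():
    """True 160 cm/s under VENC 150 appears as −140; neighbors around
    150 pull it back up by one 2·VENC period."""
    venc = 150.0
    v = np.full((7, 7, 7, 2, 3), 0.0)
    v[..., 2] = 150.0
    v[3, 3, 3, :, 2] = 160.0 - 2 * venc  # apparent -140
    field = VelocityField(spacing=np.ones(3), frame_times=np.array([0.0, 100.0]),
                          period=200.0, v=v, provenance={"venc": venc})
    seed = np.ones((7, 7, 7), bool)
    seed[3, 3, 3] = False
    out = unwrap_high(field, seed_mask=seed)
    assert np.allclose(out.v[3, 3, 3, :, 2], 160.0)


def test_unwrap_changes_are_multiples_of_two_venc():
    venc = 150.0
    rng = np.random.default_rng(5)
    v = rng.uniform(-venc, venc, size=(9, 9, 9, 3, 3))
    field = VelocityField(spacing=np.ones(3), frame_times=np.arange(3) * 50.0,
                          period=150.0, v=v, provenance={"venc": venc})
    seed = np.zeros((9, 9, 9), bool)
    seed[4, 4, 4] = True
    out = unwrap_high(field, seed_mask=seed)
    k = (out.v - field.v) / (2 * venc)
    assert np.allclose(k, np.round(k), atol=1e-9)


# --- dual-VENC merge -------------------------------------------------------


def test_merge_examples():
    low = _uniform_field(0.0, venc=50.0)
    high = _uniform_field(0.0, venc=150.0)
    low.v[..., 0] = 20.0   # true 120 aliased
    high.v[..., 0] = 120.0
    low.v[..., 1] = 20.0   # true 20, no alias
    high.v[..., 1] = 20.0
    merged = merge_dual_venc(low, high)
    assert np.allclose(merged.v[..., 0], 120.0)
    assert np.allclose(merged.v[..., 1], 20.0)
    assert merged.provenance["fallback_count"] == 0


def test_merge_tie_keeps_low():
    low = _uniform_field(0.0, venc=50.0)
    high = _uniform_field(50.0, venc=150.0)
    # |v_low - v_high| == venc_low exactly: inclusive comparison keeps low
    merged = merge_dual_venc(low, high)
    assert np.allclose(merged.v, 0.0)


def test_merge_corrects_by_nearest_multiple():
    low = _uniform_field(10.0, venc=50.0)
    high = _uniform_field(85.0, venc=150.0)
    merged = merge_dual_venc(low, high)
    src = merged.provenance["merge_source"]
    # 85-10=75 -> k=1 -> corrected 110; |110-85|=25<=50: corrected, no fallback
    assert np.allclose(merged.v, 110.0)
    assert np.all(src == 1)


def test_merge_geometry_mismatch_raises():
    low = _uniform_field(0.0, venc=50.0)
    high = _uniform_field(0.0, shape=(6, 6, 6), venc=150.0)
    with pytest.raises(ValueError):
        merge_dual_venc(low, high)


def test_merge_difference_is_multiple_of_two_venc_low(pulse_tube):
    net, acq, ph = pulse_tube
    stacks = encode(ph.truth, acq, phantom=ph)
    low = phase_to_velocity(stacks[0])
    high = phase_to_velocity(stacks[1])
    merged = merge_dual_venc(low, high)
    src = merged.provenance["merge_source"]
    k = (merged.v - low.v) / (2 * 50.0)
    ok = np.isclose(k, np.round(k), atol=1e-9) | (src == 2)
    assert np.all(ok)
    # and the merged field equals the truth to machine precision
    assert np.max(np.abs(merged.v - ph.truth.v)) < 1e-9


# --- full chain and angiogram ----------------------------------------------


def test_single_venc_reconstruction_skips_merge(pulse_tube, caplog):
    net, acq, ph = pulse_tube
    stacks = encode(ph.truth, acq, phantom=ph)
    with caplog.at_level("INFO"):
        field, static = reconstruct_dual_venc(stacks[1:])  # high VENC only
    assert any("merge skipped" in r.message for r in caplog.records)
    assert np.max(np.abs(field.v - ph.truth.v)) < 0.1


def test_angiogram_zero_velocity_empty_lumen():
    field = _uniform_field(0.0)
    phase = np.zeros(field.grid_shape + (field.n_frames, 3))
    angio = compute_angiogram(field, _stack_from_phase(phase, 150.0), threshold=0.1)
    assert not angio.lumen.any()


def test_angiogram_two_tubes_two_seeds():
    net, acq, ph = two_channel_phantom()
    stacks = encode(ph.truth, acq, phantom=ph)
    field = phase_to_velocity(stacks[0])
    seeds = np.array([[16.0, 24.0, 24.0], [40.0, 24.0, 24.0]])
    angio = compute_angiogram(field, stacks[0], threshold=0.1, seeds_mm=seeds)
    from scipy.ndimage import label

    labels, n = label(angio.lumen)
    assert n == 2
    # single seed keeps only one component
    one = compute_angiogram(field, stacks[0], threshold=0.1, seeds_mm=seeds[:1])
    assert label(one.lumen)[1] == 1


def test_angiogram_threshold_validation(tube):
    net, acq, ph = tube
    stacks = encode(ph.truth, acq, phantom=ph)
    field = phase_to_velocity(stacks[0])
    with pytest.raises(ValueError):
        compute_angiogram(field, stacks[0], threshold=1.5)
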