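"""Velocity reconstruction from wrapped multi-VENC phase data.

The processing chain mirrors standard dual-VENC phase-contrast practice:

1. ``phase_to_velocity`` — linear phase→velocity map, v = VENC·φ/π;
2. ``detect_static`` + ``correct_background`` — fit a low-order
   polynomial to the apparent velocity of static tissue and subtract it
   (eddy-current / background phase correction);
3. ``unwrap_high`` — temporal-then-spatial unwrapping of the high-VENC
   field (all corrections are multiples of 2·VENC);
4. ``merge_dual_venc`` — keep the precise low-VENC value, using the
   unwrapped high-VENC value as the aliasing referee;
5. ``compute_angiogram`` — time-averaged flow-weighted intensity
   (PC-MRA) and a connected-component lumen segmentation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, label

from .core import PhaseStack, VelocityField, n_polynomial_terms, polynomial_basis, voxel_centers

__all__ = [
    "StaticMask",
    "Angiogram",
    "phase_to_velocity",
    "detect_static",
    "correct_background",
    "unwrap_high",
    "merge_dual_venc",
    "compute_angiogram",
    "reconstruct_dual_venc",
]

log = logging.getLogger(__name__)

_NEIGHBOR_SHIFTS = [(ax, off) for ax in range(3) for off in (-1, 1)]


@dataclass
class StaticMask:
    """Boolean volume marking static-tissue voxels."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class Angiogram:
    """Time-averaged flow-weighted intensity with a lumen segmentation."""

    intensity: np.ndarray
    lumen: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.lumen = np.asarray(self.lumen, dtype=bool)
        if np.any(self.intensity < 0):
            raise ValueError("angiogram intensity must be non-negative")
        if self.lumen.shape != self.intensity.shape:
            raise ValueError("lumen mask must match the intensity volume")


def phase_to_velocity(stack: PhaseStack) -> VelocityField:
    """Convert wrapped phase to apparent velocity: v = VENC · φ / π (cm/s)."""
    v = stack.venc * stack.phase / np.pi
    return VelocityField(
        spacing=stack.spacing.copy(),
        frame_times=stack.frame_times.copy(),
        period=stack.period,
        v=v,
        provenance={"venc": stack.venc, "corrections": []},
    )


def detect_static(
    stack: PhaseStack, phase_std_max: float = 0.1, mag_min: float = 0.3
) -> StaticMask:
    """Detect static tissue from temporal phase stability and magnitude.

    A voxel is static when the temporal standard deviation of its phase
    is below ``phase_std_max`` radians in every component AND its
    time-mean magnitude exceeds ``mag_min`` times the volume maximum
    (which excludes air).  Static tissue has no velocity signal, so its
    phase is constant in time up to noise.
    """
    if phase_std_max <= 0 or mag_min <= 0:
        raise ValueError("thresholds must be positive")
    if stack.n_frames < 2:
        raise ValueError("need at least 2 cardiac frames")
    phase_std = stack.phase.std(axis=3).max(axis=-1)  # max over components
    mag_mean = stack.magnitude.mean(axis=3)
    mask = (phase_std < phase_std_max) & (mag_mean > mag_min * mag_mean.max())
    if not mask.any():
        log.warning("static-tissue detection produced an empty mask")
    else:
        log.info("static mask: %d voxels (%.1f%%)", mask.sum(), 100 * mask.mean())
    return StaticMask(mask)


def correct_background(field: VelocityField, mask: StaticMask, order: int = 1) -> VelocityField:
    """Subtract a polynomial background fitted to static-tissue velocity.

    Per component, a polynomial of total degree ``order`` in the voxel
    world coordinates is least-squares fitted to the *time-mean* apparent
    velocity over static voxels and subtracted from every voxel and
    frame.  With a perfect mask and matching order the contamination is
    removed exactly; the operation is idempotent.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    m = mask.mask
    if not m.any():
        raise ValueError("static mask is empty")
    n_terms = n_polynomial_terms(order)
    if m.sum() < n_terms:
        raise ValueError(
            f"only {int(m.sum())} static voxels for {n_terms} polynomial coefficients"
        )
    shape = field.grid_shape
    x, y, z = voxel_centers(shape, field.spacing)
    coords = np.stack([x[m], y[m], z[m]], axis=1)
    center, halfspan = field.extent / 2.0, field.extent / 2.0
    a = polynomial_basis(coords, order, center, halfspan)
    vmean = field.v.mean(axis=3)  # (nx, ny, nz, 3)
    coeffs = np.linalg.lstsq(a, vmean[m], rcond=None)[0]  # (n_terms, 3)

    allc = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    bg = (polynomial_basis(allc, order, center, halfspan) @ coeffs).reshape(shape + (3,))
    out = field.v - bg[:, :, :, None, :]
    resid = np.abs((vmean - bg)[m]).mean(axis=0)
    log.info(
        "background correction order=%d: mean |static residual| per component = %s cm/s",
        order, np.array2string(resid, precision=4),
    )
    prov_corr = field.provenance.get("corrections", []) + [f"background(order={order})"]
    return field.copy_with(out, corrections=prov_corr)


def _neighbor_median(values: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median over valid 6-neighbors; returns (median, has_any_valid_neighbor)."""
    stacked = np.full((6,) + values.shape, np.nan)
    for s, (ax, off) in enumerate(_NEIGHBOR_SHIFTS):
        src = np.where(valid, values, np.nan)
        rolled = np.roll(src, off, axis=ax)
        # zero out wrap-around slabs
        sl = [slice(None)] * values.ndim
        sl[ax] = 0 if off == 1 else -1
        rolled[tuple(sl)] = np.nan
        stacked[s] = rolled
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="All-NaN slice")
        med = np.nanmedian(stacked, axis=0)
    return med, np.isfinite(med)


def unwrap_high(
    field_high: VelocityField,
    seed_mask: np.ndarray | None = None,
    domain_mask: np.ndarray | None = None,
) -> VelocityField:
    """Unwrap residual aliasing in the high-VENC velocity field.

    Temporal stage: per voxel and component, frame values are shifted by
    multiples of 2·VENC so consecutive frames differ by less than VENC
    (minimising frame-to-frame jumps).  Spatial stage: region growing
    from the static seed; a voxel whose time-mean differs from the median
    of its already-unwrapped 6-neighbors by more than VENC is shifted (in
    all frames) by the nearest multiple of 2·VENC.  Output may exceed
    ±VENC only where unwrapping fired; on unaliased data this is the
    identity.

    ``domain_mask`` limits the region growing (typically to the body,
    excluding air where phase is meaningless); voxels outside it are
    passed through untouched by the spatial stage.
    """
    venc = field_high.provenance.get("venc")
    if venc is None:
        raise ValueError("field provenance does not record a venc; single-VENC field required")
    v = field_high.v.copy()
    nt = field_high.n_frames
    two_v = 2.0 * venc

    # temporal unwrapping
    n_temporal = 0
    for f in range(1, nt):
        k = np.round((v[:, :, :, f - 1, :] - v[:, :, :, f, :]) / two_v)
        n_temporal += int(np.count_nonzero(k))
        v[:, :, :, f, :] += two_v * k

    # spatial region growing on the time-mean, one shift per voxel/component
    if seed_mask is None:
        seed_mask = np.ones(field_high.grid_shape, dtype=bool)
    if domain_mask is None:
        domain_mask = np.ones(field_high.grid_shape, dtype=bool)
    n_spatial = 0
    for c in range(3):
        vm = v[..., c].mean(axis=3)
        done = seed_mask.copy()
        for _ in range(int(np.max(field_high.grid_shape)) * 3):
            med, has = _neighbor_median(vm, done)
            frontier = has & ~done & domain_mask
            if not frontier.any():
                break
            delta = med - vm
            fire = frontier & (np.abs(delta) > venc)
            if fire.any():
                k = np.round(delta[fire] / two_v)
                vm[fire] += two_v * k
                v[..., c][fire] += (two_v * k)[:, None]
                n_spatial += int(np.count_nonzero(k))
            done |= frontier
    log.info("unwrap_high: %d temporal and %d spatial corrections", n_temporal, n_spatial)
    prov_corr = field_high.provenance.get("corrections", []) + ["unwrap_high"]
    return field_high.copy_with(
        v, corrections=prov_corr, unwrap_counts={"temporal": n_temporal, "spatial": n_spatial}
    )


def merge_dual_venc(
    low: VelocityField, high_unwrapped: VelocityField, per_vector: bool = False
) -> VelocityField:
    """Combine low- and high-VENC fields, de-aliasing the low-VENC data.

    Per voxel, component and frame: if |v_low − v_high| ≤ VENC_low the
    precise low-VENC value is kept; otherwise the low value is shifted by
    the nearest multiple of 2·VENC_low toward the high value.  If the
    shifted value still differs from v_high by more than VENC_low the
    high-VENC value is used and the voxel flagged as a fallback.

    With ``per_vector=True`` the aliasing decision is made once per
    velocity vector (any aliased component triggers correction of the
    vector), mirroring software that compares whole velocity vectors.

    Provenance records the per-voxel source (0 = low kept, 1 = alias
    corrected, 2 = high fallback).
    """
    if low.grid_shape != high_unwrapped.grid_shape or low.n_frames != high_unwrapped.n_frames:
        raise ValueError("low and high VENC fields have mismatched geometry")
    venc_low = low.provenance.get("venc")
    venc_high = high_unwrapped.provenance.get("venc")
    if venc_low is None or venc_high is None or venc_low >= venc_high:
        raise ValueError("expected low.venc < high.venc recorded in provenance")

    vl, vh = low.v, high_unwrapped.v
    diff = vh - vl
    aliased = np.abs(diff) > venc_low
    if per_vector:
        aliased = np.broadcast_to(aliased.any(axis=-1, keepdims=True), aliased.shape)
    k = np.where(aliased, np.round(diff / (2.0 * venc_low)), 0.0)
    corrected = vl + 2.0 * venc_low * k
    fallback = np.abs(corrected - vh) > venc_low
    out = np.where(fallback, vh, corrected)

    source = np.zeros(out.shape, dtype=np.uint8)
    source[aliased & ~fallback] = 1
    source[fallback] = 2
    log.info(
        "dual-VENC merge: %d aliased voxels corrected, %d fallbacks to high VENC",
        int((source == 1).sum()), int((source == 2).sum()),
    )
    return VelocityField(
        spacing=low.spacing.copy(),
        frame_times=low.frame_times.copy(),
        period=low.period,
        v=out,
        provenance={
            "venc": (venc_low, venc_high),
            "corrections": low.provenance.get("corrections", []) + ["merge_dual_venc"],
            "merge_source": source,
            "fallback_count": int((source == 2).sum()),
        },
    )


def compute_angiogram(
    field: VelocityField,
    stack: PhaseStack,
    threshold: float = 0.1,
    seeds_mm: np.ndarray | None = None,
) -> Angiogram:
    """Time-averaged PC angiogram and connected-component lumen.

    Intensity is the time mean of magnitude·|v|.  The lumen is the set of
    connected components (26-connectivity) above ``threshold`` times the
    intensity maximum that contain a seed point; without seeds, the
    component containing the global intensity maximum is used.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if field.grid_shape != stack.grid_shape:
        raise ValueError("field and stack have mismatched geometry")
    intensity = (stack.magnitude * field.speed()).mean(axis=3)
    above = intensity > threshold * intensity.max()
    labels, n = label(above, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        log.warning("angiogram: no voxels above threshold; empty lumen")
        return Angiogram(intensity, np.zeros_like(above))
    if seeds_mm is None:
        seed_idx = [np.unravel_index(np.argmax(intensity), intensity.shape)]
    else:
        pts = np.atleast_2d(np.asarray(seeds_mm, float))
        seed_idx = [tuple(np.clip((p / field.spacing - 0.5).round().astype(int), 0,
                                  np.array(field.grid_shape) - 1)) for p in pts]
    keep = {labels[i] for i in seed_idx if labels[i] > 0}
    lumen = np.isin(labels, sorted(keep)) if keep else np.zeros_like(above)
    log.info("angiogram lumen: %d voxels in %d component(s)", int(lumen.sum()), len(keep))
    return Angiogram(intensity, lumen)


def reconstruct_dual_venc(
    stacks: list[PhaseStack],
    order: int = 1,
    phase_std_max: float = 0.1,
    mag_min: float = 0.3,
    per_vector: bool = False,
) -> tuple[VelocityField, StaticMask]:
    """Full chain: convert, background-correct, unwrap, merge.

    Accepts one stack (single-VENC: no merge) or two (dual-VENC).
    Static tissue is detected on the low-VENC stack (highest phase
    sensitivity) and the same mask corrects both fields.
    """
    if not 1 <= len(stacks) <= 2:
        raise ValueError("expected one or two PhaseStacks")
    stacks = sorted(stacks, key=lambda s: s.venc)
    static = detect_static(stacks[0], phase_std_max, mag_min)
    fields = [correct_background(phase_to_velocity(s), static, order) for s in stacks]
    mag_mean = stacks[0].magnitude.mean(axis=3)
    body = mag_mean > mag_min * mag_mean.max()  # excludes air
    high = unwrap_high(fields[-1], seed_mask=static.mask, domain_mask=body)
    if len(stacks) == 1:
        log.info("single-VENC input: dual-VENC merge skipped")
        return high, static
    return merge_dual_venc(fields[0], high, per_vector=per_vector), static
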