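"""Analytic flow phantom: rasterize a vessel network and MR-encode it.

The phantom turns a :class:`~fetalflow.network.NetworkSpec` into

* a ground-truth :class:`~fetalflow.core.VelocityField` with parabolic
  (Poiseuille) profiles across each vessel, scaled per cardiac frame by
  the vessel waveform, plus exact analytic flux oracles; and
* velocity-encoded :class:`~fetalflow.core.PhaseStack` pairs (one per
  VENC) with phase wrapping, a smooth spatial background phase and
  complex-noise-equivalent perturbations, emulating a dual-VENC fetal
  4D-flow acquisition.

Tissue model: magnitude 1.0 inside vessel lumens, 0.7 in surrounding
static tissue (an ellipsoidal "body" plus a margin around every vessel)
and 0.05 in air.  Phase noise standard deviation is ``1/SNR`` radians,
the small-angle limit of complex Gaussian noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.spatial import cKDTree

from .core import PhaseStack, VelocityField, polynomial_basis, voxel_centers, wrap_phase
from .network import NetworkSpec

__all__ = [
    "AcquisitionSpec",
    "Phantom",
    "build_phantom",
    "sample_truth",
    "analytic_flux",
    "encode",
]

log = logging.getLogger(__name__)

MAG_LUMEN = 1.0
MAG_TISSUE = 0.7
MAG_AIR = 0.05


@dataclass
class AcquisitionSpec:
    """Geometry, timing and encoding parameters of the simulated scan.

    Defaults follow the fetal protocol this package emulates: 8 cardiac
    frames, dual VENC of 50 and 150 cm/s, ~1.2–1.5 mm isotropic voxels.

    ``snr=None`` disables noise; ``background_coeffs`` holds per-component
    polynomial coefficients (radians) on normalised volume coordinates
    (see :func:`fetalflow.core.polynomial_basis`); ``None`` means no
    background phase.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] | float = 1.25
    n_frames: int = 8
    vencs: tuple[float, ...] = (50.0, 150.0)
    snr: float | None = None
    background_coeffs: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing = tuple(np.broadcast_to(np.asarray(self.spacing, float), (3,)))
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        vencs = tuple(float(v) for v in self.vencs)
        if any(v <= 0 for v in vencs) or list(vencs) != sorted(vencs):
            raise ValueError("vencs must be strictly positive and sorted ascending")
        self.vencs = vencs
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be > 0")
        if self.background_coeffs is not None:
            bg = np.atleast_2d(np.asarray(self.background_coeffs, float))
            if bg.shape[0] != 3:
                raise ValueError("background_coeffs must have one row per velocity component")
            self.background_coeffs = bg

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.spacing) * np.asarray(self.grid_shape)

    def frame_times(self, period: float) -> np.ndarray:
        return np.arange(self.n_frames) * (period / self.n_frames)


@dataclass
class Phantom:
    """Rasterized network: truth field plus the masks that define it."""

    truth: VelocityField
    lumen_mask: np.ndarray
    tissue_mask: np.ndarray
    segment_masks: dict[str, np.ndarray]
    network: NetworkSpec
    acq: AcquisitionSpec


def _rasterize_segment(seg, acq: AcquisitionSpec, step: float = 0.25):
    """Voxel indices, unit-flow velocities and radial distances for one segment.

    Returns (flat voxel indices, direction (n,3), profile factor (n,)),
    where ``profile * q(t)`` gives the voxel speed in cm/s for an
    instantaneous flow q in mL/s.
    """
    spacing = np.asarray(acq.spacing)
    shape = np.asarray(acq.grid_shape)
    # densely resample the centerline
    pts = []
    tans = []
    for a, b in zip(seg.centerline[:-1], seg.centerline[1:]):
        d = b - a
        ln = np.linalg.norm(d)
        n = max(2, int(np.ceil(ln / step)) + 1)
        ts = np.linspace(0.0, 1.0, n)
        pts.append(a + ts[:, None] * d)
        tans.append(np.tile(d / ln, (n, 1)))
    cpts = np.concatenate(pts)
    ctan = np.concatenate(tans)

    lo = np.maximum(np.floor((seg.centerline.min(axis=0) - seg.radius) / spacing - 0.5), 0).astype(int)
    hi = np.minimum(
        np.ceil((seg.centerline.max(axis=0) + seg.radius) / spacing - 0.5) + 1, shape
    ).astype(int)
    if np.any(lo >= hi):
        raise ValueError(f"segment {seg.name!r} lies outside the acquisition grid")
    axes = [(np.arange(lo[d], hi[d]) + 0.5) * spacing[d] for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    vox = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    tree = cKDTree(cpts)
    dist, idx = tree.query(vox, k=1)
    near = dist <= seg.radius + step
    if not near.any():
        raise ValueError(f"segment {seg.name!r} lies outside the acquisition grid")
    vox_n = vox[near]
    idx_n = idx[near]
    rel = vox_n - cpts[idx_n]
    tan = ctan[idx_n]
    axial = np.einsum("ij,ij->i", rel, tan)
    radial = np.linalg.norm(rel - axial[:, None] * tan, axis=1)
    inside = radial <= seg.radius
    if not inside.any():
        raise ValueError(f"segment {seg.name!r} has no lumen voxels on this grid")

    ii = np.floor(vox_n[inside] / spacing).astype(int)
    flat = np.ravel_multi_index((ii[:, 0], ii[:, 1], ii[:, 2]), tuple(shape))
    # Poiseuille: v_axial = 2 * q / area * (1 - (r/R)^2); q mL/s, area mm^2 -> cm/s
    profile = 2.0 * 100.0 / (np.pi * seg.radius**2) * (1.0 - (radial[inside] / seg.radius) ** 2)
    return flat, tan[inside], profile


def build_phantom(network: NetworkSpec, acq: AcquisitionSpec) -> Phantom:
    """Rasterize the network into a ground-truth velocity field.

    Voxel velocities follow a parabolic profile across each vessel
    oriented along the local centerline tangent, scaled per frame by the
    vessel waveform.  Where vessels overlap (junction mouths), the voxel
    velocity is the mean-flux-weighted average of the overlapping vessel
    fields — a C0 blend of the continuous anatomy.  Voxels outside all
    lumens are zero.
    """
    for seg in network.segments:
        lo = seg.centerline.min(axis=0) - seg.radius
        hi = seg.centerline.max(axis=0) + seg.radius
        if np.any(lo < 0) or np.any(hi > acq.extent):
            raise ValueError(
                f"segment {seg.name!r} does not fit inside the grid physical extent"
            )
    shape = acq.grid_shape
    period = network.period
    ftimes = acq.frame_times(period)
    nt = acq.n_frames
    nvox = int(np.prod(shape))

    vsum = np.zeros((nvox, nt, 3))
    wsum = np.zeros(nvox)
    seg_masks: dict[str, np.ndarray] = {}
    for seg in network.segments:
        flat, tan, profile = _rasterize_segment(seg, acq)
        q = np.asarray(seg.waveform(ftimes))  # mL/s per frame
        w = max(abs(seg.waveform.mean_flow), 1e-9)
        # velocity contribution: (n, nt, 3) = profile * q[t] * tangent
        contrib = profile[:, None, None] * q[None, :, None] * tan[:, None, :]
        np.add.at(vsum, flat, w * contrib)
        np.add.at(wsum, flat, w)
        m = np.zeros(nvox, dtype=bool)
        m[flat] = True
        seg_masks[seg.name] = m.reshape(shape)

    lumen = (wsum > 0).reshape(shape)
    v = np.zeros((nvox, nt, 3))
    nz = wsum > 0
    v[nz] = vsum[nz] / wsum[nz, None, None]
    v = v.reshape(shape + (nt, 3))

    # body = central ellipsoid + margin around every vessel
    x, y, z = voxel_centers(shape, acq.spacing)
    c = acq.extent / 2.0
    semi = 0.46 * acq.extent
    body = ((x - c[0]) / semi[0]) ** 2 + ((y - c[1]) / semi[1]) ** 2 + (
        (z - c[2]) / semi[2]
    ) ** 2 <= 1.0
    margin_vox = int(np.ceil(5.0 / min(acq.spacing)))
    body |= binary_dilation(lumen, iterations=margin_vox)
    tissue = body & ~lumen

    truth = VelocityField(
        spacing=np.asarray(acq.spacing),
        frame_times=ftimes,
        period=period,
        v=v,
        provenance={"source": "phantom", "weight_kg": network.weight},
    )
    return Phantom(truth, lumen, tissue, seg_masks, network, acq)


def masks_from_geometry(
    geometry: dict[str, tuple[np.ndarray, float]], acq: AcquisitionSpec
) -> dict[str, np.ndarray]:
    """Voxel lumen masks from bare (centerline, radius) geometry.

    Used to rebuild sink regions from a serialised network without
    re-instantiating waveforms.
    """
    from types import SimpleNamespace

    shape = acq.grid_shape
    out = {}
    for name, (centerline, radius) in geometry.items():
        shim = SimpleNamespace(name=name, centerline=np.asarray(centerline, float), radius=radius)
        flat, _, _ = _rasterize_segment(shim, acq)
        m = np.zeros(int(np.prod(shape)), dtype=bool)
        m[flat] = True
        out[name] = m.reshape(shape)
    return out


def sample_truth(network: NetworkSpec, acq: AcquisitionSpec) -> VelocityField:
    """Ground-truth velocity field of the network on the acquisition grid."""
    return build_phantom(network, acq).truth


def analytic_flux(
    network: NetworkSpec, segment_name: str, frame: int, n_frames: int = 8
) -> float:
    """Exact volumetric flow (mL/s) of a segment at a cardiac frame.

    Frames sample the cycle uniformly: frame ``f`` is at time
    ``f * period / n_frames``.  This is the oracle the flux-measurement
    tests compare against.
    """
    seg = network.segment(segment_name)
    if not 0 <= frame < n_frames:
        raise IndexError(f"frame {frame} out of range for {n_frames} frames")
    t = frame * (network.period / n_frames)
    return float(seg.waveform(np.array([t]))[0])


def _magnitude_volume(ph: Phantom) -> np.ndarray:
    mag = np.full(ph.lumen_mask.shape, MAG_AIR)
    mag[ph.tissue_mask] = MAG_TISSUE
    mag[ph.lumen_mask] = MAG_LUMEN
    return mag


def encode(truth: VelocityField, acq: AcquisitionSpec, phantom: Phantom | None = None) -> list[PhaseStack]:
    """Velocity-encode a truth field into one PhaseStack per VENC.

    Per voxel, component and frame the stored phase is
    ``wrap(pi * v / VENC + background(x) + noise)``; the background is a
    smooth polynomial of the voxel world coordinates shared by all VENCs
    (an eddy-current-like offset), and the phase noise standard deviation
    is ``1/SNR`` radians.  Magnitude is 1 in the lumen, 0.7 in static
    tissue and 0.05 in air, with Gaussian noise of the same SNR.
    Identical ``acq.seed`` gives identical output.
    """
    if tuple(truth.grid_shape) != tuple(acq.grid_shape):
        raise ValueError("truth geometry does not match the acquisition spec")
    shape = truth.grid_shape
    nt = truth.n_frames
    if phantom is not None:
        mag0 = _magnitude_volume(phantom)
        lumen = phantom.lumen_mask
    else:
        speed = truth.speed().max(axis=-1)
        lumen = speed > 0
        mag0 = np.where(lumen, MAG_LUMEN, MAG_TISSUE)

    if acq.background_coeffs is not None:
        x, y, z = voxel_centers(shape, acq.spacing)
        coords = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
        n_terms = acq.background_coeffs.shape[1]
        order = 0
        from .core import n_polynomial_terms

        while n_polynomial_terms(order) < n_terms:
            order += 1
        if n_polynomial_terms(order) != n_terms:
            raise ValueError("background_coeffs length does not match a polynomial order")
        basis = polynomial_basis(coords, order, truth.extent / 2.0, truth.extent / 2.0)
        bg = (basis @ acq.background_coeffs.T).reshape(shape + (3,))
    else:
        bg = np.zeros(shape + (3,))

    rng = np.random.default_rng(acq.seed)
    stacks = []
    for venc in acq.vencs:
        phase = np.pi * truth.v / venc + bg[:, :, :, None, :]
        mag = np.broadcast_to(mag0[..., None], shape + (nt,)).copy()
        if acq.snr is not None:
            phase = phase + rng.normal(0.0, 1.0 / acq.snr, size=phase.shape)
            mag = mag + rng.normal(0.0, 1.0 / acq.snr, size=mag.shape)
        stacks.append(
            PhaseStack(
                spacing=np.asarray(acq.spacing),
                frame_times=truth.frame_times.copy(),
                period=truth.period,
                magnitude=mag,
                phase=wrap_phase(phase),
                venc=venc,
            )
        )
    log.info(
        "encoded %d VENC stack(s) (vencs=%s, snr=%s, seed=%d)",
        len(stacks), acq.vencs, acq.snr, acq.seed,
    )
    return stacks
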