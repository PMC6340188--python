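"""Core containers and grid utilities shared across the pipeline.

Conventions
-----------
* Volumes are numpy arrays indexed ``[i, j, k]`` along x, y, z; the time
  (cardiac frame) axis comes after the spatial axes, and vector
  components last: magnitude ``(nx, ny, nz, nt)``, phase/velocity
  ``(nx, ny, nz, nt, 3)``.
* Voxel centers sit at ``(index + 0.5) * spacing``; the world origin is
  the volume corner; axes are right-handed.  Physical coordinates in mm,
  velocities in cm/s, time in ms, phase in radians.
* Wrapped phase lives in the half-open interval (−π, π].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "PhaseStack",
    "VelocityField",
    "wrap_phase",
    "voxel_centers",
    "polynomial_basis",
    "n_polynomial_terms",
]


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase into (−π, π]."""
    return np.pi - np.mod(np.pi - np.asarray(phi, dtype=float), 2.0 * np.pi)


def voxel_centers(shape, spacing) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World coordinates (mm) of voxel centers as a broadcastable meshgrid."""
    spacing = np.broadcast_to(np.asarray(spacing, float), (3,))
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def n_polynomial_terms(order: int) -> int:
    """Number of 3D monomials of total degree <= order."""
    return (order + 1) * (order + 2) * (order + 3) // 6


def polynomial_basis(coords: np.ndarray, order: int, center: np.ndarray, halfspan: np.ndarray) -> np.ndarray:
    """Monomial design matrix on normalised coordinates.

    ``coords`` is (N, 3) in mm; coordinates are mapped to
    ``(x - center) / halfspan`` (roughly [−1, 1] across the volume) so
    coefficients are O(1) radians regardless of FOV.  Terms are ordered
    by total degree, then lexicographically in (x, y, z) powers, e.g.
    order 1 gives columns [1, x, y, z].
    """
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    u = (np.asarray(coords, float) - center) / halfspan
    cols = [np.ones(len(u))]
    for deg in range(1, order + 1):
        for powers in combinations_with_replacement(range(3), deg):
            col = np.ones(len(u))
            for ax in powers:
                col = col * u[:, ax]
            cols.append(col)
    return np.stack(cols, axis=1)


@dataclass
class _Gridded:
    spacing: np.ndarray  # (3,) mm
    frame_times: np.ndarray  # (nt,) ms within one period
    period: float  # ms

    def _validate_timing(self, nt: int) -> None:
        self.spacing = np.broadcast_to(np.asarray(self.spacing, float), (3,)).copy()
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be > 0")
        if len(self.frame_times) != nt:
            raise ValueError("frame_times length must match the frame axis")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.period <= 0 or self.frame_times[-1] >= self.period:
            raise ValueError("frame_times must lie within one period")

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the volume (mm) per axis."""
        return self.spacing * np.array(self.grid_shape)


@dataclass
class PhaseStack(_Gridded):
    """One velocity-encoded acquisition: magnitude + wrapped phase series.

    ``magnitude`` has shape (nx, ny, nz, nt); ``phase`` has shape
    (nx, ny, nz, nt, 3) with values in (−π, π]; ``venc`` is the velocity
    (cm/s) that maps to a phase of π.
    """

    magnitude: np.ndarray = None
    phase: np.ndarray = None
    venc: float = 0.0

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.venc <= 0:
            raise ValueError("venc must be > 0")
        if self.phase.shape != self.magnitude.shape + (3,):
            raise ValueError("phase must have shape magnitude.shape + (3,)")
        if self.phase.size and (self.phase.max() > np.pi or self.phase.min() <= -np.pi):
            raise ValueError("phase values must lie in (-pi, pi]")
        self._validate_timing(self.magnitude.shape[3])

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.magnitude.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[3]


@dataclass
class VelocityField(_Gridded):
    """Cardiac-resolved 3-component velocity volume in cm/s.

    The central exchange type of the pipeline.  ``provenance`` records
    which VENC(s) produced it and which corrections have been applied.
    """

    v: np.ndarray = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 5 or self.v.shape[4] != 3:
            raise ValueError("v must have shape (nx, ny, nz, nt, 3)")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("velocity field contains non-finite values")
        self._validate_timing(self.v.shape[3])

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.v.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.v.shape[3]

    def copy_with(self, v: np.ndarray, **prov) -> "VelocityField":
        return VelocityField(
            spacing=self.spacing.copy(),
            frame_times=self.frame_times.copy(),
            period=self.period,
            v=v,
            provenance={**self.provenance, **prov},
        )

    def speed(self) -> np.ndarray:
        """|v| per voxel/frame, cm/s."""
        return np.linalg.norm(self.v, axis=-1)

    def sample_frame(self, points_mm: np.ndarray, frame: int) -> np.ndarray:
        """Trilinearly sample the 3 velocity components at world points.

        Between the boundary voxel centers and the volume faces the edge
        value is extended (nearest), so trajectories can actually reach
        the boundary instead of stalling in an artificial fade-out skirt.
        """
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        coords = (pts / self.spacing - 0.5).T  # fractional voxel indices
        out = np.empty((len(pts), 3))
        for c in range(3):
            out[:, c] = map_coordinates(self.v[..., frame, c], coords, order=1, mode="nearest")
        return out

    def sample(self, points_mm: np.ndarray, t_ms: float) -> np.ndarray:
        """Sample velocity at world points and an arbitrary time.

        Trilinear in space, linear in time with periodic wrap: the last
        frame interpolates to the first.
        """
        t = float(t_ms) % self.period
        ft = self.frame_times
        nt = self.n_frames
        i = int(np.searchsorted(ft, t, side="right") - 1)
        if i < 0:  # t before first frame time: wrap from last frame
            i = nt - 1
            t = t + self.period
        j = (i + 1) % nt
        t_hi = ft[j] if j > i else ft[0] + self.period
        alpha = (t - ft[i]) / (t_hi - ft[i])
        a = self.sample_frame(points_mm, i)
        if alpha == 0.0:
            return a
        b = self.sample_frame(points_mm, j)
        return (1.0 - alpha) * a + alpha * b
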