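"""Vessel flow quantification and derived hemodynamic statistics.

Flow is measured through oriented cross-sectional planes: the velocity
field is trilinearly resampled on an in-plane pixel grid, the through-
plane component is integrated over the lumen pixels per cardiac frame,
and the waveform is cycle-averaged and indexed to fetal body weight
(mL/min per kg).  Derived quantities follow fetal-circulation practice:

* combined ventricular output CVO = 1.03 · (MPA + AAo), the 3% term
  accounting for unmeasured coronary flow, and %CVO per vessel;
* pulmonary blood flow PBF = LPA + RPA;
* conservation-of-mass checks at the standard fetal junction identities
  (IVCp = RHV + DV + IVCd; SVC + IVCp = MPA + FO; MPA = DA + PBF;
  IVCp = DAo), reported as symmetric percent differences;
* method-comparison statistics (least-squares regression, Bland-Altman
  limits of agreement, paired t-test) for e.g. 4D-flow vs 2D PC data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .core import VelocityField
from .network import NetworkSpec

__all__ = [
    "AnalysisPlane",
    "FlowWaveform",
    "MeasurementTable",
    "JunctionCheck",
    "MethodComparison",
    "make_plane",
    "align_plane",
    "flow_waveform",
    "build_table",
    "junction_check",
    "consistency_summary",
    "compare_methods",
    "voxels_per_diameter",
    "default_measurement_planes",
    "STANDARD_JUNCTIONS",
]

log = logging.getLogger(__name__)

#: the four standard fetal conservation identities (name, inflows, outflows)
STANDARD_JUNCTIONS: list[tuple[str, tuple[str, ...], tuple[str, ...]]] = [
    ("ivc_confluence", ("RHV", "DV", "IVCd"), ("IVCp",)),
    ("right_atrium", ("SVC", "IVCp"), ("MPA", "FO")),
    ("pulmonary_bifurcation", ("MPA",), ("DA", "PBF")),
    ("lower_body_return", ("IVCp",), ("DAo",)),
]


def _orthonormal_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


@dataclass
class AnalysisPlane:
    """Oriented cross-section with an in-plane lumen mask.

    The plane is sampled on a square pixel grid spanning
    ``±(radius + margin)`` around ``center`` along two in-plane basis
    vectors; ``lumen_pixels`` marks pixels inside the vessel contour
    (default: a disc of the given radius).
    """

    center: np.ndarray
    normal: np.ndarray
    radius: float
    pixel_size: float
    vessel: str = ""
    lumen_pixels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)
        self.normal = np.asarray(self.normal, float)
        nn = np.linalg.norm(self.normal)
        if abs(nn - 1.0) > 1e-9:
            if nn == 0:
                raise ValueError("plane normal must be non-zero")
            self.normal = self.normal / nn
        if self.radius <= 0 or self.pixel_size <= 0:
            raise ValueError("radius and pixel_size must be > 0")
        self._e1, self._e2 = _orthonormal_basis(self.normal)
        half = self.radius + self.pixel_size
        n_px = int(np.ceil(2 * half / self.pixel_size))
        offs = (np.arange(n_px) - (n_px - 1) / 2.0) * self.pixel_size
        self._u, self._v = np.meshgrid(offs, offs, indexing="ij")
        if self.lumen_pixels is None:
            self.lumen_pixels = (self._u**2 + self._v**2) <= self.radius**2
        self.lumen_pixels = np.asarray(self.lumen_pixels, dtype=bool)
        if self.lumen_pixels.shape != self._u.shape:
            raise ValueError("lumen_pixels shape must match the plane pixel grid")

    @property
    def pixel_area(self) -> float:
        """Area of one in-plane pixel, mm²."""
        return self.pixel_size**2

    @property
    def lumen_area(self) -> float:
        """Lumen area from the pixel mask, mm²."""
        return float(self.lumen_pixels.sum()) * self.pixel_area

    def pixel_points(self) -> np.ndarray:
        """World coordinates (mm) of the lumen pixel centers, (n, 3)."""
        u = self._u[self.lumen_pixels]
        v = self._v[self.lumen_pixels]
        return self.center + u[:, None] * self._e1 + v[:, None] * self._e2

    def to_dict(self) -> dict:
        return {
            "vessel": self.vessel,
            "center_mm": self.center.tolist(),
            "normal": self.normal.tolist(),
            "radius_mm": self.radius,
            "pixel_size_mm": self.pixel_size,
        }


def make_plane(
    center, normal, radius: float, field: VelocityField | None = None,
    pixel_size: float | None = None, vessel: str = "",
) -> AnalysisPlane:
    """Convenience constructor; default pixel size is half the smallest voxel."""
    if pixel_size is None:
        if field is None:
            raise ValueError("provide pixel_size or a field to derive it from")
        pixel_size = float(min(field.spacing)) / 2.0
    return AnalysisPlane(center=np.asarray(center, float), normal=np.asarray(normal, float),
                         radius=radius, pixel_size=pixel_size, vessel=vessel)


@dataclass
class FlowWaveform:
    """Per-frame volumetric flow through one plane."""

    q: np.ndarray  # mL/s per frame
    frame_times: np.ndarray  # ms
    vessel: str
    weight: float  # kg

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)

    @property
    def mean_flow(self) -> float:
        """Cycle-average flow, mL/min."""
        return float(self.q.mean()) * 60.0

    @property
    def indexed_flow(self) -> float:
        """Weight-indexed mean flow, mL/min per kg."""
        return self.mean_flow / self.weight


@dataclass
class JunctionCheck:
    """Conservation-of-mass result at one junction."""

    name: str
    inflows: tuple[str, ...]
    outflows: tuple[str, ...]
    pct_diff: float
    skipped: bool = False
    reason: str = ""


@dataclass
class MethodComparison:
    """Regression + Bland-Altman + paired t-test between two methods."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    r2: float
    bias: float
    loa_low: float
    loa_high: float
    p: float
    n: int
    t_undefined: bool = False


@dataclass
class MeasurementTable:
    """Per-vessel indexed flows with CVO, %CVO and PBF for one subject."""

    flows: dict[str, float]  # vessel -> mL/min per kg
    weight: float
    cvo: float | None = None  # mL/min per kg
    pct_cvo: dict[str, int] = field(default_factory=dict)


def align_plane(
    field: VelocityField, plane: AnalysisPlane, max_iter: int = 10, tol_deg: float = 0.5
) -> AnalysisPlane:
    """Orient a plane perpendicular to the local mean flow.

    Iteratively sets the normal to the normalised time-and-space mean
    velocity within the lumen pixels, re-sampling the plane after each
    update, until the normal direction changes by less than ``tol_deg``
    or ``max_iter`` is reached.
    """
    current = plane
    for _ in range(max_iter):
        pts = current.pixel_points()
        vmean = np.zeros(3)
        for f in range(field.n_frames):
            vmean += field.sample_frame(pts, f).mean(axis=0)
        vmean /= field.n_frames
        norm = np.linalg.norm(vmean)
        if norm < 1e-9:
            raise ValueError("mean velocity in the plane lumen is zero; cannot orient")
        new_n = vmean / norm
        if np.dot(new_n, current.normal) < 0:
            new_n = -new_n  # keep orientation continuity
        angle = math.degrees(math.acos(np.clip(np.dot(new_n, current.normal), -1.0, 1.0)))
        current = AnalysisPlane(
            center=current.center, normal=new_n, radius=current.radius,
            pixel_size=current.pixel_size, vessel=current.vessel,
        )
        if angle < tol_deg:
            break
    return current


def flow_waveform(field: VelocityField, plane: AnalysisPlane, weight: float) -> FlowWaveform:
    """Integrate through-plane flow per cardiac frame.

    q(frame) = Σ over lumen pixels of (v·n̂)·pixel_area, with velocity
    trilinearly sampled at pixel centers.  Units: cm/s × mm² → mL/s via
    the factor 0.01.
    """
    if not plane.lumen_pixels.any():
        raise ValueError("plane lumen mask is empty")
    pts = plane.pixel_points()
    q = np.empty(field.n_frames)
    for f in range(field.n_frames):
        vn = field.sample_frame(pts, f) @ plane.normal
        q[f] = vn.sum() * plane.pixel_area * 0.01
    return FlowWaveform(q=q, frame_times=field.frame_times.copy(),
                        vessel=plane.vessel, weight=weight)


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def build_table(
    waveforms: list[FlowWaveform], weight: float, cvo: float | None = None
) -> MeasurementTable:
    """Assemble indexed flows, PBF, CVO and %CVO from measured waveforms.

    PBF = LPA + RPA is added when both branches are present.  CVO
    defaults to 1.03·(MPA + AAo) and may be overridden (e.g. with a
    cohort value); without MPA and AAo (and no override) CVO is undefined
    and %CVO left empty.  %CVO values are rounded half-away-from-zero to
    integers, matching how distributions are reported.
    """
    vessels = [w.vessel for w in waveforms]
    if len(set(vessels)) != len(vessels):
        raise ValueError("duplicate vessel labels in waveforms")
    flows = {w.vessel: w.indexed_flow for w in waveforms}
    if "LPA" in flows and "RPA" in flows and "PBF" not in flows:
        flows["PBF"] = flows["LPA"] + flows["RPA"]
    if cvo is None and "MPA" in flows and "AAo" in flows:
        cvo = 1.03 * (flows["MPA"] + flows["AAo"])
    pct = {}
    if cvo is not None:
        pct = {v: _round_half_away(100.0 * q / cvo) for v, q in flows.items()}
    return MeasurementTable(flows=flows, weight=weight, cvo=cvo, pct_cvo=pct)


def junction_check(
    table: MeasurementTable,
    inflows: tuple[str, ...],
    outflows: tuple[str, ...],
    name: str = "",
    denominator: str = "mean",
) -> JunctionCheck:
    """Percent difference between junction inflow and outflow.

    pct_diff = 100·|Σin − Σout| / D with D the mean of the two sides
    (symmetric, bounded; the default) or Σin (``denominator="inflow"``).
    Junctions with unmeasured vessels are skipped with the reason
    recorded rather than raising, since real studies routinely leave
    vessels unidentified.
    """
    if denominator not in ("mean", "inflow"):
        raise ValueError("denominator must be 'mean' or 'inflow'")
    missing = [v for v in (*inflows, *outflows) if v not in table.flows]
    if missing:
        log.info("junction %s skipped: missing %s", name or "?", missing)
        return JunctionCheck(name=name, inflows=tuple(inflows), outflows=tuple(outflows),
                             pct_diff=float("nan"), skipped=True,
                             reason=f"missing vessels: {', '.join(missing)}")
    qin = sum(table.flows[v] for v in inflows)
    qout = sum(table.flows[v] for v in outflows)
    denom = (qin + qout) / 2.0 if denominator == "mean" else qin
    pct = 0.0 if denom == 0 else 100.0 * abs(qin - qout) / denom
    return JunctionCheck(name=name, inflows=tuple(inflows), outflows=tuple(outflows),
                         pct_diff=float(pct))


def consistency_summary(checks: list[JunctionCheck]) -> tuple[float, float, int]:
    """Mean ± sample SD of percent differences over performed checks.

    Returns (mean, sd, n); with a single check the SD is reported as 0.
    """
    vals = [c.pct_diff for c in checks if not c.skipped]
    if not vals:
        raise ValueError("no junction checks to summarise")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return mean, sd, len(vals)


def compare_methods(pairs: list[tuple[float, float]]) -> MethodComparison:
    """Method comparison of paired flow measurements (method A vs B).

    Ordinary least squares of A on B with a normal-theory 95% slope
    confidence interval and R²; Bland-Altman bias = mean(A − B) with
    limits of agreement bias ± 1.96·SD(diff); two-sided paired t-test.
    Zero variance of the differences leaves the t-test undefined
    (flagged, p = nan).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise ValueError("need at least 3 (A, B) pairs")
    a, b = arr[:, 0], arr[:, 1]
    model = sm.OLS(a, sm.add_constant(b)).fit()
    intercept, slope = model.params
    ci = model.conf_int(alpha=0.05)
    diff = a - b
    sd = float(np.std(diff, ddof=1))
    bias = float(diff.mean())
    undefined = sd == 0.0
    if undefined:
        p = float("nan")
    else:
        p = float(stats.ttest_rel(a, b).pvalue)
    return MethodComparison(
        slope=float(slope), intercept=float(intercept),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        r2=float(model.rsquared), bias=bias,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        p=p, n=len(arr), t_undefined=undefined,
    )


def voxels_per_diameter(area_mm2: float, voxel_mm: float) -> float:
    """Vessel diameter in voxels, assuming a circular cross-section.

    The resolution adequacy check: a lumen of area A has diameter
    2·sqrt(A/π), expressed in units of the voxel size.
    """
    if area_mm2 < 0 or voxel_mm <= 0:
        raise ValueError("area must be >= 0 and voxel size > 0")
    return 2.0 * math.sqrt(area_mm2 / math.pi) / voxel_mm


def default_measurement_planes(
    network: NetworkSpec, field: VelocityField, frac: float = 0.5,
    radius_factor: float = 1.15,
) -> dict[str, AnalysisPlane]:
    """One analysis plane per vessel at mid-segment, normal to the centerline.

    The contour radius is the lumen radius times ``radius_factor`` so the
    integration captures the partial-volume skirt of edge voxels.
    """
    planes = {}
    for seg in network.segments:
        p, t = seg.point_and_tangent(frac)
        planes[seg.name] = make_plane(p, t, seg.radius * radius_factor, field=field,
                                      vessel=seg.name)
    return planes
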