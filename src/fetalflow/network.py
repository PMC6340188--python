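"""Fetal vessel network: segments, junctions and the default topology.

The default network is a schematic three-dimensional layout of the fetal
central circulation: umbilical vein (UV) and ductus venosus (DV), distal
and proximal inferior vena cava (IVCd, IVCp), right hepatic vein (RHV),
superior vena cava (SVC), the right-heart path to the main pulmonary
artery (MPA) with ductus arteriosus (DA) and branch pulmonary arteries
(LPA, RPA), the foramen ovale (FO) shunt to the left heart, ascending
aorta (AAo), brachiocephalic trunk (BT) and descending aorta (DAo).

Mean flows are anchored to indexed flows measured by fetal-sheep 4D-flow
CMR (``tables.sheep_4d_flows``).  Because measured tables are never
exactly mass-conserving, a spanning subset of vessels (MPA, AAo, DAo, UV,
DV, IVCd, SVC, LPA, RPA) takes the measured values and the remaining
flows (RHV, IVCp, FO, DA, BT) are derived from conservation of mass, so
every junction balances by construction.

Waveforms are assigned per vessel class and composed across junctions:
daughters of a splitter carry fixed fractions of the parent waveform,
confluences carry sums, and the foramen ovale carries the difference
(systemic venous return minus right-ventricular output), which produces
its characteristic diastolic-dominant flow with transient systolic
reversal.  Instantaneous junctions therefore balance at every time
point, not just on the cycle mean.  The distal identity IVCp = DAo
(lower-body return equals descending-aortic supply) holds only on the
cycle mean, as in vivo, and is flagged ``instantaneous=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tables import sheep_4d_flows
from .waveforms import CombinedWaveform, TemplateWaveform, Waveform, WaveformSpec

__all__ = [
    "VesselSegment",
    "Junction",
    "NetworkSpec",
    "make_default_network",
    "polyline_point_tangent",
]


def polyline_point_tangent(centerline: np.ndarray, frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and unit tangent at an arclength fraction along a polyline."""
    centerline = np.asarray(centerline, float)
    seg = np.diff(centerline, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(lens)])
    s = float(np.clip(frac, 0.0, 1.0)) * cum[-1]
    i = min(int(np.searchsorted(cum[1:], s, side="right")), len(lens) - 1)
    local = (s - cum[i]) / lens[i]
    return centerline[i] + local * seg[i], seg[i] / lens[i]

VESSEL_NAMES = (
    "UV", "DV", "IVCd", "IVCp", "RHV", "SVC", "MPA", "DA",
    "LPA", "RPA", "AAo", "BT", "DAo", "FO",
)

#: reference fetal weight (kg) at which the default geometry is drawn
REFERENCE_WEIGHT = 2.8
#: default fetal heart rate, beats per minute
DEFAULT_HEART_RATE = 140.0

# relative balance tolerance at junctions
_BALANCE_TOL = 1e-3


@dataclass
class VesselSegment:
    """One vessel: a centerline polyline (mm), lumen radius (mm), waveform."""

    name: str
    centerline: np.ndarray
    radius: float
    waveform: Waveform

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.radius <= 0:
            raise ValueError(f"segment {self.name}: radius must be > 0")
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3 or len(self.centerline) < 2:
            raise ValueError(f"segment {self.name}: centerline needs >= 2 3D points")
        steps = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError(f"segment {self.name}: consecutive centerline points must differ")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1).sum())

    def point_and_tangent(self, frac: float) -> tuple[np.ndarray, np.ndarray]:
        """Point and unit tangent at an arclength fraction in [0, 1]."""
        return polyline_point_tangent(self.centerline, frac)


@dataclass
class Junction:
    """A conservation-of-mass location: sum(inflows) == sum(outflows).

    ``instantaneous`` marks physical confluences/splitters where the
    balance holds frame by frame; cycle-mean-only identities (flow
    through compliant intervening structures) set it to False.
    """

    name: str
    inflows: tuple[str, ...]
    outflows: tuple[str, ...]
    instantaneous: bool = True


@dataclass
class NetworkSpec:
    """A vessel network with junction conservation enforced on construction."""

    segments: list[VesselSegment]
    junctions: list[Junction]
    weight: float
    heart_rate: float = DEFAULT_HEART_RATE

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate segment names")
        self._by_name = {s.name: s for s in self.segments}
        for j in self.junctions:
            for v in (*j.inflows, *j.outflows):
                if v not in self._by_name:
                    raise ValueError(f"junction {j.name!r} references unknown segment {v!r}")
            self._check_balance(j)

    def _check_balance(self, j: Junction) -> None:
        qin = sum(self._by_name[v].waveform.mean_flow for v in j.inflows)
        qout = sum(self._by_name[v].waveform.mean_flow for v in j.outflows)
        scale = max(abs(qin), abs(qout), 1e-12)
        if abs(qin - qout) / scale > _BALANCE_TOL:
            raise ValueError(
                f"junction {j.name!r} unbalanced: inflow {qin:.3f} vs outflow {qout:.3f} mL/min"
            )
        if j.instantaneous:
            t = np.linspace(0.0, self.period, 64, endpoint=False)
            fin = sum(np.asarray(self._by_name[v].waveform(t)) for v in j.inflows)
            fout = sum(np.asarray(self._by_name[v].waveform(t)) for v in j.outflows)
            tol = _BALANCE_TOL * max(np.max(np.abs(fin)), np.max(np.abs(fout)), 1e-12)
            if np.max(np.abs(fin - fout)) > tol:
                raise ValueError(f"junction {j.name!r} does not balance frame-by-frame")

    @property
    def period(self) -> float:
        """Cardiac period in ms."""
        return 60000.0 / self.heart_rate

    def segment(self, name: str) -> VesselSegment:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown segment {name!r}") from None

    @property
    def segment_names(self) -> list[str]:
        return [s.name for s in self.segments]

    def indexed_mean_flow(self, name: str) -> float:
        """Cycle-mean flow of a segment indexed to weight, mL/min per kg."""
        return self.segment(name).waveform.mean_flow / self.weight

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) corner of the network including lumen radii, mm."""
        lo = np.full(3, np.inf)
        hi = np.full(3, -np.inf)
        for s in self.segments:
            lo = np.minimum(lo, s.centerline.min(axis=0) - s.radius)
            hi = np.maximum(hi, s.centerline.max(axis=0) + s.radius)
        return lo, hi

    def to_dict(self) -> dict:
        """JSON-serialisable summary (geometry, radii, mean flows)."""
        return {
            "weight_kg": self.weight,
            "heart_rate_bpm": self.heart_rate,
            "period_ms": self.period,
            "segments": [
                {
                    "name": s.name,
                    "radius_mm": s.radius,
                    "centerline_mm": s.centerline.tolist(),
                    "mean_flow_ml_min": s.waveform.mean_flow,
                    "indexed_flow_ml_min_kg": s.waveform.mean_flow / self.weight,
                }
                for s in self.segments
            ],
            "junctions": [
                {
                    "name": j.name,
                    "inflows": list(j.inflows),
                    "outflows": list(j.outflows),
                    "instantaneous": j.instantaneous,
                }
                for j in self.junctions
            ],
        }


# --- default fetal network -------------------------------------------------

# schematic centerlines (mm) drawn for a ~2.8 kg fetus in a 120 mm FOV
_GEOMETRY: dict[str, tuple[list[list[float]], float]] = {
    "UV": ([[45, 20, 10], [45, 23, 22], [45, 25, 32]], 3.4),
    "DV": ([[45, 25, 32], [49, 31, 42], [55, 38, 52]], 2.8),
    "IVCd": ([[62, 45, 10], [60, 42, 36], [55, 38, 52]], 3.2),
    "RHV": ([[38, 42, 42], [55, 38, 52]], 2.4),
    "IVCp": ([[55, 38, 52], [55, 42, 64]], 4.3),
    "SVC": ([[60, 45, 105], [57, 43, 80], [55, 42, 64]], 3.4),
    "MPA": ([[55, 42, 64], [50, 46, 74], [46, 52, 86]], 4.0),
    "FO": ([[55, 42, 64], [63, 45, 66], [70, 48, 70]], 3.6),
    "AAo": ([[70, 48, 70], [66, 54, 84], [58, 58, 94]], 3.8),
    "DA": ([[46, 52, 86], [58, 58, 94]], 3.7),
    "BT": ([[58, 58, 94], [56, 52, 108]], 3.0),
    "DAo": ([[58, 58, 94], [63, 66, 80], [64, 70, 40], [62, 68, 12]], 4.2),
    "LPA": ([[46, 52, 86], [30, 56, 92]], 2.3),
    "RPA": ([[46, 52, 86], [34, 46, 80]], 2.3),
}

# per-class template parameters (peak_time, peak_to_mean, 2nd ratio, 2nd time)
_VENOUS = {
    "DV": dict(peak_time=0.25, peak_to_mean=1.5, second_peak_ratio=0.5, second_peak_time=0.7),
    "IVCd": dict(peak_time=0.25, peak_to_mean=1.6, second_peak_ratio=0.55, second_peak_time=0.7),
    "RHV": dict(peak_time=0.25, peak_to_mean=1.5, second_peak_ratio=0.5, second_peak_time=0.7),
    "SVC": dict(peak_time=0.22, peak_to_mean=1.7, second_peak_ratio=0.6, second_peak_time=0.68),
    # UV: "nearly constant" — weak residual pulsatility so it remains
    # distinguishable from static tissue in the phase time-series
    "UV": dict(peak_time=0.3, peak_to_mean=1.3, second_peak_ratio=0.4, second_peak_time=0.75),
}


def make_default_network(
    weight: float = REFERENCE_WEIGHT, heart_rate: float = DEFAULT_HEART_RATE
) -> NetworkSpec:
    """Default fetal-circulation network for a fetus of the given weight.

    Mean flows equal the sheep 4D-flow indexed values times ``weight`` for
    the anchored vessels (MPA 284, AAo 245, DAo 333, UV 197, DV 144,
    IVCd 117, SVC 181, LPA 20, RPA 18 mL/min per kg); derived vessels
    (RHV 72, IVCp 333, FO 230, DA 246, BT 158) close the junction
    balances exactly.  Lumen radii scale as ``(weight / 2.8)**(1/3)``.

    Parameters
    ----------
    weight:
        Fetal body weight in kg (> 0).
    heart_rate:
        Fetal heart rate in bpm; sets the cardiac period of all waveforms.
    """
    if weight <= 0:
        raise ValueError("weight must be > 0")
    table = sheep_4d_flows()
    period = 60000.0 / heart_rate
    idx = {k: v for k, v in table.items() if k != "CVO"}
    idx["LPA"], idx["RPA"] = 20.0, 18.0  # split of PBF = 38

    def tmpl(kind: str, name: str, indexed_flow: float, **kw) -> Waveform:
        spec = WaveformSpec(kind=kind, period=period, mean_flow=indexed_flow * weight, **kw)
        return TemplateWaveform(spec)

    wf: dict[str, Waveform] = {}
    for name, pars in _VENOUS.items():
        if name in idx:  # RHV is derived below
            wf[name] = tmpl("venous_biphasic", name, idx[name], **pars)
    wf["MPA"] = tmpl("arterial", "MPA", idx["MPA"], peak_time=0.2, peak_to_mean=2.5)
    wf["AAo"] = tmpl("arterial", "AAo", idx["AAo"], peak_time=0.2, peak_to_mean=2.5)
    # derived flows close every junction
    wf["RHV"] = tmpl(
        "venous_biphasic", "RHV", idx["DAo"] - idx["DV"] - idx["IVCd"], **_VENOUS["RHV"]
    )
    wf["IVCp"] = CombinedWaveform([(1.0, wf["RHV"]), (1.0, wf["DV"]), (1.0, wf["IVCd"])])
    wf["FO"] = CombinedWaveform([(1.0, wf["SVC"]), (1.0, wf["IVCp"]), (-1.0, wf["MPA"])])
    wf["DA"] = CombinedWaveform([((idx["MPA"] - idx["LPA"] - idx["RPA"]) / idx["MPA"], wf["MPA"])])
    wf["LPA"] = CombinedWaveform([(idx["LPA"] / idx["MPA"], wf["MPA"])])
    wf["RPA"] = CombinedWaveform([(idx["RPA"] / idx["MPA"], wf["MPA"])])
    arch_in = CombinedWaveform([(1.0, wf["AAo"]), (1.0, wf["DA"])])
    f_dao = idx["DAo"] / (arch_in.mean_flow / weight)
    wf["DAo"] = CombinedWaveform([(f_dao, arch_in)])
    wf["BT"] = CombinedWaveform([(1.0 - f_dao, arch_in)])

    rscale = (weight / REFERENCE_WEIGHT) ** (1.0 / 3.0)
    segments = [
        VesselSegment(name, np.array(pts, float), r * rscale, wf[name])
        for name, (pts, r) in _GEOMETRY.items()
    ]
    junctions = [
        Junction("ivc_confluence", ("RHV", "DV", "IVCd"), ("IVCp",)),
        Junction("right_atrium", ("SVC", "IVCp"), ("MPA", "FO")),
        Junction("pulmonary_bifurcation", ("MPA",), ("DA", "LPA", "RPA")),
        Junction("aortic_arch", ("AAo", "DA"), ("DAo", "BT")),
        Junction("lower_body_return", ("DAo",), ("IVCp",), instantaneous=False),
    ]
    return NetworkSpec(segments=segments, junctions=junctions, weight=weight, heart_rate=heart_rate)
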