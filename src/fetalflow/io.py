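"""File formats: NIfTI volumes with JSON sidecars, CSV/JSON reports, VTK.

Layout of one encoded acquisition (per VENC)::

    <prefix>_mag.nii        magnitude, 4D (x, y, z, frame)
    <prefix>_phase_x.nii    wrapped phase per component, 4D
    <prefix>_phase_y.nii
    <prefix>_phase_z.nii
    <prefix>.json           {venc, spacing_mm, frame_times_ms, period_ms, seed}

Velocity fields are stored as three component NIfTIs plus a provenance
JSON.  Pathlines are written both as legacy ASCII VTK polylines with a
per-point scalar speed array (renderable in ParaView and similar
viewers) and as a long-format CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import PhaseStack, VelocityField
from .trace import PathlineSet
from .quant import FlowWaveform

__all__ = [
    "write_phase_stack",
    "read_phase_stack",
    "write_velocity_field",
    "read_velocity_field",
    "write_waveforms_csv",
    "write_pathlines_vtk",
    "write_pathlines_csv",
    "write_streaming_csv",
]

_COMP = ("x", "y", "z")


def _affine(spacing) -> np.ndarray:
    aff = np.diag([*np.asarray(spacing, float), 1.0])
    # voxel centers at (index + 0.5) * spacing
    aff[:3, 3] = np.asarray(spacing, float) * 0.5
    return aff


def _save_nii(path: Path, data: np.ndarray, spacing) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(spacing))
    img.header.set_zooms(tuple(np.asarray(spacing, float)) + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))


def write_phase_stack(stack: PhaseStack, prefix: str | Path, seed: int | None = None) -> list[Path]:
    """Write one VENC acquisition as NIfTI series plus a JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    _save_nii(prefix.with_name(prefix.name + "_mag.nii"), stack.magnitude, stack.spacing)
    written.append(prefix.with_name(prefix.name + "_mag.nii"))
    for c in range(3):
        p = prefix.with_name(f"{prefix.name}_phase_{_COMP[c]}.nii")
        _save_nii(p, stack.phase[..., c], stack.spacing)
        written.append(p)
    sidecar = {
        "venc": stack.venc,
        "spacing_mm": list(map(float, stack.spacing)),
        "frame_times_ms": list(map(float, stack.frame_times)),
        "period_ms": float(stack.period),
    }
    if seed is not None:
        sidecar["seed"] = int(seed)
    sp = prefix.with_suffix(".json")
    sp.write_text(json.dumps(sidecar, indent=2))
    written.append(sp)
    return written


def read_phase_stack(prefix: str | Path) -> PhaseStack:
    """Read an acquisition written by :func:`write_phase_stack`."""
    prefix = Path(prefix)
    sp = prefix.with_suffix(".json")
    if not sp.exists():
        raise FileNotFoundError(f"missing sidecar metadata: {sp}")
    meta = json.loads(sp.read_text())
    mag = np.asarray(nib.load(str(prefix.with_name(prefix.name + "_mag.nii"))).dataobj, float)
    phase = np.stack(
        [
            np.asarray(
                nib.load(str(prefix.with_name(f"{prefix.name}_phase_{c}.nii"))).dataobj, float
            )
            for c in _COMP
        ],
        axis=-1,
    )
    # float32 round-trip can nudge values a hair past pi; fold back
    phase = np.clip(phase, np.nextafter(-np.pi, 0.0), np.pi)
    return PhaseStack(
        spacing=np.asarray(meta["spacing_mm"]),
        frame_times=np.asarray(meta["frame_times_ms"]),
        period=meta["period_ms"],
        magnitude=mag,
        phase=phase,
        venc=meta["venc"],
    )


def write_velocity_field(field: VelocityField, prefix: str | Path) -> list[Path]:
    """Write a velocity field as component NIfTIs plus provenance JSON."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for c in range(3):
        p = prefix.with_name(f"{prefix.name}_v{_COMP[c]}.nii")
        _save_nii(p, field.v[..., c], field.spacing)
        written.append(p)
    prov = {k: v for k, v in field.provenance.items() if not isinstance(v, np.ndarray)}
    meta = {
        "spacing_mm": list(map(float, field.spacing)),
        "frame_times_ms": list(map(float, field.frame_times)),
        "period_ms": float(field.period),
        "provenance": prov,
    }
    sp = prefix.with_suffix(".json")
    sp.write_text(json.dumps(meta, indent=2, default=str))
    written.append(sp)
    return written


def read_velocity_field(prefix: str | Path) -> VelocityField:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    v = np.stack(
        [
            np.asarray(nib.load(str(prefix.with_name(f"{prefix.name}_v{c}.nii"))).dataobj, float)
            for c in _COMP
        ],
        axis=-1,
    )
    return VelocityField(
        spacing=np.asarray(meta["spacing_mm"]),
        frame_times=np.asarray(meta["frame_times_ms"]),
        period=meta["period_ms"],
        v=v,
        provenance=meta.get("provenance", {}),
    )


def write_waveforms_csv(waveforms: list[FlowWaveform], path: str | Path) -> Path:
    """Wide-format CSV: frame_time_ms plus one q_mL_s column per vessel."""
    path = Path(path)
    df = pd.DataFrame({"frame_time_ms": waveforms[0].frame_times})
    for w in waveforms:
        df[f"q_mL_s_{w.vessel}"] = w.q
    df.to_csv(path, index=False)
    return path


def write_pathlines_vtk(paths: PathlineSet, path: str | Path) -> Path:
    """Legacy ASCII VTK polylines with a per-point scalar speed array."""
    path = Path(path)
    pts = [p.positions for p in paths.paths]
    speeds = [p.speeds for p in paths.paths]
    n_pts = sum(len(p) for p in pts)
    lines = [
        "# vtk DataFile Version 3.0",
        f"fetalflow pathlines source={paths.source}",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n_pts} float",
    ]
    for arr in pts:
        lines.extend(" ".join(f"{x:.4f}" for x in row) for row in arr)
    n_lines = len(pts)
    size = sum(len(p) + 1 for p in pts)
    lines.append(f"LINES {n_lines} {size}")
    offset = 0
    for arr in pts:
        ids = " ".join(str(offset + i) for i in range(len(arr)))
        lines.append(f"{len(arr)} {ids}")
        offset += len(arr)
    lines.append(f"POINT_DATA {n_pts}")
    lines.append("SCALARS speed_cm_s float 1")
    lines.append("LOOKUP_TABLE default")
    for arr in speeds:
        lines.extend(f"{s:.4f}" for s in arr)
    path.write_text("\n".join(lines) + "\n")
    return path


def write_pathlines_csv(paths: PathlineSet, path: str | Path) -> Path:
    """Long-format CSV: particle_id, t_ms, x, y, z, speed."""
    path = Path(path)
    rows = []
    for i, p in enumerate(paths.paths):
        rows.append(
            pd.DataFrame(
                {
                    "particle_id": i,
                    "t_ms": p.times,
                    "x_mm": p.positions[:, 0],
                    "y_mm": p.positions[:, 1],
                    "z_mm": p.positions[:, 2],
                    "speed_cm_s": p.speeds,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    return path


def write_streaming_csv(matrices: list, path: str | Path) -> Path:
    """Streaming matrices as CSV (one row per source, columns per sink)."""
    path = Path(path)
    rows = {}
    for m in matrices:
        rows[m.source] = m.fractions
    pd.DataFrame.from_dict(rows, orient="index").fillna(0.0).rename_axis("source").to_csv(path)
    return path
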