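"""Shared fixtures: small analytic phantoms and the full-size study rig."""

from __future__ import annotations

import numpy as np
import pytest

from fetalflow.network import Junction, NetworkSpec, VesselSegment, make_default_network
from fetalflow.phantom import AcquisitionSpec, build_phantom, encode
from fetalflow.recon import compute_angiogram, reconstruct_dual_venc
from fetalflow.waveforms import TemplateWaveform, WaveformSpec

try:  # derandomise hypothesis where available
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def constant_waveform(q_ml_min: float, period: float = 400.0) -> TemplateWaveform:
    return TemplateWaveform(WaveformSpec("constant", period, q_ml_min))


def straight_tube_network(
    radius: float = 3.0,
    q_ml_min: float | None = None,
    peak_cm_s: float = 40.0,
    kind: str = "constant",
    period: float = 400.0,
) -> NetworkSpec:
    """One z-aligned tube (named MPA) centred in a 48 mm box.

    Default flow is set from the requested centerline peak speed via the
    parabolic-profile relation Q = v_peak·πR²/2.
    """
    if q_ml_min is None:
        q_ml_min = peak_cm_s * np.pi * radius**2 / 2.0 / 100.0 * 60.0  # mL/min
        if kind == "arterial":  # systolic peak = peak_to_mean × cycle-mean peak
            q_ml_min /= 2.5
    spec = WaveformSpec(kind, period, q_ml_min)
    seg = VesselSegment("MPA", [[24.0, 24.0, 6.0], [24.0, 24.0, 42.0]], radius,
                        TemplateWaveform(spec))
    return NetworkSpec([seg], [], weight=1.0, heart_rate=60000.0 / period)


@pytest.fixture(scope="session")
def tube():
    """Steady Poiseuille tube phantom: R = 3 mm, centerline peak 40 cm/s."""
    net = straight_tube_network()
    acq = AcquisitionSpec(grid_shape=(48, 48, 48), spacing=1.0, n_frames=2,
                          vencs=(150.0,), snr=None)
    return net, acq, build_phantom(net, acq)


@pytest.fixture(scope="session")
def pulse_tube():
    """Pulsatile tube phantom: arterial waveform, systolic centerline peak
    ~140 cm/s, dual VENC 50/150 — the low-VENC data alias."""
    net = straight_tube_network(kind="arterial", peak_cm_s=140.0)
    acq = AcquisitionSpec(grid_shape=(48, 48, 48), spacing=1.0, n_frames=8,
                          vencs=(50.0, 150.0), snr=None)
    return net, acq, build_phantom(net, acq)


@pytest.fixture(scope="session")
def default_network():
    return make_default_network()


def ysplit_phantom():
    """Steady Y-junction: parent (DV) splits 80/20 into FO and MPA branches.

    Branch radii are matched so both daughters carry the same mean
    velocity, making uniform-area particle emission route approximately
    flux-proportionally.
    """
    period = 400.0
    segs = [
        VesselSegment("DV", [[36, 28, 6], [36, 28, 30]], 5.37, constant_waveform(400, period)),
        VesselSegment("FO", [[36, 28, 30], [54, 28, 58]], 4.8, constant_waveform(320, period)),
        VesselSegment("MPA", [[36, 28, 30], [22, 28, 54]], 2.4, constant_waveform(80, period)),
    ]
    net = NetworkSpec(segs, [Junction("split", ("DV",), ("FO", "MPA"))],
                      weight=1.0, heart_rate=60000.0 / period)
    acq = AcquisitionSpec(grid_shape=(72, 56, 72), spacing=1.0, n_frames=2,
                          vencs=(150.0,), snr=None)
    return net, acq, build_phantom(net, acq)


@pytest.fixture(scope="session")
def ysplit():
    return ysplit_phantom()


def two_channel_phantom():
    """Two parallel, non-communicating z-aligned channels (A and B)."""
    period = 400.0
    segs = [
        VesselSegment("DV", [[16, 24, 6], [16, 24, 42]], 4.0, constant_waveform(200, period)),
        VesselSegment("IVCd", [[40, 24, 6], [40, 24, 42]], 4.0, constant_waveform(200, period)),
    ]
    net = NetworkSpec(segs, [], weight=1.0, heart_rate=60000.0 / period)
    acq = AcquisitionSpec(grid_shape=(56, 48, 48), spacing=1.0, n_frames=2,
                          vencs=(150.0,), snr=None)
    return net, acq, build_phantom(net, acq)


# ---- full-size study rig (built once; used by the acceptance suite) -------

LINEAR_BACKGROUND = np.array(
    [
        [0.05, 0.10, -0.08, 0.12],
        [0.02, -0.10, 0.05, 0.03],
        [-0.04, 0.06, 0.09, -0.07],
    ]
)


@pytest.fixture(scope="session")
def study_rig():
    """Noise-free dual-VENC phantom at full study geometry, reconstructed.

    Default fetal network (2.8 kg, 140 bpm) on a 96³ grid of 1.25 mm
    voxels, 8 cardiac frames, VENC 50/150 cm/s, linear background phase;
    peak speeds ~130 cm/s so the low-VENC data alias heavily.
    """
    net = make_default_network()
    acq = AcquisitionSpec(grid_shape=(96, 96, 96), spacing=1.25, n_frames=8,
                          vencs=(50.0, 150.0), snr=None,
                          background_coeffs=LINEAR_BACKGROUND, seed=0)
    ph = build_phantom(net, acq)
    stacks = encode(ph.truth, acq, phantom=ph)
    low = min(stacks, key=lambda s: s.venc)
    merged, static = reconstruct_dual_venc(stacks)
    angio = compute_angiogram(merged, low)
    return {
        "network": net,
        "acq": acq,
        "phantom": ph,
        "stacks": stacks,
        "merged": merged,
        "static": static,
        "angiogram": angio,
    }
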