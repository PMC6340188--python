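"""Pulsatile flow waveform templates for the fetal circulation.

Three qualitative waveform classes occur in the fetal great vessels:

* ``arterial`` — a large systolic lobe with low diastolic runoff
  (MPA, AAo, DA, DAo, BT, branch pulmonary arteries);
* ``venous_biphasic`` — two unequal lobes per cycle (the S and D waves of
  systemic venous return), with pulsatility increasing toward the heart
  (SVC, IVC, DV, hepatic veins);
* ``constant`` — flat flow, the idealisation of the umbilical vein, which
  is decoupled from intracardiac pressure swings by the placenta.

Templates are built from cosine-power lobes ``((1 + cos 2πτ)/2)**m``.
These are trigonometric polynomials of degree ``m``, so any uniform
sampling with more than ``2m`` frames integrates them exactly: the mean
over ``n`` cardiac frames equals the continuous cycle mean to machine
precision for ``n >= 8`` and the default sharpness ``m = 4``.  That makes
frame-sampled flux oracles exact rather than approximately renormalised.

Waveforms evaluate to volumetric flow in mL/s at a time in ms; the stored
``mean_flow`` is in mL/min, matching how fetal flows are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np

__all__ = [
    "WaveformSpec",
    "Waveform",
    "TemplateWaveform",
    "CombinedWaveform",
    "make_waveform",
]

_KINDS = ("arterial", "venous_biphasic", "constant")


@dataclass(frozen=True)
class WaveformSpec:
    """Parameters of one waveform template.

    Parameters
    ----------
    kind:
        One of ``arterial``, ``venous_biphasic``, ``constant``.
    period:
        Cardiac period in ms (> 0).
    mean_flow:
        Cycle-mean volumetric flow in mL/min.  Must be >= 0 for the
        ``constant`` and ``venous_biphasic`` kinds.
    peak_time:
        Fraction of the cycle at which the (first) lobe peaks.
    peak_to_mean:
        Ratio of peak flow to cycle-mean flow (> 1 for pulsatile kinds).
    second_peak_ratio:
        Biphasic only: amplitude of the second lobe relative to the first.
    second_peak_time:
        Biphasic only: cycle fraction of the second lobe peak.
    sharpness:
        Lobe sharpness exponent ``m`` (integer >= 1); larger values give
        narrower lobes.  Must stay below half the number of cardiac frames
        for frame means to remain exact.
    """

    kind: str
    period: float
    mean_flow: float
    peak_time: float = 0.2
    peak_to_mean: float = 2.5
    second_peak_ratio: float = 0.6
    second_peak_time: float = 0.65
    sharpness: int = 4

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown waveform kind {self.kind!r}; expected one of {_KINDS}")
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if self.kind in ("constant", "venous_biphasic") and self.mean_flow < 0:
            raise ValueError(f"mean_flow must be >= 0 for kind {self.kind!r}")
        if self.kind != "constant":
            if self.peak_to_mean <= 1:
                raise ValueError("peak_to_mean must exceed 1 for pulsatile waveforms")
            if self.sharpness < 1:
                raise ValueError("sharpness must be a positive integer")


def _lobe_mean(m: int) -> float:
    # cycle mean of ((1+cos)/2)^m = C(2m, m) / 4^m
    return comb(2 * m, m) / 4.0**m


def _lobe(tau: np.ndarray, center: float, m: int) -> np.ndarray:
    return ((1.0 + np.cos(2.0 * np.pi * (tau - center))) / 2.0) ** m


class Waveform:
    """Periodic volumetric flow signal q(t) [mL/s]."""

    period: float
    mean_flow: float  # mL/min

    def __call__(self, t_ms):  # pragma: no cover - abstract
        raise NotImplementedError

    def frame_values(self, n_frames: int) -> np.ndarray:
        """Flow at ``n_frames`` uniformly spaced frame times (mL/s)."""
        t = np.arange(n_frames) * (self.period / n_frames)
        return np.asarray(self(t), dtype=float)

    def cycle_mean(self, n: int = 4096) -> float:
        """Numerical cycle mean in mL/min (fine uniform quadrature)."""
        t = (np.arange(n) + 0.5) * (self.period / n)
        return float(np.mean(self(t))) * 60.0


class TemplateWaveform(Waveform):
    """Waveform realised from a :class:`WaveformSpec`.

    The dimensionless shape is an offset plus one or two cosine-power
    lobes; the offset is solved so the peak-to-mean ratio matches the
    spec, then the whole shape is scaled so the analytic cycle mean
    equals ``mean_flow``.
    """

    def __init__(self, spec: WaveformSpec):
        self.spec = spec
        self.period = spec.period
        self.mean_flow = spec.mean_flow
        if spec.kind == "constant":
            self._offset = 1.0
            self._amps: tuple[float, ...] = ()
            self._centers: tuple[float, ...] = ()
            shape_mean = 1.0
        else:
            m = spec.sharpness
            mu = _lobe_mean(m)
            if spec.kind == "arterial":
                amps = (1.0,)
                centers = (spec.peak_time,)
            else:
                amps = (1.0, spec.second_peak_ratio)
                centers = (spec.peak_time, spec.second_peak_time)
            # Solve baseline d so that peak/mean == p, with unit first lobe.
            # peak value ~= d + sum of lobes at the first peak; mean = d + mu*sum(amps)
            p = spec.peak_to_mean
            peak_lobes = sum(a * _lobe(np.array([centers[0]]), c, m)[0] for a, c in zip(amps, centers))
            lobe_mean = mu * sum(amps)
            d = (lobe_mean * p - peak_lobes) / (1.0 - p)
            if d + peak_lobes <= 0:
                raise ValueError("waveform shape parameters give a non-positive peak")
            self._offset = d
            self._amps = tuple(amps)
            self._centers = tuple(centers)
            shape_mean = d + lobe_mean
        if shape_mean <= 0:
            raise ValueError("waveform shape has non-positive mean; adjust pulsatility parameters")
        # mL/min -> mL/s, then normalise the shape mean to 1
        self._scale = (spec.mean_flow / 60.0) / shape_mean

    def __call__(self, t_ms):
        t = np.asarray(t_ms, dtype=float)
        tau = t / self.period
        out = np.full_like(tau, self._offset)
        m = self.spec.sharpness
        for a, c in zip(self._amps, self._centers):
            out = out + a * _lobe(tau, c, m)
        return out * self._scale


class CombinedWaveform(Waveform):
    """Linear combination of waveforms (used to balance junctions).

    Flow splitters assign each daughter a fixed fraction of the parent
    waveform; confluences sum their tributaries; the foramen ovale is a
    difference (venous return minus right-ventricular output), which
    naturally yields its diastolic-dominant, transiently reversing
    pattern.  Linear combinations keep the trigonometric degree of the
    templates, so frame-sampled means stay exact.
    """

    def __init__(self, terms: Sequence[tuple[float, Waveform]]):
        if not terms:
            raise ValueError("CombinedWaveform needs at least one term")
        periods = {w.period for _, w in terms}
        if len(periods) != 1:
            raise ValueError("all combined waveforms must share one period")
        self.terms = [(float(c), w) for c, w in terms]
        self.period = periods.pop()
        self.mean_flow = float(sum(c * w.mean_flow for c, w in self.terms))

    def __call__(self, t_ms):
        t = np.asarray(t_ms, dtype=float)
        out = np.zeros_like(t)
        for c, w in self.terms:
            out = out + c * np.asarray(w(t))
        return out


def make_waveform(spec: WaveformSpec) -> Waveform:
    """Build the waveform for a spec, verifying the mean-flow invariant."""
    w = TemplateWaveform(spec)
    if spec.mean_flow != 0:
        rel = abs(w.cycle_mean() - spec.mean_flow) / abs(spec.mean_flow)
        if rel > 1e-3:
            raise AssertionError(f"waveform mean normalisation failed (rel err {rel:.2e})")
    return w
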