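"""Flow quantification: plane integration, derived tables, statistics."""

import numpy as np
import pytest

from fetalflow.core import VelocityField
from fetalflow.phantom import analytic_flux
from fetalflow.quant import (
    STANDARD_JUNCTIONS,
    FlowWaveform,
    JunctionCheck,
    MeasurementTable,
    align_plane,
    build_table,
    compare_methods,
    consistency_summary,
    flow_waveform,
    junction_check,
    make_plane,
    voxels_per_diameter,
)
from fetalflow.tables import reference_pct_cvo, sheep_4d_flows


def _uniform_flow_field(v_vec, shape=(32, 32, 32), nt=2, spacing=1.0):
    v = np.broadcast_to(np.asarray(v_vec, float), shape + (nt, 3)).copy()
    return VelocityField(spacing=np.full(3, spacing), frame_times=np.arange(nt) * 100.0,
                         period=nt * 100.0, v=v, provenance={})


def _wf(vessel, indexed_flow, weight=1.0, nt=8):
    q = np.full(nt, indexed_flow * weight / 60.0)
    return FlowWaveform(q=q, frame_times=np.arange(nt) * 50.0, vessel=vessel, weight=weight)


# --- plane alignment -------------------------------------------------------


def test_align_plane_converges_to_flow_direction():
    field = _uniform_flow_field([0.0, 0.0, 10.0])
    tilted = np.array([np.sin(np.radians(30)), 0.0, np.cos(np.radians(30))])
    plane = make_plane([16, 16, 16], tilted, 4.0, field=field)
    aligned = align_plane(field, plane, max_iter=3, tol_deg=0.5)
    assert np.dot(aligned.normal, [0, 0, 1]) == pytest.approx(1.0, abs=1e-9)


def test_align_plane_zero_flow_errors():
    field = _uniform_flow_field([0.0, 0.0, 0.0])
    plane = make_plane([16, 16, 16], [0, 0, 1], 4.0, field=field)
    with pytest.raises(ValueError, match="zero"):
        align_plane(field, plane)


def test_align_plane_tracks_curved_centerline(default_network, study_rig):
    """On the phantom, alignment lands within 5° of the centerline tangent."""
    field = study_rig["phantom"].truth
    seg = default_network.segment("DAo")
    center, tangent = seg.point_and_tangent(0.4)
    start = tangent + np.array([0.3, -0.2, 0.1])
    plane = make_plane(center, start / np.linalg.norm(start), seg.radius, field=field)
    aligned = align_plane(field, plane)
    angle = np.degrees(np.arccos(np.clip(abs(np.dot(aligned.normal, tangent)), 0, 1)))
    assert angle < 5.0


# --- flux integration ------------------------------------------------------


def test_uniform_flow_through_known_area():
    """10 cm/s through a 1 cm² lumen is 10 mL/s."""
    field = _uniform_flow_field([0.0, 0.0, 10.0])
    radius = np.sqrt(100.0 / np.pi)  # 1 cm² disc
    plane = make_plane([16, 16, 16], [0, 0, 1], radius, field=field)
    wf = flow_waveform(field, plane, weight=1.0)
    assert wf.q == pytest.approx(10.0, rel=0.02)


def test_flipping_normal_negates_waveform(tube):
    net, acq, ph = tube
    plane = make_plane([24, 24, 24], [0, 0, 1], 3.3, field=ph.truth, vessel="MPA")
    fwd = flow_waveform(ph.truth, plane, 1.0)
    bwd = flow_waveform(ph.truth, make_plane([24, 24, 24], [0, 0, -1], 3.3, field=ph.truth), 1.0)
    assert np.allclose(fwd.q, -bwd.q)


def test_flux_linearity_in_field_scale(tube):
    net, acq, ph = tube
    plane = make_plane([24, 24, 24], [0, 0, 1], 3.3, field=ph.truth)
    base = flow_waveform(ph.truth, plane, 1.0)
    scaled_field = ph.truth.copy_with(3.0 * ph.truth.v)
    scaled = flow_waveform(scaled_field, plane, 1.0)
    assert np.allclose(scaled.q, 3.0 * base.q)


def test_tube_flux_matches_oracle_per_frame(pulse_tube):
    """Noise-free pulsatile tube at ≥3.5 voxels/diameter: every frame's
    measured flux within 2% of the analytic waveform."""
    net, acq, ph = pulse_tube
    plane = make_plane([24, 24, 24], [0, 0, 1], 3.0 * 1.15, field=ph.truth, vessel="MPA")
    wf = flow_waveform(ph.truth, plane, 1.0)
    oracle = np.array([analytic_flux(net, "MPA", f, acq.n_frames) for f in range(acq.n_frames)])
    assert np.all(np.abs(wf.q - oracle) <= 0.02 * np.abs(oracle))


def test_empty_lumen_raises():
    field = _uniform_flow_field([0, 0, 1.0])
    plane = make_plane([16, 16, 16], [0, 0, 1], 2.0, field=field)
    plane.lumen_pixels[:] = False
    with pytest.raises(ValueError, match="empty"):
        flow_waveform(field, plane, 1.0)


# --- measurement table -----------------------------------------------------


def test_cvo_from_mpa_and_aao():
    table = build_table([_wf("MPA", 284.0), _wf("AAo", 245.0)], weight=1.0)
    assert table.cvo == pytest.approx(1.03 * 529.0)  # 544.87


def test_pct_cvo_with_external_cvo():
    table = build_table([_wf("MPA", 284.0)], weight=1.0, cvo=546.0)
    assert table.pct_cvo["MPA"] == 52


def test_pbf_is_branch_sum():
    table = build_table([_wf("LPA", 20.0), _wf("RPA", 18.0)], weight=1.0, cvo=546.0)
    assert table.flows["PBF"] == pytest.approx(38.0)
    assert table.pct_cvo["PBF"] == 7


def test_duplicate_vessels_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        build_table([_wf("MPA", 1.0), _wf("MPA", 2.0)], weight=1.0)


def test_cvo_undefined_without_outflows():
    table = build_table([_wf("SVC", 181.0)], weight=1.0)
    assert table.cvo is None
    assert table.pct_cvo == {}


def test_printed_pct_cvo_row_reproduced():
    """The integer %CVO row of the 4D-flow cohort follows from its mean
    indexed flows and CVO 546 (all vessels except DA, whose printed value
    does not round from the printed flows)."""
    flows = sheep_4d_flows()
    table = build_table(
        [_wf(v, q) for v, q in flows.items() if v != "CVO"],
        weight=1.0, cvo=flows["CVO"],
    )
    printed = reference_pct_cvo().loc["sheep_4d_flow"]
    for vessel in ("MPA", "AAo", "SVC", "PBF", "DAo", "UV", "FO", "IVCd", "IVCp", "DV"):
        assert table.pct_cvo[vessel] == printed[vessel], vessel


# --- junction checks -------------------------------------------------------


def test_junction_balance_zero():
    t = MeasurementTable(flows={"A": 50.0, "B": 30.0, "C": 80.0}, weight=1.0)
    c = junction_check(t, ("A", "B"), ("C",))
    assert c.pct_diff == 0.0


def test_junction_percent_difference_mean_denominator():
    t = MeasurementTable(flows={"in": 100.0, "out": 90.0}, weight=1.0)
    assert junction_check(t, ("in",), ("out",)).pct_diff == pytest.approx(10.526, abs=1e-3)
    assert junction_check(t, ("in",), ("out",), denominator="inflow").pct_diff == pytest.approx(10.0)


def test_junction_missing_vessel_skipped():
    t = MeasurementTable(flows={"DV": 144.0, "IVCd": 117.0, "IVCp": 357.0}, weight=1.0)
    c = junction_check(t, ("RHV", "DV", "IVCd"), ("IVCp",), name="ivc_confluence")
    assert c.skipped and "RHV" in c.reason
    assert np.isnan(c.pct_diff)


def test_consistency_summary_values():
    checks = [
        junction_check(MeasurementTable({"a": 110.0, "b": 100.0}, 1.0), ("a",), ("b",)),
        junction_check(MeasurementTable({"a": 120.0, "b": 100.0}, 1.0), ("a",), ("b",)),
    ]
    # percent diffs: 9.524 and 18.182 under the mean denominator
    mean, sd, n = consistency_summary(checks)
    assert n == 2
    assert mean == pytest.approx(np.mean([c.pct_diff for c in checks]))
    assert sd == pytest.approx(np.std([c.pct_diff for c in checks], ddof=1))


def _check(pct):
    return JunctionCheck(name="j", inflows=("a",), outflows=("b",), pct_diff=pct)


def test_consistency_summary_hand_arithmetic():
    mean, sd, n = consistency_summary([_check(10.0), _check(20.0)])
    assert (mean, n) == (15.0, 2)
    assert sd == pytest.approx(7.071, abs=1e-3)


def test_consistency_summary_degenerate_cases():
    assert consistency_summary([_check(5.0)]) == (5.0, 0.0, 1)
    assert consistency_summary([_check(0.0), _check(0.0)]) == (0.0, 0.0, 2)
    with pytest.raises(ValueError):
        consistency_summary([])
    skipped = JunctionCheck("j", ("a",), ("b",), float("nan"), skipped=True, reason="missing")
    with pytest.raises(ValueError):
        consistency_summary([skipped])


# --- method comparison -----------------------------------------------------


def test_identical_pairs_give_perfect_agreement():
    pairs = [(10.0, 10.0), (20.0, 20.0), (35.0, 35.0), (50.0, 50.0)]
    mc = compare_methods(pairs)
    assert mc.bias == 0.0
    assert mc.loa_low == mc.loa_high == 0.0
    assert mc.slope == pytest.approx(1.0)
    assert mc.r2 == pytest.approx(1.0)
    assert mc.t_undefined


def test_constant_offset_pairs_flag_undefined_t():
    mc = compare_methods([(1.0, 2.0), (2.0, 3.0), (3.0, 4.0)])
    assert mc.bias == pytest.approx(-1.0)
    assert mc.t_undefined and np.isnan(mc.p)
    assert mc.loa_low == mc.loa_high == pytest.approx(-1.0)


def test_known_bias_recovered_within_sampling_error():
    rng = np.random.default_rng(11)
    n, b, s = 65, -21.9, 30.0
    x = rng.uniform(50, 400, size=n)
    y = x + b + rng.normal(0, s, size=n)
    mc = compare_methods(list(zip(y, x)))
    assert abs(mc.bias - b) <= 3 * s / np.sqrt(n)
    assert not mc.t_undefined


def test_compare_methods_needs_three_pairs():
    with pytest.raises(ValueError):
        compare_methods([(1.0, 1.0), (2.0, 2.0)])


# --- resolution check ------------------------------------------------------


@pytest.mark.parametrize(
    "area,voxel,expected",
    [(21.5, 1.5, 3.5), (np.pi * 1.2**2, 1.2, 2.0), (1e-12, 1.0, 0.0)],
)
def test_voxels_per_diameter(area, voxel, expected):
    assert voxels_per_diameter(area, voxel) == pytest.approx(expected, abs=0.05)


def test_voxels_per_diameter_validation():
    with pytest.raises(ValueError):
        voxels_per_diameter(10.0, 0.0)
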