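"""Ring frame, densities, bootstrap, sigmoid fits, wave speed, pullers."""

import numpy as np
import pandas as pd
import pytest

from mycowave import colonysim as cs
from mycowave import netmodel as nm
from mycowave import waveprofile as wp
from mycowave.netmodel import NetworkSeries, Trail


# ---------------------------------------------------------------------------
# ring construction
# ---------------------------------------------------------------------------

def test_ring_boundaries_follow_equal_area_closed_form():
    rings = wp.make_rings((0, 0), 45.0, 15)
    k = np.arange(16)
    assert np.allclose(rings.boundaries_mm, 45.0 * np.sqrt(k / 15))
    assert rings.boundaries_mm[1] == pytest.approx(11.6189, abs=1e-3)
    # every half-annulus has the same area
    b = rings.boundaries_mm
    areas = np.pi / 2 * (b[1:] ** 2 - b[:-1] ** 2)
    assert np.allclose(areas, np.pi / 2 * 45.0**2 / 15)
    assert rings.area_mm2 == pytest.approx(areas[0])


def test_two_rings():
    rings = wp.make_rings((0, 0), 45.0, 2)
    assert rings.boundaries_mm[1] == pytest.approx(45.0 / np.sqrt(2))
    assert rings.boundaries_mm[2] == pytest.approx(45.0)


def test_rings_reject_bad_arguments():
    with pytest.raises(ValueError):
        wp.make_rings((0, 0), 45.0, 1)
    with pytest.raises(ValueError):
        wp.make_rings((0, 0), -1.0, 5)


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def _series_from_segments(segments, r_max_mm=10.0, widths=9.0):
    """A minimal one-frame series made of independent straight segments."""
    trails = {}
    for i, (a, b) in enumerate(segments):
        trails[i] = Trail(
            hypha_id=i,
            verts=np.array([a, b], dtype=float),
            times=np.array([0.0, 0.0]),
            origin_node=2 * i,
            tip_node=2 * i + 1,
            width_um=widths,
            label="RH",
        )
    return NetworkSeries(
        timepoints=np.array([0.0]),
        node_rows=pd.DataFrame(columns=["node_id", "t_h", "x_um", "y_um", "degree"]),
        trails=trails,
        root_anchors=[],
        anchor_nodes=[],
        roi={"offset_mm": 6.0, "radius_mm": r_max_mm},
    )


def test_single_edge_density_arithmetic():
    # 1,000 μm edge inside the innermost ring
    series = _series_from_segments([((0, 1000), (0, 2000))])
    rings = wp.make_rings((0, 0), 10.0, 4)
    prof = wp.ring_densities(series, rings)
    assert prof.rho[0, 0] == pytest.approx(1000.0 / rings.area_mm2, rel=1e-3)
    assert prof.rho[0, 1:].sum() == 0


def test_edge_straddling_a_boundary_is_conserved():
    rings = wp.make_rings((0, 0), 10.0, 4)
    r1_um = rings.boundaries_mm[1] * 1000
    series = _series_from_segments([((0, r1_um - 700), (0, r1_um + 300))])
    prof = wp.ring_densities(series, rings)
    total = (prof.rho[0] * rings.area_mm2).sum()
    assert total == pytest.approx(1000.0, rel=1e-3)
    assert prof.rho[0, 0] * rings.area_mm2 == pytest.approx(700.0, rel=0.05)


def test_simulated_colony_mass_balance(colony_medium):
    _, series, _, _ = colony_medium
    rings = wp.make_rings((0, 0), 25.0, 10)
    prof = wp.ring_densities(series, rings)
    for i in (-1, len(series.timepoints) // 2):
        g = nm.snapshot(series, series.timepoints[i])
        total = sum(d["length_um"] for *_, d in g.edges(data=True))
        assert (prof.rho[i] * rings.area_mm2).sum() == pytest.approx(total, rel=1e-3)


def test_empty_series_warns_and_returns_zero():
    series = _series_from_segments([])
    rings = wp.make_rings((0, 0), 10.0, 4)
    with pytest.warns(UserWarning, match="empty"):
        prof = wp.ring_densities(series, rings)
    assert prof.rho.sum() == 0


# ---------------------------------------------------------------------------
# bootstrap uncertainties
# ---------------------------------------------------------------------------

def _random_segment_series(rng, n_seg, r_lim=(0.0, 20.0), seg_len_um=30.0,
                           poisson=False):
    """Short segments scattered uniformly (by area) in a half-annulus.

    With ``poisson=True`` the segment count itself is Poisson(n_seg), so
    any sub-region's count is Poisson too (a planar Poisson process)."""
    r0, r1 = r_lim
    n = rng.poisson(n_seg) if poisson else n_seg
    segs = []
    for _ in range(n):
        r = np.sqrt(rng.uniform(r0**2, r1**2)) * 1000
        th = rng.uniform(0, np.pi)
        ang = rng.uniform(0, 2 * np.pi)
        cx, cy = r * np.cos(th), r * np.sin(th)
        dx = 0.5 * seg_len_um * np.cos(ang)
        dy = 0.5 * seg_len_um * np.sin(ang)
        segs.append(((cx - dx, cy - dy), (cx + dx, cy + dy)))
    return _series_from_segments(segs, r_max_mm=20.0)


def test_bootstrap_sd_is_deterministic(colony_medium):
    _, series, _, _ = colony_medium
    rings = wp.make_rings((0, 0), 25.0, 6)
    t = series.timepoints[-1]
    a = wp.bootstrap_density_sd(series, rings, 1, t, n_cells=400, n_boot=50, seed=3)
    b = wp.bootstrap_density_sd(series, rings, 1, t, n_cells=400, n_boot=50, seed=3)
    assert a == b and a > 0


def test_bootstrap_sd_matches_monte_carlo_for_poisson_segments():
    """For a Poisson scatter of short segments, the spatial bootstrap s.d.
    of the ring mean density agrees with the true sampling s.d. across
    independent realizations (within 30%)."""
    rings = wp.make_rings((0, 0), 20.0, 4)
    n_total = 1600  # ~400 expected in each equal-area ring
    master = np.random.default_rng(7)
    means = []
    for _ in range(150):
        series = _random_segment_series(master, n_total, poisson=True)
        prof = wp.ring_densities(series, rings)
        means.append(prof.rho[0, 1])
    mc_sd = np.std(means, ddof=1)
    boots = []
    for seed in (8, 9, 10):
        series = _random_segment_series(np.random.default_rng(seed), n_total,
                                        poisson=True)
        boots.append(wp.bootstrap_density_sd(series, rings, 1, 0.0,
                                             n_cells=2500, n_boot=200, seed=1))
    assert np.mean(boots) == pytest.approx(mc_sd, rel=0.30)


def test_uniform_field_has_vanishing_bootstrap_sd():
    """A dense uniform scatter gives a bootstrap s.d. much smaller than the
    mean (no spatial variance to resample)."""
    rings = wp.make_rings((0, 0), 20.0, 4)
    ring = (rings.boundaries_mm[1], rings.boundaries_mm[2])
    series = _random_segment_series(np.random.default_rng(5), 8000, r_lim=ring)
    prof = wp.ring_densities(series, rings)
    sd = wp.bootstrap_density_sd(series, rings, 1, 0.0, n_cells=400,
                                 n_boot=100, seed=2)
    assert sd < 0.05 * prof.rho[0, 1]


# ---------------------------------------------------------------------------
# colony radius
# ---------------------------------------------------------------------------

def test_colony_radius_closed_form():
    # half-disc of radius 10 mm sampled densely on its boundary
    th = np.linspace(0, np.pi, 200)
    pts = 10_000 * np.stack([np.cos(th), np.sin(th)], axis=1)
    pts = np.vstack([pts, [[0.0, 0.0]]])
    assert wp.colony_radius(pts) == pytest.approx(10.0, rel=0.01)
    # hull of area 2*pi mm^2 -> r = 2 mm
    square = np.array([[0, 0], [np.sqrt(2 * np.pi) * 1000, 0],
                       [np.sqrt(2 * np.pi) * 1000, np.sqrt(2 * np.pi) * 1000],
                       [0, np.sqrt(2 * np.pi) * 1000]])
    assert wp.colony_radius(square) == pytest.approx(2.0, rel=1e-6)


def test_colony_radius_rejects_degenerate_input():
    with pytest.raises(ValueError):
        wp.colony_radius(np.array([[0, 0], [1, 1]]))
    with pytest.raises(ValueError):
        wp.colony_radius(np.array([[0, 0], [1, 1], [2, 2], [3, 3]]))


def test_colony_radius_grows_linearly_near_puller_speed(colony_medium):
    from mycowave import events as evm

    _, series, _, _ = colony_medium
    tps = series.timepoints[3:]
    radii = [wp.colony_radius(series, t) for t in tps]
    slope = np.polyfit(tps, radii, 1)[0] * 1000
    resid = radii - np.polyval(np.polyfit(tps, radii, 1), tps)
    assert np.max(np.abs(resid)) < 0.12 * radii[-1]
    growing = evm.growing_tips(series)
    vps = [wp.puller_tips(series, t, growing)[1] for t in tps[2:-1]]
    v_p = np.mean([v for v in vps if np.isfinite(v)])
    assert slope == pytest.approx(v_p, rel=0.10)


# ---------------------------------------------------------------------------
# sigmoid fits
# ---------------------------------------------------------------------------

def test_noiseless_sigmoid_recovered_to_a_tenth_of_a_percent():
    t = np.arange(0, 100, 2.0)
    rho = 2000.0 / (1 + np.exp(0.1 * (50.0 - t)))
    fit = wp.fit_sigmoid_rho(t, rho, n_boot=0)
    assert fit.ok
    assert fit.K == pytest.approx(2000.0, rel=1e-3)
    assert fit.lambda_per_h == pytest.approx(0.1, rel=1e-3)
    assert fit.t_n_h == pytest.approx(50.0, rel=1e-3)


def test_noiseless_tip_pulse_recovered():
    t = np.arange(0, 100, 2.0)
    e = np.exp(0.12 * (45.0 - t))
    n = 80.0 * e / (1 + e) ** 2
    fit = wp.fit_sigmoid_tip(t, n, n_boot=0)
    assert fit.ok
    assert fit.K == pytest.approx(80.0, rel=1e-3)
    assert fit.t_n_h == pytest.approx(45.0, rel=1e-3)


def test_sigmoid_bootstrap_ci_calibration():
    """With 5% noise the true arrival time falls inside the bootstrap 95%
    CI in at least 90 of 100 replicates."""
    t = np.arange(0, 100, 2.0)
    truth = 2000.0 / (1 + np.exp(0.1 * (50.0 - t)))
    rng = np.random.default_rng(42)
    hits = 0
    for rep in range(100):
        noisy = truth + rng.normal(0, 100.0, len(t))
        fit = wp.fit_sigmoid_rho(t, noisy, n_boot=200, seed=rep)
        if fit.ok and fit.t_n_ci and fit.t_n_ci[0] <= 50.0 <= fit.t_n_ci[1]:
            hits += 1
    assert hits >= 90


def test_sigmoid_rejects_bad_input():
    t = np.arange(0, 50, 2.0)
    with pytest.raises(ValueError):
        wp.fit_sigmoid_rho(t, np.zeros_like(t))
    with pytest.raises(ValueError):
        wp.fit_sigmoid_rho(t, 100.0 - t)  # monotone decreasing


# ---------------------------------------------------------------------------
# wavefront speed and saturation
# ---------------------------------------------------------------------------

def test_wavefront_speed_on_exact_line():
    t = np.arange(10.0)
    c, ci = wp.wavefront_speed(0.28 * t, t, n_boot=100, seed=0)
    assert c == pytest.approx(280.0, rel=1e-6)
    c0, _ = wp.wavefront_speed(np.full(10, 3.0), t, n_boot=50, seed=0)
    assert c0 == pytest.approx(0.0, abs=1e-9)


def test_wavefront_speed_needs_four_points():
    with pytest.raises(ValueError):
        wp.wavefront_speed([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


def test_saturating_density_slope_zero_for_identical_plateaus():
    rings = wp.make_rings((0, 0), 30.0, 6)
    fits = [wp.SigmoidFit(K=1000.0, lambda_per_h=0.1, t_n_h=10.0 * k,
                          cov=None, ok=True) for k in range(6)]
    slope, icpt, ci = wp.saturating_density_vs_radius(fits, rings, n_boot=100)
    assert slope == pytest.approx(0.0, abs=1e-9)
    assert icpt == pytest.approx(1000.0)


def test_saturating_density_recovers_linear_ramp():
    rings = wp.make_rings((0, 0), 30.0, 6)
    fits = [wp.SigmoidFit(K=500.0 + 20.0 * r, lambda_per_h=0.1, t_n_h=0.0,
                          cov=None, ok=True) for r in rings.centers_mm]
    slope, icpt, _ = wp.saturating_density_vs_radius(fits, rings, n_boot=50)
    assert slope == pytest.approx(20.0, rel=1e-6)
    assert icpt == pytest.approx(500.0, rel=1e-6)


def test_saturating_density_requires_three_good_fits():
    rings = wp.make_rings((0, 0), 30.0, 4)
    bad = wp.SigmoidFit(np.nan, np.nan, np.nan, None, False)
    good = wp.SigmoidFit(1000.0, 0.1, 5.0, None, True)
    with pytest.raises(ValueError):
        wp.saturating_density_vs_radius([bad, bad, good, good], rings)


def test_wake_plateau_flat_across_rings(longrun_profiles):
    """Self-regulation: the fitted per-ring plateau density varies weakly
    with radius over the matured wake."""
    rings, prof = longrun_profiles
    fits = wp.arrival_times(prof, n_boot=0)
    ok = [f for f in fits[:6] if f.ok]  # matured inner rings
    assert len(ok) >= 3
    ks = np.array([f.K for f in ok])
    assert ks.std() / ks.mean() < 0.35


def test_arrival_time_alignment_collapses_ring_profiles(longrun_profiles):
    """Time-shifting each ring's density by its arrival time collapses the
    per-ring curves (translational symmetry of the travelling wave)."""
    rings, prof = longrun_profiles
    fits = wp.arrival_times(prof, n_boot=0)
    curves = []
    shifted_axis = np.arange(-40.0, 40.0, 4.0)
    for k, f in enumerate(fits[:6]):
        if not f.ok:
            continue
        curves.append(np.interp(shifted_axis, prof.t_h - f.t_n_h,
                                prof.rho[:, k] / f.K,
                                left=np.nan, right=np.nan))
    assert len(curves) >= 3
    curves = np.array(curves)
    rms = []
    for i in range(len(curves)):
        for j in range(i + 1, len(curves)):
            both = np.isfinite(curves[i]) & np.isfinite(curves[j])
            if both.sum() >= 5:
                rms.append(np.sqrt(np.mean((curves[i][both] - curves[j][both]) ** 2)))
    assert max(rms) < 0.35  # aligned curves collapse onto one another


def test_wave_speed_from_arrival_times_matches_pullers(colony_longrun, longrun_profiles):
    from mycowave import events as evm

    params, series, _, _ = colony_longrun
    rings, prof = longrun_profiles
    fits = wp.arrival_times(prof, n_boot=0)
    r = rings.centers_mm
    tn = np.array([f.t_n_h if f.ok else np.nan for f in fits])
    ok = np.isfinite(tn)
    assert ok.sum() >= 4
    c, _ = wp.wavefront_speed(r[ok], tn[ok], n_boot=100)
    growing = evm.growing_tips(series)
    vps = [wp.puller_tips(series, t, growing)[1]
           for t in series.timepoints[5:-1:4]]
    v_p = np.mean([v for v in vps if np.isfinite(v)])
    assert c == pytest.approx(v_p, rel=0.10)


# ---------------------------------------------------------------------------
# puller tips
# ---------------------------------------------------------------------------

def test_single_hypha_tip_is_a_puller():
    params = cs.SimParams(alpha_per_h=0, p_fuse=0, t_max_h=10, n_anchors=1,
                          seed=0, v_sd_um_h=0)
    series, _, _ = cs.simulate_colony(params)
    with pytest.warns(UserWarning):
        ids, v = wp.puller_tips(series, series.timepoints[3])
    tip = next(iter(series.trails.values())).tip_node
    assert ids == [tip]


def test_pullers_outpace_the_population(colony_medium):
    from mycowave import events as evm

    _, series, _, _ = colony_medium
    growing = evm.growing_tips(series)
    hist = {int(n): g[["t_h", "x_um", "y_um"]].to_numpy()
            for n, g in series.node_rows.groupby("node_id")}
    ratios = []
    for t in series.timepoints[8:-1:4]:
        ids, v_p = wp.puller_tips(series, t, growing)
        pop = growing.get(float(t), [])
        if not ids or len(pop) < 6 or not np.isfinite(v_p):
            continue
        speeds = []
        for nid in pop:
            rows = hist[nid]
            i = np.searchsorted(rows[:, 0], t + 1e-9) - 1
            if i >= 1:
                dt = rows[i][0] - rows[i - 1][0]
                speeds.append(np.hypot(*(rows[i][1:3] - rows[i - 1][1:3])) / dt)
        if speeds:
            ratios.append(v_p / np.mean(speeds))
    assert np.mean(ratios) > 1.0


def test_interior_tips_are_not_pullers(colony_medium):
    from mycowave import events as evm

    _, series, _, _ = colony_medium
    growing = evm.growing_tips(series)
    t = series.timepoints[-10]
    ids, _ = wp.puller_tips(series, t, growing)
    g = nm.snapshot(series, t)
    rmax = max(np.hypot(*g.nodes[n]["pos"]) for n in g.nodes if "pos" in g.nodes[n])
    for nid in ids:
        st = series.node_state(nid, t)
        assert np.hypot(st[0], st[1]) > 0.35 * rmax
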