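import numpy as np
import pytest

from condact.ca_empirical import (
    ca_matrix,
    conditional_activity,
    exchange_time,
    persistence_time,
)
from condact.gillespie_sim import SiteEventSeries


def series(times, site="a", window=None):
    t = np.asarray(times, dtype=float)
    if window is None:
        window = (0.0, float(t[-1]) if len(t) else 1.0)
    cfgs = np.array(["x", "empty"] * len(t), dtype=object)[: len(t)]
    return SiteEventSeries(site=site, event_times=t, new_configurations=cfgs, window=window)


def test_persistence_hand_example():
    """Events at 1 and 3 in a window of duration 3: tau_p = 2^2/(2*3)."""
    assert persistence_time(series([1.0, 3.0])) == pytest.approx(2.0 / 3.0)


def test_persistence_undefined_below_two_events():
    assert np.isnan(persistence_time(series([1.0])))


def test_periodic_events_approach_half_spacing():
    """Spacing Delta: tau_p = (N-1) Delta^2 / (2 N Delta) -> Delta / 2."""
    delta, n = 0.7, 5000
    t = delta * np.arange(1, n + 1)
    tp = persistence_time(series(t))
    assert tp == pytest.approx((n - 1) * delta / (2 * n), rel=1e-12)
    assert tp == pytest.approx(delta / 2, rel=1e-3)


def test_poisson_persistence_is_inverse_rate(rng):
    k = 2.5
    t = np.cumsum(rng.exponential(1.0 / k, size=400_000))
    tp = persistence_time(series(t))
    assert tp == pytest.approx(1.0 / k, rel=0.02)


def test_exchange_hand_example():
    """b-events at 1,2; next a-event at 2.5: single term 0.5*1 over tau."""
    a = series([2.5], "a", window=(0.0, 3.0))
    b = series([1.0, 2.0], "b", window=(0.0, 3.0))
    tx, n_terms, n_drop = exchange_time(a, b)
    assert tx == pytest.approx(0.5 * 1.0 / 3.0)
    assert n_terms == 1 and n_drop == 0


def test_poisson_self_ca_is_zero(rng):
    """i.i.d. exponential intervals: tau_x -> tau_p, CA[a<-a] -> 0."""
    t = np.cumsum(rng.exponential(1.0, size=300_000))
    s = series(t)
    est = conditional_activity(s, s, with_se=True, seed=0)
    assert est.defined
    assert abs(est.value) < 3 * est.se
    assert est.se < 0.01


def test_independent_renewal_processes_have_zero_ca(rng):
    """Exchange from an independent leader equals a's mean residual life
    (inspection paradox), so CA -> 0."""
    ta = np.cumsum(rng.exponential(1.0, size=200_000))
    tb = np.cumsum(rng.exponential(1.7, size=120_000))
    t_end = min(ta[-1], tb[-1])
    w = (0.0, t_end)
    a = series(ta[ta <= t_end], "a", w)
    b = series(tb[tb <= t_end], "b", w)
    est = conditional_activity(a, b, with_se=True, seed=1)
    assert abs(est.value) < 3 * est.se


def test_ca_log_ratio_identities():
    est = conditional_activity(series([1.0, 2.0, 3.0, 4.0]), series([1.0, 2.0, 3.0, 4.0]))
    # tau_x and tau_p are both computed from the same periodic record:
    # tau_x/tau_p = (n_terms/(n-1)) for unit spacing
    assert est.defined
    tp, tx = est.tau_p, est.tau_x
    assert est.value == pytest.approx(-np.log10(tx / tp))


def test_time_rescaling_invariance(rng):
    t = np.cumsum(rng.exponential(1.0, size=20_000))
    t2 = np.cumsum(rng.exponential(0.5, size=10_000))
    t_end = min(t[-1], t2[-1])
    a = series(t[t <= t_end], "a", (0.0, t_end))
    b = series(t2[t2 <= t_end], "b", (0.0, t_end))
    base = conditional_activity(a, b).value
    c = 37.5
    a_s = series(c * t[t <= t_end], "a", (0.0, c * t_end))
    b_s = series(c * t2[t2 <= t_end], "b", (0.0, c * t_end))
    assert conditional_activity(a_s, b_s).value == pytest.approx(base, abs=1e-12)


def test_self_ca_of_alternating_two_rate_process(single_site_31):
    """Alternating exponential intervals with rates (3,1):
    tau_x/tau_p -> 2 k1 k2 / (k1^2 + k2^2) = 0.6, CA -> 0.2218."""
    from condact.gillespie_sim import project_events, simulate

    _, _, _, dist, rm = single_site_31
    traj = simulate(rm, n_events=1_000_000, seed=101, dist=dist)
    s = project_events(traj, rm, "A")
    est = conditional_activity(s, s, with_se=True, seed=2)
    expected = -np.log10(0.6)
    assert abs(est.value - expected) < 3 * est.se


def test_ca_matrix_shape_diag_and_window_check(independent_pair):
    from condact.gillespie_sim import project_events, simulate

    spec, _, _, dist, rm = independent_pair
    traj = simulate(rm, n_events=100_000, seed=5, dist=dist)
    ser = {s: project_events(traj, rm, s) for s in spec.site_names}
    table = ca_matrix(ser, with_se=True, seed=3)
    assert set(table) == {"A", "B"}
    assert all(set(row) == {"A", "B"} for row in table.values())
    # independent sites: off-diagonal CA within 3 SE of zero
    for a, b in (("A", "B"), ("B", "A")):
        est = table[a][b]
        assert abs(est.value) < 3 * est.se
    # mismatched windows rejected
    bad = dict(ser)
    sa = ser["A"]
    bad["A"] = SiteEventSeries(
        site="A",
        event_times=sa.event_times,
        new_configurations=sa.new_configurations,
        window=(0.0, sa.window[1] * 2),
    )
    with pytest.raises(ValueError, match="window"):
        ca_matrix(bad)


def test_two_halves_agree(single_site_31):
    """Estimates from two disjoint halves of one long record agree within
    combined standard errors."""
    from condact.gillespie_sim import project_events, simulate

    _, _, _, dist, rm = single_site_31
    traj = simulate(rm, n_events=400_000, seed=7, dist=dist)
    s = project_events(traj, rm, "A")
    mid = s.window[1] / 2.0
    first = SiteEventSeries(
        "A", s.event_times[s.event_times <= mid],
        s.new_configurations[s.event_times <= mid], (0.0, mid),
    )
    sel = s.event_times > mid
    second = SiteEventSeries(
        "A", s.event_times[sel] - mid, s.new_configurations[sel],
        (0.0, s.window[1] - mid),
    )
    e1 = conditional_activity(first, first, with_se=True, seed=11)
    e2 = conditional_activity(second, second, with_se=True, seed=12)
    assert abs(e1.value - e2.value) < 3 * np.hypot(e1.se, e2.se)
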