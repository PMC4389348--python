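"""Exact stochastic simulation (Gillespie/SSA) of the microstate CTMC.

The inner jump loop is JIT-compiled with numba so that the 1e6–1e7-event
trajectories needed to estimate conditional activities from time series run
in seconds.  Trajectories are reproducible given a seed; the per-site
projections produced by :func:`project_events` are the substrate of the
empirical persistence/exchange-time estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .kinetics import RateMatrix
from .thermo import EquilibriumDistribution

__all__ = [
    "Trajectory",
    "SiteEventSeries",
    "simulate",
    "project_events",
    "empirical_occupancy",
]

_CHUNK = 1 << 20


@dataclass
class Trajectory:
    """One SSA realization: state path of the microstate chain.

    ``states[k]`` is the state entered at ``jump_times[k]``; the chain sits in
    ``initial_state`` on ``[0, jump_times[0])``.  ``t_end`` is the duration of
    the observation window (equal to the stopping time actually reached).
    """

    jump_times: np.ndarray
    states: np.ndarray
    initial_state: int
    t_end: float
    seed: int | None

    @property
    def n_events(self) -> int:
        return len(self.jump_times)


@dataclass
class SiteEventSeries:
    """Transition times of a single site within an observation window."""

    site: str
    event_times: np.ndarray
    new_configurations: np.ndarray  # configuration labels after each event
    window: tuple[float, float]

    @property
    def n_events(self) -> int:
        return len(self.event_times)

    @property
    def duration(self) -> float:
        return self.window[1] - self.window[0]


@njit(cache=True)
def _ssa_core(nbr_idx, nbr_cum, degree, exit_rate, start, u_hold, u_jump, t0, t_max):
    n_draw = u_hold.shape[0]
    times = np.empty(n_draw)
    states = np.empty(n_draw, np.int64)
    t = t0
    s = start
    m = 0
    for k in range(n_draw):
        rate = exit_rate[s]
        t += -np.log(u_hold[k]) / rate
        if t_max > 0.0 and t > t_max:
            return times[:m], states[:m], t_max, s, True
        d = degree[s]
        pos = np.searchsorted(nbr_cum[s, :d], u_jump[k])
        if pos >= d:
            pos = d - 1
        s = nbr_idx[s, pos]
        times[m] = t
        states[m] = s
        m += 1
    return times[:m], states[:m], t, s, False


def _jump_tables(rm: RateMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    q = rm.rates
    n = q.shape[0]
    exit_rate = -np.diag(q).copy()
    if np.any(exit_rate <= 0):
        raise ValueError("absorbing state in generator: zero total exit rate")
    degree = np.count_nonzero(q > 0, axis=1)
    dmax = int(degree.max())
    nbr_idx = np.zeros((n, dmax), dtype=np.int64)
    nbr_cum = np.ones((n, dmax))
    for i in range(n):
        nbrs = np.flatnonzero(q[i] > 0)
        p = q[i, nbrs] / exit_rate[i]
        nbr_idx[i, : len(nbrs)] = nbrs
        nbr_cum[i, : len(nbrs)] = np.cumsum(p)
    return nbr_idx, nbr_cum, degree, exit_rate


def simulate(
    rm: RateMatrix,
    initial: int | None = None,
    t_max: float | None = None,
    n_events: int | None = None,
    seed: int | None = None,
    dist: EquilibriumDistribution | None = None,
) -> Trajectory:
    """Exact SSA trajectory of the CTMC generated by ``rm``.

    Stops at whichever of ``t_max`` / ``n_events`` is hit first (at least one
    must be given).  If ``initial`` is None the start state is sampled from
    ``dist`` (stationary start — no burn-in needed), which must then be
    provided.
    """
    if t_max is None and n_events is None:
        raise ValueError("provide t_max and/or n_events")
    rng = np.random.default_rng(seed)
    if initial is None:
        if dist is None:
            raise ValueError("sampling the initial state requires dist")
        initial = int(rng.choice(len(dist.probabilities), p=dist.probabilities))
    if not 0 <= initial < rm.n_states:
        raise ValueError(f"initial state {initial} out of range")
    nbr_idx, nbr_cum, degree, exit_rate = _jump_tables(rm)

    times_parts: list[np.ndarray] = []
    states_parts: list[np.ndarray] = []
    t = 0.0
    s = initial
    remaining = n_events if n_events is not None else -1
    tm = t_max if t_max is not None else -1.0
    while True:
        chunk = _CHUNK if remaining < 0 else min(_CHUNK, remaining)
        u_hold = rng.random(chunk)
        u_jump = rng.random(chunk)
        ts, ss, t, s, hit_tmax = _ssa_core(
            nbr_idx, nbr_cum, degree, exit_rate, s, u_hold, u_jump, t, tm
        )
        times_parts.append(ts)
        states_parts.append(ss)
        if remaining > 0:
            remaining -= len(ts)
        if hit_tmax or remaining == 0:
            break
    times = np.concatenate(times_parts)
    states = np.concatenate(states_parts)
    t_end = tm if (t_max is not None and (hit_tmax or t >= tm)) else (
        float(times[-1]) if len(times) else 0.0
    )
    return Trajectory(
        jump_times=times,
        states=states,
        initial_state=initial,
        t_end=t_end,
        seed=seed,
    )


def project_events(
    traj: Trajectory, rm: RateMatrix, site: str
) -> SiteEventSeries:
    """Project a trajectory onto one site: jumps that change its configuration."""
    try:
        s_idx = rm.site_names.index(site)
    except ValueError:
        raise ValueError(f"unknown site {site!r}") from None
    cfg = rm.site_configs[:, s_idx]
    path = np.concatenate(([traj.initial_state], traj.states))
    site_cfg = cfg[path]
    changed = site_cfg[1:] != site_cfg[:-1]
    labels = np.asarray(rm.config_labels[s_idx], dtype=object)
    return SiteEventSeries(
        site=site,
        event_times=traj.jump_times[changed],
        new_configurations=labels[site_cfg[1:][changed]],
        window=(0.0, traj.t_end),
    )


def empirical_occupancy(traj: Trajectory, n_states: int) -> np.ndarray:
    """Time-weighted fraction of the window spent in each microstate."""
    if traj.t_end <= 0:
        raise ValueError("trajectory has zero duration")
    path = np.concatenate(([traj.initial_state], traj.states))
    bounds = np.concatenate(([0.0], traj.jump_times, [traj.t_end]))
    hold = np.diff(bounds)
    hold = np.clip(hold, 0.0, None)  # final partial interval may be clipped
    occ = np.bincount(path[: len(hold)], weights=hold, minlength=n_states)
    return occ / occ.sum()
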