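"""Persistence time, exchange time, and conditional activity from event series.

For a site *a* with transition times T(a,1) < T(a,2) < ... inside a window of
duration tau, the waiting time is W(a,t) = T(a,t+1) - T(a,t) and

    tau_p[a]      = (1 / 2 tau) * sum_t W(a,t)^2
    tau_x[a<-b]   = (1 / tau)   * sum_t W(a, T(b,t+1)) * W(b, T(b,t))
    CA[a<-b]      = -log10( tau_x[a<-b] / tau_p[a] )

where W(a, T) is the time from T to a's next transition strictly after T.
tau_p is the stationary mean residual life of a's transition process
(E[W^2] / 2E[W] in the long-record limit); tau_x weighs a's residual time
after each b-transition by b's preceding waiting time.  CA vanishes for
independent sites and for Poisson (i.i.d.-exponential-interval) transition
processes, and is positive when b's transitions hasten a's.

The estimators use a common observation-window duration for both sums; the
persistence sum runs over events with a defined next event, and exchange
terms whose next a-event falls beyond the window are dropped (and counted).
Standard errors come from a joint non-overlapping time-block bootstrap, since
successive terms are serially correlated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gillespie_sim import SiteEventSeries

__all__ = [
    "CAEstimate",
    "persistence_time",
    "exchange_time",
    "conditional_activity",
    "ca_matrix",
]

DROP_WARN_FRACTION = 0.01


@dataclass
class CAEstimate:
    """One conditional-activity estimate CA[a<-b] with its ingredients.

    ``value`` is dimensionless (log10 units).  ``defined`` is False when
    either series has too few events to estimate, in which case ``value``
    is NaN.  ``n_dropped`` counts exchange terms truncated by the window
    end; ``se`` is a block-bootstrap standard error when requested.
    """

    value: float
    tau_p: float
    tau_x: float
    n_a: int
    n_b: int
    defined: bool
    n_dropped: int = 0
    se: float | None = None


def _check_window(series: SiteEventSeries) -> None:
    t = series.event_times
    if len(t) and (t[0] < series.window[0] or t[-1] > series.window[1]):
        raise ValueError(f"events of {series.site!r} fall outside the window")


def persistence_time(series_a: SiteEventSeries) -> float:
    """tau_p[a]: half the mean squared waiting time, normalized by the window.

    Returns NaN (undefined) when the series has fewer than 2 events.
    """
    _check_window(series_a)
    if series_a.n_events < 2:
        return float("nan")
    w = np.diff(series_a.event_times)
    return float((w * w).sum() / (2.0 * series_a.duration))


def exchange_time(
    series_a: SiteEventSeries, series_b: SiteEventSeries
) -> tuple[float, int, int]:
    """tau_x[a<-b] with the number of contributing and dropped terms.

    One term per consecutive b-event pair: (residual time of a after the
    later b-event) times (the waiting time between the two b-events).  Terms
    with no further a-event inside the window are dropped.  Returns
    ``(nan, 0, 0)`` when b has fewer than 2 events or a none.
    """
    _check_window(series_a)
    _check_window(series_b)
    if abs(series_a.duration - series_b.duration) > 1e-9 * max(
        series_a.duration, 1.0
    ):
        raise ValueError("series observed over different windows")
    tb = series_b.event_times
    ta = series_a.event_times
    if len(tb) < 2 or len(ta) == 0:
        return float("nan"), 0, 0
    w_b = np.diff(tb)
    anchors = tb[1:]
    nxt = np.searchsorted(ta, anchors, side="right")
    valid = nxt < len(ta)
    n_drop = int((~valid).sum())
    if n_drop and n_drop > DROP_WARN_FRACTION * len(anchors):
        warnings.warn(
            f"{n_drop}/{len(anchors)} exchange terms truncated by the window "
            f"end for {series_a.site!r} <- {series_b.site!r}; consider a "
            "longer record",
            stacklevel=2,
        )
    w_a = ta[nxt[valid]] - anchors[valid]
    total = float((w_a * w_b[valid]).sum() / series_b.duration)
    return total, int(valid.sum()), n_drop


def _block_bootstrap_se(
    series_a: SiteEventSeries,
    series_b: SiteEventSeries,
    n_blocks: int,
    n_boot: int,
    seed: int | None,
) -> float:
    """SE of CA[a<-b] by jointly resampling non-overlapping time blocks.

    Both sums are decomposed into per-block partial sums (a term belongs to
    the block containing the event that opens it); blocks are resampled with
    replacement and CA recomputed, capturing the serial correlation and the
    tau_p/tau_x covariance.
    """
    t0, t1 = series_a.window
    edges = np.linspace(t0, t1, n_blocks + 1)
    tau = t1 - t0

    ta = series_a.event_times
    w_p = np.diff(ta) ** 2
    blk_p = np.clip(np.searchsorted(edges, ta[:-1], side="right") - 1, 0, n_blocks - 1)
    sums_p = np.bincount(blk_p, weights=w_p, minlength=n_blocks)

    tb = series_b.event_times
    w_b = np.diff(tb)
    anchors = tb[1:]
    nxt = np.searchsorted(ta, anchors, side="right")
    valid = nxt < len(ta)
    prod = (ta[nxt[valid]] - anchors[valid]) * w_b[valid]
    blk_x = np.clip(
        np.searchsorted(edges, tb[:-1][valid], side="right") - 1, 0, n_blocks - 1
    )
    sums_x = np.bincount(blk_x, weights=prod, minlength=n_blocks)

    rng = np.random.default_rng(seed)
    picks = rng.integers(0, n_blocks, size=(n_boot, n_blocks))
    tp_star = sums_p[picks].sum(axis=1) / (2.0 * tau)
    tx_star = sums_x[picks].sum(axis=1) / tau
    ok = (tp_star > 0) & (tx_star > 0)
    if ok.sum() < 2:
        return float("nan")
    ca_star = -np.log10(tx_star[ok] / tp_star[ok])
    return float(np.std(ca_star, ddof=1))


def conditional_activity(
    series_a: SiteEventSeries,
    series_b: SiteEventSeries,
    with_se: bool = False,
    n_blocks: int = 50,
    n_boot: int = 200,
    seed: int | None = None,
) -> CAEstimate:
    """CA[a<-b] = -log10(tau_x / tau_p), asymmetric in (a, b) in general."""
    tau_p = persistence_time(series_a)
    tau_x, n_terms, n_drop = exchange_time(series_a, series_b)
    defined = np.isfinite(tau_p) and np.isfinite(tau_x) and tau_p > 0
    if not defined:
        value = float("nan")
    elif tau_x == 0.0:
        value = float("inf")  # flagged infinite: a always fires instantly
    else:
        value = -float(np.log10(tau_x / tau_p))
    se = None
    if with_se and defined and np.isfinite(value):
        se = _block_bootstrap_se(series_a, series_b, n_blocks, n_boot, seed)
    return CAEstimate(
        value=value,
        tau_p=tau_p,
        tau_x=tau_x,
        n_a=series_a.n_events,
        n_b=series_b.n_events,
        defined=bool(defined),
        n_dropped=n_drop,
        se=se,
    )


def ca_matrix(
    series: dict[str, SiteEventSeries],
    with_se: bool = False,
    n_blocks: int = 50,
    n_boot: int = 200,
    seed: int | None = None,
) -> dict[str, dict[str, CAEstimate]]:
    """Full asymmetric CA table over all ordered site pairs.

    ``result[a][b]`` estimates CA[a<-b]; the diagonal is the self-CA.  All
    series must share one observation window.
    """
    items = list(series.items())
    if not items:
        return {}
    w0 = items[0][1].window
    for name, s in items:
        if not np.allclose(s.window, w0):
            raise ValueError(f"series {name!r} has a mismatched window")
    out: dict[str, dict[str, CAEstimate]] = {}
    for a, sa in items:
        out[a] = {}
        for b, sb in items:
            out[a][b] = conditional_activity(
                sa, sb, with_se=with_se, n_blocks=n_blocks, n_boot=n_boot, seed=seed
            )
    return out
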