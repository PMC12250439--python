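"""Independent numerical oracles used by the test suite.

These deliberately avoid the closed-form segment decomposition the engine
uses: incremental QALYs are obtained by building each arm's piecewise
utility curve on a fine time grid and integrating the discounted
difference with the midpoint rule.
"""

from __future__ import annotations

import numpy as np


def _midpoints(t0: float, t1: float, dt: float):
    n = max(1, int(np.ceil((t1 - t0) / dt)))
    edges = np.linspace(t0, t1, n + 1)
    return (edges[:-1] + edges[1:]) / 2, np.diff(edges)


def _integrate_diff(curve_early, curve_cf, horizon: float, rate: float, dt: float,
                    breakpoints=()) -> float:
    """∫ (u_early(t) − u_cf(t)) (1+rate)^(−t) dt over [0, horizon].

    Grid edges are snapped to the curves' jump locations so that the
    midpoint rule sees only the smooth discount factor inside each cell.
    """
    knots = sorted({0.0, horizon, *[b for b in breakpoints if 0.0 < b < horizon]})
    total = 0.0
    for t0, t1 in zip(knots[:-1], knots[1:]):
        mid, widths = _midpoints(t0, t1, dt)
        diff = curve_early(mid) - curve_cf(mid)
        disc = (1.0 + rate) ** (-mid)
        total += float(np.sum(diff * disc * widths))
    return total


def _step(mid, breakpoints, levels):
    """Piecewise-constant curve: levels[i] on [breakpoints[i], breakpoints[i+1])."""
    out = np.zeros_like(mid)
    for (t0, t1), level in zip(zip(breakpoints[:-1], breakpoints[1:]), levels):
        out = np.where((mid >= t0) & (mid < t1), level, out)
    return out


def riemann_reduced_wait(u_wait, u_post_early, u_post_delayed,
                         t_early, t_delayed, t_death_cf, t_death_early,
                         rate, dt=1e-3) -> float:
    def early(mid):
        return _step(mid, [0.0, t_early, t_death_early], [u_wait, u_post_early])

    def cf(mid):
        return _step(mid, [0.0, t_delayed, t_death_cf], [u_wait, u_post_delayed])

    return _integrate_diff(early, cf, t_death_early, rate, dt,
                           breakpoints=(t_early, t_delayed, t_death_cf))


def riemann_missed_surgery(u_missed, u_post_early,
                           t_early, t_death_cf, t_death_early,
                           rate, dt=1e-3, u_wait=0.0) -> float:
    def early(mid):
        return _step(mid, [0.0, t_early, t_death_early], [u_wait, u_post_early])

    def cf(mid):
        return _step(mid, [0.0, t_early, t_death_cf], [u_wait, u_missed])

    return _integrate_diff(early, cf, t_death_early, rate, dt,
                           breakpoints=(t_early, t_death_cf))


def riemann_lifesaving(u_post_early, t_early, t_death_early,
                       rate, dt=1e-3, u_wait=0.0) -> float:
    def early(mid):
        return _step(mid, [0.0, t_early, t_death_early], [u_wait, u_post_early])

    def cf(mid):
        return _step(mid, [0.0, t_early, t_early], [u_wait])

    return _integrate_diff(early, cf, t_death_early, rate, dt,
                           breakpoints=(t_early,))


def draw_scenario_params(rng: np.random.Generator) -> dict:
    """One random, invariant-respecting parameter set shared by all scenarios."""
    u_post_early = rng.uniform(0.5, 0.95)
    u_wait = rng.uniform(0.2, u_post_early)
    u_post_delayed = rng.uniform(u_wait, u_post_early)
    u_missed = rng.uniform(0.2, u_wait)
    t_early = rng.uniform(0.05, 0.5)
    t_delayed = t_early + rng.uniform(0.1, 3.0)
    t_death_cf = t_delayed + rng.uniform(5.0, 40.0)
    t_death_early = t_death_cf + rng.uniform(0.0, 10.0)
    return dict(
        u_wait=u_wait, u_post_early=u_post_early, u_post_delayed=u_post_delayed,
        u_missed=u_missed, t_early=t_early, t_delayed=t_delayed,
        t_death_cf=t_death_cf, t_death_early=t_death_early,
        rate=rng.uniform(0.0, 0.08),
    )
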