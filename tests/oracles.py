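"""Independent oracles for the simulators, the SRTM forward model and the
exact rank tests.

All compartment oracles integrate the model ODEs with an adaptive
integrator (scipy ``solve_ivp``) and carry an extra cumulative state so
that frame means are exact integrals, fully independent of the package's
fixed-step trapezoidal convolution. The statistics oracles enumerate sign
patterns / group assignments directly.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import rankdata

from tspopet.core import FrameSchedule, TimeActivityCurve
from tspopet.srtm import SrtmParams

_IVP_OPTS = dict(method="LSODA", rtol=1e-9, atol=1e-12, dense_output=True)


def _frame_means_from_cumulative(sol, state_index, schedule: FrameSchedule):
    bounds = np.concatenate([[0.0], schedule.ends])
    cum = sol.sol(bounds)[state_index]
    return np.diff(cum) / schedule.durations


def ode_1tc(cp, K1: float, k2: float, schedule: FrameSchedule) -> np.ndarray:
    """Frame-averaged one-tissue TAC by adaptive ODE integration."""

    def rhs(t, y):
        return [K1 * cp(t) - k2 * y[0], y[0]]

    sol = solve_ivp(rhs, (0.0, schedule.total_duration), [0.0, 0.0], **_IVP_OPTS)
    return _frame_means_from_cumulative(sol, 1, schedule)


def ode_2tc(cp, K1, k2, k3, k4, schedule: FrameSchedule) -> np.ndarray:
    """Frame-averaged two-tissue TAC (C1 + C2) by adaptive ODE integration."""

    def rhs(t, y):
        c1, c2, _ = y
        return [K1 * cp(t) - (k2 + k3) * c1 + k4 * c2, k3 * c1 - k4 * c2, c1 + c2]

    sol = solve_ivp(rhs, (0.0, schedule.total_duration), [0.0, 0.0, 0.0], **_IVP_OPTS)
    return _frame_means_from_cumulative(sol, 2, schedule)


def ode_srtm(reference: TimeActivityCurve, params: SrtmParams) -> np.ndarray:
    """SRTM target TAC with the dispersion integral computed by an adaptive
    integrator: u' = C_R - k2a*u, C_T = R1*C_R + (k2 - R1*k2a)*u, frame
    means taken exactly via a cumulative state."""
    t_knots = np.concatenate([[0.0], reference.schedule.midpoints])
    v_knots = np.concatenate([[0.0], reference.values])

    def cr(t):
        return np.interp(t, t_knots, v_knots)

    def rhs(t, y):
        return [cr(t) - params.k2a * y[0], y[0]]

    sched = reference.schedule
    sol = solve_ivp(rhs, (0.0, sched.total_duration), [0.0, 0.0], **_IVP_OPTS)
    conv_means = _frame_means_from_cumulative(sol, 1, sched)
    theta2 = params.k2 - params.R1 * params.k2a
    return params.R1 * reference.values + theta2 * conv_means


def dense_grid_peak(cp, t_max: float = 10.0, step: float = 1e-4):
    """(t_peak, peak value) of an input function by dense-grid argmax."""
    t = np.arange(0.0, t_max, step)
    v = cp(t)
    i = int(np.argmax(v))
    return t[i], v[i]


def wilcoxon_brute_force(diffs) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    eps = 1e-9
    p_le = np.mean(ws <= w_obs + eps)
    p_ge = np.mean(ws >= w_obs - eps)
    return min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney_brute_force(x, y) -> float:
    """Two-sided Mann-Whitney p by enumerating all group assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    nx = x.size
    r_obs = ranks[:nx].sum()
    sums = [sum(ranks[list(idx)]) for idx in itertools.combinations(range(pooled.size), nx)]
    sums = np.asarray(sums)
    eps = 1e-9
    p_le = np.mean(sums <= r_obs + eps)
    p_ge = np.mean(sums >= r_obs - eps)
    return min(1.0, 2.0 * min(p_le, p_ge))


def spearman_brute_force(x, y) -> float:
    """Pearson correlation of average ranks."""
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def nnls_grid_oracle(m: np.ndarray, y: np.ndarray,
                     w_max: float = 2.0) -> np.ndarray:
    """Two-stage exhaustive grid search for min ||M w - y||, w >= 0."""
    best = np.zeros(m.shape[1])
    step = w_max / 50.0
    lo = np.zeros(m.shape[1])
    hi = np.full(m.shape[1], w_max)
    for _ in range(4):
        axes = [np.arange(l, h + step / 2, step) for l, h in zip(lo, hi)]
        grids = np.meshgrid(*axes, indexing="ij")
        w = np.stack([g.ravel() for g in grids], axis=1)
        resid = w @ m.T - y
        cost = np.einsum("ij,ij->i", resid, resid)
        best = w[int(np.argmin(cost))]
        lo = np.maximum(best - step, 0.0)
        hi = best + step
        step = step / 10.0
    return best
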