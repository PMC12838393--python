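"""Independent oracles used by the test suite.

These deliberately avoid the package's integration path: the adaptive
oracle uses scipy's DOP853 with tight tolerances on an independently
written right-hand side, the linear-system oracle uses the matrix
exponential, and the ROC oracle counts concordant pairs by brute force.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from vancohd.pk import dialyzer_clearance


def _breakpoints(doses, sessions, t_end):
    pts = {0.0, t_end}
    for d in doses:
        pts.update((d.time, min(d.time + d.t_inf, t_end)))
    for s in sessions:
        if s.start < t_end:
            pts.update((s.start, min(s.end, t_end)))
    return sorted(p for p in pts if 0 <= p <= t_end)


def adaptive_conc(doses, params, sessions, settings, t_eval):
    """High-accuracy concentrations at t_eval via segment-wise DOP853."""
    t_eval = np.asarray(t_eval, dtype=float)
    t_end = float(t_eval.max())
    cl_hd = dialyzer_clearance(settings) if settings is not None else 0.0
    bps = _breakpoints(doses, sessions, t_end)
    y = np.zeros(2)
    out = np.empty_like(t_eval)
    done = np.zeros(t_eval.shape, dtype=bool)
    if np.any(t_eval == 0.0):
        out[t_eval == 0.0] = 0.0
        done[t_eval == 0.0] = True
    for b0, b1 in zip(bps[:-1], bps[1:]):
        if b1 - b0 <= 1e-12:
            continue
        mid = 0.5 * (b0 + b1)
        rin = sum(d.amount / d.t_inf for d in doses if d.time <= mid < d.time + d.t_inf)
        cl = params.cl_body + (
            cl_hd if any(s.start <= mid < s.end for s in sessions) else 0.0
        )

        def rhs(_t, yy, rin=rin, cl=cl):
            a1, a2 = yy
            return [
                rin - (cl + params.q) / params.v1 * a1 + params.q / params.v2 * a2,
                params.q / params.v1 * a1 - params.q / params.v2 * a2,
            ]

        mask = (~done) & (t_eval > b0) & (t_eval <= b1 + 1e-12)
        ts = np.clip(t_eval[mask], b0, b1)
        sol = solve_ivp(rhs, (b0, b1), y, method="DOP853", rtol=1e-11, atol=1e-12,
                        t_eval=np.unique(np.concatenate([ts, [b1]])))
        lookup = dict(zip(sol.t, sol.y[0]))
        out[mask] = [lookup[min(lookup, key=lambda k, t=t: abs(k - t))] for t in ts]
        done |= mask
        y = sol.y[:, -1]
    return out / params.v1


def expm_conc(dose, params, t):
    """Exact concentration at t for a single infusion, via the matrix
    exponential of the constant-coefficient linear system."""
    A = np.array(
        [
            [-(params.cl_body + params.q) / params.v1, params.q / params.v2],
            [params.q / params.v1, -params.q / params.v2],
        ]
    )
    b = np.array([dose.amount / dose.t_inf, 0.0])
    Ainv_b = np.linalg.solve(A, b)
    t_on = min(t, dose.t_inf)
    y = expm(A * t_on) @ Ainv_b - Ainv_b  # y(0)=0 with constant forcing
    if t > dose.t_inf:
        y = expm(A * (t - dose.t_inf)) @ y
    return y[0] / params.v1


def brute_force_concordance(scores, labels):
    """All-pairs concordance (ties count half) = ROC AUC."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def bisect_koa(cl_baseline, qb, qd, forward, lo=1e-9, hi=1e7, iters=200):
    """Plain bisection on a supplied forward dialyzer formula."""
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if forward(mid, qb, qd) < cl_baseline:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
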