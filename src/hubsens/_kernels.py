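"""Numba-compiled numerical kernels.

Two integrators share one array-encoded model representation (see
:class:`hubsens.models.CompiledModel`):

* an adaptive Dormand-Prince RK45 ODE integrator that lands exactly on a
  requested output grid and can replay a frozen step schedule (used so that a
  perturbed sensitivity run takes *identical* steps to its base run, making
  quadrature and truncation error cancel to first order);
* a fixed-step Euler-Maruyama integrator for the chemical Langevin equation,
  drift ``v a(X) dt`` and diffusion ``v sqrt(a(X)) dW`` per reaction, run over
  replicate ensembles with one RNG seed per replicate.

Status codes: 0 ok, 1 step budget exhausted, 2 non-finite state,
3 step-size underflow.
"""
from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_MAXSTEPS = 1
STATUS_NONFINITE = 2
STATUS_UNDERFLOW = 3

# Dormand-Prince 5(4) tableau
_C2, _C3, _C4, _C5 = 1.0 / 5.0, 3.0 / 10.0, 4.0 / 5.0, 8.0 / 9.0
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = 19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0
_A61, _A62, _A63, _A64, _A65 = (9017.0 / 3168.0, -355.0 / 33.0, 46732.0 / 5247.0,
                                49.0 / 176.0, -5103.0 / 18656.0)
_B1, _B3, _B4, _B5, _B6 = 35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0, -2187.0 / 6784.0, 11.0 / 84.0
# embedded 4th-order weights
_E1, _E3, _E4, _E5, _E6, _E7 = (5179.0 / 57600.0, 7571.0 / 16695.0, 393.0 / 640.0,
                                -92097.0 / 339200.0, 187.0 / 2100.0, 1.0 / 40.0)


@njit(cache=True, inline="always")
def _signal(code, kon, koff, ts, t):
    if code == 1:
        return kon  # constant form stores the level in kon
    if t <= ts:
        return 1.0 - np.exp(-kon * t)
    peak = 1.0 - np.exp(-kon * ts)
    if koff <= 0.0:
        return peak
    return peak * np.exp(-koff * (t - ts))


@njit(cache=True)
def _rates(y_full, s, params, law, kidx, kmidx, subidx, modidx, sigf, out):
    for j in range(law.size):
        v = params[kidx[j]]
        if sigf[j] == 1:
            v *= s
        m = modidx[j]
        if m >= 0:
            ym = y_full[m]
            if ym < 0.0:
                ym = 0.0
            v *= ym
        si = subidx[j]
        if si >= 0:
            ys = y_full[si]
            if ys < 0.0:
                ys = 0.0
            if law[j] == 0:
                v *= ys
            else:
                v *= ys / (params[kmidx[j]] + ys)
        out[j] = v


@njit(cache=True)
def _full_state(y_dyn, dyn_idx, elim_idx, elim_total, elim_ptr, elim_members, y_full):
    for i in range(dyn_idx.size):
        y_full[dyn_idx[i]] = y_dyn[i]
    for e in range(elim_idx.size):
        ssum = 0.0
        for p in range(elim_ptr[e], elim_ptr[e + 1]):
            ssum += y_dyn[elim_members[p]]
        v = elim_total[e] - ssum
        if v < 0.0:
            v = 0.0
        y_full[elim_idx[e]] = v


@njit(cache=True)
def _rhs(t, y, params, pat_code, pat_kon, pat_koff, pat_ts,
         law, kidx, kmidx, subidx, modidx, sigf, stoich_dyn,
         dyn_idx, elim_idx, elim_total, elim_ptr, elim_members,
         y_full, a, dydt):
    _full_state(y, dyn_idx, elim_idx, elim_total, elim_ptr, elim_members, y_full)
    s = _signal(pat_code, pat_kon, pat_koff, pat_ts, t)
    _rates(y_full, s, params, law, kidx, kmidx, subidx, modidx, sigf, a)
    for i in range(y.size):
        acc = 0.0
        for j in range(a.size):
            acc += stoich_dyn[i, j] * a[j]
        dydt[i] = acc


@njit(cache=True)
def integrate_rk45(law, kidx, kmidx, subidx, modidx, sigf, stoich_dyn,
                   dyn_idx, elim_idx, elim_total, elim_ptr, elim_members,
                   n_species, params, y0,
                   pat_code, pat_kon, pat_koff, pat_ts,
                   t_out, rtol, atol, max_step, max_steps, fixed_steps):
    """Integrate the reduced ODE system, landing exactly on ``t_out``.

    If ``fixed_steps`` is non-empty it must be an increasing array of times
    starting at the initial time; the integrator then replays exactly those
    steps with no error control.  Returns ``(y_out, step_times, status)``
    where ``step_times`` contains every accepted step time (including 0).
    """
    n = y0.size
    nt = t_out.size
    y_out = np.full((nt, n), np.nan)
    y_full = np.empty(n_species)
    a = np.empty(law.size)
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n); k4 = np.empty(n)
    k5 = np.empty(n); k6 = np.empty(n); k7 = np.empty(n)
    ytmp = np.empty(n)
    ynew = np.empty(n)

    y = y0.copy()
    t = 0.0
    io = 0
    if nt > 0 and t_out[0] == 0.0:
        y_out[0] = y
        io = 1

    fixed_mode = fixed_steps.size > 0
    if fixed_mode:
        nbuf = fixed_steps.size
    else:
        nbuf = max_steps + nt + 2
    step_times = np.empty(nbuf)
    step_times[0] = 0.0
    ns = 1

    t_end = t_out[nt - 1]
    _rhs(t, y, params, pat_code, pat_kon, pat_koff, pat_ts,
         law, kidx, kmidx, subidx, modidx, sigf, stoich_dyn,
         dyn_idx, elim_idx, elim_total, elim_ptr, elim_members, y_full, a, k1)

    h = max_step
    if h > 0.1:
        h = 0.1
    if h > t_end:
        h = t_end
    err_prev = 1.0
    fi = 1  # pointer into fixed_steps
    n_iter = 0

    while t < t_end:
        n_iter += 1
        if ns - 1 >= max_steps or n_iter > 4 * max_steps:
            return y_out, step_times[:ns], STATUS_MAXSTEPS
        if fixed_mode:
            if fi >= fixed_steps.size:
                return y_out, step_times[:ns], STATUS_UNDERFLOW
            t_next = fixed_steps[fi]
            h = t_next - t
        else:
            if h > max_step:
                h = max_step
            if t + h >= t_out[io]:
                h = t_out[io] - t
                t_next = t_out[io]
            else:
                t_next = t + h
            if h <= 1e-14 * (1.0 + t):
                return y_out, step_times[:ns], STATUS_UNDERFLOW

        # Dormand-Prince stages
        for i in range(n):
            ytmp[i] = y[i] + h * _A21 * k1[i]
        _rhs(t + _C2 * h, ytmp, params, pat_code, pat_kon, pat_koff, pat_ts,
             law, kidx, kmidx, subidx, modidx, sigf, stoich_dyn,
             dyn_idx, elim_idx, elim_total, elim_ptr, elim_members, y_full, a, k2)
        for i in range(n):
            ytmp[i] = y[i] + h * (_A31 * k1[i] + _A32 * k2[i])
        _rhs(t + _C3 * h, ytmp, params, pat_code, pat_kon, pat_koff, pat_ts,
             law, kidx, kmidx, subidx, modidx, sigf, stoich_dyn,
             dyn_idx, elim_idx, elim_total, elim_ptr, elim_members, y_full, a, k3)
        for i in range(n):
            ytmp[i] = y[i] + h * (_A41 * k1[i] + _A42 * k2[i] + _A43 * k3[i])
        _rhs(t + _C4 * h, ytmp, params, pat_code, pat_kon, pat_koff, pat_ts,
             law, kidx, kmidx, subidx, modidx, sigf, stoich_dyn,
             dyn_idx, elim_idx, elim_total, elim_ptr, elim_members, y_full, a, k4)
        for i in range(n):
            ytmp[i] = y[i] + h * (_A51 * k1[i] + _A52 * k2[i] + _A53 * k3[i] + _A54 * k4[i])
        _rhs(t + _C5 * h, ytmp, params, pat_code, pat_kon, pat_koff, pat_ts,
             law, kidx, kmidx, subidx, modidx, sigf, stoich_dyn,
             dyn_idx, elim_idx, elim_total, elim_ptr, elim_members, y_full, a, k5)
        for i in range(n):
            ytmp[i] = y[i] + h * (_A61 * k1[i] + _A62 * k2[i] + _A63 * k3[i]
                                  + _A64 * k4[i] + _A65 * k5[i])
        _rhs(t + h, ytmp, params, pat_code, pat_kon, pat_koff, pat_ts,
             law, kidx, kmidx, subidx, modidx, sigf, stoich_dyn,
             dyn_idx, elim_idx, elim_total, elim_ptr, elim_members, y_full, a, k6)
        for i in range(n):
            ynew[i] = y[i] + h * (_B1 * k1[i] + _B3 * k3[i] + _B4 * k4[i]
                                  + _B5 * k5[i] + _B6 * k6[i])
        _rhs(t + h, ynew, params, pat_code, pat_kon, pat_koff, pat_ts,
             law, kidx, kmidx, subidx, modidx, sigf, stoich_dyn,
             dyn_idx, elim_idx, elim_total, elim_ptr, elim_members, y_full, a, k7)

        finite = True
        for i in range(n):
            if not np.isfinite(ynew[i]):
                finite = False
        if not finite:
            return y_out, step_times[:ns], STATUS_NONFINITE

        if fixed_mode:
            accept = True
        else:
            errn = 0.0
            for i in range(n):
                y4 = y[i] + h * (_E1 * k1[i] + _E3 * k3[i] + _E4 * k4[i]
                                 + _E5 * k5[i] + _E6 * k6[i] + _E7 * k7[i])
                ay = abs(y[i])
                an = abs(ynew[i])
                sc = atol + rtol * (ay if ay > an else an)
                d = (ynew[i] - y4) / sc
                errn += d * d
            errn = np.sqrt(errn / n)
            if not np.isfinite(errn):
                errn = 1e6  # overflowed error estimate: hard reject
            accept = errn <= 1.0
            # PI step-size controller
            if errn < 1e-12:
                fac = 5.0
            else:
                fac = 0.9 * errn ** -0.2 * err_prev ** 0.08
                if fac > 5.0:
                    fac = 5.0
                if fac < 0.2:
                    fac = 0.2
            if accept:
                err_prev = errn if errn > 1e-12 else 1e-12

        if accept:
            t = t_next
            for i in range(n):
                y[i] = ynew[i]
                k1[i] = k7[i]  # FSAL
            step_times[ns] = t
            ns += 1
            if fixed_mode:
                fi += 1
            if io < nt and t == t_out[io]:
                y_out[io] = y
                io += 1
        if not fixed_mode:
            h = h * fac
            if not (h >= 1e-14):  # catches underflow and NaN
                return y_out, step_times[:ns], STATUS_UNDERFLOW

    return y_out, step_times[:ns], STATUS_OK


@njit(cache=True)
def cle_ensemble(law, kidx, kmidx, subidx, modidx, sigf, stoich_dyn,
                 dyn_idx, elim_idx, elim_total, elim_ptr, elim_members,
                 n_species, params, y0,
                 pat_code, pat_kon, pat_koff, pat_ts,
                 dt, n_steps, sample_every, noise_scale, seeds):
    """Euler-Maruyama CLE ensemble.

    Returns ``(states, status)`` with ``states`` of shape
    ``(n_rep, n_samples, n_dyn)`` sampled every ``sample_every`` steps
    (excluding t=0), and per-replicate status codes.
    """
    n = y0.size
    n_r = law.size
    n_rep = seeds.size
    n_samples = n_steps // sample_every
    states = np.full((n_rep, n_samples, n), np.nan)
    status = np.zeros(n_rep, dtype=np.int64)
    y_full = np.empty(n_species)
    a = np.empty(n_r)
    sqdt = np.sqrt(dt)

    for r in range(n_rep):
        np.random.seed(seeds[r])
        y = y0.copy()
        isamp = 0
        ok = True
        for step in range(n_steps):
            t = step * dt
            _full_state(y, dyn_idx, elim_idx, elim_total, elim_ptr, elim_members, y_full)
            s = _signal(pat_code, pat_kon, pat_koff, pat_ts, t)
            _rates(y_full, s, params, law, kidx, kmidx, subidx, modidx, sigf, a)
            for j in range(n_r):
                aj = a[j]
                if aj < 0.0:
                    aj = 0.0
                incr = aj * dt + noise_scale * np.sqrt(aj) * sqdt * np.random.normal()
                for i in range(n):
                    y[i] += stoich_dyn[i, j] * incr
            # clipping policy: non-negative species, pools capped at their totals
            for i in range(n):
                if y[i] < 0.0:
                    y[i] = 0.0
                elif not np.isfinite(y[i]):
                    ok = False
            if not ok:
                status[r] = STATUS_NONFINITE
                break
            for e in range(elim_idx.size):
                ssum = 0.0
                for p in range(elim_ptr[e], elim_ptr[e + 1]):
                    ssum += y[elim_members[p]]
                tot = elim_total[e]
                if ssum > tot:
                    sc = tot / ssum
                    for p in range(elim_ptr[e], elim_ptr[e + 1]):
                        y[elim_members[p]] *= sc
            if (step + 1) % sample_every == 0:
                states[r, isamp] = y
                isamp += 1
    return states, status
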