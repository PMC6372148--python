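"""Deterministic ODE integration and chemical Langevin simulation.

This module is the pipeline's data generator: the "control data" that every
later stage fits against are themselves replicate ensembles of stochastic
(CLE / Euler-Maruyama) simulations of a hub model at its reference parameter
values, summarised as per-time-point mean, SD and SE of the output on the
30-min sampling grid.

The primary ODE path is the in-package adaptive RK45 kernel (fast enough to
sit inside a genetic search); scipy's LSODA is used as a fallback for stiff
parameter corners.  Parameter sets for which both fail raise
:class:`IntegrationError` so callers can apply the exclusion rule.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import odeint

from . import _kernels
from .models import CompiledModel, ModelSpec
from .signals import SignalPattern, load_patterns

__all__ = [
    "IntegrationError",
    "StochasticStateError",
    "Trajectory",
    "ControlData",
    "integrate_ode",
    "simulate_cle",
    "cle_ensemble",
    "generate_control_data",
    "euler_maruyama",
    "simulate_patterns",
    "DEFAULT_SAMPLE_TIMES",
]

log = logging.getLogger(__name__)

#: (30, 60, ..., 300) min — ten samples, t=0 excluded (all patterns share the
#: same initial state, so the origin is uninformative for fitting).
DEFAULT_SAMPLE_TIMES = np.arange(30.0, 301.0, 30.0)


class IntegrationError(RuntimeError):
    """Numerical integration failed; carries the parameter-set id if known."""

    def __init__(self, message: str, set_id: str | None = None):
        super().__init__(message)
        self.set_id = set_id


class StochasticStateError(RuntimeError):
    """A CLE replicate left the admissible state space (non-finite values)."""


@dataclass
class Trajectory:
    """Sampled trajectory of the dynamic (independent) species."""

    pattern_id: str
    times: np.ndarray
    states: np.ndarray  # (time, dyn species)
    species: tuple[str, ...]
    output: np.ndarray  # output species X* at the sample times
    step_times: np.ndarray | None = None

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")


def _as_vector(model: ModelSpec, params) -> np.ndarray:
    if isinstance(params, Mapping):
        return model.params_to_vector(params)
    vec = np.asarray(params, dtype=float)
    if vec.shape != (len(model.param_names),):
        raise ValueError("parameter vector has wrong length")
    return vec


def _kernel_args(cm: CompiledModel):
    return (cm.law, cm.kidx, cm.kmidx, cm.subidx, cm.modidx, cm.sigf, cm.stoich_dyn,
            cm.dyn_idx, cm.elim_idx, cm.elim_total, cm.elim_ptr, cm.elim_members,
            cm.spec.n_species)


def integrate_ode(model: ModelSpec, params, pattern: SignalPattern, *,
                  t_end: float = 300.0, sample_times: Sequence[float] | None = None,
                  rtol: float = 1e-8, atol: float = 1e-8, max_step: float = np.inf,
                  max_steps: int = 200_000, fixed_steps: np.ndarray | None = None,
                  method: str = "auto", set_id: str | None = None,
                  compiled: CompiledModel | None = None) -> Trajectory:
    """Integrate the deterministic hub ODEs, sampling at ``sample_times``.

    ``method`` is ``"auto"`` (RK45 kernel with LSODA fallback), ``"rk45"`` or
    ``"lsoda"``.  When ``fixed_steps`` is given the RK45 kernel replays that
    exact step schedule (no adaptivity); the accepted step times of an
    adaptive run are returned on the trajectory for this purpose.
    """
    cm = compiled if compiled is not None else model.compile()
    vec = _as_vector(model, params)
    if np.any(vec <= 0) or not np.all(np.isfinite(vec)):
        raise ValueError("parameters must be positive and finite")
    if sample_times is None:
        sample_times = DEFAULT_SAMPLE_TIMES[DEFAULT_SAMPLE_TIMES <= t_end]
    t_out = np.asarray(sample_times, dtype=float)
    if t_out.size == 0 or (t_out.size and t_out[-1] < t_end):
        t_out = np.append(t_out, t_end) if t_out.size else np.array([t_end])
        extra = True
    else:
        extra = False
    if t_end < t_out[-1]:
        raise ValueError("t_end must cover the sampling grid")
    if t_out[-1] == 0.0:  # identity case: no integration needed
        y0 = cm.y0_dyn.copy()
        return Trajectory(pattern.id, np.array([0.0]), y0[None, :], cm.dyn_species,
                          np.array([y0[cm.out_dyn]]))

    code, kon, koff, ts = pattern.as_kernel_params()
    if method in ("auto", "rk45"):
        fs = fixed_steps if fixed_steps is not None else np.empty(0)
        y_out, steps, status = _kernels.integrate_rk45(
            *_kernel_args(cm), vec, cm.y0_dyn.copy(), code, kon, koff, ts,
            t_out, rtol, atol, max_step, max_steps, fs)
        if status == _kernels.STATUS_OK:
            if extra:
                y_out = y_out[:-1]
                t_ret = t_out[:-1]
            else:
                t_ret = t_out
            return Trajectory(pattern.id, t_ret, y_out, cm.dyn_species,
                              y_out[:, cm.out_dyn], step_times=steps)
        if method == "rk45":
            raise IntegrationError(f"RK45 failed with status {status}", set_id)
    # LSODA fallback (stiff corners of the random parameter box); mxstep
    # bounds the effort so a pathological set fails fast and gets excluded
    y_full = np.empty(cm.spec.n_species)
    a = np.empty(cm.law.size)
    dydt = np.empty(cm.y0_dyn.size)

    def rhs(t, y):
        _kernels._rhs(t, y, vec, code, kon, koff, ts,
                      cm.law, cm.kidx, cm.kmidx, cm.subidx, cm.modidx, cm.sigf,
                      cm.stoich_dyn, cm.dyn_idx, cm.elim_idx, cm.elim_total,
                      cm.elim_ptr, cm.elim_members, y_full, a, dydt)
        return dydt.copy()

    t_ode = t_out if t_out[0] == 0.0 else np.concatenate(([0.0], t_out))
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # step-budget failures are handled below
        y_sol, info = odeint(rhs, cm.y0_dyn.copy(), t_ode, tfirst=True, rtol=rtol,
                             atol=atol, mxstep=10_000, full_output=True,
                             printmessg=False)
    if info["message"] != "Integration successful." or not np.all(np.isfinite(y_sol)):
        raise IntegrationError(f"integration failed: {info['message']}", set_id)
    y_out = y_sol if t_ode is t_out else y_sol[1:]
    if extra:
        y_out, t_ret = y_out[:-1], t_out[:-1]
    else:
        t_ret = t_out
    return Trajectory(pattern.id, t_ret, y_out, cm.dyn_species, y_out[:, cm.out_dyn])


def simulate_patterns(model: ModelSpec, params, patterns: Sequence[SignalPattern] | None = None,
                      sample_times: Sequence[float] | None = None, *,
                      set_id: str | None = None, compiled: CompiledModel | None = None,
                      **kw) -> np.ndarray:
    """Output matrix (n_patterns x n_times) of X* for all signal patterns."""
    patterns = patterns if patterns is not None else load_patterns()
    st = DEFAULT_SAMPLE_TIMES if sample_times is None else np.asarray(sample_times, float)
    cm = compiled if compiled is not None else model.compile()
    out = np.empty((len(patterns), st.size))
    for i, pat in enumerate(patterns):
        traj = integrate_ode(model, params, pat, t_end=float(st[-1]), sample_times=st,
                             set_id=set_id, compiled=cm, **kw)
        out[i] = traj.output
    return out


# ---------------------------------------------------------------------------
# stochastic simulation


def simulate_cle(model: ModelSpec, params, pattern: SignalPattern, *, dt: float = 0.01,
                 t_end: float = 300.0, sample_times: Sequence[float] | None = None,
                 seed: int, noise_scale: float = 1.0,
                 compiled: CompiledModel | None = None) -> Trajectory:
    """One Euler-Maruyama CLE trajectory (bit-reproducible under ``seed``)."""
    states = cle_ensemble(model, params, pattern, n_replicates=1, dt=dt, t_end=t_end,
                          sample_times=sample_times, seed=seed, noise_scale=noise_scale,
                          compiled=compiled, full_states=True)
    cm = compiled if compiled is not None else model.compile()
    st = _check_grid(dt, t_end, sample_times)
    return Trajectory(pattern.id, st, states[0], cm.dyn_species,
                      states[0][:, cm.out_dyn])


def _check_grid(dt: float, t_end: float, sample_times) -> np.ndarray:
    st = DEFAULT_SAMPLE_TIMES if sample_times is None else np.asarray(sample_times, float)
    st = st[st <= t_end + 1e-9]
    if dt <= 0:
        raise ValueError("dt must be positive")
    every = st[0] / dt
    if abs(every - round(every)) > 1e-8 or np.any(np.abs(np.diff(st) - st[0]) > 1e-9):
        raise ValueError("dt must divide a uniform sampling interval")
    return st


def cle_ensemble(model: ModelSpec, params, pattern: SignalPattern, *, n_replicates: int,
                 dt: float = 0.01, t_end: float = 300.0,
                 sample_times: Sequence[float] | None = None, seed: int | np.ndarray,
                 noise_scale: float = 1.0, max_retries: int = 3,
                 compiled: CompiledModel | None = None, full_states: bool = False):
    """Replicate ensemble of CLE trajectories.

    Returns the output-species matrix ``(n_replicates, n_samples)`` (or the
    full dynamic-state array when ``full_states``).  Replicates whose state
    becomes non-finite are re-drawn with fresh derived seeds up to
    ``max_retries`` times, then :class:`StochasticStateError` is raised.
    """
    cm = compiled if compiled is not None else model.compile()
    vec = _as_vector(model, params)
    st = _check_grid(dt, t_end, sample_times)
    sample_every = int(round(st[0] / dt))
    n_steps = int(round(st[-1] / dt))
    code, kon, koff, ts = pattern.as_kernel_params()

    if isinstance(seed, (int, np.integer)):
        seeds = np.random.SeedSequence(int(seed)).generate_state(n_replicates).astype(np.int64)
    else:
        seeds = np.asarray(seed, dtype=np.int64)
    states, status = _kernels.cle_ensemble(
        *_kernel_args(cm), vec, cm.y0_dyn.copy(), code, kon, koff, ts,
        float(dt), n_steps, sample_every, float(noise_scale), seeds)
    retry = 0
    while np.any(status != 0):
        retry += 1
        if retry > max_retries:
            raise StochasticStateError(
                f"{int(np.sum(status != 0))} CLE replicates failed after {max_retries} retries")
        bad = np.flatnonzero(status != 0)
        reseeds = np.random.SeedSequence([int(seeds[bad[0]]), retry]).generate_state(
            bad.size).astype(np.int64)
        redo, redo_status = _kernels.cle_ensemble(
            *_kernel_args(cm), vec, cm.y0_dyn.copy(), code, kon, koff, ts,
            float(dt), n_steps, sample_every, float(noise_scale), reseeds)
        states[bad] = redo
        status[bad] = redo_status
    if full_states:
        return states
    return states[:, :, cm.out_dyn]


@dataclass
class ControlData:
    """Per-pattern replicate-ensemble summaries of the output X*.

    ``mean``/``sd``/``se`` have shape (n_patterns, n_times); ``se`` is
    ``sd / sqrt(n_replicates)`` elementwise.
    """

    model_id: str
    pattern_ids: tuple[str, ...]
    sample_times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    se: np.ndarray
    n_replicates: int
    dt: float
    rng_seed: int
    noise_scale: float = 1.0

    @property
    def norms(self) -> np.ndarray:
        """|x̂_control,i| per pattern (used by the scaling factor α)."""
        return np.linalg.norm(self.mean, axis=1)

    def band(self, kind: str = "sd") -> np.ndarray:
        if kind not in ("sd", "se"):
            raise ValueError("band must be 'sd' or 'se'")
        return self.sd if kind == "sd" else self.se

    def to_frame(self):
        import pandas as pd
        rows = []
        for i, pid in enumerate(self.pattern_ids):
            for j, t in enumerate(self.sample_times):
                rows.append((pid, t, self.mean[i, j], self.sd[i, j], self.se[i, j]))
        return pd.DataFrame(rows, columns=["pattern", "time", "mean", "sd", "se"])


def generate_control_data(model: ModelSpec, *, n_replicates: int = 1000, dt: float = 0.01,
                          seed: int, noise_scale: float = 1.0,
                          patterns: Sequence[SignalPattern] | None = None,
                          sample_times: Sequence[float] | None = None,
                          compiled: CompiledModel | None = None) -> ControlData:
    """Run the replicate CLE ensembles at the model's reference parameters.

    One child seed stream is derived per pattern from the root seed (via
    ``numpy.random.SeedSequence(seed).spawn``), and one per replicate within a
    pattern, so the full ensemble is reproducible from the root seed alone.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates for SD/SE")
    if not model.reference_params:
        raise ValueError(f"model {model.id} carries no reference parameter values")
    patterns = patterns if patterns is not None else load_patterns()
    cm = compiled if compiled is not None else model.compile()
    st = _check_grid(dt, 300.0 if sample_times is None else float(np.max(sample_times)),
                     sample_times)
    children = np.random.SeedSequence(int(seed)).spawn(len(patterns))
    mean = np.empty((len(patterns), st.size))
    sd = np.empty_like(mean)
    for i, pat in enumerate(patterns):
        seeds = children[i].generate_state(n_replicates).astype(np.int64)
        out = cle_ensemble(model, model.reference_params, pat, n_replicates=n_replicates,
                           dt=dt, t_end=float(st[-1]), sample_times=st, seed=seeds,
                           noise_scale=noise_scale, compiled=cm)
        mean[i] = out.mean(axis=0)
        sd[i] = out.std(axis=0, ddof=1)
    se = sd / np.sqrt(n_replicates)
    return ControlData(model.id, tuple(p.id for p in patterns), st, mean, sd, se,
                       n_replicates, dt, int(seed), noise_scale)


# ---------------------------------------------------------------------------
# generic Euler-Maruyama (used by the stochastic-moment oracles)


def euler_maruyama(drift: Callable, diffusion: Callable, x0: float, *, dt: float,
                   t_end: float, n_replicates: int, seed: int,
                   sample_times: Sequence[float] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised scalar Euler-Maruyama: dX = drift(X,t) dt + diffusion(X,t) dW.

    Returns ``(times, X)`` with ``X`` of shape (n_replicates, n_times).
    """
    rng = np.random.default_rng(seed)
    n_steps = int(round(t_end / dt))
    st = np.asarray(sample_times, float) if sample_times is not None else np.array([t_end])
    x = np.full(n_replicates, float(x0))
    sqdt = np.sqrt(dt)
    out = np.empty((n_replicates, st.size))
    io = 0
    for step in range(n_steps):
        t = step * dt
        x = x + drift(x, t) * dt + diffusion(x, t) * sqdt * rng.standard_normal(n_replicates)
        t_new = (step + 1) * dt
        while io < st.size and t_new >= st[io] - 1e-9:
            out[:, io] = x
            io += 1
    return st, out
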