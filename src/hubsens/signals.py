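"""Time-varying input signal patterns S1-S10.

Each pattern is a pure, exogenous function of time ``s(t)`` (it carries no ODE
state).  The built-in family realises combinations of fast/slow initiation and
fast/slow (or absent) decay phases on the 0-300 min horizon:

.. math::

    s(t) = 1 - e^{-k_{on} t}                       \\quad t \\le t_s

    s(t) = s(t_s)\\, e^{-k_{off} (t - t_s)}        \\quad t > t_s

with ``koff = 0`` denoting a sustained stimulus.  A ``constant`` form
(``s(t) = level``) is also provided for test systems.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = ["SignalPattern", "load_patterns", "pattern_by_id", "PATTERN_IDS"]

# integer codes used by the compiled kernels
FORM_RISE_DECAY = 0
FORM_CONSTANT = 1

_FORM_CODES = {"rise_decay": FORM_RISE_DECAY, "constant": FORM_CONSTANT}


@dataclass(frozen=True)
class SignalPattern:
    """One input stimulation pattern.

    Parameters
    ----------
    id:
        Pattern label (``S1`` .. ``S10`` for the built-in set).
    form:
        ``"rise_decay"`` or ``"constant"``.
    kon:
        Initiation rate constant (1/min).  For the ``constant`` form this
        field stores the constant level instead.
    koff:
        Decay rate constant (1/min); 0 means sustained.
    t_switch:
        Time (min) at which the initiation phase hands over to decay.
    """

    id: str
    form: str = "rise_decay"
    kon: float = 0.5
    koff: float = 0.0
    t_switch: float = 300.0

    @property
    def form_code(self) -> int:
        return _FORM_CODES[self.form]

    def value(self, t):
        """Evaluate ``s(t)``; accepts scalars or arrays, requires ``t >= 0``."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("signal time must be non-negative")
        if self.form == "constant":
            out = np.full_like(t, float(self.kon))
            return out if out.ndim else float(out)
        rise = 1.0 - np.exp(-self.kon * t)
        peak = 1.0 - np.exp(-self.kon * self.t_switch)
        if self.koff > 0.0:
            decay = peak * np.exp(-self.koff * (t - self.t_switch))
        else:
            decay = np.full_like(t, peak)
        out = np.where(t <= self.t_switch, rise, decay)
        return out if out.ndim else float(out)

    __call__ = value

    def as_kernel_params(self) -> tuple[int, float, float, float]:
        """(form_code, kon, koff, t_switch) tuple consumed by the kernels."""
        return (self.form_code, float(self.kon), float(self.koff), float(self.t_switch))


def load_patterns() -> list[SignalPattern]:
    """Load the ten built-in stimulation patterns from the package data file."""
    text = resources.files("hubsens.data").joinpath("signals.yaml").read_text()
    raw = yaml.safe_load(text)
    return [SignalPattern(**entry) for entry in raw["patterns"]]


PATTERN_IDS = tuple(f"S{i}" for i in range(1, 11))


def pattern_by_id(pattern_id: str) -> SignalPattern:
    for p in load_patterns():
        if p.id == pattern_id:
            return p
    raise KeyError(f"unknown signal pattern {pattern_id!r}")
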