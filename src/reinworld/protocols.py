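"""External perturbation protocols: the abiotic forcing P(t).

P plays the role insolation plays in Daisyworld: a prescribed,
deterministic forcing on each environmental variable.  ``linear_ramp``
reproduces the slow-forcing regime in which homeostatic plateaus appear;
``shock`` adds an instantaneous displacement of the environmental state at
a set time on top of a constant baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _vec(x, n_env: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_env, float(arr))
    if arr.shape != (n_env,):
        raise ValueError(f"expected scalar or length-{n_env} vector, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class PerturbationProtocol:
    """Time-dependent forcing, evaluable at any t >= 0 via ``__call__``.

    ``shock_magnitude`` is not part of P(t): it is an instantaneous jump
    applied to the environmental state at ``shock_time`` by the integrator.
    Piecewise protocols are right-continuous step functions.
    """

    kind: str
    n_env: int
    base: np.ndarray = None
    rate: np.ndarray = None
    shock_time: float | None = None
    shock_magnitude: np.ndarray = None
    times: np.ndarray = None
    values: np.ndarray = None

    @classmethod
    def constant(cls, level=0.0, n_env: int = 1) -> "PerturbationProtocol":
        return cls(kind="constant", n_env=n_env, base=_vec(level, n_env))

    @classmethod
    def linear_ramp(cls, rate, base=0.0, n_env: int = 1) -> "PerturbationProtocol":
        """P(t) = base + rate * t (rate in units of E per unit time)."""
        return cls(kind="linear_ramp", n_env=n_env, base=_vec(base, n_env),
                   rate=_vec(rate, n_env))

    @classmethod
    def shock(cls, shock_time, magnitude, base=0.0, n_env: int = 1) -> "PerturbationProtocol":
        return cls(kind="shock", n_env=n_env, base=_vec(base, n_env),
                   shock_time=float(shock_time),
                   shock_magnitude=_vec(magnitude, n_env))

    @classmethod
    def piecewise(cls, times, values, n_env: int = 1) -> "PerturbationProtocol":
        times = np.asarray(times, dtype=float)
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[1] == 1 and n_env > 1:
            values = np.repeat(values, n_env, axis=1)
        if values.shape != (times.size, n_env):
            raise ValueError("piecewise values must be (len(times), n_env)")
        if not (np.diff(times) > 0).all():
            raise ValueError("piecewise times must be strictly increasing")
        return cls(kind="piecewise", n_env=n_env, times=times, values=values)

    def __call__(self, t: float) -> np.ndarray:
        if self.kind == "constant" or self.kind == "shock":
            return self.base.copy()
        if self.kind == "linear_ramp":
            return self.base + self.rate * t
        if self.kind == "piecewise":
            i = int(np.searchsorted(self.times, t, side="right")) - 1
            if i < 0:
                return np.zeros(self.n_env)
            return self.values[i].copy()
        raise ValueError(self.kind)

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.base is not None:
            d["base"] = self.base.tolist()
        if self.rate is not None:
            d["rate"] = self.rate.tolist()
        if self.shock_time is not None:
            d["shock_time"] = self.shock_time
            d["shock_magnitude"] = self.shock_magnitude.tolist()
        if self.times is not None:
            d["times"] = self.times.tolist()
            d["values"] = self.values.tolist()
        return d
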