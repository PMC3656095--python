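"""Time integration of the coupled biota-environment system.

The environmental variables follow

    dE_i/dt = ( P_i(t) + F_i(E) ) / tau_env

where P is the external forcing and F the total biotic force.  In the
default quasi-steady regime the abundances are slaved to their
environment-determined steady state (biotic relaxation much faster than
environmental change) and only E is integrated.  The full system
additionally integrates every abundance,

    d alpha_j/dt = ( alpha*_j(E) - alpha_j ) / tau_biotic,

with the force computed from the *actual* abundances.

The integrator is fixed-step classical Runge-Kutta (RK4); forward Euler is
available for pedagogy.  Both are deterministic given the inputs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .population import BioticPopulation, abundances as _abundances
from .protocols import PerturbationProtocol


def as_force(source):
    """Normalise a force source to a callable ``E -> (n_env,) array``.

    Accepts a :class:`BioticPopulation`, anything with a ``.force`` method
    (e.g. a sampled GP force field), a plain callable, or ``None`` (no
    biota: zero force).
    """
    if source is None:
        return lambda E: np.zeros_like(np.atleast_1d(E))
    if hasattr(source, "force"):
        return source.force
    if callable(source):
        return source
    raise TypeError(f"cannot interpret {type(source).__name__} as a force source")


def env_derivative(E, source, P, tau_env: float) -> np.ndarray:
    """dE/dt = (P + F(E)) / tau_env; pure function of its arguments."""
    if not tau_env > 0:
        raise ValueError(f"tau_env must be positive, got {tau_env}")
    E = np.atleast_1d(np.asarray(E, dtype=float))
    P = np.atleast_1d(np.asarray(P, dtype=float))
    return (P + as_force(source)(E)) / tau_env


def biotic_derivative(alpha, alpha_star, tau_biotic: float) -> np.ndarray:
    """Linear relaxation of abundances towards their steady state."""
    if not tau_biotic > 0:
        raise ValueError(f"tau_biotic must be positive, got {tau_biotic}")
    alpha = np.asarray(alpha, dtype=float)
    alpha_star = np.asarray(alpha_star, dtype=float)
    if alpha.shape != alpha_star.shape:
        raise ValueError("alpha and alpha_star must have equal length")
    return (alpha_star - alpha) / tau_biotic


def apply_shock(E, shock) -> np.ndarray:
    """Instantaneous displacement of the environmental state."""
    E = np.atleast_1d(np.asarray(E, dtype=float))
    shock = np.atleast_1d(np.asarray(shock, dtype=float))
    if shock.shape != E.shape:
        raise ValueError("shock must have length n_env")
    return E + shock


@dataclass
class Trajectory:
    """Sampled time series of a run: E, P, F and optionally abundances."""

    times: np.ndarray          # (T,)
    env: np.ndarray            # (T, n_env)
    force: np.ndarray          # (T, n_env)
    perturbation: np.ndarray   # (T, n_env)
    abundances: np.ndarray | None = None  # (T, K)

    def __post_init__(self):
        T = self.times.shape[0]
        for name in ("env", "force", "perturbation"):
            if getattr(self, name).shape[0] != T:
                raise ValueError(f"{name} does not share the time dimension")
        if not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")

    @property
    def n_env(self) -> int:
        return self.env.shape[1]

    def to_text(self) -> str:
        n = self.n_env
        cols = (["t"] + [f"E_{i+1}" for i in range(n)]
                + [f"P_{i+1}" for i in range(n)] + [f"F_{i+1}" for i in range(n)])
        mats = [self.times[:, None], self.env, self.perturbation, self.force]
        if self.abundances is not None:
            cols += [f"alpha_{j+1}" for j in range(self.abundances.shape[1])]
            mats.append(self.abundances)
        buf = io.StringIO()
        buf.write(f"# reinworld trajectory n_env={n}\n")
        buf.write("\t".join(cols) + "\n")
        np.savetxt(buf, np.hstack(mats), fmt="%.17g", delimiter="\t")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "Trajectory":
        lines = text.splitlines()
        n = None
        for ln in lines:
            if ln.startswith("# reinworld trajectory"):
                n = int(ln.split("n_env=")[1])
                break
        if n is None:
            raise ValueError("not a reinworld trajectory file")
        body = [ln for ln in lines if ln and not ln.startswith("#")]
        data = np.array([[float(v) for v in ln.split("\t")] for ln in body[1:]])
        ab = data[:, 1 + 3 * n:] if data.shape[1] > 1 + 3 * n else None
        return cls(times=data[:, 0], env=data[:, 1:1 + n],
                   perturbation=data[:, 1 + n:1 + 2 * n],
                   force=data[:, 1 + 2 * n:1 + 3 * n], abundances=ab)


def _rk4_step(f, t, y, dt):
    k1 = f(t, y)
    k2 = f(t + dt / 2, y + dt / 2 * k1)
    k3 = f(t + dt / 2, y + dt / 2 * k2)
    k4 = f(t + dt, y + dt * k3)
    return y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)


def _euler_step(f, t, y, dt):
    return y + dt * f(t, y)


_STEPPERS = {"rk4": _rk4_step, "euler": _euler_step}


def integrate(source, E0, protocol: PerturbationProtocol | None, config,
              t_end: float, stride: int = 1, record_abundances: bool = False,
              method: str = "rk4") -> Trajectory:
    """Integrate the system from ``E0`` to ``t_end`` and sample every
    ``stride`` steps.

    ``source`` is a population, GP force field, callable or ``None``.  If
    ``config.quasi_steady_biota`` only E is integrated; the full
    (K + n_env)-dimensional system requires a :class:`BioticPopulation`.
    A ``shock`` protocol displaces E instantaneously at its shock time.
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    E0 = np.atleast_1d(np.asarray(E0, dtype=float))
    n = E0.shape[0]
    if protocol is None:
        protocol = PerturbationProtocol.constant(0.0, n)
    if protocol.n_env != n:
        raise ValueError("protocol dimension does not match E0")
    step = _STEPPERS[method]
    F = as_force(source)
    dt = config.dt
    tau = config.tau_env

    full = not config.quasi_steady_biota
    if full:
        if not isinstance(source, BioticPopulation):
            raise TypeError("full (non-quasi-steady) integration needs a BioticPopulation")
        pop = source

        def deriv(t, y):
            alpha, E = y[:pop.K], y[pop.K:]
            a_star = _abundances(pop, E)
            dE = (protocol(t) + pop.effects.T @ alpha) / tau
            return np.concatenate([(a_star - alpha) / config.tau_biotic, dE])

        y = np.concatenate([_abundances(pop, E0), E0])
    else:
        def deriv(t, y):
            return (protocol(t) + F(y)) / tau

        y = E0.copy()

    shock_at = protocol.shock_time if protocol.kind == "shock" else None

    times, envs, forces, perts, abunds = [], [], [], [], []

    def record(t, y):
        E = y[-n:]
        times.append(t)
        envs.append(E.copy())
        forces.append(pop.effects.T @ y[:pop.K] if full else F(E))
        perts.append(protocol(t))
        if record_abundances:
            abunds.append(y[:-n].copy() if full
                          else _abundances(source, E) if isinstance(source, BioticPopulation)
                          else np.empty(0))

    # build the step schedule, splitting at the shock time if any
    breaks = [0.0, t_end]
    if shock_at is not None and 0.0 < shock_at < t_end:
        breaks = [0.0, shock_at, t_end]

    t = 0.0
    k = 0
    record(t, y)
    for b0, b1 in zip(breaks[:-1], breaks[1:]):
        nsteps = max(1, int(round((b1 - b0) / dt)))
        h = (b1 - b0) / nsteps
        for _ in range(nsteps):
            y = step(deriv, t, y, h)
            t += h
            k += 1
            if not np.isfinite(y).all():
                raise FloatingPointError(f"non-finite state at t={t:.6g}")
            if k % stride == 0:
                record(t, y)
        t = b1  # kill accumulated rounding
        if shock_at is not None and np.isclose(t, shock_at):
            y = y.copy()
            y[-n:] = apply_shock(y[-n:], protocol.shock_magnitude)
            if k % stride != 0:
                record(t, y)
    if k % stride != 0:
        record(t, y)

    return Trajectory(times=np.array(times), env=np.array(envs),
                      force=np.array(forces), perturbation=np.array(perts),
                      abundances=np.array(abunds) if record_abundances else None)


@dataclass
class RelaxResult:
    """Outcome of relaxing the system under constant forcing."""

    E: np.ndarray
    t: float
    settled: bool
    escaped: bool
    left_range: bool  # E left [lo, hi] at any time (escape is terminal only
                      # when escape_terminal is set)


def relax(source, E0, config, P=0.0, t_max: float = 500.0,
          settle_tol: float | None = None, window: float | None = None,
          lo: float = 0.0, hi: float | None = None,
          escape_terminal: bool = True, dt: float | None = None) -> RelaxResult:
    """Integrate with constant forcing until settling or escape.

    Settled when ``||dE/dt|| < settle_tol`` holds continuously for one
    window of ``10 * tau_env`` (default tolerance ``1e-6 * R / tau_env``).
    Escaped when any variable leaves ``[lo, hi]`` (default the essential
    range) — trajectories that leave are counted as lost to the analysis.
    """
    F = as_force(source)
    tau = config.tau_env
    R = config.essential_range
    hi = R if hi is None else hi
    dt = (0.1 * tau) if dt is None else dt
    settle_tol = (1e-6 * R / tau) if settle_tol is None else settle_tol
    window = 10.0 * tau if window is None else window
    E = np.atleast_1d(np.asarray(E0, dtype=float)).copy()
    P = np.atleast_1d(np.asarray(P, dtype=float)) * np.ones_like(E)

    def deriv(t, y):
        return (P + F(y)) / tau

    t = 0.0
    quiet_since = None
    left = False
    while t < t_max:
        E = _rk4_step(deriv, t, E, dt)
        t += dt
        if not np.isfinite(E).all():
            raise FloatingPointError(f"non-finite state at t={t:.6g}")
        if (E < lo).any() or (E > hi).any():
            left = True
            if escape_terminal:
                return RelaxResult(E=E, t=t, settled=False, escaped=True, left_range=True)
        speed = float(np.linalg.norm(deriv(t, E)))
        if speed < settle_tol:
            if quiet_since is None:
                quiet_since = t
            elif t - quiet_since >= window:
                return RelaxResult(E=E, t=t, settled=True, escaped=False, left_range=left)
        else:
            quiet_since = None
    return RelaxResult(E=E, t=t, settled=False, escaped=False, left_range=left)
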