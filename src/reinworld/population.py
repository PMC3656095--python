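"""Random communities of biotic components and the total biotic force.

A community of K components is drawn once and then fixed: each component
has a niche optimum uniform over the essential range ``[0, R]`` on every
environmental axis and a signed effect vector uniform over
``[-effect_bound, +effect_bound]`` per axis.  The force a component exerts
on an environmental variable is its effect times its current abundance;
the total biotic force is the plain sum over components (no interactions).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import numpy as np

from .niches import NicheShape

_CHUNK = 4_000_000  # cap on K*M floats materialised at once in grid evaluation


@dataclass(frozen=True)
class BioticComponent:
    """One biotic unit: niche optimum, per-variable effect, niche shape."""

    optimum: np.ndarray
    effect: np.ndarray
    shape: NicheShape

    def __post_init__(self):
        opt = np.atleast_1d(np.asarray(self.optimum, dtype=float))
        eff = np.atleast_1d(np.asarray(self.effect, dtype=float))
        if opt.shape != eff.shape:
            raise ValueError("optimum and effect must have the same length")
        if not (np.isfinite(opt).all() and np.isfinite(eff).all()):
            raise ValueError("optimum and effect entries must be finite")
        object.__setattr__(self, "optimum", opt)
        object.__setattr__(self, "effect", eff)


@dataclass
class BioticPopulation:
    """K biotic components sharing one niche shape.

    ``optima`` and ``effects`` are ``(K, n_env)`` arrays.  The population
    is immutable in spirit: traits are fixed at initialisation.
    """

    optima: np.ndarray
    effects: np.ndarray
    shape: NicheShape

    def __post_init__(self):
        self.optima = np.atleast_2d(np.asarray(self.optima, dtype=float))
        self.effects = np.atleast_2d(np.asarray(self.effects, dtype=float))
        if self.optima.shape != self.effects.shape:
            raise ValueError("optima and effects must have identical shapes (K, n_env)")

    @property
    def K(self) -> int:
        return self.optima.shape[0]

    @property
    def n_env(self) -> int:
        return self.optima.shape[1]

    @property
    def components(self) -> list[BioticComponent]:
        return [
            BioticComponent(self.optima[j], self.effects[j], self.shape)
            for j in range(self.K)
        ]

    @classmethod
    def from_components(cls, components) -> "BioticPopulation":
        components = list(components)
        if not components:
            raise ValueError("cannot build a population from zero components")
        shape = components[0].shape
        if any(c.shape != shape for c in components):
            raise ValueError("all components must share the same niche shape")
        return cls(
            np.array([c.optimum for c in components]),
            np.array([c.effect for c in components]),
            shape,
        )

    # -- evaluation ---------------------------------------------------------

    def abundances(self, E) -> np.ndarray:
        return abundances(self, E)

    def force(self, E) -> np.ndarray:
        return total_biotic_force(self, E)

    # -- serialisation ------------------------------------------------------

    def to_text(self) -> str:
        """Delimited text: one row per component, full float precision."""
        n = self.n_env
        cols = [f"optimum_{i+1}" for i in range(n)] + [f"effect_{i+1}" for i in range(n)]
        buf = io.StringIO()
        buf.write(f"# reinworld population K={self.K} n_env={n}\n")
        buf.write(f"# family={self.shape.family} width={self.shape.width!r} "
                  f"shape_params={json.dumps(dict(self.shape.shape_params))}\n")
        buf.write("\t".join(cols) + "\n")
        data = np.hstack([self.optima, self.effects])
        for row in data:
            buf.write("\t".join(repr(float(v)) for v in row) + "\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "BioticPopulation":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        meta = {}
        for ln in lines:
            if ln.startswith("# reinworld population"):
                for tok in ln.split()[3:]:
                    k, v = tok.split("=")
                    meta[k] = int(v)
            elif ln.startswith("# family="):
                parts = ln[2:].split(" ", 2)
                meta["family"] = parts[0].split("=", 1)[1]
                meta["width"] = float(parts[1].split("=", 1)[1])
                meta["shape_params"] = json.loads(parts[2].split("=", 1)[1])
        rows = [ln for ln in lines if not ln.startswith("#")]
        data = np.array([[float(v) for v in ln.split("\t")] for ln in rows[1:]])
        n = meta["n_env"]
        shape = NicheShape(meta["family"], meta["width"],
                           tuple(meta["shape_params"].items()))
        return cls(data[:, :n], data[:, n:], shape)

    def to_json(self) -> str:
        return json.dumps(
            {
                "K": self.K,
                "n_env": self.n_env,
                "shape": {
                    "family": self.shape.family,
                    "width": self.shape.width,
                    "shape_params": dict(self.shape.shape_params),
                },
                "optima": self.optima.tolist(),
                "effects": self.effects.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BioticPopulation":
        d = json.loads(text)
        shape = NicheShape(
            d["shape"]["family"], d["shape"]["width"],
            tuple(d["shape"]["shape_params"].items()),
        )
        return cls(np.array(d["optima"]), np.array(d["effects"]), shape)


def sample_population(config, rng=None) -> BioticPopulation:
    """Draw a random community per the model's initialisation rules.

    Optima ~ Uniform(0, R) and effects ~ Uniform(-effect_bound, +effect_bound)
    independently per component and axis; deterministic given the stream.
    """
    if config.K < 1:
        raise ValueError(f"K must be >= 1, got {config.K}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    optima = rng.uniform(0.0, config.essential_range, size=(config.K, config.n_env))
    effects = rng.uniform(-config.effect_bound, config.effect_bound,
                          size=(config.K, config.n_env))
    return BioticPopulation(optima, effects, config.niche_shape())


def abundances(pop: BioticPopulation | None, E) -> np.ndarray:
    """Vector of the K components' steady-state abundances at ``E``."""
    if pop is None or pop.K == 0:
        return np.empty(0)
    E = np.atleast_1d(np.asarray(E, dtype=float))
    if E.shape[0] != pop.n_env:
        raise ValueError(f"E has length {E.shape[0]}, expected n_env={pop.n_env}")
    resp = pop.shape.profile(E[None, :] - pop.optima)  # (K, n_env)
    return resp.prod(axis=1)


def total_biotic_force(pop: BioticPopulation | None, E) -> np.ndarray:
    """Sum over components of effect times abundance, one entry per variable."""
    E = np.atleast_1d(np.asarray(E, dtype=float))
    if pop is None or pop.K == 0:
        return np.zeros_like(E)
    a = abundances(pop, E)
    return pop.effects.T @ a


def force_on_grid(pop: BioticPopulation, points: np.ndarray) -> np.ndarray:
    """Total biotic force at many points at once.

    ``points`` is ``(M, n_env)``; returns ``(M, n_env)``.  Evaluation is
    chunked so K*M never materialises more than a few million floats.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    M = points.shape[0]
    out = np.empty_like(points)
    step = max(1, _CHUNK // max(pop.K, 1))
    for s in range(0, M, step):
        chunk = points[s : s + step]  # (m, n_env)
        resp = pop.shape.profile(chunk[:, None, :] - pop.optima[None, :, :])
        out[s : s + step] = resp.prod(axis=2) @ pop.effects
    return out
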