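"""Canned scenarios reproducing the standard figure setups of this model
class, each deterministic per seed.

All use the standard parameters (essential range 100, niche width 5).
Quantities the source setups leave unspecified — ramp rate, shock
magnitude, the community size of the four-variable shock run — take the
package defaults documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .config import ModelConfig
from .gp import GPForceField, build_kernel, sample_field
from .population import BioticPopulation, sample_population
from .protocols import PerturbationProtocol
from .rng import stage_rng


@dataclass
class Scenario:
    """A ready-to-run scenario: config, force source, forcing, start state."""

    name: str
    config: ModelConfig
    E0: np.ndarray
    protocol: PerturbationProtocol | None = None
    population: BioticPopulation | None = None
    field: GPForceField | None = None
    t_end: float = 100.0
    analysis: dict = dfield(default_factory=dict)

    @property
    def source(self):
        return self.population if self.population is not None else self.field


FIXTURES = ("fig2_ramp", "fig3_shock", "fig5_sweep", "fig6_shapes",
            "fig7_portrait", "fig9_hysteresis")


def make_fixture(name: str, seed: int = 0) -> Scenario:
    """Build one of the canned scenarios; unknown names list the valid ones."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; valid fixtures: {FIXTURES}")
    rng = stage_rng(seed, f"fixture:{name}")

    if name == "fig2_ramp":
        # single environmental variable, 100 components, started at E = 10,
        # slowly ramped external forcing
        cfg = ModelConfig(K=100, n_env=1, seed=seed, dt=0.05)
        pop = sample_population(cfg, rng)
        # slow-forcing regime: P traverses [0, 3] over 4000 tau_env
        proto = PerturbationProtocol.linear_ramp(rate=3.0 / 4000.0, n_env=1)
        return Scenario(name=name, config=cfg, E0=np.array([10.0]),
                        protocol=proto, population=pop, t_end=4000.0)

    if name == "fig3_shock":
        # four environmental variables, all initialised mid-range; an
        # instantaneous shock at t = 50 kicks the system between attractors.
        # With K = 1e4 the four-variable force is gentle (few components sit
        # near their optimum in all four variables at once), so the
        # environmental timescale is shortened to keep settling, shock and
        # recovery on a time-100 axis.
        cfg = ModelConfig(K=10_000, n_env=4, seed=seed, tau_env=0.25, dt=0.05)
        pop = sample_population(cfg, rng)
        direction = rng.standard_normal(4)
        direction /= np.linalg.norm(direction)
        shock = 5.0 * cfg.niche_width * direction  # norm 5 sigma
        proto = PerturbationProtocol.shock(50.0, shock, base=0.0, n_env=4)
        return Scenario(name=name, config=cfg, E0=np.full(4, 50.0),
                        protocol=proto, population=pop, t_end=100.0)

    if name == "fig5_sweep":
        cfg = ModelConfig(K=1000, n_env=1, seed=seed)
        return Scenario(name=name, config=cfg, E0=np.array([50.0]),
                        analysis={"K_grid": [1, 2, 5, 10, 20, 50, 100, 200,
                                             500, 1000],
                                  "n_populations": 100,
                                  "widths": [5.0, 10.0]})

    if name == "fig6_shapes":
        cfg = ModelConfig(K=1000, n_env=1, seed=seed)
        return Scenario(name=name, config=cfg, E0=np.array([50.0]),
                        analysis={"families": ["gaussian", "skewed", "bimodal"],
                                  "n_fields": 200})

    if name == "fig7_portrait":
        cfg = ModelConfig(K=10_000, n_env=2, seed=seed)
        kernel = build_kernel(cfg.niche_shape())
        fld = sample_field(kernel, R=cfg.essential_range, n_env=2, rng=rng,
                           seed=seed)
        return Scenario(name=name, config=cfg, E0=np.full(2, 50.0), field=fld,
                        analysis={"resolution": 21})

    if name == "fig9_hysteresis":
        cfg = ModelConfig(K=1000, n_env=1, seed=seed)
        kernel = build_kernel(cfg.niche_shape())
        fld = sample_field(kernel, R=cfg.essential_range, n_env=1, rng=rng,
                           seed=seed)
        return Scenario(name=name, config=cfg, E0=np.array([50.0]), field=fld,
                        analysis={"p_lo": -2.0, "p_hi": 2.0, "n_steps": 81})

    raise AssertionError(name)
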