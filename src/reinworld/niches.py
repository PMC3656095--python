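"""Niche (environmental response) functions of biotic components.

A biotic component's steady-state abundance is a bounded, non-negative
function of the environment, maximal (value 1) at the component's niche
optimum and decaying to zero far from it.  Four shape families are
provided: ``gaussian``, ``skewed`` (skew-normal bump), ``bimodal``
(two-Gaussian mixture) and ``fat_tailed`` (Student-t-like bump).  In
several environmental dimensions the response is the separable product of
the one-dimensional profile along each axis.

Every family is calibrated so that its *characteristic width* equals the
requested ``width``.  The characteristic width is defined through the
curvature of the response autocorrelation at zero lag,

    w = sqrt( integral(n^2) / integral(n'^2) ) / sqrt(2),

which for a Gaussian profile equals its standard deviation sigma.  This is
the width that controls the statistics of the summed biotic force in a
large random community — two families with equal characteristic width
produce force fields with the same zero-crossing rate — which is why it,
rather than e.g. the response standard deviation, is the calibrated
quantity.  The response standard deviation is exposed separately as a
diagnostic (:func:`response_std`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable

import numpy as np
from scipy.special import ndtr  # fast standard-normal CDF

FAMILIES = ("gaussian", "skewed", "bimodal", "fat_tailed")

#: default family-specific shape parameters
DEFAULT_SHAPE_PARAMS = {
    "gaussian": {},
    "skewed": {"skewness": 3.0},
    "bimodal": {"mode_separation": 1.3},
    "fat_tailed": {"tail_exponent": 3.0},
}


@dataclass(frozen=True)
class NicheShape:
    """A niche-function family with its characteristic width.

    Parameters
    ----------
    family:
        One of ``gaussian``, ``skewed``, ``bimodal``, ``fat_tailed``.
    width:
        Characteristic width (curvature/Rice width; equals the standard
        deviation for the Gaussian family).  Strictly positive.
    shape_params:
        Family-specific parameters: ``skewness`` (skewed),
        ``mode_separation`` (bimodal, in units of the underlying Gaussian
        scale; > 1 gives two modes), ``tail_exponent`` (fat_tailed,
        Student-t degrees of freedom; must be > 0).
    """

    family: str = "gaussian"
    width: float = 5.0
    shape_params: tuple = field(default=())

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown niche family {self.family!r}; valid: {FAMILIES}"
            )
        if not np.isfinite(self.width) or self.width <= 0:
            raise ValueError(f"niche width must be positive and finite, got {self.width}")
        # normalise shape_params to a sorted tuple of (key, value) pairs so the
        # dataclass stays hashable and order-insensitive
        params = dict(DEFAULT_SHAPE_PARAMS[self.family])
        given = dict(self.shape_params) if self.shape_params else {}
        unknown = set(given) - set(params)
        if unknown:
            raise ValueError(f"unknown shape_params for {self.family}: {sorted(unknown)}")
        params.update(given)
        if self.family == "fat_tailed" and params["tail_exponent"] <= 0:
            raise ValueError("tail_exponent must be positive")
        object.__setattr__(self, "shape_params", tuple(sorted(params.items())))

    @property
    def params(self) -> dict:
        return dict(self.shape_params)

    # -- profile evaluation -------------------------------------------------

    def profile(self, u):
        """Normalised 1-D response at displacement ``u`` from the optimum.

        Maximal value 1 at ``u = 0`` (for the symmetric bimodal family the
        optimum is the centre of symmetry and the two modes flank it).
        """
        u = np.asarray(u, dtype=float)
        base, x_peak, peak, w0, _ = _calibration(self.family, self.shape_params)
        s = self.width / w0
        return base(u / s + x_peak) / peak

    def response_std(self) -> float:
        """Standard deviation of the response treated as a density (diagnostic)."""
        _, _, _, w0, s0 = _calibration(self.family, self.shape_params)
        return s0 * self.width / w0


def _base_profile(family: str, params: dict) -> Callable:
    if family == "gaussian":
        return lambda x: np.exp(-np.square(x) / 2.0)
    if family == "skewed":
        a = params["skewness"]
        return lambda x: np.exp(-np.square(x) / 2.0) * ndtr(a * x)
    if family == "bimodal":
        d = params["mode_separation"]
        return lambda x: 0.5 * (
            np.exp(-np.square(x - d) / 2.0) + np.exp(-np.square(x + d) / 2.0)
        )
    if family == "fat_tailed":
        nu = params["tail_exponent"]
        return lambda x: np.power(1.0 + np.square(x) / nu, -(nu + 1.0) / 2.0)
    raise ValueError(family)


@lru_cache(maxsize=64)
def _calibration(family: str, shape_params: tuple):
    """Numeric calibration of a base profile at unit internal scale.

    Returns ``(base, x_peak, peak_value, rice_width, response_std)`` where
    ``rice_width = sqrt(int b^2 / int b'^2) / sqrt 2`` (== 1 for gaussian).
    """
    params = dict(shape_params)
    base = _base_profile(family, params)
    if family == "gaussian":
        return base, 0.0, 1.0, 1.0, 1.0
    # wide, dense grid: fat tails need range; curvature needs resolution
    x = np.linspace(-80.0, 80.0, 320001)
    b = base(x)
    mass = np.trapezoid(b, x)
    mean = np.trapezoid(x * b, x) / mass
    s0 = float(np.sqrt(np.trapezoid((x - mean) ** 2 * b, x) / mass))
    db = np.gradient(b, x)
    w0 = float(np.sqrt(np.trapezoid(b * b, x) / np.trapezoid(db * db, x)) / np.sqrt(2.0))
    i = int(np.argmax(b))
    # parabolic refinement of the peak.  The bimodal optimum anchors at the
    # centre of symmetry (between the two modes), but the response is still
    # normalised by its true maximum so it never exceeds 1.
    if family == "bimodal":
        x0, x1, x2 = x[i - 1 : i + 2]
        y0, y1, y2 = b[i - 1 : i + 2]
        denom = y0 - 2 * y1 + y2
        x_mode = float(x1 - 0.5 * (x1 - x0) * (y2 - y0) / denom) if denom != 0 else float(x1)
        x_peak, peak = 0.0, float(base(x_mode))
    else:
        x0, x1, x2 = x[i - 1 : i + 2]
        y0, y1, y2 = b[i - 1 : i + 2]
        denom = y0 - 2 * y1 + y2
        x_peak = float(x1 - 0.5 * (x1 - x0) * (y2 - y0) / denom) if denom != 0 else float(x1)
        peak = float(base(x_peak))
    return base, x_peak, peak, w0, s0


def niche_value(shape: NicheShape, optimum, E) -> float:
    """Steady-state abundance of one component at environment ``E``.

    ``optimum`` and ``E`` are vectors of equal length (the number of
    environmental variables); the response is the separable product of the
    1-D profile along each axis and lies in ``[0, 1]``.
    """
    optimum = np.atleast_1d(np.asarray(optimum, dtype=float))
    E = np.atleast_1d(np.asarray(E, dtype=float))
    if optimum.shape != E.shape:
        raise ValueError(
            f"optimum and E must have equal length, got {optimum.shape} vs {E.shape}"
        )
    return float(np.prod(shape.profile(E - optimum)))
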