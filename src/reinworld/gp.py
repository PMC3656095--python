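"""The large-K limit: the total biotic force as a Gaussian random field.

Summing very many components with independent uniform optima and
symmetric random effects, the total biotic force per environmental axis
converges (central limit theorem) to a zero-mean stationary Gaussian
process whose covariance is the autocorrelation of the niche profile,

    k(delta)  proportional to  integral n(E) n(E + delta) dE.

For a Gaussian niche of width sigma this is itself a Gaussian of width
sigma * sqrt(2).  A realisation is drawn on a rectilinear grid over
[0, R]^n_env (Cholesky factorisation of the grid covariance, with the
Kronecker shortcut for separable kernels) and evaluated anywhere by
multilinear interpolation.  Different environmental axes carry
independent fields.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import CubicSpline, RegularGridInterpolator

from .niches import NicheShape

#: diagonal jitter added before factorisation, relative to covariance(0)
JITTER = 1e-10


@dataclass(frozen=True)
class ForceKernel:
    """Stationary covariance of the large-K force field.

    ``corr1`` is the per-axis correlation function (1 at zero lag); the
    full covariance over a displacement vector is ``variance_scale`` times
    the product of ``corr1`` over the axes.  ``curvature`` is
    ``-k''(0)/k(0)`` of the per-axis correlation — the quantity that sets
    the zero-crossing rate — and ``length_scale = 1/sqrt(curvature)``
    (``sigma * sqrt(2)`` for a Gaussian niche of width sigma).
    """

    corr1: Callable
    variance_scale: float
    curvature: float
    family: str = "gaussian"
    width: float = 5.0

    @property
    def length_scale(self) -> float:
        return 1.0 / np.sqrt(self.curvature)

    def covariance(self, delta) -> np.ndarray:
        """Covariance at displacement vector(s) ``delta`` (last axis = n_env)."""
        delta = np.asarray(delta, dtype=float)
        if delta.ndim == 0:
            delta = delta[None]
        return self.variance_scale * np.prod(self.corr1(delta), axis=-1)


def build_kernel(shape: NicheShape, variance_scale: float = 1.0) -> ForceKernel:
    """Kernel implied by the large-K sum for the given niche shape.

    Closed form for the Gaussian family; numerical autocorrelation of the
    profile (dense grid + cubic-spline interpolation) for the others.  The
    autocorrelation of a square-integrable profile is positive
    semi-definite by construction.
    """
    w = shape.width
    if shape.family == "gaussian":
        corr1 = lambda d: np.exp(-np.square(d) / (4.0 * w * w))
        curvature = 1.0 / (2.0 * w * w)
        return ForceKernel(corr1=corr1, variance_scale=variance_scale,
                           curvature=curvature, family=shape.family, width=w)
    # numerical autocorrelation on a dense displacement grid
    half = 60.0 * w
    m = 1 << 15
    x = np.linspace(-half, half, m)
    dx = x[1] - x[0]
    b = shape.profile(x)
    ac = np.correlate(b, b, mode="full") * dx
    lags = np.arange(-(m - 1), m) * dx
    ac = ac / ac[m - 1]
    # keep the informative part of the lag axis
    keep = np.abs(lags) <= 20.0 * w
    spline = CubicSpline(lags[keep], ac[keep], extrapolate=False)
    cutoff = 20.0 * w

    def corr1(d):
        d = np.asarray(d, dtype=float)
        out = np.zeros_like(d)
        inside = np.abs(d) < cutoff
        out[inside] = spline(d[inside])
        return out

    curvature = float(-(ac[m] - 2 * ac[m - 1] + ac[m - 2]) / dx**2)
    return ForceKernel(corr1=corr1, variance_scale=variance_scale,
                       curvature=curvature, family=shape.family, width=w)


@dataclass
class GPForceField:
    """A sampled realisation of the large-K force on a rectilinear grid.

    ``samples`` has shape ``(n_env,) + (m,)*n_env``: one independent field
    per environmental axis, each over the same ``[0, R]^n_env`` grid.
    Off-grid evaluation is multilinear; outside the hull the query is
    clamped to the hull (with a warning) unless ``strict`` is set.
    """

    axis: np.ndarray           # shared 1-D grid, shape (m,)
    samples: np.ndarray        # (n_env, m, ..., m)
    kernel: ForceKernel
    seed: int | None = None
    strict: bool = False
    _interp: list = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        n = self.n_env
        h = float(self.axis[1] - self.axis[0])
        # default spacing is length_scale/(4 sqrt 2); a coarsened grid (used
        # for 3-D fields) may go up to length_scale/2 before sampling becomes
        # too sparse to trust crossing counts
        if h > self.kernel.length_scale / 2 + 1e-12:
            raise ValueError(
                f"grid spacing h={h:.4g} violates the resolution contract "
                f"h <= length_scale/2 = {self.kernel.length_scale / 2:.4g}")
        grids = (self.axis,) * n
        object.__setattr__(self, "_interp", [
            RegularGridInterpolator(grids, self.samples[i], method="linear",
                                    bounds_error=False, fill_value=None)
            for i in range(n)
        ])

    @property
    def n_env(self) -> int:
        return self.samples.shape[0]

    @property
    def h(self) -> float:
        return float(self.axis[1] - self.axis[0])

    def force(self, E) -> np.ndarray:
        """Multilinear interpolation of each axis's field at ``E``.

        ``E`` may be a single point ``(n_env,)`` or a batch ``(M, n_env)``.
        """
        E = np.asarray(E, dtype=float)
        single = E.ndim == 1
        pts = np.atleast_2d(E)
        lo, hi = self.axis[0], self.axis[-1]
        if (pts < lo).any() or (pts > hi).any():
            if self.strict:
                raise ValueError("evaluation point outside the sampled grid hull")
            # sub-cell excursions (integrator sub-steps probing just past the
            # hull) clamp silently; anything larger is worth a warning
            if (pts < lo - self.h).any() or (pts > hi + self.h).any():
                warnings.warn("query outside grid hull; clamping to hull",
                              stacklevel=2)
            pts = np.clip(pts, lo, hi)
        if single:
            return self._force_single(pts[0])
        return np.stack([f(pts) for f in self._interp], axis=-1)

    def _force_single(self, E: np.ndarray) -> np.ndarray:
        """Multilinear interpolation at one (already clamped) point; avoids
        per-call interpolator overhead in integration-heavy analyses."""
        n = E.size
        h = self.h
        lo = self.axis[0]
        m = self.axis.size
        idx = np.clip(((E - lo) / h).astype(int), 0, m - 2)
        frac = (E - lo) / h - idx
        out = np.zeros(n)
        for corner in itertools.product((0, 1), repeat=n):
            w = 1.0
            for d, c in enumerate(corner):
                w *= frac[d] if c else (1.0 - frac[d])
            if w == 0.0:
                continue
            pos = tuple(idx[d] + corner[d] for d in range(n))
            out += w * self.samples[(slice(None),) + pos]
        return out

    # -- serialisation ------------------------------------------------------

    def to_text(self) -> str:
        import io, json
        buf = io.StringIO()
        meta = {"n_env": self.n_env, "h": self.h, "m": int(self.axis.size),
                "lo": float(self.axis[0]), "hi": float(self.axis[-1]),
                "family": self.kernel.family, "width": self.kernel.width,
                "variance_scale": self.kernel.variance_scale, "seed": self.seed}
        buf.write("# reinworld gp-field " + json.dumps(meta) + "\n")
        np.savetxt(buf, self.samples.reshape(self.n_env, -1), fmt="%.17g",
                   delimiter="\t")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "GPForceField":
        import io, json
        first, _, rest = text.partition("\n")
        meta = json.loads(first.split("# reinworld gp-field ", 1)[1])
        flat = np.loadtxt(io.StringIO(rest), delimiter="\t", ndmin=2)
        n, m = meta["n_env"], meta["m"]
        axis = np.linspace(meta["lo"], meta["hi"], m)
        kernel = build_kernel(NicheShape(meta["family"], meta["width"]),
                              meta["variance_scale"])
        return cls(axis=axis, samples=flat.reshape((n,) + (m,) * n),
                   kernel=kernel, seed=meta["seed"])


def _cholesky_1d(kernel: ForceKernel, axis: np.ndarray) -> np.ndarray:
    C = kernel.corr1(axis[:, None] - axis[None, :])
    C = C + JITTER * np.eye(axis.size)
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        ev_min = float(np.linalg.eigvalsh(C).min())
        raise np.linalg.LinAlgError(
            f"grid covariance not positive definite after jitter "
            f"{JITTER:g}; smallest eigenvalue {ev_min:.3e}")


def sample_field(kernel: ForceKernel, R: float = 100.0, h: float | None = None,
                 n_env: int = 1, rng=None, seed: int | None = None,
                 method: str = "auto") -> GPForceField:
    """Draw one realisation of the force field on ``[0, R]^n_env``.

    Default spacing ``h = length_scale / (4 sqrt 2)`` (i.e. sigma/4 for a
    Gaussian niche).  ``method='direct'`` factorises the full tensor-grid
    covariance; ``method='separable'`` (valid because the kernel is a
    product over axes) applies the per-axis Cholesky factor along each
    tensor dimension.  Both draw from the same multivariate normal —
    ``chol(A (x) B) = chol(A) (x) chol(B)`` — and agree draw-for-draw.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if h is None:
        h = kernel.length_scale / (4.0 * np.sqrt(2.0))
    m = int(np.ceil(R / h)) + 1
    axis = np.linspace(0.0, R, m)
    L = _cholesky_1d(kernel, axis)
    sd = np.sqrt(kernel.variance_scale)
    if method == "auto":
        method = "direct" if n_env == 1 else "separable"
    fields = []
    for _ in range(n_env):
        z = rng.standard_normal((m,) * n_env)
        if n_env == 1:
            fields.append(sd * (L @ z))
        elif method == "separable":
            y = z
            # apply L along each tensor axis in turn
            for ax in range(n_env):
                y = np.moveaxis(np.tensordot(L, y, axes=([1], [ax])), 0, ax)
            fields.append(sd * y)
        elif method == "direct":
            Lfull = L
            for _ in range(n_env - 1):
                Lfull = np.kron(Lfull, L)
            fields.append(sd * (Lfull @ z.ravel()).reshape((m,) * n_env))
        else:
            raise ValueError(f"unknown method {method!r}")
    return GPForceField(axis=axis, samples=np.stack(fields), kernel=kernel,
                        seed=seed)


def interpolate(fld: GPForceField, E) -> np.ndarray:
    """Module-level alias for :meth:`GPForceField.force`."""
    return fld.force(E)
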