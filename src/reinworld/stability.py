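"""Stable-point census, crossing statistics, basins, survival, hysteresis.

Homeostatic states of the model are the zeros of the total biotic force
where the force crosses from positive to negative (1-D), or, in several
dimensions, fixed points whose Jacobian eigenvalues all have negative real
part.  This module finds them on finite populations, sampled Gaussian-
process fields and plain callables; evaluates the closed-form expected
count in the large-K limit together with its Rice-formula oracle; and
provides the derived analyses: rein-pair probability, essential-range
survival, basin-of-attraction maps, quasi-static hysteresis sweeps and
plateau detection on forced trajectories.

Expected stable points in the large-K (Gaussian-process) limit
--------------------------------------------------------------
For a Gaussian niche of width sigma, the force per axis is a stationary
Gaussian process with correlation exp(-delta^2 / 4 sigma^2).  By the
Kac-Rice formula the expected number of stable fixed points in
[0, R]^n is

    E[N_stable] = ( R / (2 sigma sqrt(pi)) )^n * m_n,

where m_n = E[ |det G| ; all eigenvalues of G have negative real part ]
for G an n x n matrix of iid standard normals.  m_1 = 1/sqrt(2 pi) and
m_2 = 1/4 are closed forms; m_3, m_4 are frozen high-precision Monte-
Carlo constants.  For n = 1 this reduces to R / (2 sqrt(2) pi sigma):
the expected number of down-crossings, determined only by the ratio of
essential range to niche width.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, root
from statsmodels.stats.proportion import proportion_confint

from .dynamics import Trajectory, as_force, relax
from .gp import ForceKernel, GPForceField, build_kernel, sample_field
from .population import BioticPopulation, force_on_grid

#: m_n = E[|det G| ; Re(eig) < 0] for G ~ iid N(0,1)^{n x n}.  n = 1, 2 are
#: exact; n = 3, 4 are Monte-Carlo (3e7 / 1e6 draws; SE ~ 1.4e-4 / 9e-4).
STABILITY_DET_MOMENTS = {
    1: 1.0 / np.sqrt(2.0 * np.pi),
    2: 0.25,
    3: 0.158159,
    4: 0.097678,
}

DUPLICATE_TOL = 1e-3     # root-merge tolerance, in units of R
JACOBIAN_STEP = 1e-5     # finite-difference step, in units of R
DEGENERATE_EIG = 1e-8    # |Re(eigenvalue)| below this -> degenerate


@dataclass(frozen=True)
class StablePoint:
    """A fixed point of the force field with its linear classification."""

    location: np.ndarray
    classification: str          # stable | unstable | saddle | degenerate
    eigenvalues: np.ndarray = None
    basin_id: int | None = None


def _scalar_force(force):
    """1-D evaluation helpers: vectorised grid call + scalar call."""
    if isinstance(force, GPForceField):
        if force.n_env != 1:
            raise ValueError("find_stable_points_1d needs a 1-D field")
        return (lambda xs: force.force(np.asarray(xs)[:, None])[:, 0],
                lambda x: float(force.force(np.array([x]))[0]))
    if isinstance(force, BioticPopulation):
        if force.n_env != 1:
            raise ValueError("find_stable_points_1d needs a 1-D population")
        return (lambda xs: force_on_grid(force, np.asarray(xs)[:, None])[:, 0],
                lambda x: float(force.force(np.array([x]))[0]))
    return (lambda xs: np.asarray([float(np.atleast_1d(force(x))[0]) for x in xs]),
            lambda x: float(np.atleast_1d(force(x))[0]))


def find_stable_points_1d(force, R: float = 100.0, h: float | None = None) -> list[StablePoint]:
    """Census of the zero crossings of a 1-D force over ``[0, R]``.

    Scans a grid for sign changes and refines each by bisection to
    ``1e-6 * R``.  Crossings from + to - (moving left to right) are the
    stable, homeostatic points; - to + crossings are unstable.  For a
    sampled GP field the scan grid is the field's own grid, so no crossing
    of the interpolant can be missed.
    """
    if isinstance(force, GPForceField):
        xs = force.axis
    else:
        if h is None:
            h = R / 1000.0
        xs = np.linspace(0.0, R, int(np.ceil(R / h)) + 1)
    fgrid, fscalar = _scalar_force(force)
    v = fgrid(xs)
    s = np.sign(v)
    # a node exactly at zero inherits the following sign (tangential touches
    # are not crossings)
    for i in range(s.size - 2, -1, -1):
        if s[i] == 0:
            s[i] = s[i + 1]
    out = []
    for i in np.nonzero(s[:-1] * s[1:] < 0)[0]:
        x = brentq(fscalar, xs[i], xs[i + 1], xtol=1e-6 * R)
        cls = "stable" if s[i] > 0 else "unstable"
        slope = np.array([(fscalar(x + 1e-5 * R) - fscalar(x - 1e-5 * R)) / (2e-5 * R)])
        out.append(StablePoint(location=np.array([x]), classification=cls,
                               eigenvalues=slope))
    return out


def _grid_force(force, pts: np.ndarray) -> np.ndarray:
    if isinstance(force, GPForceField):
        return force.force(pts)
    if isinstance(force, BioticPopulation):
        return force_on_grid(force, pts)
    return np.asarray([np.atleast_1d(force(p)) for p in pts])


def _classify(Ffun, x: np.ndarray, R: float) -> tuple[str, np.ndarray]:
    n = x.size
    step = JACOBIAN_STEP * R
    J = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n); e[j] = step
        J[:, j] = (Ffun(x + e) - Ffun(x - e)) / (2 * step)
    ev = np.linalg.eigvals(J)
    re = ev.real
    if (np.abs(re) < DEGENERATE_EIG).any():
        return "degenerate", ev
    if (re < 0).all():
        return "stable", ev
    if (re > 0).all():
        return "unstable", ev
    return "saddle", ev


def _merge(points: list[np.ndarray], tol: float) -> list[np.ndarray]:
    kept: list[np.ndarray] = []
    for p in points:
        if not any(np.linalg.norm(p - q) < tol for q in kept):
            kept.append(p)
    return kept


def _bilinear_cell_roots(c00, c10, c01, c11) -> list[tuple[float, float]]:
    """Roots of two bilinear forms on the unit cell, in local coordinates.

    Corner values ``c..`` are length-2 (one per force component).  Solving
    f1 = f2 = 0 reduces to a quadratic in one local coordinate.
    """
    a = np.asarray(c00, float)
    b = np.asarray(c10, float) - a
    c = np.asarray(c01, float) - a
    d = np.asarray(c11, float) - np.asarray(c10, float) - np.asarray(c01, float) + a
    A = c[1] * d[0] - d[1] * c[0]
    B = a[1] * d[0] + c[1] * b[0] - b[1] * c[0] - d[1] * a[0]
    C = a[1] * b[0] - b[1] * a[0]
    eps = 1e-12
    if abs(A) < eps * max(abs(B), abs(C), 1.0):
        vs = [-C / B] if abs(B) > eps else []
    else:
        disc = B * B - 4 * A * C
        if disc < 0:
            return []
        r = np.sqrt(disc)
        vs = [(-B + r) / (2 * A), (-B - r) / (2 * A)]
    out = []
    for v in vs:
        if not -1e-9 <= v <= 1 + 1e-9:
            continue
        den = b[0] + d[0] * v
        if abs(den) > eps:
            u = -(a[0] + c[0] * v) / den
        else:
            den2 = b[1] + d[1] * v
            if abs(den2) < eps:
                continue
            u = -(a[1] + c[1] * v) / den2
        if -1e-9 <= u <= 1 + 1e-9:
            out.append((float(u), float(v)))
    return out


def find_fixed_points_nd(force, R: float = 100.0, h: float | None = None,
                         n_env: int | None = None) -> list[StablePoint]:
    """Census of the fixed points of an N-D force field over ``[0, R]^n``.

    The seed grid (the field's own grid for a sampled GP field) is scanned
    for cells in which every force component changes sign among the cell
    corners.  For 2-D sampled fields the multilinear interpolant is solved
    exactly in each candidate cell; otherwise a Newton-type root search
    starts from each candidate cell centre.  Duplicates are merged within
    ``1e-3 * R`` and every root is classified by the eigenvalues of a
    finite-difference Jacobian.
    """
    if isinstance(force, GPForceField):
        n = force.n_env
        axis = force.axis
    else:
        if n_env is None:
            raise ValueError("n_env is required for a non-field force")
        n = n_env
        if h is None:
            h = R / 40.0
        axis = np.linspace(0.0, R, int(np.ceil(R / h)) + 1)
    if n == 1:
        return find_stable_points_1d(force, R)
    m = axis.size
    mesh = np.stack(np.meshgrid(*([axis] * n), indexing="ij"), axis=-1)
    vals = _grid_force(force, mesh.reshape(-1, n)).reshape(mesh.shape)
    sgn = np.sign(vals)
    sgn[sgn == 0] = 1.0  # a node exactly at zero counts as positive

    corners = list(itertools.product((0, 1), repeat=n))
    sl = {0: slice(0, m - 1), 1: slice(1, m)}
    mins = np.ones((m - 1,) * n + (n,))
    maxs = -np.ones((m - 1,) * n + (n,))
    for corner in corners:
        view = sgn[tuple(sl[c] for c in corner)]
        mins = np.minimum(mins, view)
        maxs = np.maximum(maxs, view)
    cand = ((mins < 0) & (maxs > 0)).all(axis=-1)
    idxs = np.argwhere(cand)

    Ffun = as_force(force) if not isinstance(force, BioticPopulation) else force.force
    roots: list[np.ndarray] = []
    if isinstance(force, GPForceField) and n == 2:
        hh = axis[1] - axis[0]
        for i, j in idxs:
            cell = vals[i:i + 2, j:j + 2]  # (2, 2, 2)
            for u, v in _bilinear_cell_roots(cell[0, 0], cell[1, 0],
                                             cell[0, 1], cell[1, 1]):
                roots.append(np.array([axis[i] + u * hh, axis[j] + v * hh]))
    else:
        hh = axis[1] - axis[0]
        for idx in idxs:
            x0 = np.array([axis[k] + hh / 2 for k in idx])
            sol = root(lambda x: np.asarray(Ffun(x), float), x0, method="hybr",
                       tol=1e-12)
            if not sol.success:
                continue
            x = sol.x
            if (x < -DUPLICATE_TOL * R).any() or (x > R + DUPLICATE_TOL * R).any():
                continue
            if np.linalg.norm(np.atleast_1d(Ffun(x))) > 1e-8:
                continue
            roots.append(x)
    roots = _merge(roots, DUPLICATE_TOL * R)

    out = []
    for x in roots:
        cls, ev = _classify(lambda p: np.atleast_1d(Ffun(p)).astype(float), x, R)
        out.append(StablePoint(location=x, classification=cls, eigenvalues=ev))
    return out


def count_stable_points_1d(force, R: float = 100.0, h: float | None = None) -> int:
    """Fast count of + -> - sign changes on a grid (no root refinement).

    The count — not the locations — is all the Monte-Carlo expectations
    need, so this skips the bisection of :func:`find_stable_points_1d`.
    """
    if isinstance(force, GPForceField):
        xs = force.axis
    else:
        if h is None:
            h = R / 1000.0
        xs = np.linspace(0.0, R, int(np.ceil(R / h)) + 1)
    fgrid, _ = _scalar_force(force)
    s = np.sign(fgrid(xs))
    for i in range(s.size - 2, -1, -1):
        if s[i] == 0:
            s[i] = s[i + 1]
    return int(((s[:-1] > 0) & (s[1:] < 0)).sum())


def saturation_sweep(K_grid, config, n_populations: int = 100, rng=None):
    """Mean stable-point count of random K-component communities, per K.

    Returns a pandas DataFrame with columns ``K``, ``mean``, ``se``
    (standard error over the sampled communities).  This is the
    diversity-saturation experiment: the count rises with K and then
    plateaus near the large-K value once K exceeds the diversity
    threshold.
    """
    import pandas as pd

    from .config import ModelConfig
    from .population import sample_population

    if rng is None:
        rng = np.random.default_rng(config.seed)
    R = config.essential_range
    h = config.niche_width / 4.0
    xs = np.linspace(0.0, R, int(np.ceil(R / h)) + 1)[:, None]
    rows = []
    for K in K_grid:
        cfg = ModelConfig(**{**config.to_dict(), "K": int(K)})
        counts = np.empty(n_populations)
        for i in range(n_populations):
            pop = sample_population(cfg, rng)
            F = force_on_grid(pop, xs)[:, 0]
            s = np.sign(F)
            counts[i] = ((s[:-1] > 0) & (s[1:] < 0)).sum()
        rows.append({"K": int(K), "mean": counts.mean(),
                     "se": counts.std(ddof=1) / np.sqrt(n_populations)})
    return pd.DataFrame(rows)


def mc_gp_stable_count(kernel: ForceKernel, R: float, n_fields: int = 200,
                       rng=None, h: float | None = None,
                       n_env: int = 1) -> tuple[float, float]:
    """Monte-Carlo mean (and standard error) of the stable-point count over
    independently sampled GP force fields."""
    if rng is None:
        rng = np.random.default_rng()
    counts = np.empty(n_fields)
    for i in range(n_fields):
        fld = sample_field(kernel, R=R, h=h, n_env=n_env, rng=rng)
        if n_env == 1:
            counts[i] = count_stable_points_1d(fld, R)
        else:
            counts[i] = sum(p.classification == "stable"
                            for p in find_fixed_points_nd(fld, R))
    return float(counts.mean()), float(counts.std(ddof=1) / np.sqrt(n_fields))


# ---------------------------------------------------------------------------
# closed forms and oracles


def expected_stable_points(n_env: int, R: float, width: float) -> float:
    """Expected number of stable points in the large-K limit (Gaussian niche).

    ``(R / (2 width sqrt(pi)))**n_env * m_n`` — see the module docstring.
    Depends on R and width only through their ratio; for ``n_env = 1`` it
    equals ``R / (2 sqrt(2) pi width)``, the expected number of
    down-crossings of the force.
    """
    if not R > width > 0:
        raise ValueError("need R > width > 0")
    if n_env not in STABILITY_DET_MOMENTS:
        raise NotImplementedError(
            f"n_env={n_env}: stability constants tabulated for n_env <= 4")
    return (R / (2.0 * width * np.sqrt(np.pi))) ** n_env * STABILITY_DET_MOMENTS[n_env]


def rice_downcrossings(kernel: ForceKernel, R: float,
                       numeric: bool = False) -> float:
    """Rice-formula expected down-crossings over ``[0, R]`` (1-D).

    ``R * sqrt(-k''(0)/k(0)) / (2 pi)``.  With ``numeric`` the curvature
    is re-derived by finite differences of the correlation function, which
    keeps the oracle independent of the kernel's stored closed form.
    """
    if numeric:
        d = kernel.length_scale * 1e-4
        lam = -(kernel.corr1(np.array([d]))[0] - 2.0
                + kernel.corr1(np.array([-d]))[0]) / (d * d)
    else:
        lam = kernel.curvature
    return R * np.sqrt(lam) / (2.0 * np.pi)


def threshold_K(R: float, width: float, n_env: int = 1) -> float:
    """Approximate diversity threshold beyond which the expected stable-
    point count saturates at its large-K value.

    Saturation requires a few components per niche-width cell of the
    essential-range volume: ``K_T ~ 2 (R / width)^n_env`` (the prefactor
    calibrated once against saturation sweeps; operationally, the K beyond
    which the finite-K count is within ~5% of its large-K plateau).
    """
    if not R > width > 0:
        raise ValueError("need R > width > 0")
    return 2.0 * (R / width) ** n_env


def rein_pair_probability(mode: str = "analytic", n_trials: int = 100_000,
                          rng=None, positive_prob: float = 0.5) -> float:
    """Probability that two random components form an opposing rein pair.

    The pair regulates when the component with the lower niche optimum
    pushes the variable up (positive effect) and the higher-optimum one
    pushes it down.  With optima exchangeable and effect signs independent
    and positive with probability p, the analytic value is ``p (1 - p)``
    — 1/4 for the symmetric default.
    """
    p = positive_prob
    if mode == "analytic":
        return p * (1.0 - p)
    if mode != "monte_carlo":
        raise ValueError(f"unknown mode {mode!r}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    optima = rng.uniform(0.0, 1.0, size=(n_trials, 2))
    signs = np.where(rng.uniform(size=(n_trials, 2)) < p, 1.0, -1.0)
    low = np.argmin(optima, axis=1)
    hi = 1 - low
    rows = np.arange(n_trials)
    ok = (signs[rows, low] > 0) & (signs[rows, hi] < 0)
    return float(ok.mean())


# ---------------------------------------------------------------------------
# survival, basins, hysteresis, plateaus


@dataclass
class SurvivalEstimate:
    """Fraction of random initialisations that settle without leaving the
    essential range, with a 95% Wilson confidence interval.  Non-settling
    trajectories are counted separately, not as failures."""

    estimate: float
    ci_low: float
    ci_high: float
    n_trials: int
    n_survived: int
    n_escaped: int
    n_unsettled: int


def survival_probability(n_env: int, config, n_trials: int, rng=None,
                         t_max: float = 500.0, margin: float = 0.0,
                         field_factory=None) -> SurvivalEstimate:
    """Monte-Carlo essential-range survival probability in the GP limit.

    Each trial draws a fresh force field and a uniform initial state in
    ``[0, R]^n_env`` and relaxes it with no external forcing; the trial
    survives if it settles with every variable staying inside
    ``[-margin, R + margin]`` throughout.  ``field_factory(rng)`` may
    supply the per-trial force source instead of GP sampling (used for
    constructed fields and finite populations).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    R = config.essential_range
    if field_factory is None:
        kernel = build_kernel(config.niche_shape())
        h = None if n_env <= 2 else kernel.length_scale / (2.0 * np.sqrt(2.0))
        field_factory = lambda r: sample_field(kernel, R=R, h=h, n_env=n_env,
                                               rng=r)
    survived = escaped = unsettled = 0
    for _ in range(n_trials):
        fld = field_factory(rng)
        E0 = rng.uniform(0.0, R, size=n_env)
        # survival only needs basin membership and range exit, so the
        # relaxation can take coarser steps than the default integrator
        res = relax(fld, E0, config, P=0.0, t_max=t_max,
                    lo=-margin, hi=R + margin, dt=0.5 * config.tau_env)
        if res.escaped or res.left_range:
            escaped += 1
        elif res.settled:
            survived += 1
        else:
            unsettled += 1
    est = survived / n_trials
    lo, hi = proportion_confint(survived, n_trials, alpha=0.05, method="wilson")
    return SurvivalEstimate(estimate=est, ci_low=float(lo), ci_high=float(hi),
                            n_trials=n_trials, n_survived=survived,
                            n_escaped=escaped, n_unsettled=unsettled)


ESCAPED = -1
UNSETTLED = -2
UNMATCHED = -3


@dataclass
class BasinMap:
    """Basin labels on a grid of initial conditions.

    ``labels[i, j, ...]`` is the index into ``stable_points`` of the
    attractor reached from the cell centre, or ESCAPED (-1) when the
    trajectory leaves the essential range, UNSETTLED (-2) when it fails to
    settle within the horizon, UNMATCHED (-3) when it settles somewhere no
    censused stable point lies within the match tolerance.
    """

    axes: np.ndarray
    labels: np.ndarray
    stable_points: list[StablePoint]
    match_tol: float


def basin_map(force, config, resolution: int = 21,
              stable_points: list[StablePoint] | None = None,
              t_max: float = 500.0, margin: float = 0.0,
              match_tol: float | None = None) -> BasinMap:
    """Integrate from a grid of initial conditions (P = 0) and label each
    cell with the stable point it reaches, or ESCAPED if it leaves the
    essential range on the way."""
    R = config.essential_range
    n = force.n_env if hasattr(force, "n_env") else config.n_env
    if stable_points is None:
        stable_points = [p for p in find_fixed_points_nd(force, R, n_env=n)
                         if p.classification == "stable"]
    else:
        stable_points = [p for p in stable_points if p.classification == "stable"]
    if match_tol is None:
        match_tol = 1e-2 * R
    centres = np.linspace(0.0, R, resolution)
    labels = np.empty((resolution,) * n, dtype=int)
    locs = np.array([p.location for p in stable_points]) if stable_points else \
        np.empty((0, n))
    for idx in itertools.product(range(resolution), repeat=n):
        E0 = np.array([centres[k] for k in idx])
        res = relax(force, E0, config, P=0.0, t_max=t_max,
                    lo=-margin, hi=R + margin)
        if res.escaped or res.left_range:
            labels[idx] = ESCAPED
        elif not res.settled:
            labels[idx] = UNSETTLED
        else:
            if locs.size == 0:
                labels[idx] = UNMATCHED
            else:
                d = np.linalg.norm(locs - res.E, axis=1)
                labels[idx] = int(np.argmin(d)) if d.min() < match_tol else UNMATCHED
    return BasinMap(axes=centres, labels=labels, stable_points=stable_points,
                    match_tol=match_tol)


@dataclass
class HysteresisLoop:
    """Quasi-static sweep record: occupied state E*(P) on both branches."""

    p_up: np.ndarray
    e_up: np.ndarray
    p_down: np.ndarray
    e_down: np.ndarray
    up_transitions: list[tuple[float, float, float]]    # (P, E_from, E_to)
    down_transitions: list[tuple[float, float, float]]

    @property
    def is_hysteretic(self) -> bool:
        if not self.up_transitions or not self.down_transitions:
            return False
        first_up = self.up_transitions[0][0]
        first_down = self.down_transitions[0][0]
        return first_down < first_up


def hysteresis_sweep(force, config, p_lo: float, p_hi: float,
                     n_steps: int = 201, E_init: float | None = None,
                     t_relax: float = 400.0) -> HysteresisLoop:
    """Sweep a constant forcing up from ``p_lo`` to ``p_hi`` and back,
    relaxing the (1-D) system at each step, and locate the jumps between
    homeostatic branches (changes of occupied state larger than the niche
    width between consecutive forcing steps)."""
    sigma = config.niche_width
    R = config.essential_range
    fgrid, fscalar = _scalar_force(force)

    if E_init is None:
        pts = [p for p in find_stable_points_1d(
            lambda x: fscalar(x) + p_lo, R) if p.classification == "stable"]
        if not pts:
            raise ValueError("no stable point at p_lo to start the sweep from")
        E = float(pts[0].location[0])
    else:
        E = float(E_init)

    def settle(E0, P):
        res = relax(lambda x: np.atleast_1d(fscalar(float(np.atleast_1d(x)[0]))),
                    np.array([E0]), config, P=P, t_max=t_relax,
                    lo=-2.0 * R, hi=3.0 * R, escape_terminal=False)
        return float(res.E[0])

    ps = np.linspace(p_lo, p_hi, n_steps)
    e_up = np.empty(n_steps)
    for i, P in enumerate(ps):
        E = settle(E, P)
        e_up[i] = E
    e_down = np.empty(n_steps)
    for i, P in enumerate(ps[::-1]):
        E = settle(E, P)
        e_down[i] = E

    def jumps(pvals, evals):
        out = []
        for i in range(1, len(pvals)):
            if abs(evals[i] - evals[i - 1]) > sigma:
                out.append((float(pvals[i]), float(evals[i - 1]), float(evals[i])))
        return out

    return HysteresisLoop(p_up=ps, e_up=e_up, p_down=ps[::-1].copy(),
                          e_down=e_down, up_transitions=jumps(ps, e_up),
                          down_transitions=jumps(ps[::-1], e_down))


@dataclass
class Plateau:
    """A homeostatic plateau of a forced trajectory."""

    t_start: float
    t_end: float
    e_range: float        # total range of E over the plateau
    comp_max: float       # max |P + F| over the plateau (compensation band)
    comp_max_interior: float  # same, excluding one detection window at each
                              # edge (the detector's span includes the tail of
                              # the preceding jump and the onset of the next)
    p_change: float       # change of P across the plateau

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def detect_plateaus(traj: Trajectory, config, window: float | None = None,
                    threshold: float | None = None) -> list[Plateau]:
    """Detect homeostatic plateaus on a (1-D) trajectory.

    A plateau is a maximal interval over which every sliding window of
    width ``10 tau_env`` has an E-range below ``0.5 sigma`` — the regime
    where the biotic force cancels the external forcing and the
    environmental variable stays put.
    """
    if traj.n_env != 1:
        raise ValueError("plateau detection is defined for 1-D trajectories")
    window = 10.0 * config.tau_env if window is None else window
    threshold = 0.5 * config.niche_width if threshold is None else threshold
    t = traj.times
    dt = float(np.median(np.diff(t)))
    k = max(2, int(round(window / dt)))
    E = traj.env[:, 0]
    if E.size < k + 1:
        return []
    # rolling range over k-sample windows aligned to the window start
    sw = np.lib.stride_tricks.sliding_window_view(E, k)
    ranges = sw.max(axis=1) - sw.min(axis=1)
    nwin = ranges.size
    mask = ranges < threshold
    plateaus = []
    i = 0
    comp = np.abs(traj.perturbation[:, 0] + traj.force[:, 0])
    while i < nwin:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < nwin and mask[j + 1]:
            j += 1
        i0, i1 = i, j + k - 1  # sample span covered by the quiet windows
        if t[i1] - t[i0] >= window:
            a, b = min(i0 + k, i1), max(i1 - k, i0)
            interior = comp[a:b + 1] if b >= a else comp[i0:i1 + 1]
            plateaus.append(Plateau(
                t_start=float(t[i0]), t_end=float(t[i1]),
                e_range=float(E[i0:i1 + 1].max() - E[i0:i1 + 1].min()),
                comp_max=float(comp[i0:i1 + 1].max()),
                comp_max_interior=float(interior.max()),
                p_change=float(traj.perturbation[i1, 0] - traj.perturbation[i0, 0]),
            ))
        i = j + 1
    return plateaus


def transition_intervals(plateaus: list[Plateau]) -> list[tuple[float, float]]:
    """Gaps between consecutive plateaus (the fast state-to-state jumps)."""
    return [(p0.t_end, p1.t_start) for p0, p1 in zip(plateaus[:-1], plateaus[1:])]
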