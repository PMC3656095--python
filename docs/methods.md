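# Methods

## Model

The model couples a community of `K` *biotic components* to `N_E` shared
*environmental variables* `E`.  Component `j` is defined by three fixed
traits drawn once at initialisation:

- a niche optimum `mu_j`, uniform over the essential range `[0, R]` on
  every environmental axis;
- a signed effect vector `omega_j`, uniform over
  `[-effect_bound, +effect_bound]` per axis;
- a niche function `n(E; mu_j, sigma)`: a bounded response, maximal near
  the optimum, decaying with distance, with characteristic width `sigma`.
  In several dimensions the response is the separable product of the 1-D
  profile per axis.

The abundance of component `j` relaxes linearly towards its
environment-determined steady state,

    d alpha_j / dt = ( alpha*_j(E) - alpha_j ) / tau_biotic,
    alpha*_j(E)    = n(E; mu_j, sigma)  in [0, 1],

and each environmental variable moves under the external forcing `P` plus
the summed biotic force,

    dE_i / dt = ( P_i(t) + F_i(E) ) / tau_env,
    F_i(E)    = sum_j  omega_{j,i} * alpha_j.

There are no direct interactions between components (no competition, no
trophic structure) and no mutation: all coupling is mediated by `E`.
Environmental variables are not confined to `[0, R]`; the essential range
is a prescribed habitability window, not a wall.

In the default *quasi-steady* regime (`tau_biotic << tau_env`) the
abundances are slaved to `alpha*_j(E)` and only `E` is integrated.  The
package also integrates the full `(K + N_E)`-dimensional system; on a
ramped one-variable run with `tau_biotic = tau_env/100` the two agree on
`E(t)` to ~0.05% (asserted at <1% in the tests).

Homeostasis appears where `F` crosses zero from positive to negative
(1-D), or where all Jacobian eigenvalues of `F` have negative real parts
(N-D): there the community opposes displacements in either direction —
*rein control* by opposing unidirectional affecters.  The probability
that two random components form such an opposing pair (lower optimum
pushing up, higher optimum pushing down) is exactly `p(1-p) = 1/4` for
independent symmetric effect signs.

## Default parameters

| parameter        | default | units        | rationale                                  |
|------------------|---------|--------------|--------------------------------------------|
| `essential_range` R | 100  | E-units      | standard setting of this model class       |
| `niche_width` sigma | 5    | E-units      | standard setting; only R/sigma matters     |
| `effect_bound`   | 1       | force units  | scale-free: rescales F and P jointly       |
| `tau_env`        | 1       | time         | sets the unit of time                      |
| `tau_biotic`     | 0.01    | time         | quasi-steady regime (<< tau_env)           |
| `dt`             | 0.01·tau_env | time    | fixed-step RK4 default                     |
| grid spacing h   | sigma/4 | E-units      | resolution of sampled force fields         |

## The large-K limit

At a fixed `E`, `F_i(E)` is a sum of `K` independent terms; by the
central limit theorem the force per axis converges (for `K` above a
threshold) to a zero-mean stationary Gaussian process over `E` whose
covariance is the autocorrelation of the niche profile:

    k(delta) ∝ ∫ n(E) n(E + delta) dE.

For a Gaussian niche of width sigma, `k` is a Gaussian of width
`sigma*sqrt(2)`; for the other families the autocorrelation is computed
numerically (dense FFT correlation + cubic spline).  Realisations are
drawn on a rectilinear grid over `[0, R]^{N_E}` by Cholesky factorisation
of the grid covariance with diagonal jitter `1e-10 * k(0)`.  Because the
kernel is a product over axes, the tensor-grid factor is the Kronecker
power of the per-axis factor (`chol(A ⊗ A) = chol(A) ⊗ chol(A)`); the
separable route is used for `N_E >= 2` and agrees draw-for-draw with
factorising the full covariance (asserted in tests).  Off-grid values are
multilinear interpolations; queries outside the hull clamp (with a
warning beyond one cell) or raise in strict mode.  Different axes carry
independent fields.  Fields enter the analyses only through their sign
structure and relative magnitudes, so the marginal variance defaults
to 1.

### Expected number of stable states

By the Kac–Rice formula, for independent stationary Gaussian components
with per-axis correlation `rho(delta)` and curvature
`lambda = -rho''(0)` (`= 1/(2 sigma^2)` for the Gaussian niche):

    E[N_stable] = ( R sqrt(lambda) / sqrt(2 pi) )^{N_E} * m_{N_E}
                = ( R / (2 sigma sqrt(pi)) )^{N_E} * m_{N_E},

where `m_n = E[|det G|; all eigenvalue real parts < 0]` for an `n x n`
iid standard normal matrix `G`.  `m_1 = 1/sqrt(2 pi)` and `m_2 = 1/4`
exactly; `m_3 = 0.158159` and `m_4 = 0.097678` are frozen Monte-Carlo
constants (3e7 and 1e6 draws; SE ~1.4e-4 and ~9e-4).  For `N_E = 1` this
is the down-crossing rate `R / (2 sqrt(2) pi sigma)`: 2.25 expected
homeostatic states at the standard `R/sigma = 20`.  The count grows
exponentially with `N_E` and depends on `R` and `sigma` only through
their ratio.  The independent oracle used in tests recomputes the rate
from finite differences of the correlation function rather than from the
stored closed form.

### Characteristic width

The crossing statistics of the summed force depend on the niche profile
only through `lambda = ∫ n'^2 / ∫ n^2`.  The package therefore defines
the *characteristic width* of every family as the curvature (Rice) width

    w = sqrt( ∫ n^2 / ∫ n'^2 ) / sqrt(2),

which equals the standard deviation for a Gaussian profile.  Each family
(skew-normal bump, two-Gaussian mixture, Student-t bump) is rescaled
numerically so its curvature width equals the requested `width`; with
this calibration the shape-invariance of the expected stable-state count
is a theorem at the level of the crossing rate, and the Monte-Carlo
tests confirm it end to end through the numerically built kernels.  The
response standard deviation is exposed as a diagnostic
(`NicheShape.response_std`); matching *that* instead would bias crossing
counts by up to ~15–35% for strongly skewed or well-separated bimodal
shapes, which is why it is not the calibrated quantity.  The bimodal
optimum anchors at the centre of symmetry (between the modes); all other
families peak exactly at the optimum.

### Diversity threshold

The finite-K count rises with `K` and saturates.  Two empirical
observations from the saturation sweeps (recorded here because they
shape the defaults):

- the finite-K plateau sits a few percent *below* the stationary-GP
  value (e.g. 2.17 vs 2.25 at `R/sigma = 20`), because optima confined
  to `[0, R]` deflate the force variance within ~0.7 sigma of each
  boundary — the true large-K limit is nonstationary at the edges;
- the 95%-of-plateau knee scales with `R/sigma` and sits near
  `K ~ 2 R/sigma`.

The closed form `threshold_K(R, sigma, n_env) = 2 (R/sigma)^{n_env}`
freezes that calibration; the `n_env` power follows from requiring a
fixed number of components per niche-width cell of the essential-range
volume.  It is an order-of-magnitude quantity; the tests assert the
measured knee lies within a factor of two.

## Dynamics protocols and derived analyses

- **Integrator**: fixed-step classical RK4 (order checked by step
  halving: error ratio ~16); forward Euler available for comparison.
  Shock protocols split the schedule at the shock time and displace `E`
  instantaneously.  Non-finite states raise with the failure time.
- **Settling**: `||dE/dt|| < 1e-6 R / tau_env` held continuously for one
  window of `10 tau_env`.  Relaxation-only analyses (survival, basins)
  take coarser steps (`0.1–0.5 tau_env`) since only basin membership and
  range exit matter.
- **Plateau detection**: a plateau is a maximal interval over which every
  sliding window of width `10 tau_env` has E-range `< 0.5 sigma`.  Over a
  long plateau the tracked stable point drifts as the forcing moves it
  (`dE*/dP = -1/F'`), so the 0.5-sigma bound is a per-window quantity,
  not a whole-plateau one.  The compensation band `max |P+F|` is reported
  both for the full span and for the interior (excluding one window at
  each edge, which overlaps the neighbouring jumps); the interior figure
  is the meaningful one.  Under the default ramp (P: 0 -> 3 over
  4000 tau_env) the number of plateaus is realisation-dependent (1–3):
  communities whose maximum compensable force is exceeded part-way escape
  upward, which is itself model behaviour, not a detection artefact.
- **Census**: 1-D crossings are grid-scanned and refined by bisection to
  `1e-6 R`; nodes exactly at zero count as positive (tangential touches
  are not crossings).  N-D fixed points start from every grid cell whose
  corners mix signs in every component; 2-D sampled fields are solved
  exactly per cell (the multilinear interpolant reduces to a quadratic),
  other sources use a Newton-type search from cell centres.  Duplicates
  merge within `1e-3 R`; classification uses finite-difference Jacobians
  (step `1e-5 R`), with eigenvalue real parts below `1e-8` flagged
  degenerate and excluded from stable counts.
- **Survival**: fresh field + uniform initial state per trial, no
  forcing; a trial survives if it settles without any variable leaving
  `[-margin, R + margin]` (default margin 0, the strict essential range).
  Non-settling trials are tallied separately, not counted as failures.
  Wilson 95% intervals accompany every estimate.  3-D fields use the
  coarsened grid `h = sigma/2` to keep the factorisation and integration
  desk-scale.
- **Hysteresis**: quasi-static sweep; at each forcing step the system is
  re-relaxed from its previous state; a jump larger than sigma between
  consecutive steps marks a branch transition.  On the cubic benchmark
  the detected transition forcings match the analytic fold values to
  within one sweep step.

## Seeding

One root seed per run; every stage forks its own stream as
`default_rng([seed, crc32(label)])`, so adding a stage never perturbs
another stage's draws and identical (seed, label) pairs reproduce
identical streams.  All outputs are bit-reproducible given (config,
seed).

## What the synthetic scenarios do and do not show

The canned scenarios are realisations of the model itself, not
observations: uniform optima and effects, a single shared niche family,
no trait evolution, deterministic forcing, and (in the large-K limit) a
*stationary* Gaussian field that ignores the edge deflation noted above.
Passing tests therefore demonstrate the internal consistency of the
model and its Gaussian-process analysis — they say nothing about whether
real ecosystem–environment feedbacks satisfy the model's assumptions
(fast biota, fixed traits, no direct interactions, effect sizes
independent of niche position).

## Problem sizes

The test suite and the acceptance script run: 1e5 rein-pair trials; one
4000-tau ramp (K=100); saturation sweeps of 100 communities per K up to
K=1000 for two widths; 200 sampled fields per (R, sigma) and per niche
family; 50 two-dimensional censuses; 120/80/50 survival trials for 1/2/3
environmental variables; and a 101-step hysteresis sweep.  These sizes
put Monte-Carlo standard errors at the few-percent level appropriate to
the 2-SE checks while keeping the full suite under a minute of compute.

## Known limitations

- `expected_stable_points` is tabulated for `n_env <= 4` (the `m_n`
  constants); higher dimensions raise.
- The stationary-kernel GP limit overestimates the finite-K stable-state
  count by the boundary effect (~4% at `R/sigma = 20`); analyses that mix
  the two regimes should expect that gap.
- The hysteresis sweep follows stable branches only (no continuation of
  unstable branches, no bifurcation tracking).
- Timescale regimes with `tau_biotic ~ tau_env` are integrable with the
  full system but none of the analyses are specialised to them.
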