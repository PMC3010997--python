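# Methods

## Models

Both models are linear subthreshold systems `dx/dt = A x` driven by
instantaneous EPSPs (`v -> v + s` at each input event, recovery unchanged).

**IF.** One variable, `A = [[-alpha]]`.  `alpha = 0` (perfect integrator) is
a legal limit object: propagation is exact, but cumulative quantities
diverge and are reported as `inf`.

**GIF.** Two variables in the relaxing-recovery realization

    dv/dt = -a v - b w
    dw/dt =  v - w,        A = [[-a, -b], [1, -1]],

parameterized spectrally through `a = 2*lam - 1`, `b = (lam-1)^2 + omega^2`,
which places the eigenvalues at `-lam ± i*omega`.  The canonical model
(`lam = 1`, `omega = 2`) has the PSP kernel `Kv(t) = e^(-t) cos(2t)`,
`Kw(t) = e^(-t) sin(2t)/2`.  Constructors also accept structural `(a, b)`
pairs and real eigenvalue pairs `mu1 < mu2 < 0` (non-oscillatory GIF).
Unstable parameter sets raise a stability error; `lam = 0` is rejected at
construction (the divergence path is exercised through the IF integrator).

## Exact propagation

The propagator is the closed-form matrix exponential: `e^(-alpha t)` (IF),
the damped rotation `e^(-lam t)[cos(omega t) I + sin(omega t)/omega (A + lam I)]`
(oscillatory GIF), the Lagrange two-point form (real distinct eigenvalues),
or its confluent limit (repeated eigenvalue).  Train propagation alternates
exact free evolution over inter-event gaps with the EPSP jumps.  The
propagator is validated in the tests against a high-accuracy ODE oracle
(`scipy.integrate.solve_ivp`, DOP853 at `rtol = 1e-12`) and against the
semigroup and linearity identities.

## Discriminability

With both trains re-referenced so their last event is at `t = 0`, the state
difference `sd = x_A(0+) - x_B(0+)` (shared events cancel exactly by
linearity) determines everything:

- instantaneous: `d(t) = (dv(t))²`, a squared damped sinusoid (GIF) or
  squared exponential (IF);
- cumulative: `D = sd' W sd`, with `W` assembled from the elementary
  integrals `∫ e^(-2 lam t) {cos², sin², sin·cos}(omega t) dt`
  (oscillatory), bi-exponential integrals (real case), or `1/(2 alpha)`
  (IF).  `W` equals the observability gramian of `(A, e1')`, which the tests
  cross-check via `scipy.linalg.solve_continuous_lyapunov`;
- the maximum of `d(t)` on `t >= 0` is located in closed form from the
  critical-point condition `tan(omega t - phi) = -lam/omega`;
- an adaptive-quadrature evaluator (piecewise `scipy.integrate.quad` up to
  an envelope-decay horizon) serves as an independent oracle and agrees with
  the closed form to better than `1e-8` relative over random models.

## HDE

For a fixed voltage threshold the analytic HDE is `theta - v(t)` along the
free evolution.  The numerical probe treats the simulator as a black box
spike predicate `spikes(t_probe, amplitude)` and bisects on the amplitude;
the predicate must be monotone in amplitude (checked at the bracket ends,
violations raise).  Probes falling outside the bracket report
`above_bracket` (amplitude `inf`) or `below_bracket` rather than guessing.
With a positive look-ahead horizon the post-event voltage maximum is located
by a dense scan refined with bounded scalar minimization — reliable for
these damped, at most bi-harmonic trajectories.

## Protocols

**Doublet maps.** `D(isi1, isi2)` between the doublets `{-isi1, 0}` and
`{-isi2, 0}` is evaluated as a quadratic form over kernel samples
(vectorized), not train by train.

**Ridge maximum.** The raw cumulative doublet map of an oscillatory GIF has
*no strict two-dimensional interior maximum*: exhaustive fine-grid scans
show the near-diagonal ridge rising monotonically toward short ISIs.  The
well-defined, parameter-trackable feature carved by the intrinsic
oscillation is the **coordinate-wise maximum** — an interior point that is a
local maximum of D along each ISI axis separately (a saddle of the 2-D
surface).  `locate_doublet_maximum` finds grid candidates, refines them by a
gradient root-solve, and validates stationarity, interiority, and negative
curvature along both coordinates; it returns `None` when the feature is
absent.  At the canonical parameters it sits at `(pi/4, 3*pi/4)`, both below
the intrinsic period; lowering `omega` at fixed `lam` moves it to longer
ISIs, and at strong damping (`lam = omega`) it merges into the short-ISI
axis and is undefined.

**Fixed-duration triplets.** Accelerating `{-2m, -(m-Δ/2), 0}` versus
decelerating `{-2m, -(m+Δ/2), 0}`.  The IF value is closed form,
`(2 s²/alpha) e^(-2 alpha m) sinh²(alpha Δ/2)`, and the minimal significant
difference `Δ_min` (where D reaches `theta_D`) inverts it analytically;
undefined when the inversion reaches the admissible bound `2m`.  GIF curves
can be non-monotone, so `Δ_min` uses a grid scan with sign-change counting
plus bisection and is left undefined when the threshold is crossed more or
fewer than exactly once (e.g. `lam = 1, omega = 3, m = 1, s = 2` has three
crossings).

**Memory decay.** Appending `k` shared trailing events and re-referencing
multiplies D by exactly `e^(-2 alpha L)` per step (IF) and by `Q² =
e^(-4 pi lam/omega)` per intrinsic period (GIF).  Numerically the state
difference shrinks geometrically while the shared events stay O(1), so deep
appends lose the difference to floating-point cancellation; the packaged
checks use depth 4, where the log-slope error is far below the `1e-9`
assertion and dominated by theory, not noise.

## Ensembles

Trains concatenate ISIs drawn from an exponential distribution (rate
`1/mean`) or a narrow positive-truncated gaussian, referenced so the last
event is at `t = 0`.  Determinism: each train pair uses
`np.random.default_rng(SeedSequence(entropy=seed, spawn_key=(pair_index,)))`,
so runs are bit-reproducible and individual pairs can be regenerated.

The gaussian ISI standard deviation defaults to a **constant** `0.05` time
units (not proportional to the mean): the near-regular-train comparison
requires the jitter, not the relative jitter, to stay fixed across the
mean-ISI grid — with proportional sd the short-mean discriminability would
grow like `m²` instead of decreasing.  Draws at or below zero are redrawn
(negligible at the default sd; counts are logged at debug level).

For the single-differing-ISI construction with exponential ISIs the mean
discriminability has a closed form.  IF:

    E[D] = s²/(2 alpha) [ r_A/(r_A+2 alpha) + r_B/(r_B+2 alpha)
                          - 2 r_A r_B /((r_A+alpha)(r_B+alpha)) ],

equal to `1/12` at unit rates and parameters.  GIF: `E[D] =
s² (tr(W M_A) + tr(W M_B) - 2 K_A' W K_B)` with the kernel Laplace moments
`K = r (rI - A)^{-1} e1` and `M = r Y`, `Y` solving the shifted Lyapunov
equation `(A - r/2 I) Y + Y (A - r/2 I)' = -e1 e1'`.  The GIF value at unit
rates is `0.1091667`, verified against a double quadrature of the pairwise
closed form over the exponential density.

Monte-Carlo settings in the packaged checks (10000 pairs for closed-form
comparisons, 800–1500 pairs per grid point for mean-ISI profiles) are sized
so statistical assertions hold at 3 standard errors with margin on one CPU
in seconds; they are package choices, not inherited constants.

## Known limitations

- EPSPs are instantaneous voltage jumps; no synaptic kernels, noise
  currents, conductances, or reset dynamics.
- The spike mechanism is a fixed voltage threshold used only for HDE; the
  discriminability theory is purely subthreshold.
- `Δ_min` for GIF models relies on a finite scan grid (default 2000 points);
  paired crossings closer than the grid spacing could be missed.
- The ridge maximum is reported only when it exists inside the search region
  (default twice the intrinsic period per axis); heavily damped models
  legitimately return `None`.
- Closed ensemble means cover the single-differing-ISI (doublet)
  construction with exponential ISIs; triplet and gaussian ensembles are
  Monte-Carlo only.
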