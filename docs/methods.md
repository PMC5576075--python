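# Methods

This note records the models implemented in `mixsync`, the assumptions and
numerical choices behind them, what the synthetic fixtures do and do not
emulate, and the package's known limitations.

## Trajectory model

A track set is a tidy table `(track_id, frame, t_min, x_um, y_um, z_um)`
with one uniform frame interval `dt_frame` per set. `dt_frame` is always
user-supplied — acquisition cadence is metadata the table cannot be trusted
to carry. Frames within a track may be gapped; gaps are recorded and any
displacement or velocity whose interval spans a missing frame is discarded
rather than bridged, because identity across a detection dropout is
unreliable. Positions are micrometers; times minutes.

The bundled linker is greedy mutual-nearest-neighbor between consecutive
frames with a hard distance gate. It is a convenience for raw detection
tables, not a validated tracker: two detections that cross paths closer
than their frame-to-frame displacement will swap identities (this failure
mode is exercised in the tests). Quantification should normally start from
the tracker's own output.

## Reference-frame-free mixing statistics

Velocity is the forward difference over lag Δt, default 5 min. The lag is
deliberately longer than the frame interval so that the sub-minute jitter
of a nucleus inside its cell does not masquerade as cell movement; it is
configurable for sensitivity checks.

**Directional derivative.** (vⱼ−vᵢ)/|δᵢⱼ| approximates the spatial
derivative of the velocity field along the separation vector; its modulus
averaged over neighbors within δ = 16 μm (≈ one cell diameter as seen by
nuclear imaging thresholds) is the per-cell mixing magnitude D_v. Cells
with no neighbor in range are *undefined*, not zero, and are excluded from
population averages — imputing zero would bias sparse regions towards
apparent stillness. Neighborhoods may also be taken from a 3D Voronoi
tessellation (Delaunay facet sharing); open boundaries generate unbounded
Voronoi cells with spurious long edges, so Voronoi adjacency is pruned at
2δ. Degenerate geometries (coplanar points) fall back to the distance rule
with a warning.

**Strain rate.** A continuum velocity field is reconstructed from the
scattered per-cell velocities with a Monaghan cubic-spline kernel
(smoothing length h, default 32 μm ≈ two nominal cell diameters as seen by
the 16 μm neighborhood scale; support 2h). The gradient is evaluated with
first-order-consistent (gradient-corrected) SPH — equivalent to a
kernel-weighted linear least-squares fit around each evaluation point.
The correction matters: a Shepard-normalized kernel sum alone is not exact
on affine fields, and exactness on affine fields is precisely what the
rigid-motion oracle demands (translation → zero tensor, rotation → purely
antisymmetric gradient, v = a·x → a·I). Points with fewer than 4 support
neighbors, or rank-deficient local geometry, are flagged undefined.

**MSDD.** Pairs are seeded at their *first* time of mutual approach within
r = 16 μm inside the observation window; re-contacts never re-seed a pair
(a literal reading of the first-contact definition — the alternative of
re-seeding would overweight slowly separating pairs). From t₀ the squared
difference of the two displacement vectors is accumulated at every lag
where both tracks have data, with lags restricted to exact multiples of
`dt_frame` (no interpolation) and per-lag pair counts n_t reported. Pairs
are aligned by time-since-t₀, so pairs seeded late in the window simply
contribute to fewer lags. Restricting to initial neighbors keeps the
statistic local, and differencing the displacement vectors cancels global
translation exactly (drift invariance is asserted bitwise-to-float in the
tests).

Closed forms used as oracles: independent 3D Brownian motion with
diffusion constant D gives E[m(t)] = 12·D·t (each displacement contributes
6Dt and they are independent); a single pair separating at constant rate
v_rel gives m(t) = v_rel²·t² exactly; rigid motions give m ≡ 0.

**Power-law regimes.** Exponents come from least squares on
(log t, log m) in a lag window, requiring ≥4 strictly positive points.
The default regime boundary between "short" and "long" lags is 3 min,
overridable; diffusive motion gives slope 1, ballistic/persistent motion
slope → 2, caged motion < 1.

## The physical model

Cells are soft spheres of diameter d_c with over-damped dynamics

    dxᵢ/dt = v₀ nᵢ + µ Σⱼ F_rep(xᵢ, xⱼ) + k_b F_wall(xᵢ)

- **Self-propulsion**: speed v₀ along a polarity nᵢ that diffuses on the
  unit sphere. Numerically: an isotropic Gaussian kick of per-axis variance
  2·D_φ·dt projected on the tangent plane, then renormalization; this gives
  ⟨n(0)·n(t)⟩ = e^(−2 D_φ t), which the velocity-autocorrelation test checks
  against the force-free simulator.
- **Volume exclusion**: a linear spring below contact,
  F_rep = (d_c − r)·(xᵢ−xⱼ)/r for r < d_c, zero otherwise. Only the
  existence of short-range repulsion is physically constrained; the linear
  form is the simplest choice and is equal-and-opposite by construction.
- **Confinement**: soft harmonic walls, inward force k_b × penetration
  depth outside each box face. The box stands for a local neighborhood of
  PSM/tailbud tissue, not the organ's geometry.
- **Nucleus**: tracking follows nuclei, not cell centers, so each cell
  carries a nuclear offset uᵢ performing free diffusion (constant D_n)
  radially clipped to the cytoplasmic shell |u| ≤ d_c/2 − r_n. Clipping
  (rather than rejection or reflection) is cheap and preserves the feature
  that matters: confined diffusion saturates, so nuclear motion dominates
  short lags and contributes a plateau at long lags.

Integration is Euler–Maruyama with dt = 0.01 min by default; recording
cadence is decoupled from the step. All stochastic draws come from one
seeded generator in a fixed order (polarity kicks, then nuclear kicks,
each as a single vectorized draw), so runs are bit-reproducible.
Initialization places N = round(ρ·V) cells uniformly in the box and relaxes
them with a force-only settling phase; a residual pair distance below
d_c/2 raises an error (the requested density cannot be realized by this
soft packing). Pair search uses a scipy cKD-tree per step, which is exact
(identical to all-pairs) at these N.

Default parameters (all configurable) describe a tailbud-like condition:

| parameter | default | units | rationale |
|---|---|---|---|
| v₀ | 1.39 | μm/min | measured-scale tailbud single-cell speed |
| µ | 6.0 | 1/min | sets v₀/µ ≈ 0.23 μm, inside the 0.16–0.3 range that controls the MSDD growth rate |
| d_c | 10 | μm | mesenchymal PSM cell diameter |
| D_φ | 0.1 | 1/min | directional persistence ≈ 5 min |
| D_n | 0.3 | μm²/min | makes 12·D_n·t dominate m(t) below ~2 min without saturating there |
| r_n | 3 | μm | 6 μm nucleus; cytoplasmic shell 2 μm |
| k_b | 5.0 | 1/min | walls soft enough for sub-d_c excursions only |
| ρ | 0.001 | μm⁻³ | neighbor spacing ρ^(−1/3) = 10 μm = d_c: cells at contact, volume fraction ≈ 0.52 |
| box | 70³ | μm³ | N = 343, a few-hundred-cell neighborhood |

With these defaults the model reproduces the qualitative MSDD anatomy seen
in embryos: slope ≈ 2 at short lags when D_n = 0, slope ≈ 1 there when
nuclear diffusion dominates, long-lag exponents sweeping sub-diffusive
(< 1 at v₀ = 0.14 μm/min) through ≈ 1.3–1.6 (tailbud-like) as v₀/µ and
the noise scales vary. At substantially higher volume fractions the cage
relaxation time (~1/µ per contact) shortens until it hides the ballistic
short-lag regime at practical recording cadences; the chosen density keeps
all regimes resolvable.

## ABC MCMC fitting

The MSDD of the model has no tractable likelihood, so fitting uses the
Marjoram accept/reject chain: Gaussian proposals per free parameter
(default scale 5% of the prior width), truncated-rejected at the bounds of
the uniform box priors, accepted iff the simulation-to-target distance
d_s ≤ ε. With uniform priors the Metropolis prior ratio is 1, so the
distance test is the whole acceptance rule. The chain is initialized by
prior sampling until a state within ε is found; if a probe budget is
exhausted the error reports the observed d_s quantiles so ε can be
reassessed — ε is a tolerance the user owns, not a fitted quantity.

d_s is the RMS of log m differences on the target's lag grid (simulated
curves are interpolated log-log). Log space weights the diffusive and
ballistic decades evenly; the distance is pluggable. Each proposal's curve
is averaged over a few short replicate simulations (default 3) to tame
stochastic distance noise. Directly measurable quantities — cell density,
cell diameter, nuclear radius — are held fixed; any subset of
{v₀, µ, D_φ, D_n, k_b} may be freed.

Behavioral checks: with ε = ∞ the chain reproduces its priors
(KS < 0.05 per marginal on thinned draws); on a synthetic target of known
parameters it recovers v₀ sharply and µ more softly (the contact-force
response is only weakly expressed in MSDD at contact-level densities),
both within 20% of the prior width, with the v₀/µ posterior covering the
truth. D_v is deliberately *not* a fit target, so population-averaged D_v
remains available as held-out validation.

## Phase oscillators on moving cells

Each cell carries θᵢ with frequency ωᵢ ~ N(ω₀, σ_ω) drawn once at
initialization; ω₀ = 2π/40 min⁻¹ (somitogenesis period at 23 °C). Coupling
is mean-field over current contacts (|xⱼ−xᵢ| ≤ cell diameter), strength κ
(default 0.07 1/min, inside the experimentally plausible 0.01–0.11 range),
with the coupling term zero for isolated cells. Noise is white with
intensity D_θ. σ_ω = 0.008 rad/min and D_θ = 0.001 1/min are this
package's defaults (a few percent of ω₀); quantitative work should set
them explicitly. Phases are stored unwrapped and wrapped only for output.

Movement and phases are co-integrated with independent steps; the contact
graph is rebuilt at the movement-recording cadence (default 1 min) and
held fixed for the phase substeps in between — contacts change on the
minutes scale at these speeds, and halving the refresh interval does not
change the ensemble Z(t) beyond its realization spread. Frequencies are
drawn from the phase seed and realization index only, so two conditions
differing in movement parameters see identical ωᵢ draws: comparisons
isolate the effect of mixing. A two-oscillator contacting pair relaxes its
phase difference as dψ/dt = −2κ sin ψ (each member pulls at κ sin ψ under
the 1/nᵢ normalization), which the tests verify against direct ODE
integration.

First-passage times τ(Z*) are computed per realization (the first recorded
time with Z ≥ Z*) and then averaged; realizations that never cross are
right-censored and reported separately, never mixed into the mean.
Per-realization passage preserves variance information; ensemble-mean
crossing can be obtained by thresholding `Z_mean` directly. Δτ between a
slow- and fast-mixing condition divided by the 40-min period converts to a
predicted defective-segment count. The desynchronization/resynchronization
protocol (wash-out experiment) is coupled evolution from uniformly random
initial phases.

## Synthetic fixtures

The generators produce track sets *with* their closed-form expectations:
rigid translation (D_v = 0, m ≡ 0), rigid rotation (per-neighbor
directional derivative |Ω×δ|/|δ|, zero strain-rate symmetric part),
independent Brownian tracks (E m(t) = 12Dt; a "pairs" layout places
statistically independent pairs for clean standard errors), constant-rate
pair separation (m = v_rel²t²), and drift overlays (constant velocity,
sinusoidal wobble, stage bump) that must leave every mixing statistic
unchanged. They emulate the *statistics* real recordings should satisfy,
not their texture: no detection noise, no track fragmentation, no spatial
gradients of motility, no cell division or extrusion. Tests passing on
these fixtures therefore certify the estimators' correctness and frame
independence, not robustness to segmentation artifacts.

## Problem sizes used in tests and the acceptance script

MSDD regime checks run the default ~340-cell box for 60 simulated minutes,
averaged over 10 replicate seeds (short-lag fits on 0.05–0.3 min at 0.05-min
recording; long-lag fits on 5–30 min at 0.5-min recording). ABC recovery
uses a 64-cell box, 20-min simulations, 2 replicates per proposal and a
300-iteration chain. Synchronization comparisons use 125 cells, 350 min,
20 realizations per condition, movement step 0.02 min and phase step
0.05 min. These sizes make every run a desk-scale computation while keeping
the measured exponents and orderings stable across seeds.

## Known limitations

- No proliferation, apoptosis, or cell-size heterogeneity in the physical
  model; the box is a homogeneous neighborhood, not a tissue with a
  motility gradient.
- The linear repulsion and harmonic walls are generic choices; exponents
  and stiffnesses are config-exposed for sensitivity analysis but no model
  selection across force laws is attempted.
- MSDD lag alignment assumes pairs comparable by time-since-first-contact;
  in strongly non-stationary recordings early- and late-seeded pairs may
  sample different dynamical states.
- The phase model is a Kuramoto reduction: no signaling delays, no
  explicit Delta-Notch gene circuit, no frequency gradient or traveling
  waves across the PSM.
- The Voronoi neighbor mode requires non-degenerate 3D geometry and is
  heuristically pruned at the hull; the distance-threshold mode is the
  validated default.
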