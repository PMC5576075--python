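# mixsync

Quantify **cell mixing** from 3D single-cell trajectories without choosing a
reference frame, fit a physical model of motile cells to the measured mixing,
and ask whether that mixing is fast enough to promote **synchronization** of
coupled genetic oscillators — the setting of the zebrafish segmentation clock,
where presomitic-mesoderm (PSM) and tailbud cells carry her1/her7 oscillations
while actively rearranging.

It is written for developmental biologists and biophysicists with nuclear
tracking data (any tracker that exports `track_id, frame, x, y, z` tables)
and for modelers studying synchronization on mobile contact networks.

## The statistics and models

Velocities are forward finite differences over a lag Δt (default 5 min, so
intracellular nuclear jitter is averaged out):
**v**ᵢ(t) = (**x**ᵢ(t+Δt) − **x**ᵢ(t))/Δt.

Two reference-frame-free mixing measures are built from *differences* between
nearby cells, so any global embryo drift or axis elongation cancels exactly:

- **Directional derivative modulus** — for each cell i with neighbors j
  within δ (default 16 μm):
  D_v(**x**ᵢ) = (1/nᵢ) Σⱼ |**v**ⱼ − **v**ᵢ| / |**δ**ᵢⱼ|, units 1/min.
  A kernel-based strain-rate tensor (symmetric velocity gradient, zero under
  rigid-body motion) is provided as the continuum counterpart.
- **MSDD** (mean squared difference of displacement vectors) — every pair
  (i, j) enters once, at the first time t₀ it satisfies |**x**ᵢ−**x**ⱼ| ≤ r
  (default 16 μm):
  m(t) = ⟨|(**x**ᵢ(t₀+t)−**x**ᵢ(t₀)) − (**x**ⱼ(t₀+t)−**x**ⱼ(t₀))|²⟩.
  Log-log regression extracts its power-law regimes: diffusive (t¹),
  persistent (→t²), sub-diffusive (<1).

The **physical model** describes cells as self-propelled soft spheres with
over-damped dynamics
d**x**ᵢ/dt = v₀**n**ᵢ + µ ΣⱼF_rep + k_b F_wall, with the polarity **n**ᵢ
diffusing on the unit sphere (rate D_φ) and a nucleus of radius r_n
diffusing inside each cell (constant D_n, confined to the cytoplasm).
Nuclear diffusion reproduces the diffusive short-lag MSDD regime seen in
embryos; persistent cell-body motion produces the super-diffusive long-lag
regime. Parameters are fitted to a target MSDD curve by **ABC MCMC**
(accept a proposal iff the log-space RMS distance d_s ≤ ε), which
approximates P(ϑ | d_s ≤ ε).

**Phase oscillators** θᵢ with frequencies ωᵢ ~ N(ω₀, σ_ω) (period
2π/ω₀ = 40 min) ride on the moving cells and couple to touching neighbors:
dθᵢ/dt = ωᵢ + (κ/nᵢ) Σⱼ sin(θⱼ−θᵢ) + noise. Synchrony is the Kuramoto
order parameter Z = |⟨e^{iθ}⟩| and is compared between conditions through
first-passage times τ(Z*), with Δτ/period the predicted number of defective
segments after a desynchronizing perturbation.

## Worked example

`examples/01_quantify_mixing.py` builds 40 Brownian tracks (D = 0.5 μm²/min),
overlays an erratic microscope-stage drift, and quantifies both versions:

```
tissue frame:
  mean D_v over frames  = 0.1623 1/min
  m(10 min)             = 59.4 um^2 (12*D*t = 60)
  MSDD exponent (2-15')  = 1.07 (diffusive: 1)
with stage drift:
  mean D_v over frames  = 0.1623 1/min
  m(10 min)             = 59.4 um^2 (12*D*t = 60)
  MSDD exponent (2-15')  = 1.07 (diffusive: 1)
```

The drifted and undrifted recordings give identical mixing numbers (the
statistics cancel global motion), m(10) matches the closed form 12·D·t, and
the fitted exponent identifies diffusive relative motion.

`examples/02_simulate_and_fit.py` recovers v₀ = 1.39 μm/min from a
simulated MSDD target (posterior median 1.389, 90% CI 1.29–1.51);
`examples/03_synchronization.py` shows tailbud-like mixing reaching each
synchrony threshold earlier than a near-static tissue, with the gap growing
in Z*.

The same pipeline is scriptable from the shell:

```sh
mixsync make-fixture --kind brownian --D 1.0 --N 100 --T 60 --out fix.csv
mixsync msdd --in fix.csv --r 16 --out m.csv
mixsync fit-powerlaw --in m.csv --t-lo 2 --t-hi 30
mixsync simulate --T 60 --out sim.csv    # the physical model
mixsync sync --v0 1.39 --kappa 0.07 --realizations 10 --out z.csv
```

## Layout

- `src/mixsync/tracks.py` — trajectory data model, CSV I/O, box clipping, a
  convenience nearest-neighbor linker
- `src/mixsync/mixing.py` — velocities, D_v, strain rate, MSDD, power-law fits
- `src/mixsync/motility.py` — the self-propelled-particle / nuclear-diffusion
  simulator
- `src/mixsync/abc_fit.py` — ABC MCMC fitting of the model to MSDD curves
- `src/mixsync/phase.py` — phase oscillators on moving cells, Z(t),
  first-passage analysis
- `src/mixsync/synthetic.py` — fixture generators with closed-form statistics
- `src/mixsync/cli.py` — the `mixsync` command
- `docs/methods.md` — models, assumptions, parameter choices, limitations
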