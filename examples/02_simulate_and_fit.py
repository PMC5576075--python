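"""Simulate the physical model of motile cells and fit it back by ABC MCMC.

Generates a target MSDD curve from the self-propelled-particle model at
known intrinsic speed v0 and repulsion strength µ, then recovers both with
likelihood-free MCMC using only the curve.  The run takes a couple of
minutes at this scale.
"""

import numpy as np

from mixsync import (AbcConfig, MotilityParams, RegionBox, fit_power_law,
                     make_motility_simulator, posterior_summary, run_abc_mcmc,
                     synthetic_msdd_target)

box = RegionBox((0, 0, 0), (40, 40, 40))
true = MotilityParams(v0=1.39, mu=6.0, rho=0.001, box=box, dt=0.02, seed=42)
print(f"ground truth: v0={true.v0} um/min, mu={true.mu} 1/min "
      f"(v0/mu = {true.v0 / true.mu:.3f} um), N={true.n_cells} cells")

target, _ = synthetic_msdd_target(true, T=20, replicates=4, record_every=0.5,
                                  r=16, max_lag=15)
print(f"target MSDD: m(10 min) = {np.interp(10, target.t, target.m):.1f} um^2, "
      f"long-lag exponent = {fit_power_law(target, (3, 15)).exponent:.2f}")

fixed = {"d_c": 10.0, "r_n": 3.0, "rho": 0.001, "box": box, "dt": 0.02,
         "D_phi": 0.1, "D_n": 0.3, "k_b": 5.0}  # directly measured / held
simulator = make_motility_simulator(fixed, T=20, record_every=0.5, r=16,
                                    max_lag=15, sim_replicates=2)
cfg = AbcConfig(priors={"v0": (0.3, 2.5), "mu": (2.0, 10.0)}, epsilon=0.08,
                proposal_scales={"v0": 0.15, "mu": 0.8},
                n_iterations=300, burn_in=50, seed=7)
chain = run_abc_mcmc(cfg, target, simulator=simulator)
summary = posterior_summary(chain)

for name, s in summary["params"].items():
    print(f"posterior {name}: median {s['median']:.3f}, "
          f"90% CI ({s['ci90'][0]:.2f}, {s['ci90'][1]:.2f})")
print(f"acceptance rate {chain.acceptance_rate:.2f} "
      f"(accepted states satisfy d_s <= {cfg.epsilon})")
print("\nv0 is sharply identified by the MSDD level and long-lag growth;\n"
      "mu is softer (it only shapes the contact-force response), matching\n"
      "the idea that the mixing rate is set mainly by v0 and the ratio v0/mu.")
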