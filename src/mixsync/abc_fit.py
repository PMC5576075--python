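"""Likelihood-free fitting of the motility model to a target MSDD curve.

The model's MSDD has no tractable likelihood, so parameters are sampled
with Approximate Bayesian Computation over a Markov chain (the Marjoram
scheme): from the current parameter set ϑ, propose ϑ′ from a Gaussian
kernel, simulate the model, and accept ϑ′ iff the simulation-to-data
distance d_s falls below a tolerance ε (with uniform box priors the prior
ratio is 1 inside the support, so acceptance reduces to the distance test
plus the bounds).  The accepted states approximate P(ϑ | d_s ≤ ε).

The distance is the log-space RMS between curves

    d_s = sqrt( mean_t (log m_sim(t) − log m_target(t))² ) ,

which weights the diffusive and ballistic regimes evenly across decades;
it is pluggable for sensitivity work.  Cell density, cell diameter and
nuclear radius are direct measurements and enter as fixed parameters; the
free parameters are any subset of {v0, mu, D_phi, D_n, k_b}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixing import MsddCurve, msdd
from .motility import MotilityParams, simulate

__all__ = [
    "AbcConfig",
    "AbcChain",
    "msdd_distance",
    "make_motility_simulator",
    "run_abc_mcmc",
    "posterior_summary",
]


def msdd_distance(sim: MsddCurve, target: MsddCurve) -> float:
    """Log-space RMS distance between two MSDD curves.

    The simulated curve is interpolated onto the target's lag grid
    (linearly in log-log space); lags with nonpositive m on either side are
    dropped.  Symmetric on a common grid and zero iff the curves agree.
    """
    ts_ok = (sim.t > 0) & (sim.m > 0) & np.isfinite(sim.m)
    tt_ok = (target.t > 0) & (target.m > 0) & np.isfinite(target.m)
    st, sm = sim.t[ts_ok], sim.m[ts_ok]
    common = tt_ok & (target.t >= st.min(initial=np.inf)) & (target.t <= st.max(initial=-np.inf))
    if common.sum() < 4:
        raise ValueError("curves share fewer than 4 positive common lag points")
    lt = np.log(target.t[common])
    lm_sim = np.interp(lt, np.log(st), np.log(sm))
    resid = lm_sim - np.log(target.m[common])
    return float(np.sqrt(np.mean(resid**2)))


@dataclass(frozen=True)
class AbcConfig:
    """ABC MCMC settings.

    priors: {name: (lower, upper)} bounded uniform per free parameter;
    parameters absent from ``priors`` stay fixed.  proposal_scales default
    to 5% of each prior width.
    """

    priors: dict = field(default_factory=lambda: {"v0": (0.1, 3.0), "mu": (1.0, 12.0)})
    epsilon: float = 0.2
    proposal_scales: dict | None = None
    n_iterations: int = 500
    burn_in: int = 100
    sim_replicates: int = 3
    seed: int = 0
    probe_budget: int = 200

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not (self.n_iterations > self.burn_in >= 0):
            raise ValueError("need n_iterations > burn_in >= 0")
        for name, (lo, hi) in self.priors.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"prior for {name} must be a finite interval with lo < hi")

    def scales(self) -> dict:
        if self.proposal_scales is not None:
            return dict(self.proposal_scales)
        return {k: 0.05 * (hi - lo) for k, (lo, hi) in self.priors.items()}


@dataclass
class AbcChain:
    """Recorded chain: one row per iteration (state repeats on rejection)."""

    samples: pd.DataFrame   # columns: iter, <params...>, d_s, accepted
    acceptance_rate: float
    target: MsddCurve
    config: AbcConfig

    @property
    def param_names(self) -> list[str]:
        return list(self.config.priors.keys())

    def post_burn_in(self) -> pd.DataFrame:
        return self.samples[self.samples["iter"] >= self.config.burn_in]


def make_motility_simulator(fixed: dict, T: float = 20.0, record_every: float = 0.5,
                            r: float | None = None, max_lag: float | None = None,
                            sim_replicates: int = 1):
    """Build the default simulator: motility run → nuclear-track MSDD.

    ``fixed`` holds the directly measured / held parameters (typically
    d_c, r_n, rho, box, dt); free parameters are merged in per call.  The
    returned callable has signature ``simulator(theta: dict, seed: int) ->
    MsddCurve``; replicate curves are averaged pointwise.
    """
    def simulator(theta: dict, seed: int) -> MsddCurve:
        merged = {**fixed, **theta}
        curves = []
        for rep in range(sim_replicates):
            params = MotilityParams(**merged, seed=int((seed + rep) % (2**31 - 1)))
            ts, _ = simulate(params, T=T, record_every=record_every)
            curves.append(msdd(ts, r=r if r is not None else merged.get("d_c", 10.0),
                               max_lag=max_lag))
        t0 = curves[0].t
        m = np.mean([np.interp(t0, c.t, c.m) for c in curves], axis=0)
        n = np.sum([np.interp(t0, c.t, c.n_pairs) for c in curves], axis=0)
        return MsddCurve(t0, m, n.astype(int), curves[0].r)

    return simulator


def run_abc_mcmc(cfg: AbcConfig, target: MsddCurve, fixed: dict | None = None,
                 simulator=None, distance=msdd_distance) -> AbcChain:
    """Sample P(ϑ | d_s ≤ ε) with ABC MCMC (Marjoram scheme).

    The chain is initialized by prior sampling until a state with
    d_s ≤ ε is found (up to ``probe_budget`` draws; failing that, an error
    reports the observed d_s distribution so ε can be reassessed).  At each
    iteration a Gaussian proposal is drawn per free parameter; proposals
    outside the prior box are rejected outright (Metropolis rejection of
    zero-prior states), otherwise acceptance requires d_s(ϑ′) ≤ ε.
    Identical seeds give identical chains.
    """
    if simulator is None:
        simulator = make_motility_simulator(fixed or {},
                                            sim_replicates=cfg.sim_replicates)
    rng = np.random.default_rng(cfg.seed)
    names = list(cfg.priors.keys())
    lo = np.array([cfg.priors[k][0] for k in names])
    hi = np.array([cfg.priors[k][1] for k in names])
    scale = np.array([cfg.scales()[k] for k in names])

    def sim_distance(vec: np.ndarray) -> float:
        theta = dict(zip(names, vec.tolist()))
        seed = int(rng.integers(2**31 - 1))
        return distance(simulator(theta, seed), target)

    # initialization: prior sampling until inside the tolerance
    probes = []
    cur, cur_d = None, None
    for _ in range(cfg.probe_budget):
        cand = lo + rng.random(len(names)) * (hi - lo)
        d = sim_distance(cand)
        probes.append(d)
        if d <= cfg.epsilon:
            cur, cur_d = cand, d
            break
    if cur is None:
        q = np.percentile(probes, [5, 50, 95])
        raise RuntimeError(
            f"epsilon={cfg.epsilon} too tight: no prior draw within tolerance in "
            f"{cfg.probe_budget} probes (observed d_s quantiles 5/50/95% = "
            f"{q[0]:.3g}/{q[1]:.3g}/{q[2]:.3g})"
        )

    rows = []
    n_accept = 0
    for it in range(cfg.n_iterations):
        prop = cur + rng.normal(0.0, scale)
        accepted = False
        d_prop = np.nan
        if np.all((prop >= lo) & (prop <= hi)):
            d_prop = sim_distance(prop)
            if d_prop <= cfg.epsilon:
                cur, cur_d = prop, d_prop
                accepted = True
        if accepted:
            n_accept += 1
        rows.append((it, *cur.tolist(), cur_d, accepted))
    samples = pd.DataFrame(rows, columns=["iter", *names, "d_s", "accepted"])
    return AbcChain(samples=samples, acceptance_rate=n_accept / cfg.n_iterations,
                    target=target, config=cfg)


def posterior_summary(chain: AbcChain, min_samples: int = 100) -> dict:
    """Median, central 90% interval and pairwise correlations of the
    post-burn-in states."""
    post = chain.post_burn_in()
    if len(post) < min_samples:
        raise ValueError(f"only {len(post)} post-burn-in samples (< {min_samples})")
    names = chain.param_names
    summary = {}
    for k in names:
        v = post[k].to_numpy()
        summary[k] = {
            "median": float(np.median(v)),
            "ci90": (float(np.percentile(v, 5)), float(np.percentile(v, 95))),
        }
    corr = post[names].corr() if len(names) > 1 else pd.DataFrame(index=names, columns=names)
    return {"params": summary, "correlations": corr,
            "n_samples": len(post), "acceptance_rate": chain.acceptance_rate}
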