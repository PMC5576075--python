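"""Physical model of motile cells with diffusing nuclei.

Cells are soft spheres of diameter ``d_c`` in a confined box, obeying an
over-damped equation of motion

    dx_i/dt = v0 n_i + µ Σ_j F_rep(x_i, x_j) + k_b F_wall(x_i) ,

where ``n_i`` is a polarity unit vector performing rotational diffusion on
the sphere (coefficient ``D_phi``), F_rep is a linear volume-exclusion
spring active below contact distance, and F_wall is a soft harmonic
confinement at the box faces.  Because experimental tracking follows
*nuclei*, each cell carries a nucleus of radius ``r_n`` whose offset from
the cell center diffuses with constant ``D_n`` and is confined to the
cytoplasm (|u| ≤ d_c/2 − r_n).  Nuclear diffusion produces the diffusive
(∝ t) short-lag regime of the MSDD; persistent cell-body motion produces
the super-diffusive long-lag regime; low v0 with saturated nuclear motion
gives sub-diffusive curves.

Integration is Euler-Maruyama with step ``dt`` (0.01 min by default); runs
are bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .tracks import CellTrackSet, RegionBox

__all__ = [
    "MotilityParams",
    "MotilityState",
    "SimulationHistory",
    "init_state",
    "step",
    "simulate",
    "velocity_autocorrelation",
    "DEFAULT_BOX",
]

DEFAULT_BOX = RegionBox(origin=(0.0, 0.0, 0.0), extent=(70.0, 70.0, 70.0))


@dataclass(frozen=True)
class MotilityParams:
    """Parameters of the cell-movement model (μm, min).

    Defaults describe a tailbud-like condition: intrinsic speed
    v0 = 1.39 μm/min with v0/µ ≈ 0.23, ~340 cells of diameter 10 μm at a
    density where neighbors sit at contact distance (volume fraction ≈ 0.5,
    mesenchymal packing) in a 70 μm box, nuclei of radius 3 μm.
    """

    v0: float = 1.39          # intrinsic self-propulsion speed, μm/min
    mu: float = 6.0           # repulsion strength per unit overlap, 1/min
    d_c: float = 10.0         # cell diameter, μm
    D_phi: float = 0.1        # polarity rotational diffusion, 1/min
    D_n: float = 0.3          # nuclear diffusion constant, μm²/min
    r_n: float = 3.0          # nuclear radius, μm
    k_b: float = 5.0          # boundary spring stiffness, 1/min
    box: RegionBox = field(default_factory=lambda: DEFAULT_BOX)
    rho: float = 0.001        # cell number density, cells/μm³ (sets N)
    dt: float = 0.01          # integration step, min
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu", "d_c", "D_phi", "D_n", "k_b", "rho", "dt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.v0 < 0 or self.d_c <= 0 or self.dt <= 0:
            raise ValueError("v0 ≥ 0 and d_c, dt > 0 required")
        if not self.r_n < self.d_c / 2:
            raise ValueError("nuclear radius must satisfy r_n < d_c/2")
        if self.n_cells < 2:
            raise ValueError("rho × box volume must give at least 2 cells")

    @property
    def n_cells(self) -> int:
        return int(round(self.rho * self.box.volume))

    @property
    def nucleus_confinement(self) -> float:
        return self.d_c / 2 - self.r_n

    def with_(self, **kw) -> "MotilityParams":
        return replace(self, **kw)


@dataclass
class MotilityState:
    """Full state: cell centers, polarities, nuclear offsets, time."""

    x: np.ndarray      # (N, 3) cell centers, μm
    n: np.ndarray      # (N, 3) unit polarity vectors
    u: np.ndarray      # (N, 3) nuclear offsets, |u| ≤ d_c/2 − r_n
    t: float = 0.0     # minutes

    @property
    def nuclei(self) -> np.ndarray:
        """Absolute nuclear positions (the tracked observable)."""
        return self.x + self.u

    def copy(self) -> "MotilityState":
        return MotilityState(self.x.copy(), self.n.copy(), self.u.copy(), self.t)


@dataclass
class SimulationHistory:
    """Recorded snapshots at uniform cadence."""

    times: np.ndarray       # (F,)
    centers: np.ndarray     # (F, N, 3)
    nuclei: np.ndarray      # (F, N, 3)
    polarities: np.ndarray  # (F, N, 3)
    params: MotilityParams

    def center_velocities(self) -> np.ndarray:
        """(F-1, N, 3) finite-difference cell-center velocities."""
        dt = np.diff(self.times)[:, None, None]
        return np.diff(self.centers, axis=0) / dt


def _pair_forces(x: np.ndarray, d_c: float) -> np.ndarray:
    """Linear-spring volume exclusion: F_i = Σ_j (d_c − r_ij) (x_i − x_j)/r_ij
    over pairs with r_ij < d_c.  Equal and opposite by construction."""
    F = np.zeros_like(x)
    if len(x) < 2:
        return F
    pairs = cKDTree(x).query_pairs(d_c, output_type="ndarray")
    if len(pairs):
        a, b = pairs[:, 0], pairs[:, 1]
        d = x[a] - x[b]
        r = np.linalg.norm(d, axis=1)
        r = np.maximum(r, 1e-12)
        fv = ((d_c - r) / r)[:, None] * d
        np.add.at(F, a, fv)
        np.add.at(F, b, -fv)
    return F


def _wall_forces(x: np.ndarray, box: RegionBox) -> np.ndarray:
    """Soft harmonic walls: inward force proportional to penetration depth
    outside each box face (zero inside)."""
    lo, hi = box.origin, box.origin + box.extent
    return np.clip(lo - x, 0.0, None) - np.clip(x - hi, 0.0, None)


def init_state(params: MotilityParams, settle_steps: int = 400,
               rng: np.random.Generator | None = None) -> MotilityState:
    """Random initial condition with a force-only settling phase.

    N = round(rho × box volume) centers are placed uniformly in the box,
    then relaxed under repulsion + wall forces only (no propulsion, no
    noise) to remove deep overlaps.  Polarities are uniform on the unit
    sphere; nuclear offsets start at zero.  Raises if the density is too
    high to settle (a pair closer than d_c/2 remains).
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    N = params.n_cells
    x = params.box.origin + rng.random((N, 3)) * params.box.extent
    # settle with repulsion + walls only
    for _ in range(settle_steps):
        F = params.mu * _pair_forces(x, params.d_c) + params.k_b * _wall_forces(x, params.box)
        x = x + F * params.dt
    if N >= 2:
        dmin, _ = cKDTree(x).query(x, k=2)
        if dmin[:, 1].min() < 0.5 * params.d_c:
            raise RuntimeError(
                "initial settling failed: residual overlap deeper than 0.5 d_c "
                f"(min pair distance {dmin[:, 1].min():.2f} μm); density too high"
            )
    n = rng.normal(size=(N, 3))
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    u = np.zeros((N, 3))
    return MotilityState(x=x, n=n, u=u, t=0.0)


def step(state: MotilityState, params: MotilityParams,
         rng: np.random.Generator) -> MotilityState:
    """One Euler-Maruyama step of length ``params.dt``.

    Deterministic draw order (polarity kicks, then nuclear kicks, each over
    all cells at once) makes runs reproducible for a given generator state.
    """
    p, dt = params, params.dt
    x, n, u = state.x, state.n, state.u
    # squared distances overflow inside the neighbor search long before the
    # positions themselves do, so bound the magnitude up front
    if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 1e100:
        raise FloatingPointError(
            f"diverging cell positions at t={state.t:.3f}; "
            f"dt={dt} too large for mu={p.mu}, k_b={p.k_b}"
        )
    F = p.v0 * n + p.mu * _pair_forces(x, p.d_c) + p.k_b * _wall_forces(x, p.box)
    x_new = x + F * dt
    if not np.all(np.isfinite(x_new)):
        raise FloatingPointError(
            f"non-finite cell positions after step at t={state.t:.3f}; "
            f"dt={dt} too large for mu={p.mu}, k_b={p.k_b}"
        )
    # rotational diffusion of polarity: isotropic Gaussian kick projected on
    # the tangent plane, then renormalized -> <n(0)·n(t)> = exp(-2 D_phi t)
    xi = rng.normal(0.0, np.sqrt(2.0 * p.D_phi * dt), size=n.shape)
    xi -= np.sum(xi * n, axis=1, keepdims=True) * n
    n_new = n + xi
    n_new /= np.linalg.norm(n_new, axis=1, keepdims=True)
    # confined nuclear diffusion: Gaussian increment, radial clip to the
    # cytoplasmic shell
    u_new = u + rng.normal(0.0, np.sqrt(2.0 * p.D_n * dt), size=u.shape)
    cap = p.nucleus_confinement
    r = np.linalg.norm(u_new, axis=1)
    over = r > cap
    if np.any(over):
        u_new[over] *= (cap / r[over])[:, None]
    return MotilityState(x=x_new, n=n_new, u=u_new, t=state.t + dt)


def simulate(params: MotilityParams, T: float, record_every: float = 1.0,
             state: MotilityState | None = None,
             return_centers: bool = False) -> tuple[CellTrackSet, SimulationHistory]:
    """Run the model for ``T`` minutes, recording every ``record_every`` min.

    Returns a :class:`CellTrackSet` of *nuclear* positions (the observable
    matched to experimental tracking; pass ``return_centers=True`` for
    cell-center tracks instead) plus the full recorded history.  Identical
    seeds give identical output.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    k_rec = max(1, int(round(record_every / params.dt)))
    n_steps = int(round(T / params.dt))
    rng = np.random.default_rng(params.seed)
    st = init_state(params, rng=rng) if state is None else state.copy()
    times, centers, nuclei, pols = [st.t], [st.x.copy()], [st.nuclei.copy()], [st.n.copy()]
    for k in range(1, n_steps + 1):
        st = step(st, params, rng)
        if k % k_rec == 0:
            times.append(st.t)
            centers.append(st.x.copy())
            nuclei.append(st.nuclei.copy())
            pols.append(st.n.copy())
    hist = SimulationHistory(np.array(times), np.array(centers), np.array(nuclei),
                             np.array(pols), params)
    obs = hist.centers if return_centers else hist.nuclei
    F, N, _ = obs.shape
    df = pd.DataFrame({
        "track_id": np.tile(np.arange(N), F),
        "frame": np.repeat(np.arange(F), N),
        "x_um": obs[:, :, 0].ravel(),
        "y_um": obs[:, :, 1].ravel(),
        "z_um": obs[:, :, 2].ravel(),
    })
    dt_frame = params.dt * k_rec
    ts = CellTrackSet(df, dt_frame=dt_frame)
    return ts, hist


def velocity_autocorrelation(history: SimulationHistory,
                             max_lag: float | None = None) -> pd.DataFrame:
    """Normalized autocorrelation C(τ) of cell-center velocities, C(0)=1.

    Averaged over cells and over time origins; lags on the recording grid.
    For a force-free self-propelled cell the decay is exp(−2 D_phi τ).
    """
    v = history.center_velocities()
    F = v.shape[0]
    if F < 1:
        raise ValueError("need at least two recorded frames")
    dt = float(np.mean(np.diff(history.times)))
    kmax = F - 1 if max_lag is None else min(F - 1, int(round(max_lag / dt)))
    c = np.empty(kmax + 1)
    for k in range(kmax + 1):
        c[k] = np.mean(np.sum(v[: F - k] * v[k:], axis=-1))
    c0 = c[0] if c[0] > 0 else 1.0
    return pd.DataFrame({"lag_min": np.arange(kmax + 1) * dt, "C": c / c0})
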