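"""Trajectory generators with closed-form mixing statistics.

These fixtures are the oracles of the package: each generator returns a
track set *together with* the exact statistics the mixing estimators must
reproduce on it.

kind                 closed-form expectations
-------------------  -----------------------------------------------------
rigid-translation    D_v = 0 everywhere; m(t) = 0
rigid-rotation       per-neighbor directional derivative |Ω×δ|/|δ|;
                     strain-rate symmetric part = 0
brownian             E[m(t)] = 12·D·t  (two independent 3D diffusers:
                     E|Δx_i − Δx_j|² = 2·6·D·t)
pair-separation      m(t) = v_rel²·t² exactly (one pair, constant-rate
                     separation from initial contact)
drift-overlay        statistics identical to the undrifted base fixture
simulator-passthrough tracks from the physical model, no closed form

Drift overlays model the global motions real recordings contain — embryo
translation on the stage (constant), wobble (sinusoidal) and stage bumps
(piecewise linear) — and must leave every mixing statistic unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixing import MsddCurve, msdd
from .motility import MotilityParams, simulate
from .tracks import CellTrackSet

__all__ = ["FixtureSpec", "generate", "drift_profile", "synthetic_msdd_target"]

_KINDS = {"rigid-translation", "rigid-rotation", "brownian", "pair-separation",
          "drift-overlay", "simulator-passthrough"}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic track set (μm, min)."""

    kind: str
    params: dict = field(default_factory=dict)
    N: int = 50
    T: float = 20.0
    dt_frame: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {sorted(_KINDS)}")
        if self.N < 1 or self.T <= 0 or self.dt_frame <= 0:
            raise ValueError("need N ≥ 1, T > 0, dt_frame > 0")


def drift_profile(drift_id: str, times: np.ndarray, params: dict) -> np.ndarray:
    """Global translation g(t) per frame time, shape (F, 3).

    constant:   g(t) = v_drift · t
    sinusoidal: g(t) = A · sin(2π t / period) · direction
    stage-bump: g(t) = 0 for t < t_bump, offset afterwards
    """
    t = np.asarray(times, dtype=float)[:, None]
    if drift_id == "constant":
        v = np.asarray(params.get("v_drift", (3.0, -1.0, 0.5)), dtype=float)
        return t * v
    if drift_id == "sinusoidal":
        amp = float(params.get("amplitude", 5.0))
        period = float(params.get("period", 12.0))
        direction = np.asarray(params.get("direction", (1.0, 1.0, 0.0)), dtype=float)
        direction = direction / np.linalg.norm(direction)
        return amp * np.sin(2 * np.pi * t / period) * direction
    if drift_id == "stage-bump":
        t_bump = float(params.get("t_bump", 5.0))
        offset = np.asarray(params.get("offset", (8.0, 0.0, 0.0)), dtype=float)
        return (t >= t_bump) * offset
    raise ValueError(f"unknown drift id {drift_id!r}")


def _frame_table(pos: np.ndarray, dt_frame: float) -> pd.DataFrame:
    F, N, _ = pos.shape
    return pd.DataFrame({
        "track_id": np.tile(np.arange(N), F),
        "frame": np.repeat(np.arange(F), N),
        "x_um": pos[:, :, 0].ravel(),
        "y_um": pos[:, :, 1].ravel(),
        "z_um": pos[:, :, 2].ravel(),
    })


def _rotation_matrices(omega: np.ndarray, times: np.ndarray) -> np.ndarray:
    w = np.linalg.norm(omega)
    if w == 0:
        return np.tile(np.eye(3), (len(times), 1, 1))
    axis = omega / w
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    out = np.empty((len(times), 3, 3))
    for k, t in enumerate(times):
        a = w * t
        out[k] = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
    return out


def generate(spec: FixtureSpec) -> tuple[CellTrackSet, dict]:
    """Build the fixture and its expected-statistics record.

    The record's keys depend on the kind (see module docstring); every
    generator is deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    F = int(round(spec.T / spec.dt_frame)) + 1
    times = np.arange(F) * spec.dt_frame
    p = spec.params

    if spec.kind == "rigid-translation":
        v = np.asarray(p.get("velocity", (1.0, 0.5, -0.25)), dtype=float)
        spread = float(p.get("spread", 30.0))
        x0 = rng.random((spec.N, 3)) * spread
        pos = x0[None, :, :] + times[:, None, None] * v
        expected = {"kind": spec.kind, "Dv": 0.0, "msdd": {"form": "zero"},
                    "strain_sym_norm": 0.0}

    elif spec.kind == "rigid-rotation":
        omega = np.asarray(p.get("omega", (0.0, 0.0, 0.05)), dtype=float)
        spread = float(p.get("spread", 30.0))
        x0 = (rng.random((spec.N, 3)) - 0.5) * spread
        R = _rotation_matrices(omega, times)
        pos = np.einsum("fab,nb->fna", R, x0)
        expected = {"kind": spec.kind, "omega": omega,
                    "dv_per_neighbor": "|omega × delta| / |delta|",
                    "strain_sym_norm": 0.0}

    elif spec.kind == "brownian":
        D = float(p.get("D", 1.0))
        layout = p.get("layout", "cluster")
        if layout == "pairs":
            # N/2 statistically independent pairs: pair centers far apart
            # (no cross-pair contact), partners seeded in contact
            n_pairs = spec.N // 2
            centers = np.arange(n_pairs)[:, None] * np.array([200.0, 0.0, 0.0])
            offs = rng.normal(0.0, 1.0, size=(n_pairs, 3))
            offs *= (2.0 / np.linalg.norm(offs, axis=1))[:, None]
            x0 = np.empty((2 * n_pairs, 3))
            x0[0::2] = centers
            x0[1::2] = centers + offs
        else:
            cluster = float(p.get("cluster_radius", 6.0))
            x0 = rng.normal(0.0, cluster / np.sqrt(3), size=(spec.N, 3))
        steps = rng.normal(0.0, np.sqrt(2 * D * spec.dt_frame), size=(F - 1, len(x0), 3))
        pos = np.concatenate([x0[None], x0[None] + np.cumsum(steps, axis=0)])
        expected = {"kind": spec.kind, "D": D,
                    "msdd": {"form": "linear", "coefficient": 12.0 * D}}

    elif spec.kind == "pair-separation":
        v_rel = float(p.get("v_rel", 0.5))
        d0 = float(p.get("d0", 1.0))
        pos = np.zeros((F, 2, 3))
        pos[:, 1, 0] = d0 + v_rel * times
        expected = {"kind": spec.kind, "v_rel": v_rel,
                    "msdd": {"form": "quadratic", "coefficient": v_rel**2}}

    elif spec.kind == "drift-overlay":
        base_spec = FixtureSpec(kind=p["base_kind"], params=p.get("base_params", {}),
                                N=spec.N, T=spec.T, dt_frame=spec.dt_frame, seed=spec.seed)
        base_ts, expected = generate(base_spec)
        g = drift_profile(p.get("drift_id", "constant"), times, p)
        ts = base_ts.translated(lambda frames: g[frames])
        expected = {**expected, "kind": spec.kind, "base_kind": p["base_kind"],
                    "note": "all mixing statistics equal the undrifted base"}
        return ts, expected

    elif spec.kind == "simulator-passthrough":
        mp = p.get("motility_params") or MotilityParams(seed=spec.seed)
        ts, _ = simulate(mp, T=spec.T, record_every=spec.dt_frame)
        return ts, {"kind": spec.kind, "motility_params": mp}

    else:  # pragma: no cover - guarded by FixtureSpec
        raise ValueError(spec.kind)

    ts = CellTrackSet(_frame_table(pos, spec.dt_frame), dt_frame=spec.dt_frame)
    return ts, expected


def synthetic_msdd_target(params: MotilityParams, T: float = 20.0,
                          replicates: int = 3, record_every: float = 0.5,
                          r: float | None = None, max_lag: float | None = None,
                          ) -> tuple[MsddCurve, dict]:
    """Ensemble MSDD from the simulator with its true parameters recorded.

    Used as the ground-truth target in parameter-recovery experiments: fit
    the model to this curve and compare the posterior against the
    provenance record.
    """
    curves = []
    for rep in range(replicates):
        p = params.with_(seed=int((params.seed + 7919 * rep) % (2**31 - 1)))
        ts, _ = simulate(p, T=T, record_every=record_every)
        curves.append(msdd(ts, r=r if r is not None else params.d_c, max_lag=max_lag))
    t0 = curves[0].t
    m = np.mean([np.interp(t0, c.t, c.m) for c in curves], axis=0)
    n = np.sum([np.interp(t0, c.t, c.n_pairs) for c in curves], axis=0).astype(int)
    curve = MsddCurve(t0, m, n, curves[0].r)
    provenance = {"true_params": params, "T": T, "replicates": replicates,
                  "record_every": record_every}
    return curve, provenance
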