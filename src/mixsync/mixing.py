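"""Reference-frame-free quantification of cell mixing.

Embryos drift on the microscope stage and the body axis deforms and
elongates, so velocities measured in the laboratory frame conflate
spontaneous cell movement with global tissue motion.  The statistics here
are built from *differences* between nearby cells and are therefore exactly
invariant under any time-dependent global translation of all positions:

* directional derivative modulus ``D_v`` — per-cell average over neighbors
  within ``delta`` of |v_j − v_i| / |x_j − x_i|, a local mixing magnitude
  with units 1/min;
* MSDD ``m(t)`` — mean squared difference of the displacement vectors of
  cell pairs, each pair entering once at the first time it comes within a
  threshold ``r`` of contact;
* strain-rate tensor — symmetric part of the spatial velocity gradient,
  reconstructed from scattered cell velocities with a kernel-weighted
  (SPH-style) estimator; it vanishes under any rigid-body motion.

Power-law regimes of ``m(t)`` (diffusive t^1, persistent t^1.5-2,
sub-diffusive <1) are extracted by log-log least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import Delaunay, QhullError, cKDTree

from .tracks import CellTrackSet

__all__ = [
    "VelocityField",
    "MixingProfile",
    "MsddCurve",
    "PowerLawFit",
    "compute_velocities",
    "neighbor_graph",
    "directional_derivative",
    "strain_rate",
    "msdd",
    "fit_power_law",
    "population_average_dv",
    "DEFAULT_DELTA_UM",
    "DEFAULT_R_UM",
    "DEFAULT_VELOCITY_LAG_MIN",
]

# Neighborhood threshold and MSDD contact radius default to 16 μm (close to
# the measured cell size in zebrafish PSM); velocity lag defaults to 5 min so
# that finite differences average over intracellular nuclear fluctuation.
DEFAULT_DELTA_UM = 16.0
DEFAULT_R_UM = 16.0
DEFAULT_VELOCITY_LAG_MIN = 5.0


@dataclass
class VelocityField:
    """Forward-difference velocities per (track_id, frame), μm/min."""

    data: pd.DataFrame  # columns: track_id, frame, vx, vy, vz
    lag: float  # minutes


@dataclass
class MixingProfile:
    """Per-cell, per-frame mixing measures.

    ``data`` columns always include track_id and frame; ``Dv`` (1/min) and
    ``n_neighbors`` for directional-derivative profiles, and the six
    independent strain-rate components plus ``strain_norm`` (Frobenius, 1/min)
    for strain-rate profiles.  Undefined entries (no neighbors / not enough
    kernel support) are NaN and are excluded from population averages.
    """

    data: pd.DataFrame
    delta: float | None = None
    kernel_scale: float | None = None


@dataclass
class MsddCurve:
    """MSDD m(t) on a uniform lag grid with per-lag pair counts."""

    t: np.ndarray        # minutes, starting at 0
    m: np.ndarray        # μm²
    n_pairs: np.ndarray  # contributing pairs per lag
    r: float             # contact threshold, μm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_min": self.t, "msdd_um2": self.m, "n_pairs": self.n_pairs})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, r: float = DEFAULT_R_UM) -> "MsddCurve":
        return cls(df["t_min"].to_numpy(float), df["msdd_um2"].to_numpy(float),
                   df["n_pairs"].to_numpy(), r)


@dataclass
class PowerLawFit:
    """Least-squares line on (log t, log m): m(t) ≈ prefactor · t^exponent."""

    window: tuple[float, float]
    exponent: float
    prefactor: float
    r_squared: float
    n_points: int


def compute_velocities(ts: CellTrackSet, lag: float = DEFAULT_VELOCITY_LAG_MIN) -> VelocityField:
    """Forward finite-difference velocities v_i(t) = (x_i(t+Δt) − x_i(t)) / Δt.

    ``lag`` must be an integer multiple of the frame interval.  Velocities
    are defined only where the same track contains both endpoints of the
    lag; displacements across gaps are discarded, never bridged.
    """
    k = lag / ts.dt_frame
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ValueError(
            f"velocity lag {lag} min is not a positive integer multiple of dt_frame={ts.dt_frame}"
        )
    k = int(round(k))
    parts = []
    for tid, grp in ts.data.groupby("track_id"):
        f = grp["frame"].to_numpy()
        pos = grp[["x_um", "y_um", "z_um"]].to_numpy()
        if len(f) <= k:
            continue
        # frame f+k must exist AND the run f..f+k must be gap-free: a
        # displacement spanning missing frames is discarded, not bridged
        contiguous = f[k:] - f[:-k] == k
        idx = np.nonzero(contiguous)[0]
        if idx.size == 0:
            continue
        v = (pos[idx + k] - pos[idx]) / lag
        part = pd.DataFrame({"track_id": tid, "frame": f[idx]})
        part[["vx", "vy", "vz"]] = v
        parts.append(part)
    cols = ["track_id", "frame", "vx", "vy", "vz"]
    data = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=cols)
    return VelocityField(data, lag=lag)


def neighbor_graph(positions: np.ndarray, method: str = "distance",
                   delta: float = DEFAULT_DELTA_UM) -> list[np.ndarray]:
    """Symmetric adjacency for a 3D point set.

    method="distance": j is a neighbor of i iff 0 < |x_j − x_i| ≤ delta.
    method="voronoi": cells sharing a Voronoi facet (Delaunay co-simplex
    membership), pruned to distances ≤ 2·delta to suppress the spurious long
    edges that unbounded Voronoi cells produce at an open boundary.
    Degenerate geometry (e.g. coplanar points) falls back to the distance
    rule with a warning.
    """
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(pts)
    if n < 2:
        raise ValueError("need at least two points")
    if method == "voronoi":
        try:
            tri = Delaunay(pts)
        except QhullError:
            warnings.warn("degenerate geometry: falling back to distance-threshold "
                          "neighbors", stacklevel=2)
            method = "distance"
        else:
            adj: list[set[int]] = [set() for _ in range(n)]
            for simplex in tri.simplices:
                for a in simplex:
                    for b in simplex:
                        if a != b and np.linalg.norm(pts[a] - pts[b]) <= 2 * delta:
                            adj[a].add(b)
            return [np.array(sorted(s), dtype=int) for s in adj]
    if method != "distance":
        raise ValueError(f"unknown neighbor method {method!r}")
    tree = cKDTree(pts)
    pairs = tree.query_pairs(delta, output_type="ndarray")
    adj = [set() for _ in range(n)]
    for a, b in pairs:
        if not np.array_equal(pts[a], pts[b]):
            adj[a].add(int(b))
            adj[b].add(int(a))
    return [np.array(sorted(s), dtype=int) for s in adj]


def directional_derivative(ts: CellTrackSet, vf: VelocityField,
                           delta: float = DEFAULT_DELTA_UM) -> MixingProfile:
    """Average directional-derivative modulus D_v per cell per frame.

    For each cell i with at least one neighbor j within ``delta``::

        D_v(x_i) = (1/n_i) Σ_j |v_j − v_i| / |x_j − x_i|

    The finite difference (v_j − v_i)/|δ_ij| approximates the spatial
    derivative of the velocity field along the separation vector δ_ij, so
    any global velocity drift cancels exactly.  Cells with no neighbors are
    flagged undefined (NaN) rather than assigned zero.
    """
    merged = ts.data.merge(vf.data, on=["track_id", "frame"])
    records = []
    for frame, grp in merged.groupby("frame"):
        pos = grp[["x_um", "y_um", "z_um"]].to_numpy()
        vel = grp[["vx", "vy", "vz"]].to_numpy()
        tids = grp["track_id"].to_numpy()
        m = len(grp)
        dv_sum = np.zeros(m)
        n_nb = np.zeros(m, dtype=int)
        if m >= 2:
            pairs = cKDTree(pos).query_pairs(delta, output_type="ndarray")
            if len(pairs):
                a, b = pairs[:, 0], pairs[:, 1]
                sep = np.linalg.norm(pos[b] - pos[a], axis=1)
                ok = sep > 0
                a, b, sep = a[ok], b[ok], sep[ok]
                dmod = np.linalg.norm(vel[b] - vel[a], axis=1) / sep
                np.add.at(dv_sum, a, dmod)
                np.add.at(dv_sum, b, dmod)
                np.add.at(n_nb, a, 1)
                np.add.at(n_nb, b, 1)
        with np.errstate(invalid="ignore"):
            dv = np.where(n_nb > 0, dv_sum / np.maximum(n_nb, 1), np.nan)
        records.append(pd.DataFrame({"track_id": tids, "frame": frame,
                                     "Dv": dv, "n_neighbors": n_nb}))
    data = (pd.concat(records, ignore_index=True)
            if records else pd.DataFrame(columns=["track_id", "frame", "Dv", "n_neighbors"]))
    return MixingProfile(data, delta=delta)


def _cubic_spline_weight(q: np.ndarray) -> np.ndarray:
    # Monaghan cubic spline, support q < 2; normalization constant dropped
    # (weights are renormalized by the least-squares solve).
    w = np.zeros_like(q)
    lo = q <= 1.0
    mid = (q > 1.0) & (q < 2.0)
    w[lo] = 1.0 - 1.5 * q[lo] ** 2 + 0.75 * q[lo] ** 3
    w[mid] = 0.25 * (2.0 - q[mid]) ** 3
    return w


def strain_rate(ts: CellTrackSet, vf: VelocityField, kernel_scale: float = 32.0,
                k_min: int = 4) -> MixingProfile:
    """Strain-rate tensor (symmetric velocity gradient) at each cell.

    A continuum velocity field is reconstructed from the scattered cell
    velocities with a cubic-spline kernel of smoothing length
    ``kernel_scale`` (support radius 2×) and its gradient evaluated with
    first-order-consistent (gradient-corrected) SPH, i.e. a kernel-weighted
    linear fit v(x) ≈ v0 + G·(x − x_i) around each cell.  The correction
    makes the estimator exact on affine fields, so rigid translations give
    G = 0 and rigid rotations a purely antisymmetric G.  Cells with fewer
    than ``k_min`` support points (or degenerate local geometry) are
    flagged undefined.

    Returns the six independent components Sxx..Szz of S = (G + Gᵀ)/2 and
    the Frobenius norm ``strain_norm``.
    """
    merged = ts.data.merge(vf.data, on=["track_id", "frame"])
    comp_names = ["Sxx", "Syy", "Szz", "Sxy", "Sxz", "Syz"]
    records = []
    h = float(kernel_scale)
    for frame, grp in merged.groupby("frame"):
        pos = grp[["x_um", "y_um", "z_um"]].to_numpy()
        vel = grp[["vx", "vy", "vz"]].to_numpy()
        tids = grp["track_id"].to_numpy()
        m = len(grp)
        tree = cKDTree(pos)
        comps = np.full((m, 6), np.nan)
        norm = np.full(m, np.nan)
        for i in range(m):
            idx = tree.query_ball_point(pos[i], 2.0 * h)
            idx = np.asarray(idx, dtype=int)
            if len(idx) < k_min:
                continue
            dx = pos[idx] - pos[i]
            w = _cubic_spline_weight(np.linalg.norm(dx, axis=1) / h)
            keep = w > 0
            dx, w, vloc = dx[keep], w[keep], vel[idx[keep]]
            if len(w) < k_min:
                continue
            # weighted linear fit: columns [1, dx, dy, dz]
            A = np.hstack([np.ones((len(w), 1)), dx]) * np.sqrt(w)[:, None]
            b = vloc * np.sqrt(w)[:, None]
            sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
            if rank < 4:
                continue
            G = sol[1:].T  # G[a, b] = ∂v_a/∂x_b
            S = 0.5 * (G + G.T)
            comps[i] = [S[0, 0], S[1, 1], S[2, 2], S[0, 1], S[0, 2], S[1, 2]]
            norm[i] = np.linalg.norm(S)
        rec = pd.DataFrame({"track_id": tids, "frame": frame})
        rec[comp_names] = comps
        rec["strain_norm"] = norm
        records.append(rec)
    cols = ["track_id", "frame", *comp_names, "strain_norm"]
    data = pd.concat(records, ignore_index=True) if records else pd.DataFrame(columns=cols)
    return MixingProfile(data, kernel_scale=kernel_scale)


def msdd(ts: CellTrackSet, r: float = DEFAULT_R_UM,
         max_lag: float | None = None) -> MsddCurve:
    """Mean squared difference of displacement vectors of initially close pairs.

    For every unordered pair (i, j), let t0 be the *first* time within the
    observation window at which |x_i − x_j| ≤ r (re-contacts never re-seed
    the pair).  From t0 the pair contributes, at every lag t where both
    tracks have data,

        |(x_i(t0+t) − x_i(t0)) − (x_j(t0+t) − x_j(t0))|²

    and m(t) is the average over the n_t contributing pairs.  Restricting to
    initial neighbors and differencing the two displacement vectors removes
    global drift exactly, so m(t) measures relative (mixing) motion only.
    Lags are exact multiples of the frame interval; no interpolation.
    """
    frames = ts.frames
    tids = ts.track_ids
    nT, nF = len(tids), len(frames)
    if nT < 2:
        warnings.warn("fewer than two tracks: empty MSDD", stacklevel=2)
        return MsddCurve(np.array([0.0]), np.array([0.0]), np.array([0]), r)
    fidx = {f: k for k, f in enumerate(frames)}
    tidx = {t: k for k, t in enumerate(tids)}
    dense = np.full((nT, nF, 3), np.nan)
    df = ts.data
    dense[df["track_id"].map(tidx).to_numpy(),
          df["frame"].map(fidx).to_numpy()] = df[["x_um", "y_um", "z_um"]].to_numpy()

    # first-contact frame per pair, vectorized over frames
    keys_all, f0_all = [], []
    for k in range(nF):
        present = np.where(np.isfinite(dense[:, k, 0]))[0]
        if len(present) < 2:
            continue
        pairs = cKDTree(dense[present, k]).query_pairs(r, output_type="ndarray")
        if not len(pairs):
            continue
        a = present[pairs[:, 0]]
        b = present[pairs[:, 1]]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        keys_all.append(lo.astype(np.int64) * nT + hi)
        f0_all.append(np.full(len(lo), k, dtype=np.int64))
    if not keys_all:
        warnings.warn("no cell pair ever within the contact threshold", stacklevel=2)
        return MsddCurve(np.array([0.0]), np.array([0.0]), np.array([0]), r)
    keys = np.concatenate(keys_all)
    f0s = np.concatenate(f0_all)
    order = np.argsort(keys, kind="stable")
    keys, f0s = keys[order], f0s[order]
    first = np.ones(len(keys), dtype=bool)
    first[1:] = keys[1:] != keys[:-1]
    # frames were appended in increasing order; stable sort keeps the earliest
    pair_keys, pair_t0 = keys[first], f0s[first]

    if max_lag is None:
        max_lag_frames = nF - 1
    else:
        max_lag_frames = int(round(max_lag / ts.dt_frame))
    m_sum = np.zeros(max_lag_frames + 1)
    n_t = np.zeros(max_lag_frames + 1, dtype=np.int64)
    for key, k0 in zip(pair_keys, pair_t0):
        i, j = int(key // nT), int(key % nT)
        kend = min(nF, k0 + max_lag_frames + 1)
        disp_i = dense[i, k0:kend] - dense[i, k0]
        disp_j = dense[j, k0:kend] - dense[j, k0]
        d2 = np.sum((disp_i - disp_j) ** 2, axis=1)
        ok = np.isfinite(d2)
        lags = np.nonzero(ok)[0]
        m_sum[lags] += d2[ok]
        n_t[lags] += 1
    with np.errstate(invalid="ignore"):
        m = np.where(n_t > 0, m_sum / np.maximum(n_t, 1), np.nan)
    keep = n_t > 0
    t = np.arange(max_lag_frames + 1) * ts.dt_frame
    return MsddCurve(t[keep], m[keep], n_t[keep], r)


def fit_power_law(curve: MsddCurve, window: tuple[float, float]) -> PowerLawFit:
    """Fit m(t) ∝ t^α on log-log values within a lag window [t_lo, t_hi].

    Nonpositive t or m are dropped with a warning; at least four points must
    remain.  The exponent distinguishes diffusive (α=1), persistent/ballistic
    (α→2) and sub-diffusive (α<1) relative motion.
    """
    t_lo, t_hi = window
    sel = (curve.t >= t_lo) & (curve.t <= t_hi)
    t, m = curve.t[sel], curve.m[sel]
    pos = (t > 0) & (m > 0) & np.isfinite(m)
    if pos.sum() < sel.sum():
        warnings.warn("dropping nonpositive MSDD points from power-law window",
                      stacklevel=2)
    t, m = t[pos], m[pos]
    if len(t) < 4:
        raise ValueError(f"power-law fit needs ≥4 positive points in window, got {len(t)}")
    res = stats.linregress(np.log(t), np.log(m))
    return PowerLawFit(window=(t_lo, t_hi), exponent=float(res.slope),
                       prefactor=float(np.exp(res.intercept)),
                       r_squared=float(res.rvalue ** 2), n_points=len(t))


def population_average_dv(profile: MixingProfile,
                          frames=None) -> pd.DataFrame:
    """Mean ± sd of D_v over cells with a defined value, per frame.

    Cells with no neighbors (NaN D_v) are excluded rather than imputed;
    frames with no defined value are skipped with a warning.
    """
    df = profile.data
    if frames is not None:
        df = df[df["frame"].isin(list(frames))]
    rows = []
    for frame, grp in df.groupby("frame"):
        vals = grp["Dv"].dropna()
        if vals.empty:
            warnings.warn(f"frame {frame}: no defined D_v values, skipped", stacklevel=2)
            continue
        rows.append({"frame": frame, "Dv_mean": vals.mean(),
                     "Dv_sd": vals.std(ddof=0), "n_cells": len(vals)})
    return pd.DataFrame(rows, columns=["frame", "Dv_mean", "Dv_sd", "n_cells"])
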