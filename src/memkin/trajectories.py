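"""Trajectory observables: MSD diffusivity, acyl-chain order, box shrinkage.

Operates on generic particle trajectories (e.g. lipid phosphorus positions)
and C-H bond-vector ensembles:

* ensemble/time-averaged mean-squared displacement with overlapping origins,
* point-lag and linear-fit diffusion estimators D = MSD(tau)/(2 d tau),
* the deuterium order parameter S_CD = <P2(cos a)> with a the angle between
  a bond vector and the bilayer normal (z),
* percent area shrinkage of a simulation box over stated windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MSDCurve:
    lags: np.ndarray  # time units
    msd: np.ndarray
    n_samples: np.ndarray  # displacement pairs per lag
    dt: float
    dimensionality: int


def _positions_array(traj: pd.DataFrame) -> tuple[np.ndarray, int]:
    cols = [c for c in ("x", "y", "z") if c in traj.columns]
    d = len(cols)
    pivot = traj.sort_values(["particle", "frame"])
    n_frames = pivot["frame"].nunique()
    n_particles = pivot["particle"].nunique()
    pos = pivot[cols].to_numpy().reshape(n_particles, n_frames, d)
    return pos, d


def msd(
    traj: pd.DataFrame, lags: np.ndarray | list[int] | None = None, dt: float | None = None
) -> MSDCurve:
    """Mean-squared displacement averaged over particles and all time
    origins (overlapping windows); per-lag sample counts are returned so a
    non-overlapping average can be recomputed.

    ``lags`` are frame counts; lags at or beyond the trajectory length are
    skipped with a warning.
    """
    pos, d = _positions_array(traj)
    n_frames = pos.shape[1]
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if dt is None:
        dt = float(traj.attrs.get("dt", 1.0))
    if lags is None:
        lags = np.unique(np.round(np.logspace(0, np.log10(n_frames - 1), 30)).astype(int))
    lags = np.asarray(lags, dtype=int)
    good = lags[(lags >= 1) & (lags < n_frames)]
    if good.size < lags.size:
        warnings.warn("dropping lags >= trajectory length")
    out = np.empty(good.size)
    n_samp = np.empty(good.size, dtype=int)
    for i, lag in enumerate(good):
        disp = pos[:, lag:, :] - pos[:, :-lag, :]
        sq = np.sum(disp**2, axis=-1)
        out[i] = sq.mean()
        n_samp[i] = sq.size
    return MSDCurve(lags=good * dt, msd=out, n_samples=n_samp, dt=dt, dimensionality=d)


def diffusivity_from_msd(
    curve: MSDCurve,
    lag: float | None = None,
    dimensionality: int | None = None,
    method: str = "point",
    fit_range: tuple[float, float] | None = None,
) -> float:
    """Diffusion coefficient from an MSD curve.

    point: D = MSD(lag) / (2 d lag) at a single stated lag.
    fit:   D = slope/(2 d) of a least-squares line through the origin over
           ``fit_range`` (defaults to the whole curve).

    Also emits a log-log slope diagnostic: slopes far from 1 indicate
    subdiffusion/poor sampling, and the point estimate then depends on the
    chosen lag.
    """
    d = dimensionality or curve.dimensionality
    if method == "point":
        if lag is None:
            raise ValueError("point estimator needs a lag")
        if lag <= 0:
            raise ValueError("lag must be positive")
        idx = int(np.argmin(np.abs(curve.lags - lag)))
        if not np.isclose(curve.lags[idx], lag, rtol=1e-6):
            raise ValueError(f"lag {lag} not present in the curve")
        return float(curve.msd[idx] / (2.0 * d * lag))
    if method == "fit":
        sel = np.ones(curve.lags.size, dtype=bool)
        if fit_range is not None:
            sel = (curve.lags >= fit_range[0]) & (curve.lags <= fit_range[1])
        x, y = curve.lags[sel], curve.msd[sel]
        if x.size < 2:
            raise ValueError("fit range contains fewer than 2 lags")
        slope = float(np.dot(x, y) / np.dot(x, x))  # through the origin
        loglog = np.polyfit(np.log(x), np.log(np.maximum(y, 1e-300)), 1)[0]
        if not 0.8 <= loglog <= 1.2:
            warnings.warn(
                f"log-log MSD slope {loglog:.2f} departs from 1: "
                "anomalous diffusion or poor sampling"
            )
        return slope / (2.0 * d)
    raise ValueError(f"unknown method: {method}")


def order_parameter_scd(
    vectors: np.ndarray,
    carbon_index: np.ndarray | None = None,
    axis: np.ndarray = np.array([0.0, 0.0, 1.0]),
) -> pd.DataFrame:
    """S_CD = <P2(cos a)> per carbon, a = angle between bond and the axis.

    ``vectors`` is (n, 3); zero-length vectors raise.  Without carbon
    indices all vectors pool into carbon 0.  Values lie in [-0.5, 1]:
    1 parallel, 0 isotropic, -0.5 perpendicular.  Reported as raw <P2>
    (no sign flip or absolute value), with the ensemble sd of P2 per carbon.
    """
    v = np.asarray(vectors, dtype=np.float64)
    if v.ndim != 2 or v.shape[1] != 3:
        raise ValueError("vectors must be (n, 3)")
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length bond vector")
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    cos_a = v @ axis / norms
    p2 = 0.5 * (3.0 * cos_a**2 - 1.0)
    if carbon_index is None:
        carbon_index = np.zeros(v.shape[0], dtype=int)
    df = pd.DataFrame({"carbon": np.asarray(carbon_index, dtype=int), "p2": p2})
    out = df.groupby("carbon")["p2"].agg(["mean", "std", "count"]).reset_index()
    out.columns = ["carbon", "S_CD", "sd", "n"]
    return out


def pool_chains(profiles: list[pd.DataFrame]) -> pd.DataFrame:
    """Average S_CD profiles across chains (e.g. sn-1 and sn-2), weighting
    each carbon by its sample count."""
    allp = pd.concat(profiles, ignore_index=True)
    def _agg(g):
        w = g["n"].to_numpy(dtype=float)
        return pd.Series(
            {
                "S_CD": np.average(g["S_CD"], weights=w),
                "sd": np.sqrt(np.average(g["sd"] ** 2, weights=w)),
                "n": int(w.sum()),
            }
        )
    return allp.groupby("carbon").apply(_agg, include_groups=False).reset_index()


def box_shrinkage(
    dims: np.ndarray,
    windows: list[tuple[int, int, int, int]] | None = None,
    edge_frames: int = 1,
) -> dict:
    """Percent area change of a (frame, 2) box-dimension series.

    Area = x * y per frame.  Per window (s0, s1, e0, e1):
    100 * (1 - <A[e0:e1]>/<A[s0:s1]>), start/end means over frame ranges.
    Positive values are shrinkage; expansion is negative.  Without explicit
    windows, one window spanning the whole series (edge means over
    ``edge_frames`` frames) is used.  The cumulative change across windows
    is the compounded product.
    """
    dims = np.asarray(dims, dtype=np.float64)
    if dims.ndim != 2 or dims.shape[1] != 2:
        raise ValueError("dims must be (frame, 2)")
    area = dims[:, 0] * dims[:, 1]
    n = area.size
    if windows is None:
        windows = [(0, edge_frames, n - edge_frames, n)]
    pct = []
    for s0, s1, e0, e1 in windows:
        if s1 - s0 < 1 or e1 - e0 < 1:
            raise ValueError("each window edge needs >= 1 frame")
        a0 = area[s0:s1].mean()
        a1 = area[e0:e1].mean()
        if a0 <= 0:
            raise ValueError("zero start area")
        pct.append(100.0 * (1.0 - a1 / a0))
    retained = np.prod([1.0 - p / 100.0 for p in pct])
    return {
        "window_pct": np.asarray(pct),
        "cumulative_pct": 100.0 * (1.0 - retained),
    }
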