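"""Synthetic data with known ground truth for every analysis modality.

The generators emulate the experimental inputs of the study system —
annexin-V (A5) 2D-lattices ordering a DOPC/DOPS membrane — with parameters
that reproduce the experimental conditions:

* three-level HS-AFM height movies (mica 0 nm, membrane 3.15 nm, A5-covered
  6.1 nm) whose lattice border performs a per-angular-bin birth-death jump
  process in 8.85 nm radial steps (half a lattice unit cell);
* scripted membrane-patch movies (growth, fusion, shrinkage, A5 aggregates);
* two-channel FRAP series: a lipid channel recovering by exact 2-D free
  diffusion of a Gaussian bleach profile, and an immobile A5 channel;
* two/three-channel GUV equatorial ring images with exactly known
  generalized polarization (GP) and ring radius;
* 2-D/3-D Brownian trajectories and axially distributed bond-vector sets
  with numerically exact orientational order.

Every generator takes a seed, uses a single numpy Generator, and returns a
GroundTruthLog recording the seed, the parameters, and every latent quantity
a downstream test needs.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import integrate

from memkin.border_kinetics import AFMMovie


@dataclass
class GroundTruthLog:
    """Seed, parameters, and latent ground truth of one generator run."""

    kind: str
    seed: int | None
    params: dict[str, Any]
    data: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Any:
        return self.data[key]


def _params_dict(p) -> dict[str, Any]:
    d = dataclasses.asdict(p)
    return {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}


# ---------------------------------------------------------------------------
# AFM lattice-border movies
# ---------------------------------------------------------------------------

@dataclass
class LatticeSimParams:
    """Parameters of the lattice-border jump-process movie.

    Rates are per angular bin; heights in nm; the border of each bin
    performs exponential-waiting-time +/- step_length jumps reflected at 0
    and patch_radius (a jump that would leave the range is suppressed by
    zeroing the corresponding rate while at the boundary).
    """

    grid_size_px: tuple[int, int] = (256, 256)
    pixel_size: float = 2.0  # nm/px
    frame_interval: float = 0.3  # s
    n_frames: int = 100
    n_theta: int = 64
    k_assoc: float = 2.3  # 1/s per angular bin
    k_dissoc: float = 2.0  # 1/s per angular bin
    step_length: float = 8.85  # nm
    h_mica: float = 0.0
    h_membrane: float = 3.15
    h_lattice: float = 6.1
    noise_sd: float = 0.1  # nm
    patch_radius: float = 180.0  # nm
    init_lattice_radius: float = 90.0  # nm
    seed: int | None = None

    def validate(self) -> None:
        if min(self.grid_size_px) <= 0:
            raise ValueError("grid_size_px must be positive")
        if self.pixel_size <= 0 or self.frame_interval <= 0 or self.n_frames < 1:
            raise ValueError("pixel_size, frame_interval, n_frames must be positive")
        if self.n_theta < 1:
            raise ValueError("n_theta must be >= 1")
        if self.k_assoc < 0 or self.k_dissoc < 0:
            raise ValueError("rates must be non-negative")
        if self.step_length <= 0:
            raise ValueError("step_length must be positive")
        if not self.h_mica < self.h_membrane < self.h_lattice:
            raise ValueError("need h_mica < h_membrane < h_lattice")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.init_lattice_radius <= self.patch_radius:
            raise ValueError("init_lattice_radius must lie inside the patch")
        if (self.k_assoc + self.k_dissoc) * self.frame_interval > 1.0:
            warnings.warn(
                "more than one expected border event per bin per frame: "
                "frame-sampled kinetics will miss events",
                stacklevel=3,
            )


def _simulate_border(params: LatticeSimParams, rng: np.random.Generator):
    """Gillespie simulation of each bin's border radius; returns
    (radii[n_frames, n_theta] sampled at frame times, event arrays)."""
    n_f, n_b = params.n_frames, params.n_theta
    dt, step = params.frame_interval, params.step_length
    t_end = n_f * dt
    radii = np.empty((n_f, n_b))
    ev_t: list[float] = []
    ev_bin: list[int] = []
    ev_dir: list[int] = []
    for b in range(n_b):
        r = params.init_lattice_radius
        t = 0.0
        nxt = 0
        while nxt < n_f:
            up = params.k_assoc if r + step <= params.patch_radius else 0.0
            down = params.k_dissoc if r - step >= 0.0 else 0.0
            k_tot = up + down
            t_event = t + rng.exponential(1.0 / k_tot) if k_tot > 0 else math.inf
            while nxt < n_f and nxt * dt < t_event:
                radii[nxt, b] = r
                nxt += 1
            if t_event >= t_end:
                break
            if rng.random() < up / k_tot:
                r += step
                ev_dir.append(+1)
            else:
                r -= step
                ev_dir.append(-1)
            ev_t.append(t_event)
            ev_bin.append(b)
            t = t_event
    return radii, np.array(ev_t), np.array(ev_bin, dtype=int), np.array(ev_dir, dtype=int)


def _render_lattice_frames(params: LatticeSimParams, radii: np.ndarray):
    """Render the three-level height stack and the ground-truth label stack."""
    nrow, ncol = params.grid_size_px
    center = ((nrow - 1) / 2.0, (ncol - 1) / 2.0)
    rows = (np.arange(nrow)[:, None] - center[0])
    cols = (np.arange(ncol)[None, :] - center[1])
    ang = np.degrees(np.arctan2(-rows, cols)) % 360.0
    bin_idx = np.minimum(
        (ang / (360.0 / params.n_theta)).astype(np.intp), params.n_theta - 1
    )
    dist = np.hypot(rows, cols) * params.pixel_size
    membrane = dist <= params.patch_radius
    labels = np.empty((params.n_frames,) + membrane.shape, dtype=np.int8)
    heights = np.empty((params.n_frames,) + membrane.shape, dtype=np.float64)
    for f in range(params.n_frames):
        lattice = dist <= radii[f][bin_idx]
        lab = np.zeros(membrane.shape, dtype=np.int8)
        lab[membrane] = 1
        lab[lattice & membrane] = 2
        labels[f] = lab
        heights[f] = np.choose(lab, (params.h_mica, params.h_membrane, params.h_lattice))
    return heights, labels, center


def render_lattice_movie(
    params: LatticeSimParams, radii_nm: np.ndarray, noise: bool = True
) -> AFMMovie:
    """Render an arbitrary scripted border-radius array (frame, theta_bin)
    as a three-level height movie; useful for hand-built border scenarios."""
    params.validate()
    radii_nm = np.asarray(radii_nm, dtype=np.float64)
    if radii_nm.shape != (params.n_frames, params.n_theta):
        raise ValueError("radii_nm must be (n_frames, n_theta)")
    heights, _, _ = _render_lattice_frames(params, radii_nm)
    if noise and params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        heights = heights + rng.normal(0.0, params.noise_sd, size=heights.shape)
    return AFMMovie(heights, params.pixel_size, params.frame_interval)


def generate_afm_lattice_movie(
    params: LatticeSimParams,
) -> tuple[AFMMovie, GroundTruthLog]:
    """Height-map movie of a lattice whose border radius jumps by +/- one
    trimer step per angular bin, plus a log of every event.

    The log records (t, bin, direction) for every event, the true border
    radius per (frame, bin) sampled at frame times, the ground-truth label
    stack (0 mica / 1 membrane / 2 lattice), and the render center.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    radii, ev_t, ev_bin, ev_dir = _simulate_border(params, rng)
    heights, labels, center = _render_lattice_frames(params, radii)
    if params.noise_sd > 0:
        heights = heights + rng.normal(0.0, params.noise_sd, size=heights.shape)
    movie = AFMMovie(
        heights=heights,
        pixel_size=params.pixel_size,
        frame_interval=params.frame_interval,
    )
    log = GroundTruthLog(
        kind="afm_lattice_movie",
        seed=params.seed,
        params=_params_dict(params),
        data={
            "events_t": ev_t,
            "events_bin": ev_bin,
            "events_dir": ev_dir,
            "radii_nm": radii,
            "labels": labels,
            "center_px": center,
            "k_assoc": params.k_assoc,
            "k_dissoc": params.k_dissoc,
        },
    )
    return movie, log


# ---------------------------------------------------------------------------
# scripted membrane-patch movies
# ---------------------------------------------------------------------------

@dataclass
class PatchScript:
    """One scripted disk: per-frame center (nm, image row/col axes) and
    radius (nm). Arrays must have one entry per frame; radius 0 hides the
    disk in that frame."""

    centers_nm: np.ndarray  # (n_frames, 2)
    radii_nm: np.ndarray  # (n_frames,)
    level: str = "membrane"  # "membrane" or "lattice"


@dataclass
class MembranePatchParams:
    grid_size_px: tuple[int, int] = (256, 256)
    pixel_size: float = 2.0
    frame_interval: float = 1.0
    n_frames: int = 10
    h_mica: float = 0.0
    h_membrane: float = 3.15
    h_lattice: float = 6.1
    noise_sd: float = 0.1
    patches: list[PatchScript] = field(default_factory=list)
    seed: int | None = None


def generate_membrane_patch_movie(
    params: MembranePatchParams,
) -> tuple[AFMMovie, GroundTruthLog]:
    """Render scripted membrane patches and A5 aggregates as height levels.

    Overlapping scripted disks of the same level merge into one region (the
    union of their masks); the log stores, per frame, the true membrane area
    (nm^2, from the rendered union mask), the A5 coverage fraction, the
    number of A5 components, and the membrane mass center (nm).
    """
    if not params.patches:
        raise ValueError("at least one PatchScript is required")
    rng = np.random.default_rng(params.seed)
    nrow, ncol = params.grid_size_px
    rows = np.arange(nrow)[:, None] * params.pixel_size
    cols = np.arange(ncol)[None, :] * params.pixel_size

    from skimage import measure

    heights = np.empty((params.n_frames, nrow, ncol))
    area = np.empty(params.n_frames)
    coverage = np.empty(params.n_frames)
    n_agg = np.empty(params.n_frames, dtype=int)
    mass_center = np.empty((params.n_frames, 2))
    labels = np.empty((params.n_frames, nrow, ncol), dtype=np.int8)
    for f in range(params.n_frames):
        mem = np.zeros((nrow, ncol), dtype=bool)
        lat = np.zeros((nrow, ncol), dtype=bool)
        for p in params.patches:
            r = float(p.radii_nm[f])
            if r <= 0:
                continue
            cy, cx = p.centers_nm[f]
            disk = (rows - cy) ** 2 + (cols - cx) ** 2 <= r**2
            if p.level == "lattice":
                lat |= disk
            else:
                mem |= disk
        mem |= lat  # lattice sits on membrane
        lab = np.zeros((nrow, ncol), dtype=np.int8)
        lab[mem] = 1
        lab[lat] = 2
        labels[f] = lab
        heights[f] = np.choose(lab, (params.h_mica, params.h_membrane, params.h_lattice))
        px2 = params.pixel_size**2
        area[f] = mem.sum() * px2
        coverage[f] = lat.sum() / mem.sum() if mem.any() else 0.0
        n_agg[f] = int(measure.label(lat, connectivity=2).max()) if lat.any() else 0
        if mem.any():
            rr, cc = np.nonzero(mem)
            mass_center[f] = (rr.mean() * params.pixel_size, cc.mean() * params.pixel_size)
        else:
            mass_center[f] = (np.nan, np.nan)
    if params.noise_sd > 0:
        heights = heights + rng.normal(0.0, params.noise_sd, size=heights.shape)
    movie = AFMMovie(heights, params.pixel_size, params.frame_interval)
    log = GroundTruthLog(
        kind="membrane_patch_movie",
        seed=params.seed,
        params={"n_frames": params.n_frames, "pixel_size": params.pixel_size},
        data={
            "area_nm2": area,
            "coverage": coverage,
            "aggregate_count": n_agg,
            "mass_center_nm": mass_center,
            "labels": labels,
        },
    )
    return movie, log


# ---------------------------------------------------------------------------
# FRAP series
# ---------------------------------------------------------------------------

@dataclass
class FRAPSimParams:
    """Two-channel FRAP movie parameters.

    The bleach is an instantaneous Gaussian dip of 1/e^2 radius
    ``r_effective`` (profile 1 - K exp(-2 rho^2 / r_e^2)) centered in a
    nominal circular ROI of radius ``r_nominal``; the lipid channel then
    recovers by exact 2-D free diffusion (Gaussian variance grows as
    2 D t per axis), scaled by the mobile fraction, while the A5 channel
    keeps the frozen bleach profile.
    """

    D_true: float = 2.6  # um^2/s
    r_nominal: float = 1.0  # um
    r_effective: float = 2.0  # um
    frame_interval: float = 0.1  # s
    n_prebleach: int = 10
    n_postbleach: int = 300
    immobile_fraction: float = 0.0
    bleach_depth: float = 0.8
    noise_sd: float = 0.01  # relative to the pre-bleach level
    field_size: tuple[float, float] = (20.0, 20.0)  # um
    pixel_size: float = 0.1  # um/px
    seed: int | None = None

    def validate(self) -> None:
        if self.D_true < 0:
            raise ValueError("D_true must be non-negative")
        if not 0 < self.r_nominal <= self.r_effective:
            raise ValueError("need r_effective >= r_nominal > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not 0 <= self.immobile_fraction <= 1:
            raise ValueError("immobile_fraction must be in [0, 1]")
        if not 0 < self.bleach_depth <= 1:
            raise ValueError("bleach_depth must be in (0, 1]")
        if self.r_effective > min(self.field_size) / 2:
            raise ValueError("r_effective exceeds half the field")
        if self.n_prebleach < 1 or self.n_postbleach < 2:
            raise ValueError("need at least 1 pre- and 2 post-bleach frames")


@dataclass
class FluorescenceSeries:
    """Two-channel fluorescence stack with bleach bookkeeping."""

    lipid: np.ndarray  # (frame, row, col)
    a5: np.ndarray
    pixel_size: float  # um/px
    frame_interval: float  # s
    bleach_frame: int  # index of the first post-bleach frame
    center_px: tuple[float, float] = (0.0, 0.0)


def frap_recovery_curve_analytic(
    t: np.ndarray,
    D: float,
    r_nominal: float,
    r_effective: float,
    bleach_depth: float,
    immobile_fraction: float = 0.0,
) -> np.ndarray:
    """Mean normalized intensity in the nominal ROI at times t after an
    instantaneous Gaussian bleach, under free 2-D diffusion.

    Closed form of the disk average of the evolving Gaussian dip with
    initial variance sigma0^2 = r_e^2/4 and sigma^2(t) = sigma0^2 + 2 D t.
    """
    t = np.asarray(t, dtype=np.float64)
    s0 = r_effective**2 / 4.0
    st = s0 + 2.0 * D * t
    dip = (2.0 * s0 / r_nominal**2) * (1.0 - np.exp(-(r_nominal**2) / (2.0 * st)))
    dip0 = (2.0 * s0 / r_nominal**2) * (1.0 - np.exp(-(r_nominal**2) / (2.0 * s0)))
    mobile = 1.0 - immobile_fraction
    return 1.0 - bleach_depth * (immobile_fraction * dip0 + mobile * dip)


def generate_frap_series(
    params: FRAPSimParams,
) -> tuple[FluorescenceSeries, GroundTruthLog]:
    """Two-channel FRAP stack plus ground truth (analytic ROI curve, radii)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    nrow = int(round(params.field_size[0] / params.pixel_size))
    ncol = int(round(params.field_size[1] / params.pixel_size))
    center = ((nrow - 1) / 2.0, (ncol - 1) / 2.0)
    rows = (np.arange(nrow)[:, None] - center[0]) * params.pixel_size
    cols = (np.arange(ncol)[None, :] - center[1]) * params.pixel_size
    rho2 = rows**2 + cols**2

    s0 = params.r_effective**2 / 4.0
    dip0 = np.exp(-rho2 / (2.0 * s0))
    n_total = params.n_prebleach + params.n_postbleach
    lipid = np.ones((n_total, nrow, ncol))
    a5 = np.ones((n_total, nrow, ncol))
    K = params.bleach_depth
    mobile = 1.0 - params.immobile_fraction
    for j in range(params.n_postbleach):
        t = j * params.frame_interval
        st = s0 + 2.0 * params.D_true * t
        evolved = (s0 / st) * np.exp(-rho2 / (2.0 * st))
        f = params.n_prebleach + j
        lipid[f] = 1.0 - K * (params.immobile_fraction * dip0 + mobile * evolved)
        a5[f] = 1.0 - K * dip0
    if params.noise_sd > 0:
        lipid = lipid + rng.normal(0.0, params.noise_sd, size=lipid.shape)
        a5 = a5 + rng.normal(0.0, params.noise_sd, size=a5.shape)

    t_post = np.arange(params.n_postbleach) * params.frame_interval
    log = GroundTruthLog(
        kind="frap_series",
        seed=params.seed,
        params=_params_dict(params),
        data={
            "D_true": params.D_true,
            "r_nominal": params.r_nominal,
            "r_effective": params.r_effective,
            "bleach_depth": K,
            "bleach_frame": params.n_prebleach,
            "center_px": center,
            "t_post": t_post,
            "roi_curve_analytic": frap_recovery_curve_analytic(
                t_post,
                params.D_true,
                params.r_nominal,
                params.r_effective,
                K,
                params.immobile_fraction,
            ),
        },
    )
    series = FluorescenceSeries(
        lipid=lipid,
        a5=a5,
        pixel_size=params.pixel_size,
        frame_interval=params.frame_interval,
        bleach_frame=params.n_prebleach,
        center_px=center,
    )
    return series, log


# ---------------------------------------------------------------------------
# GUV ring images
# ---------------------------------------------------------------------------

@dataclass
class GUVSimParams:
    """Equatorial-plane GUV ring images with exactly known GP.

    The total Laurdan signal T = I_ch1 + G * I_ch2 follows a Gaussian ring
    cross-section of sigma ``ring_width`` about ``ring_radius``; channels are
    split as I_ch1 = T (1 + gp)/2 and I_ch2 = T (1 - gp)/(2 G), so the GP
    equation with the configured G returns gp_true exactly at every pixel
    before noise.
    """

    gp_true: float = 0.0
    g_factor: float = 1.0 / 3.0
    ring_radius: float = 3.15  # um
    ring_width: float = 0.15  # um (Gaussian sigma)
    intensity_total: float = 1000.0  # peak counts of T
    noise_model: str = "gaussian"  # or "poisson"
    noise_sd: float = 0.01  # fraction of peak, gaussian model only
    pixel_size: float = 0.05  # um/px
    diameter_series: list[float] | None = None  # um per frame
    gp_series: list[float] | None = None
    a5_series: list[float] | None = None  # relative ch3 ring amplitude per frame
    background: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if not -1.0 <= self.gp_true <= 1.0:
            raise ValueError("gp_true must be in [-1, 1]")
        if self.g_factor <= 0:
            raise ValueError("g_factor must be positive")
        if not 0 < self.ring_width < self.ring_radius:
            raise ValueError("need 0 < ring_width < ring_radius")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be gaussian or poisson")
        if self.gp_series is not None and any(abs(g) > 1 for g in self.gp_series):
            raise ValueError("gp_series values must be in [-1, 1]")


@dataclass
class TwoChannelImageSeries:
    ch1: np.ndarray  # (frame, row, col)
    ch2: np.ndarray
    ch3: np.ndarray | None
    pixel_size: float  # um/px


def generate_guv_images(
    params: GUVSimParams,
) -> tuple[TwoChannelImageSeries, GroundTruthLog]:
    """Render GUV equatorial rings; per-frame GP/diameter follow the
    optional series (single frame with scalar values otherwise)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    diam = params.diameter_series or [2.0 * params.ring_radius]
    n_frames = len(diam)
    gps = params.gp_series or [params.gp_true] * n_frames
    if len(gps) != n_frames:
        raise ValueError("gp_series and diameter_series lengths differ")
    r_max = max(diam) / 2.0
    half = r_max + 8.0 * params.ring_width
    n_px = int(round(2.0 * half / params.pixel_size)) | 1  # odd: centered pixel
    center = (n_px - 1) / 2.0
    ax = (np.arange(n_px) - center) * params.pixel_size
    rho = np.hypot(ax[:, None], ax[None, :])

    ch1 = np.empty((n_frames, n_px, n_px))
    ch2 = np.empty_like(ch1)
    ch3 = np.empty_like(ch1) if params.a5_series is not None else None
    sums = np.empty((n_frames, 2))
    for f in range(n_frames):
        ring = params.intensity_total * np.exp(
            -((rho - diam[f] / 2.0) ** 2) / (2.0 * params.ring_width**2)
        )
        total = ring + params.background
        i1 = total * (1.0 + gps[f]) / 2.0
        i2 = total * (1.0 - gps[f]) / (2.0 * params.g_factor)
        if params.noise_model == "poisson":
            i1 = rng.poisson(i1).astype(float)
            i2 = rng.poisson(i2).astype(float)
        else:
            sd = params.noise_sd * params.intensity_total
            i1 = i1 + rng.normal(0.0, sd, size=i1.shape)
            i2 = i2 + rng.normal(0.0, sd, size=i2.shape)
        ch1[f], ch2[f] = i1, i2
        sums[f] = (i1.sum(), i2.sum())
        if ch3 is not None:
            amp = params.a5_series[f] * params.intensity_total
            ch3[f] = amp * np.exp(
                -((rho - diam[f] / 2.0) ** 2) / (2.0 * params.ring_width**2)
            ) + params.background
    log = GroundTruthLog(
        kind="guv_images",
        seed=params.seed,
        params=_params_dict(params),
        data={
            "gp_true": np.asarray(gps),
            "diameter_um": np.asarray(diam),
            "g_factor": params.g_factor,
            "channel_sums": sums,
            "center_px": (center, center),
            "split": "I1 = T(1+gp)/2, I2 = T(1-gp)/(2G), T = ring profile",
        },
    )
    return TwoChannelImageSeries(ch1, ch2, ch3, params.pixel_size), log


# ---------------------------------------------------------------------------
# trajectories and bond vectors
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySimParams:
    """Brownian-walk and bond-vector ensemble parameters.

    order_concentration kappa >= 0 parameterizes the axial (Watson-type)
    orientation density p(cos a) ~ exp(kappa cos^2 a): kappa = 0 is
    isotropic (S = 0), kappa -> inf aligns all vectors with z (S = 1).
    """

    D_true: float = 1.0  # um^2/s
    n_particles: int = 100
    n_steps: int = 500
    dt: float = 1.0
    dimensionality: int = 2
    order_concentration: float = 0.0
    n_vectors: int = 10000
    seed: int | None = None

    def validate(self) -> None:
        if self.D_true < 0:
            raise ValueError("D_true must be non-negative")
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        if self.n_particles < 1 or self.n_steps < 1 or self.dt <= 0:
            raise ValueError("n_particles, n_steps, dt must be positive")
        if self.order_concentration < 0:
            raise ValueError("order_concentration must be non-negative")


def generate_brownian_trajectories(params: TrajectorySimParams) -> pd.DataFrame:
    """Independent Gaussian random walks, per-step variance 2 D dt per axis.

    Returns a tidy table (particle, frame, x, y[, z]); coordinates share the
    units implied by D_true and dt.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    d = params.dimensionality
    sd = math.sqrt(2.0 * params.D_true * params.dt)
    steps = rng.normal(0.0, sd, size=(params.n_particles, params.n_steps, d))
    pos = np.concatenate(
        [np.zeros((params.n_particles, 1, d)), np.cumsum(steps, axis=1)], axis=1
    )
    n_frames = params.n_steps + 1
    cols = ["x", "y", "z"][:d]
    df = pd.DataFrame(
        pos.reshape(-1, d),
        columns=cols,
    )
    df.insert(0, "frame", np.tile(np.arange(n_frames), params.n_particles))
    df.insert(0, "particle", np.repeat(np.arange(params.n_particles), n_frames))
    df.attrs["dt"] = params.dt
    df.attrs["D_true"] = params.D_true
    df.attrs["dimensionality"] = d
    return df


def watson_order_parameter(kappa: float) -> float:
    """Exact <P2(cos a)> of the axial density p(u) ~ exp(kappa u^2), u = cos a.

    Evaluated by numerical quadrature; kappa = 0 gives 0 and the large-kappa
    limit tends to 1.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 0:
        return 0.0
    # factor exp(-kappa) for numerical stability at large kappa
    num, _ = integrate.quad(
        lambda u: 0.5 * (3 * u * u - 1) * math.exp(kappa * (u * u - 1)), 0, 1
    )
    den, _ = integrate.quad(lambda u: math.exp(kappa * (u * u - 1)), 0, 1)
    return num / den


def generate_bond_vectors(
    params: TrajectorySimParams, carbon_index: int | None = None
) -> tuple[np.ndarray, GroundTruthLog]:
    """Unit vectors from an axially symmetric distribution about z.

    cos(a) is sampled by inverse-CDF lookup of the Watson-type density
    p(u) ~ exp(kappa u^2) on [-1, 1]; the azimuth is uniform.  The log
    stores the numerically exact ground-truth order parameter.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    kappa = params.order_concentration
    n = params.n_vectors
    if kappa == 0:
        u = rng.uniform(-1.0, 1.0, size=n)
    else:
        grid = np.linspace(-1.0, 1.0, 4001)
        pdf = np.exp(kappa * (grid**2 - 1.0))
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2.0)])
        cdf /= cdf[-1]
        u = np.interp(rng.uniform(0.0, 1.0, size=n), cdf, grid)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    s = np.sqrt(np.clip(1.0 - u**2, 0.0, None))
    vectors = np.column_stack([s * np.cos(phi), s * np.sin(phi), u])
    log = GroundTruthLog(
        kind="bond_vectors",
        seed=params.seed,
        params=_params_dict(params),
        data={
            "S_true": watson_order_parameter(kappa),
            "carbon_index": carbon_index,
        },
    )
    return vectors, log
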