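"""Lattice-border kinetics from HS-AFM height movies.

A finite annexin-V (A5) 2D-lattice on a supported membrane patch has a
dynamic border: trimers associate and dissociate in radial steps of half a
unit cell (8.85 nm).  This module implements the full analysis chain from a
calibrated height movie to rate constants and an energy diagram:

1. three-level segmentation (mica / membrane / lattice),
2. polar projection of the lattice border about a fixed reference center,
3. kymographs r(t) at fixed angle,
4. step idealization of kymographs,
5. dwell-time extraction and exponential rate fitting (k_a, k_d, K_eq),
6. radius-change occurrence histograms and their Boltzmann inversion
   dG = -k_B T ln N (zero level at single-count occupancy, so positions
   never visited sit at the zero-energy reference).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage import measure

MICA, MEMBRANE, LATTICE, BACKGROUND = 0, 1, 2, -1


@dataclass
class AFMMovie:
    """Calibrated height-map time series.

    heights : (frame, row, col) array in nm relative to the mica plane.
    pixel_size : nm per pixel.
    frame_interval : seconds per frame.
    """

    heights: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.heights.ndim != 3:
            raise ValueError("heights must be (frame, row, col)")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.heights.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class BorderTrace:
    """Lattice-border radius r(theta, t) about a fixed center.

    theta_bins : bin centers in degrees, [0, 360).
    radii : (frame, bin) array in nm.
    center : (row, col) reference point in px, fixed across frames.
    """

    theta_bins: np.ndarray
    radii: np.ndarray
    center: tuple[float, float]
    frame_interval: float
    empty_bin_flags: np.ndarray | None = None
    lost_frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta_bins = np.asarray(self.theta_bins, dtype=np.float64)
        self.radii = np.asarray(self.radii, dtype=np.float64)
        if self.radii.ndim != 2 or self.radii.shape[1] != self.theta_bins.size:
            raise ValueError("radii must be (frame, theta_bin)")
        if np.any(self.radii < 0):
            raise ValueError("radii must be non-negative")


@dataclass
class Kymograph:
    """(t, r) series of the border radius at one angle."""

    theta_deg: float
    theta_bin: int
    times: np.ndarray
    radii: np.ndarray
    frame_interval: float


@dataclass
class StepTrace:
    """Idealized step trace: contiguous constant-level segments.

    Segments are (start_frame, end_frame, level_nm) with inclusive frame
    bounds; levels are integer multiples of step_length relative to the
    initial level.
    """

    theta_bin: int
    segments: list[tuple[int, int, float]]
    step_length: float
    low_confidence: bool = False

    @property
    def levels(self) -> np.ndarray:
        return np.array([s[2] for s in self.segments])


@dataclass
class RateEstimate:
    """Fitted association/dissociation rate constants at the lattice border."""

    k_assoc: float
    k_dissoc: float
    n_events_assoc: int
    n_events_dissoc: int
    fit_method: str
    confidence_assoc: tuple[float, float]
    confidence_dissoc: tuple[float, float]

    @property
    def K_eq(self) -> float:
        return equilibrium_constant(self.k_assoc, self.k_dissoc)


@dataclass
class OccurrenceHistogram:
    """Counts of border-radius changes Delta r on a step_length grid."""

    delta_r_steps: np.ndarray  # signed integer multiples of step_length
    counts: np.ndarray
    step_length: float
    lag_frames: int
    total: int


@dataclass
class EnergyProfile:
    """Boltzmann-inverted occurrence histogram, in k_B T.

    delta_G = -ln N; finite where N >= 1, zero at N = 1 (i.e. the zero of
    energy sits at single-occupancy, matching the convention that positions
    without occurrence define the zero level).
    """

    delta_r_steps: np.ndarray
    counts: np.ndarray
    delta_G: np.ndarray  # NaN where N == 0
    step_length: float
    local_minima: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# segmentation and polar projection
# ---------------------------------------------------------------------------

def segment_levels(
    frame: np.ndarray,
    level_centers: tuple[float, float, float],
    tolerance: float | None = None,
) -> np.ndarray:
    """Assign each pixel to the nearest height level.

    Returns an int mask with values MICA(0)/MEMBRANE(1)/LATTICE(2) and
    BACKGROUND(-1) for pixels farther than ``tolerance`` from every level.
    Only the largest connected lattice component is kept as lattice; smaller
    lattice fragments are relabeled membrane.
    """
    frame = np.asarray(frame, dtype=np.float64)
    centers = np.asarray(level_centers, dtype=np.float64)
    if centers.size != 3 or np.any(np.diff(centers) <= 0):
        raise ValueError("level_centers must be 3 strictly increasing values")
    dist = np.abs(frame[..., None] - centers[None, None, :])
    labels = np.argmin(dist, axis=-1).astype(np.int8)
    if tolerance is not None:
        labels[np.min(dist, axis=-1) > tolerance] = BACKGROUND
    lattice = labels == LATTICE
    if lattice.any():
        comp = measure.label(lattice, connectivity=2)
        sizes = np.bincount(comp.ravel())
        sizes[0] = 0
        keep = np.argmax(sizes)
        labels[lattice & (comp != keep)] = MEMBRANE
    return labels


def _lattice_mask(frame, level_centers, tolerance):
    return segment_levels(frame, level_centers, tolerance) == LATTICE


def extract_border_polar(
    movie: AFMMovie,
    n_theta: int = 120,
    level_centers: tuple[float, float, float] = (0.0, 3.15, 6.1),
    tolerance: float | None = None,
) -> BorderTrace:
    """Project the lattice border into polar coordinates r(theta, t).

    The reference center is the mass center of the lattice mask in frame 0
    and is held fixed for all frames.  Per frame and angular bin, the radius
    is the distance (nm) to the outermost lattice pixel whose angle falls in
    the bin.  Empty bins carry the last observed value and are flagged;
    frames with no lattice at all get radius 0 and a lost-frame flag.
    Angles are measured counterclockwise from the +x (column) axis.
    """
    if n_theta < 1:
        raise ValueError("n_theta must be >= 1")
    mask0 = _lattice_mask(movie.heights[0], level_centers, tolerance)
    if not mask0.any():
        raise ValueError("no lattice detectable in frame 0")
    rr, cc = np.nonzero(mask0)
    center = (float(rr.mean()), float(cc.mean()))

    n_frames = movie.n_frames
    radii = np.zeros((n_frames, n_theta))
    empty = np.zeros((n_frames, n_theta), dtype=bool)
    lost = np.zeros(n_frames, dtype=bool)

    # per-pixel geometry is frame independent: precompute once
    nrow, ncol = movie.heights.shape[1:]
    rows = np.arange(nrow)[:, None] - center[0]
    cols = np.arange(ncol)[None, :] - center[1]
    # counterclockwise from +col axis; image rows grow downward
    ang = np.degrees(np.arctan2(-rows, cols)) % 360.0
    bin_idx = np.minimum((ang / (360.0 / n_theta)).astype(np.intp), n_theta - 1)
    dist_nm = np.hypot(rows, cols) * movie.pixel_size

    last = np.zeros(n_theta)
    for f in range(n_frames):
        mask = _lattice_mask(movie.heights[f], level_centers, tolerance)
        if not mask.any():
            lost[f] = True
            radii[f] = 0.0
            empty[f] = True
            continue
        r_f = np.full(n_theta, -1.0)
        np.maximum.at(r_f, bin_idx[mask], dist_nm[mask])
        missing = r_f < 0
        r_f[missing] = last[missing]
        radii[f] = r_f
        empty[f] = missing
        last = r_f
    return BorderTrace(
        theta_bins=(np.arange(n_theta) + 0.5) * (360.0 / n_theta),
        radii=radii,
        center=center,
        frame_interval=movie.frame_interval,
        empty_bin_flags=empty,
        lost_frames=lost,
    )


def build_kymograph(trace: BorderTrace, theta: float) -> Kymograph:
    """The r(t) series of the angular bin containing ``theta`` (degrees).

    Angles outside [0, 360) are normalized by modulo.
    """
    theta = float(theta) % 360.0
    width = 360.0 / trace.theta_bins.size
    b = min(int(theta / width), trace.theta_bins.size - 1)
    n = trace.radii.shape[0]
    return Kymograph(
        theta_deg=trace.theta_bins[b],
        theta_bin=b,
        times=np.arange(n) * trace.frame_interval,
        radii=trace.radii[:, b].copy(),
        frame_interval=trace.frame_interval,
    )


# ---------------------------------------------------------------------------
# step idealization and dwell times
# ---------------------------------------------------------------------------

def idealize_trace(
    kymo: Kymograph,
    step_length: float = 8.85,
    threshold_fraction: float = 0.5,
    min_segment_frames: int = 1,
    median_window: int = 1,
) -> StepTrace:
    """Change-point step fit of a kymograph.

    A new segment opens when the running median of the last
    ``median_window`` incoming points departs from the current segment level
    by more than ``threshold_fraction * step_length``.  The default window
    of 1 reacts within a single frame (dwells of one frame are common at
    realistic rates); widen it when pixel noise approaches the step size.
    Each segment level is then snapped
    to the nearest integer multiple of ``step_length`` relative to the
    initial level, and segments shorter than ``min_segment_frames`` are
    merged into the longer neighbor (ties go to the earlier one).

    A linear-ramp or all-noise input yields segments whose residual against
    the step model is large; such traces are flagged low-confidence.
    """
    if step_length <= 0:
        raise ValueError("step_length must be positive")
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    r = np.asarray(kymo.radii, dtype=np.float64)
    n = r.size
    if n == 0:
        raise ValueError("empty kymograph")
    thr = threshold_fraction * step_length

    # change-point pass
    breaks = [0]
    level = r[0]
    count = 1
    level_sum = r[0]
    for i in range(1, n):
        lo = max(breaks[-1], i - median_window + 1)
        med = float(np.median(r[lo : i + 1]))
        if abs(med - level) > thr:
            breaks.append(i)
            level_sum = r[i]
            count = 1
            level = r[i]
        else:
            level_sum += r[i]
            count += 1
            level = level_sum / count
    breaks.append(n)

    segs = [
        (breaks[j], breaks[j + 1] - 1, float(np.median(r[breaks[j] : breaks[j + 1]])))
        for j in range(len(breaks) - 1)
    ]

    # merge sub-minimum segments into the longer neighbor (tie -> earlier)
    def seg_len(s):
        return s[1] - s[0] + 1

    changed = True
    while changed and len(segs) > 1:
        changed = False
        for j, s in enumerate(segs):
            if seg_len(s) < min_segment_frames:
                left = segs[j - 1] if j > 0 else None
                right = segs[j + 1] if j + 1 < len(segs) else None
                if right is None or (left is not None and seg_len(left) >= seg_len(right)):
                    merged = (left[0], s[1], left[2])
                    segs[j - 1 : j + 1] = [merged]
                else:
                    merged = (s[0], right[1], right[2])
                    segs[j : j + 2] = [merged]
                changed = True
                break

    # snap levels to the step grid relative to the initial level
    base = segs[0][2]
    snapped = []
    for s0, s1, lev in segs:
        k = round((lev - base) / step_length)
        snapped.append((s0, s1, base + k * step_length))
    # merge adjacent segments that snapped to the same level
    merged_segs: list[tuple[int, int, float]] = []
    for seg in snapped:
        if merged_segs and math.isclose(merged_segs[-1][2], seg[2]):
            merged_segs[-1] = (merged_segs[-1][0], seg[1], seg[2])
        else:
            merged_segs.append(seg)

    ideal = np.concatenate([np.full(s1 - s0 + 1, lev) for s0, s1, lev in merged_segs])
    resid = float(np.sqrt(np.mean((r - ideal) ** 2)))
    # a faithful step process leaves only pixel/instrument noise behind;
    # drifts (ramps) leave rms residuals of order the detection threshold
    low_conf = resid > 0.25 * step_length
    if len(merged_segs) == 1 and n > 1 and np.ptp(r) > step_length:
        warnings.warn("trace reduced to a single segment; treating as all-noise")
        low_conf = True
    return StepTrace(
        theta_bin=kymo.theta_bin,
        segments=merged_segs,
        step_length=step_length,
        low_confidence=low_conf,
    )


def extract_dwell_times(
    traces: list[StepTrace],
    frame_interval: float,
    include_censored: bool = False,
) -> tuple[list[float], list[float]]:
    """Pool dwell times preceding association (+step) and dissociation (-step).

    Each internal segment contributes its duration to the association list
    when the following transition is upward (lattice growth) and to the
    dissociation list when downward.  First and last segments are censored
    by the movie boundaries and excluded by default.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    assoc: list[float] = []
    dissoc: list[float] = []
    for tr in traces:
        segs = tr.segments
        if len(segs) < 2:
            continue
        first_internal = 0 if include_censored else 1
        for j in range(first_internal, len(segs) - 1):
            s0, s1, lev = segs[j]
            dwell = (s1 - s0 + 1) * frame_interval
            if segs[j + 1][2] > lev:
                assoc.append(dwell)
            else:
                dissoc.append(dwell)
    return assoc, dissoc


# ---------------------------------------------------------------------------
# rate fitting
# ---------------------------------------------------------------------------

def fit_exponential_rate(
    dwells: list[float] | np.ndarray,
    method: str = "mle",
    min_dwells: int = 10,
    n_bins: int = 20,
    confidence_level: float = 0.95,
) -> tuple[float, tuple[float, float], int]:
    """Rate constant of exponentially distributed dwell times.

    mle: k = 1/mean with an exact gamma confidence interval.
    histogram: least-squares fit of log bin counts versus bin centers
    (the decay constant of the dwell-time histogram), as in a classical
    histogram-exponential workflow.

    Returns (k_hat, (lo, hi), n).
    """
    d = np.asarray(dwells, dtype=np.float64)
    n = d.size
    if n < min_dwells:
        raise ValueError(f"need at least {min_dwells} dwells, got {n}")
    if np.any(d <= 0):
        raise ValueError("dwell times must be positive")
    total = d.sum()
    alpha = 1.0 - confidence_level
    # exact CI: 2*k*total ~ chi2(2n) under Exp(k)
    lo = stats.chi2.ppf(alpha / 2, 2 * n) / (2 * total)
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * n) / (2 * total)
    if method == "mle":
        return n / total, (float(lo), float(hi)), n
    if method == "histogram":
        counts, edges = np.histogram(d, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0
        if keep.sum() < 2:
            raise ValueError("too few occupied histogram bins for a decay fit")
        slope, _ = np.polyfit(centers[keep], np.log(counts[keep]), 1)
        k = -float(slope)
        if k <= 0:
            raise ValueError("histogram fit produced a non-decaying rate")
        return k, (float(lo), float(hi)), n
    raise ValueError(f"unknown method: {method}")


def equilibrium_constant(k_assoc: float, k_dissoc: float) -> float:
    """K_eq = k_a / k_d."""
    if k_dissoc <= 0:
        raise ValueError("k_dissoc must be positive")
    return k_assoc / k_dissoc


def estimate_border_rates(
    assoc_dwells: list[float],
    dissoc_dwells: list[float],
    method: str = "mle",
    frame_interval: float | None = None,
    min_dwells: int = 10,
) -> RateEstimate:
    """Competing-risks estimate of (k_a, k_d) from pooled dwell times.

    At a lattice border where association (rate k_a) and dissociation
    (rate k_d) compete, every dwell is Exp(k_a + k_d) and the sign of the
    following step picks the winner, so the per-channel MLE is

        k_a = n_assoc / T_observed,   k_d = n_dissoc / T_observed,

    with T_observed the total dwell time across both channels.  The total
    rate k_a + k_d is obtained by ``fit_exponential_rate`` on the pooled
    dwells (``method`` selects mle or histogram) and split by event
    fractions.

    When ``frame_interval`` is given, dwells are treated as whole-frame
    quantized and the total rate uses the geometric correction
    k_tot = -ln(1 - 1/m) / dt with m the mean dwell in frames, which removes
    the first-order bias of frame sampling.
    """
    n_a, n_d = len(assoc_dwells), len(dissoc_dwells)
    if n_a + n_d == 0:
        raise ValueError("no transitions: cannot fit rates")
    pooled = list(assoc_dwells) + list(dissoc_dwells)
    k_tot, ci, n = fit_exponential_rate(pooled, method=method, min_dwells=min_dwells)
    if frame_interval is not None:
        mean_frames = np.mean(pooled) / frame_interval
        if mean_frames <= 1.0:
            raise ValueError(
                "mean dwell is a single frame: frame rate too slow for the kinetics"
            )
        k_tot_corr = -math.log(1.0 - 1.0 / mean_frames) / frame_interval
        # rescale the reported CI by the same correction factor
        factor = k_tot_corr / (len(pooled) / np.sum(pooled))
        ci = (ci[0] * factor, ci[1] * factor)
        k_tot = k_tot_corr if method == "mle" else k_tot * factor
    f_a = n_a / (n_a + n_d)
    k_a = f_a * k_tot
    k_d = (1 - f_a) * k_tot
    return RateEstimate(
        k_assoc=k_a,
        k_dissoc=k_d,
        n_events_assoc=n_a,
        n_events_dissoc=n_d,
        fit_method=method,
        confidence_assoc=(ci[0] * f_a, ci[1] * f_a),
        confidence_dissoc=(ci[0] * (1 - f_a), ci[1] * (1 - f_a)),
    )


# ---------------------------------------------------------------------------
# occurrence histogram and energy landscape
# ---------------------------------------------------------------------------

def delta_r_histogram(
    trace: BorderTrace,
    lag_frames: int = 1,
    step_length: float = 8.85,
    max_steps: int | None = None,
) -> OccurrenceHistogram:
    """Occurrence histogram of radius changes between frames t and t + lag.

    Delta r is pooled over all angular bins and all frame pairs, binned on a
    grid of width ``step_length`` centered on integer multiples of
    step_length.  The total count is exactly
    n_theta * (n_frames - lag_frames).
    """
    if lag_frames < 1:
        raise ValueError("lag_frames must be >= 1")
    n_frames = trace.radii.shape[0]
    if n_frames <= lag_frames:
        raise ValueError("movie shorter than the requested lag")
    dr = (trace.radii[lag_frames:] - trace.radii[:-lag_frames]).ravel()
    steps = np.round(dr / step_length).astype(int)
    if max_steps is None:
        max_steps = max(1, int(np.max(np.abs(steps)))) if steps.size else 1
    steps = np.clip(steps, -max_steps, max_steps)
    grid = np.arange(-max_steps, max_steps + 1)
    counts = np.bincount(steps + max_steps, minlength=grid.size)
    return OccurrenceHistogram(
        delta_r_steps=grid,
        counts=counts,
        step_length=step_length,
        lag_frames=lag_frames,
        total=int(counts.sum()),
    )


def energy_landscape(hist: OccurrenceHistogram) -> EnergyProfile:
    """Boltzmann inversion of an occurrence histogram: dG = -k_B T ln N.

    The zero of energy is at N = 1, so grid positions without occurrence sit
    at the zero level and the global minimum falls at the most populated
    Delta r.  Local minima are grid points whose dG is below both defined
    neighbors.
    """
    if hist.total == 0:
        raise ValueError("empty histogram")
    i0 = int(np.where(hist.delta_r_steps == 0)[0][0])
    if hist.counts[i0] < 1:
        raise ValueError("no occurrences at Delta r = 0")
    with np.errstate(divide="ignore"):
        dG = np.where(hist.counts > 0, -np.log(hist.counts.astype(float)), np.nan)
    minima = []
    for i in range(len(dG)):
        if not np.isfinite(dG[i]):
            continue
        left = dG[i - 1] if i > 0 and np.isfinite(dG[i - 1]) else 0.0
        right = dG[i + 1] if i + 1 < len(dG) and np.isfinite(dG[i + 1]) else 0.0
        if dG[i] < left and dG[i] < right:
            minima.append(int(hist.delta_r_steps[i]))
    return EnergyProfile(
        delta_r_steps=hist.delta_r_steps.copy(),
        counts=hist.counts.copy(),
        delta_G=dG,
        step_length=hist.step_length,
        local_minima=minima,
    )


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def analyze_movie(
    movie: AFMMovie,
    n_theta: int = 120,
    step_length: float = 8.85,
    level_centers: tuple[float, float, float] = (0.0, 3.15, 6.1),
    lag_frames: int = 1,
    method: str = "mle",
    frame_sampling_correction: bool = True,
) -> dict:
    """Movie -> border trace -> rates + energy profile, with defaults.

    Returns a dict with the BorderTrace, StepTraces, RateEstimate,
    OccurrenceHistogram and EnergyProfile.
    """
    trace = extract_border_polar(movie, n_theta=n_theta, level_centers=level_centers)
    steps = [
        idealize_trace(build_kymograph(trace, th), step_length=step_length)
        for th in trace.theta_bins
    ]
    assoc, dissoc = extract_dwell_times(steps, movie.frame_interval)
    rates = estimate_border_rates(
        assoc,
        dissoc,
        method=method,
        frame_interval=movie.frame_interval if frame_sampling_correction else None,
    )
    hist = delta_r_histogram(trace, lag_frames=lag_frames, step_length=step_length)
    return {
        "trace": trace,
        "step_traces": steps,
        "rates": rates,
        "histogram": hist,
        "energy": energy_landscape(hist),
    }
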