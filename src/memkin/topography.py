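"""AFM topography quantification: height levels, patch areas, fusion metrics.

Implements the time-lapse bookkeeping of A5 self-assembly on supported
membrane patches: three-Gaussian fits of pixel-height histograms (mica /
membrane / A5 top), membrane and A5-coverage areas, aggregate counting with
a minimum-size floor, mass-center tracking, the perimeter/area fusion
metric, and integer-pixel drift correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal
from skimage import measure, morphology
from skimage.registration import phase_cross_correlation

from memkin.border_kinetics import AFMMovie


@dataclass
class LevelFit:
    """Three-Gaussian fit of a pixel-height histogram.

    centers are nm heights of (mica, membrane, lattice-top); thickness of the
    bare membrane is centers[1]-centers[0]; of the A5-covered membrane,
    centers[2]-centers[0].  Widths are the fitted Gaussian sd per level (the
    reported uncertainty of each thickness).
    """

    centers: tuple[float, float, float]
    widths: tuple[float, float, float]
    amplitudes: tuple[float, float, float]
    residual: float

    @property
    def thickness_membrane(self) -> float:
        return self.centers[1] - self.centers[0]

    @property
    def thickness_total(self) -> float:
        return self.centers[2] - self.centers[0]


def _triple_gauss(x, a1, m1, s1, a2, m2, s2, a3, m3, s3):
    return (
        a1 * np.exp(-((x - m1) ** 2) / (2 * s1**2))
        + a2 * np.exp(-((x - m2) ** 2) / (2 * s2**2))
        + a3 * np.exp(-((x - m3) ** 2) / (2 * s3**2))
    )


def fit_gaussian_levels(
    frame_or_movie: np.ndarray | AFMMovie,
    n_bins: int = 200,
    min_peak_separation_nm: float = 1.0,
) -> LevelFit:
    """Least-squares 3-Gaussian mixture fit of the pixel-height histogram.

    Peak picking on the smoothed histogram initializes the fit; fewer than
    three separated modes, or a non-converging fit, raises with the raw
    histogram attached to the exception for inspection.
    """
    if isinstance(frame_or_movie, AFMMovie):
        values = frame_or_movie.heights.ravel()
    else:
        values = np.asarray(frame_or_movie, dtype=np.float64).ravel()
    counts, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_w = edges[1] - edges[0]
    smooth = signal.savgol_filter(counts.astype(float), 7, 2) if n_bins >= 7 else counts
    smooth = np.maximum(smooth, 0.0)  # smoothing ringing must not fake peaks
    min_dist = max(1, int(min_peak_separation_nm / bin_w))
    # zero-pad so modes at the histogram edges count as peaks
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, props = signal.find_peaks(
        padded, distance=min_dist, prominence=0.05 * counts.max()
    )
    peaks = peaks - 1
    if peaks.size < 3:
        err = ValueError(
            "fewer than 3 distinguishable height modes; run fit_gaussian_levels "
            "on a frame containing mica, membrane and lattice"
        )
        err.histogram = (centers, counts)  # type: ignore[attr-defined]
        raise err
    top3 = peaks[np.argsort(props["prominences"])[-3:]]
    top3 = np.sort(top3)
    p0 = []
    lo, hi = [], []
    span = edges[-1] - edges[0]
    for pk in top3:
        p0 += [max(smooth[pk], 1.0), centers[pk], max(bin_w, 0.05)]
        # width floor of half a bin keeps noise-free (discrete) histograms,
        # whose modes are single spikes, from collapsing the fit
        lo += [0.0, edges[0], bin_w / 2.0]
        hi += [np.inf, edges[-1], span]
    try:
        popt, _ = optimize.curve_fit(
            _triple_gauss, centers, counts, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except RuntimeError as exc:
        err = ValueError(f"3-Gaussian fit did not converge: {exc}")
        err.histogram = (centers, counts)  # type: ignore[attr-defined]
        raise err from exc
    trip = sorted(
        [(popt[3 * i + 1], abs(popt[3 * i + 2]), popt[3 * i]) for i in range(3)]
    )
    resid = float(np.sqrt(np.mean((counts - _triple_gauss(centers, *popt)) ** 2)))
    return LevelFit(
        centers=tuple(t[0] for t in trip),
        widths=tuple(t[1] for t in trip),
        amplitudes=tuple(t[2] for t in trip),
        residual=resid,
    )


def rezero_to_mica(movie: AFMMovie, fit: LevelFit | None = None) -> AFMMovie:
    """Shift heights so the mica mode sits at 0 nm."""
    if fit is None:
        fit = fit_gaussian_levels(movie)
    return AFMMovie(
        movie.heights - fit.centers[0], movie.pixel_size, movie.frame_interval
    )


def thickness_series(movie: AFMMovie, n_bins: int = 200) -> pd.DataFrame:
    """Per-frame membrane and A5 thickness from 3-Gaussian height fits."""
    rows = []
    for f in range(movie.n_frames):
        fit = fit_gaussian_levels(movie.heights[f], n_bins=n_bins)
        rows.append(
            {
                "frame": f,
                "time_s": f * movie.frame_interval,
                "thickness_membrane_nm": fit.thickness_membrane,
                "thickness_total_nm": fit.thickness_total,
                "width_membrane_nm": fit.widths[1],
                "width_a5_nm": fit.widths[2],
            }
        )
    return pd.DataFrame(rows)


def patch_metrics(
    movie: AFMMovie,
    levels: LevelFit | tuple[float, float, float],
    min_aggregate_size: float = 200.0,
    tolerance: float | None = None,
) -> pd.DataFrame:
    """Per-frame membrane area, A5 coverage, aggregate count, perimeter,
    and membrane mass center.

    membrane mask = pixels within tolerance of the membrane OR lattice
    level; A5 mask = lattice level.  Aggregates are 8-connected components
    of the A5 mask with area >= min_aggregate_size (nm^2); perimeter is the
    boundary-pixel count times pixel_size; mass center is of the membrane
    mask, in nm.  Tolerance defaults to 3x the fitted membrane width (or
    half the smallest level gap for raw center tuples).
    """
    if isinstance(levels, LevelFit):
        centers = levels.centers
        if tolerance is None:
            tolerance = 3.0 * levels.widths[1]
    else:
        centers = tuple(levels)
        if tolerance is None:
            tolerance = 0.5 * min(np.diff(np.asarray(centers)))
    c_mica, c_mem, c_lat = centers
    px = movie.pixel_size
    px2 = px * px
    min_px = min_aggregate_size / px2
    rows = []
    for f in range(movie.n_frames):
        h = movie.heights[f]
        mem_like = (np.abs(h - c_mem) <= tolerance) | (np.abs(h - c_lat) <= tolerance)
        a5 = np.abs(h - c_lat) <= tolerance
        if not mem_like.any():
            warnings.warn(f"frame {f}: empty membrane mask")
            rows.append(
                {
                    "frame": f,
                    "membrane_area_nm2": 0.0,
                    "a5_coverage": 0.0,
                    "aggregate_count": 0,
                    "perimeter_nm": 0.0,
                    "cx_nm": np.nan,
                    "cy_nm": np.nan,
                    "flag_empty": True,
                }
            )
            continue
        comp = measure.label(a5, connectivity=2)
        n_agg = 0
        if comp.max() > 0:
            sizes = np.bincount(comp.ravel())[1:]
            n_agg = int(np.sum(sizes >= min_px))
        boundary = mem_like & ~morphology.binary_erosion(mem_like)
        rr, cc = np.nonzero(mem_like)
        rows.append(
            {
                "frame": f,
                "membrane_area_nm2": float(mem_like.sum() * px2),
                "a5_coverage": float(a5.sum() / mem_like.sum()),
                "aggregate_count": n_agg,
                "perimeter_nm": float(boundary.sum() * px),
                "cy_nm": float(rr.mean() * px),
                "cx_nm": float(cc.mean() * px),
                "flag_empty": False,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["pixel_size"] = px
    df.attrs["frame_interval"] = movie.frame_interval
    return df


def mass_center_track(series: pd.DataFrame) -> pd.DataFrame:
    """Frame-to-frame displacement (nm) of the membrane mass center and the
    cumulative path length; flagged empty frames propagate as NaN."""
    if len(series) < 2:
        raise ValueError("need at least 2 frames")
    cy = series["cy_nm"].to_numpy()
    cx = series["cx_nm"].to_numpy()
    disp = np.hypot(np.diff(cy), np.diff(cx))
    disp = np.concatenate([[0.0], disp])
    path = np.nancumsum(disp)
    return pd.DataFrame(
        {"frame": series["frame"], "displacement_nm": disp, "path_length_nm": path}
    )


def fusion_efficiency(
    series: pd.DataFrame, region_mask: np.ndarray | None = None
) -> np.ndarray:
    """Per-frame perimeter/area ratio (1/nm) of the membrane.

    A decreasing ratio indicates coalescence of patches into fewer, larger
    regions (a disk of radius r has ratio 2/r).  Zero-area frames yield NaN.
    ``region_mask`` (boolean, per-frame selector) restricts the series to
    newly formed membrane frames when supplied.
    """
    area = series["membrane_area_nm2"].to_numpy(dtype=float)
    perim = series["perimeter_nm"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(area > 0, perim / area, np.nan)
    if region_mask is not None:
        ratio = np.where(np.asarray(region_mask, dtype=bool), ratio, np.nan)
    return ratio


def drift_correct(movie: AFMMovie) -> tuple[AFMMovie, np.ndarray]:
    """Integer-pixel translation alignment of every frame to frame 0.

    Shifts maximize the image cross-correlation (phase correlation at
    integer-pixel precision); frames are rolled by the recovered shift.
    Degenerate (flat) frames get zero shift with a warning.  Returns the
    corrected movie and the (n_frames, 2) array of applied (row, col) shifts.
    """
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames")
    ref = movie.heights[0]
    out = movie.heights.copy()
    shifts = np.zeros((movie.n_frames, 2), dtype=int)
    for f in range(1, movie.n_frames):
        frame = movie.heights[f]
        if np.ptp(frame) == 0 or np.ptp(ref) == 0:
            warnings.warn(f"frame {f}: flat image, zero shift assumed")
            continue
        shift, _, _ = phase_cross_correlation(ref, frame, upsample_factor=1)
        shifts[f] = np.round(shift).astype(int)
        out[f] = np.roll(frame, shifts[f], axis=(0, 1))
    return AFMMovie(out, movie.pixel_size, movie.frame_interval), shifts
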