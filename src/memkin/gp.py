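"""Laurdan generalized-polarization (GP) imaging of lipid order.

GP is the ratiometric observable of the solvatochromic dye Laurdan,

    GP = (I_ch1 - G * I_ch2) / (I_ch1 + G * I_ch2),

with ch1 the blue (ordered-phase) and ch2 the red (disordered-phase)
spectral window and G an instrument gain calibrated so <GP> = 0 in a
defined reference condition.  Higher GP = more ordered lipids.  Two GP
estimators are implemented and never silently interchanged: the per-pixel
GP image (histograms, peak, mean over a GUV ring mask) and the sum-based
time-lapse GP computed from whole-mask channel sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize


@dataclass
class GPImage:
    """Per-pixel GP field; NaN where the total intensity is below floor."""

    gp: np.ndarray
    g_factor: float
    mask: np.ndarray | None = None

    def defined(self) -> np.ndarray:
        """GP values that are defined (and inside the mask, if any)."""
        sel = np.isfinite(self.gp)
        if self.mask is not None:
            sel &= self.mask
        return self.gp[sel]


@dataclass
class GPStats:
    histogram: tuple[np.ndarray, np.ndarray]  # (bin_centers, counts)
    peak: float
    mean: float
    sd: float
    n_pixels: int


@dataclass
class GUVProfile:
    """360-fold averaged radial intensity profile of one GUV ring."""

    center: tuple[float, float]  # px
    radii_um: np.ndarray
    profile: np.ndarray
    diameter_um: float


def gp_of_channels(i1, i2, g_factor: float):
    """Elementwise GP = (I1 - G I2)/(I1 + G I2); no floor applied."""
    i1 = np.asarray(i1, dtype=np.float64)
    i2 = np.asarray(i2, dtype=np.float64)
    denom = i1 + g_factor * i2
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom != 0, (i1 - g_factor * i2) / denom, np.nan)


def calibrate_g_factor(
    ch1: np.ndarray,
    ch2: np.ndarray,
    mask: np.ndarray | None = None,
    method: str = "sum",
    tol: float = 1e-6,
    max_iter: int = 100,
) -> float:
    """Gain factor G that zeroes the reference GP.

    'sum': G = sum(I1)/sum(I2) over the masked pixels — the exact solution
    for the sum-based GP.  'pixel_mean': G iterated until the mean of the
    per-pixel GP is below ``tol`` in magnitude.
    """
    ch1 = np.asarray(ch1, dtype=np.float64)
    ch2 = np.asarray(ch2, dtype=np.float64)
    if mask is not None:
        ch1, ch2 = ch1[mask], ch2[mask]
    s2 = ch2.sum()
    if s2 <= 0:
        raise ValueError("channel-2 sum is zero: cannot calibrate")
    g = float(ch1.sum() / s2)
    if method == "sum":
        return g
    if method != "pixel_mean":
        raise ValueError(f"unknown method: {method}")

    def mean_gp(gg: float) -> float:
        return float(np.nanmean(gp_of_channels(ch1, ch2, gg)))

    lo, hi = g / 10.0, g * 10.0
    try:
        return float(optimize.brentq(mean_gp, lo, hi, xtol=tol * g, maxiter=max_iter))
    except ValueError as exc:
        raise ValueError("pixel-mean calibration did not bracket zero") from exc


def gp_image(
    ch1: np.ndarray,
    ch2: np.ndarray,
    g_factor: float,
    intensity_floor: float | None = None,
    mask: np.ndarray | None = None,
) -> GPImage:
    """Per-pixel GP image; pixels with I1 + G I2 below the floor are NaN.

    The floor defaults to 2% of the median total intensity over the mask
    (or the whole image without one).
    """
    if g_factor <= 0:
        raise ValueError("g_factor must be positive")
    ch1 = np.asarray(ch1, dtype=np.float64)
    ch2 = np.asarray(ch2, dtype=np.float64)
    total = ch1 + g_factor * ch2
    if intensity_floor is None:
        ref = total[mask] if mask is not None else total
        intensity_floor = 0.02 * float(np.median(ref))
    gp = gp_of_channels(ch1, ch2, g_factor)
    gp = np.where(total >= max(intensity_floor, 1e-300), gp, np.nan)
    return GPImage(gp=gp, g_factor=g_factor, mask=mask)


def gp_statistics(
    gpimg: GPImage, bin_width: float = 0.01, min_pixels: int = 100
) -> GPStats:
    """Histogram over [-1, 1], most-probable (peak) bin, mean and sd."""
    vals = gpimg.defined()
    if vals.size < min_pixels:
        raise ValueError(f"need >= {min_pixels} defined masked pixels, got {vals.size}")
    n_bins = int(round(2.0 / bin_width))
    counts, edges = np.histogram(vals, bins=n_bins, range=(-1.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return GPStats(
        histogram=(centers, counts),
        peak=float(centers[np.argmax(counts)]),
        mean=float(vals.mean()),
        sd=float(vals.std()),
        n_pixels=int(vals.size),
    )


def timelapse_gp(
    ch1: np.ndarray,
    ch2: np.ndarray,
    g_factor: float,
    mask_per_frame: np.ndarray | None = None,
    ch3: np.ndarray | None = None,
    background: float | np.ndarray = 0.0,
) -> dict[str, np.ndarray]:
    """Sum-based GP(t) and normalized A5 intensity over frame masks.

    GP_t = (S1 - G S2)/(S1 + G S2) with S the masked channel sums per frame;
    A5_t = (S3 - background)/max_t(S3 - background).  Empty-mask frames give
    NaN.
    """
    ch1 = np.asarray(ch1, dtype=np.float64)
    ch2 = np.asarray(ch2, dtype=np.float64)
    n = ch1.shape[0]
    gp_t = np.full(n, np.nan)
    s1 = np.empty(n)
    s2 = np.empty(n)
    for f in range(n):
        m = (
            mask_per_frame[f]
            if mask_per_frame is not None and mask_per_frame.ndim == 3
            else mask_per_frame
        )
        if m is not None and not m.any():
            s1[f] = s2[f] = np.nan
            continue
        s1[f] = ch1[f][m].sum() if m is not None else ch1[f].sum()
        s2[f] = ch2[f][m].sum() if m is not None else ch2[f].sum()
        denom = s1[f] + g_factor * s2[f]
        if denom > 0:
            gp_t[f] = (s1[f] - g_factor * s2[f]) / denom
    out = {"gp": gp_t, "sum_ch1": s1, "sum_ch2": s2}
    if ch3 is not None:
        ch3 = np.asarray(ch3, dtype=np.float64)
        s3 = np.empty(n)
        for f in range(n):
            m = (
                mask_per_frame[f]
                if mask_per_frame is not None and mask_per_frame.ndim == 3
                else mask_per_frame
            )
            s3[f] = ch3[f][m].sum() if m is not None else ch3[f].sum()
        bg = np.broadcast_to(np.asarray(background, dtype=np.float64), s3.shape)
        corr = s3 - bg
        peak = np.nanmax(corr)
        out["a5"] = corr / peak if peak > 0 else np.zeros_like(corr)
    return out


def guv_profile(
    img: np.ndarray,
    pixel_size_um: float,
    search_region: tuple[slice, slice] | None = None,
    n_sectors: int = 360,
    refine_px: int = 2,
) -> GUVProfile:
    """GUV diameter by the 360-fold radial average.

    The ring center is the intensity centroid of the thresholded image
    (Otsu-like: half of the max), refined over a small integer-pixel grid by
    maximizing the sharpness (peak height) of the sector-averaged radial
    profile.  The radial profile is the mean over ``n_sectors`` angular
    sectors of the per-sector radial averages; the diameter is twice the
    radius of the profile maximum.
    """
    img = np.asarray(img, dtype=np.float64)
    region = img[search_region] if search_region is not None else img
    offset = (
        (search_region[0].start or 0, search_region[1].start or 0)
        if search_region is not None
        else (0, 0)
    )
    if region.max() <= 0:
        raise ValueError("no ring found in the search region")
    thr = region >= 0.5 * region.max()
    rr, cc = np.nonzero(thr)
    w = region[rr, cc]
    c0 = (float(np.average(rr, weights=w)) + offset[0],
          float(np.average(cc, weights=w)) + offset[1])

    def radial_profile(center):
        rows = np.arange(img.shape[0])[:, None] - center[0]
        cols = np.arange(img.shape[1])[None, :] - center[1]
        rho = np.hypot(rows, cols)
        ang = (np.degrees(np.arctan2(-rows, cols)) % 360.0)
        sector = np.minimum((ang * n_sectors / 360.0).astype(np.intp), n_sectors - 1)
        rbin = rho.astype(np.intp)
        n_r = int(rho.max()) + 1
        flat = sector.ravel() * n_r + rbin.ravel()
        sums = np.bincount(flat, weights=img.ravel(), minlength=n_sectors * n_r)
        cnts = np.bincount(flat, minlength=n_sectors * n_r)
        with np.errstate(invalid="ignore"):
            per_sector = (sums / np.where(cnts > 0, cnts, np.nan)).reshape(
                n_sectors, n_r
            )
        return np.nanmean(per_sector, axis=0)

    best = (-np.inf, c0, None)
    for dr in range(-refine_px, refine_px + 1):
        for dc in range(-refine_px, refine_px + 1):
            cand = (c0[0] + dr, c0[1] + dc)
            prof = radial_profile(cand)
            peak = np.nanmax(prof)
            if peak > best[0]:
                best = (peak, cand, prof)
    _, center, prof = best
    r_peak_px = int(np.nanargmax(prof))
    return GUVProfile(
        center=center,
        radii_um=np.arange(prof.size) * pixel_size_um,
        profile=prof,
        diameter_um=2.0 * r_peak_px * pixel_size_um,
    )


def ring_mask_from_profile(
    img_total: np.ndarray,
    profile: GUVProfile,
    pixel_size_um: float,
    width_bins: int = 2,
) -> np.ndarray:
    """Boolean GUV ring mask: pixels within +/- width_bins radial bins of
    the profile peak."""
    rows = np.arange(img_total.shape[0])[:, None] - profile.center[0]
    cols = np.arange(img_total.shape[1])[None, :] - profile.center[1]
    rho_um = np.hypot(rows, cols) * pixel_size_um
    r_peak = profile.diameter_um / 2.0
    half_width = width_bins * pixel_size_um
    return np.abs(rho_um - r_peak) <= half_width
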