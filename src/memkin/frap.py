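"""FRAP quantification: double normalization, half time, effective radius,
and the simplified circular-bleach diffusion estimate.

The diffusion coefficient of the labeled lipid follows from the half time
of recovery and two radii,

    D = (r_n^2 + r_e^2) / (8 * tau_1/2),

where r_n is the radius of the designed circular bleach region and r_e the
effective (1/e^2 Gaussian) bleach radius measured on the first post-bleach
image.  The relation is exact in the r_n << r_e limit and accurate to a few
percent for r_e >~ 2 r_n; tau_1/2 must be the model-free half-recovery time
(an exponential-fit tau*ln2 is strongly biased for diffusive recovery, whose
tail is hyperbolic, and is provided only as an explicit option).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize


@dataclass
class ROISpec:
    """Circular region of interest, in pixels."""

    center: tuple[float, float]  # (row, col)
    radius: float  # px

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr = np.arange(shape[0])[:, None] - self.center[0]
        cc = np.arange(shape[1])[None, :] - self.center[1]
        return rr**2 + cc**2 <= self.radius**2


@dataclass
class FRAPCurve:
    """Double-normalized recovery curve; time zero at the bleach frame and
    pre-bleach mean normalized to 1."""

    time: np.ndarray  # s, negative values are pre-bleach
    intensity_norm: np.ndarray
    channel: str
    roi_radius_nominal: float  # um
    bleach_frame: int
    control_used: bool

    @property
    def post(self) -> tuple[np.ndarray, np.ndarray]:
        sel = self.time >= 0
        return self.time[sel], self.intensity_norm[sel]


@dataclass
class FRAPResult:
    tau_half: float  # s
    r_nominal: float  # um
    r_effective: float  # um
    mobile_fraction: float
    D: float  # um^2/s


def detect_bleach_frame(series: np.ndarray, roi: ROISpec) -> int:
    """Index of the first post-bleach frame: the largest single-frame drop
    of the mean intensity in the bleach ROI."""
    m = roi.mask(series.shape[1:])
    trace = series[:, m].mean(axis=1)
    return int(np.argmin(np.diff(trace))) + 1


def extract_frap_curve(
    series: np.ndarray,
    frame_interval: float,
    bleach_roi: ROISpec,
    control_roi: ROISpec | None = None,
    background_roi: ROISpec | None = None,
    pixel_size: float = 1.0,
    channel: str = "lipid",
    bleach_frame: int | None = None,
    min_prebleach: int = 3,
) -> FRAPCurve:
    """Double-normalized FRAP curve from a (frame, row, col) stack.

    The bleach-ROI mean is first calibrated by a control region without
    photobleaching (cancelling acquisition photofading), then normalized to
    its pre-bleach mean:

        I_norm(t) = [(I_bleach - I_bg) / (I_ctrl - I_bg)](t) / prebleach mean

    Without a control ROI the calibration step is skipped (control == 1);
    without a background ROI, background = 0.
    """
    series = np.asarray(series, dtype=np.float64)
    shape = series.shape[1:]
    for roi in (bleach_roi, control_roi, background_roi):
        if roi is None:
            continue
        if (
            roi.center[0] - roi.radius < -0.5
            or roi.center[1] - roi.radius < -0.5
            or roi.center[0] + roi.radius > shape[0] - 0.5
            or roi.center[1] + roi.radius > shape[1] - 0.5
        ):
            raise ValueError("ROI extends outside the image")
    bleach = series[:, bleach_roi.mask(shape)].mean(axis=1)
    bg = (
        series[:, background_roi.mask(shape)].mean(axis=1)
        if background_roi is not None
        else 0.0
    )
    if bleach_frame is None:
        bleach_frame = detect_bleach_frame(series, bleach_roi)
    if bleach_frame < min_prebleach:
        raise ValueError(f"need >= {min_prebleach} pre-bleach frames")
    sig = bleach - bg
    if control_roi is not None:
        ctrl = series[:, control_roi.mask(shape)].mean(axis=1) - bg
        pre_ctrl = ctrl[:bleach_frame].mean()
        if ctrl[bleach_frame] < 0.8 * pre_ctrl:
            raise ValueError("control ROI was bleached (> 20% drop)")
        sig = sig / ctrl
    pre = sig[:bleach_frame].mean()
    if pre <= 0:
        raise ValueError("non-positive pre-bleach intensity")
    t = (np.arange(series.shape[0]) - bleach_frame) * frame_interval
    return FRAPCurve(
        time=t,
        intensity_norm=sig / pre,
        channel=channel,
        roi_radius_nominal=bleach_roi.radius * pixel_size,
        bleach_frame=bleach_frame,
        control_used=control_roi is not None,
    )


def fit_half_time(
    curve: FRAPCurve,
    method: str = "crossing",
    min_points: int = 10,
    mobile_threshold: float = 0.02,
) -> tuple[float, float]:
    """Half time of recovery and mobile fraction from the post-bleach curve.

    'crossing' (default): tau_1/2 is the model-free linear interpolation of
    the first crossing of (I0 + I_inf)/2, with the plateau I_inf taken from
    whichever of two tail models fits better — the single exponential
    I(t) = I_inf - (I_inf - I0) exp(-t/tau) or the hyperbola
    I(t) = I_inf - b/(t + c), the exact late-time form of 2-D diffusive
    recovery (robust when the plateau is not reached within the record).
    'exponential' returns tau*ln2 of the exponential fit instead (biased
    slow for pure diffusion; see module docstring).

    Raises when the curve is flat (mobile fraction ~ 0: tau undefined).
    """
    t, y = curve.post
    if t.size < min_points:
        raise ValueError(f"need >= {min_points} post-bleach points")
    i0 = float(y[0])
    tau = np.nan
    candidates = []  # (sse, i_inf, i0_fit)
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, i_inf, i_0, tau: i_inf - (i_inf - i_0) * np.exp(-tt / tau),
            t,
            y,
            p0=[1.0, i0, max(t[-1] / 5.0, 1e-6)],
            maxfev=20000,
        )
        tau = float(popt[2])
        if tau > 0 and popt[0] > popt[1]:
            resid = y - (popt[0] - (popt[0] - popt[1]) * np.exp(-t / tau))
            candidates.append((float(np.sum(resid**2)), float(popt[0]), float(popt[1])))
        else:
            tau = np.nan
    except RuntimeError:
        pass
    if method == "exponential" and np.isnan(tau):
        raise ValueError("exponential fit did not converge")
    try:
        span = max(t[-1], 1e-6)
        popt, _ = optimize.curve_fit(
            lambda tt, i_inf, b, c: i_inf - b / (tt + c),
            t,
            y,
            p0=[max(y[-1], i0 + 0.1), (y[-1] - i0) * span / 4.0, span / 4.0],
            bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        i_inf_h = float(popt[0])
        i0_h = float(i_inf_h - popt[1] / popt[2])
        if i_inf_h > i0_h:
            resid = y - (i_inf_h - popt[1] / (t + popt[2]))
            candidates.append((float(np.sum(resid**2)), i_inf_h, i0_h))
    except (RuntimeError, ValueError):
        pass
    if candidates:
        _, i_inf, i0_fit = min(candidates)
    else:
        warnings.warn("recovery-model fits failed; using tail mean as plateau")
        i_inf = float(np.mean(y[-max(3, t.size // 10) :]))
        i0_fit = i0
    mobile = (i_inf - i0_fit) / (1.0 - i0_fit) if i0_fit < 1.0 else 0.0
    if i_inf - i0_fit < mobile_threshold:
        raise ValueError("flat recovery curve: mobile fraction ~ 0, tau undefined")
    if method == "exponential":
        return tau * np.log(2.0), float(np.clip(mobile, 0.0, 1.0))
    if method != "crossing":
        raise ValueError(f"unknown method: {method}")
    half = 0.5 * (i0 + i_inf)
    above = np.nonzero(y >= half)[0]
    above = above[above > 0]
    if above.size == 0:
        raise ValueError("recovery never reaches the half level in the record")
    j = int(above[0])
    t_half = t[j - 1] + (half - y[j - 1]) / (y[j] - y[j - 1]) * (t[j] - t[j - 1])
    return float(t_half), float(np.clip(mobile, 0.0, 1.0))


def estimate_effective_radius(
    postbleach_frame: np.ndarray,
    center: tuple[float, float],
    pixel_size: float,
    r_max: float | None = None,
    n_radial_bins: int = 60,
) -> tuple[float, float]:
    """Effective bleach radius from the first post-bleach image.

    The azimuthally averaged radial profile about the bleach center is fit
    to the Gaussian dip I(rho) = 1 - K exp(-2 rho^2 / r_e^2); returns
    (r_e in length units of pixel_size, bleach depth K).  A fitted K <= 0
    (no bleach) raises.
    """
    img = np.asarray(postbleach_frame, dtype=np.float64)
    rr = (np.arange(img.shape[0])[:, None] - center[0]) * pixel_size
    cc = (np.arange(img.shape[1])[None, :] - center[1]) * pixel_size
    rho = np.hypot(rr, cc).ravel()
    if r_max is None:
        r_max = float(rho.max()) * 0.7
    vals = img.ravel()
    sel = rho <= r_max
    bins = np.linspace(0.0, r_max, n_radial_bins + 1)
    idx = np.digitize(rho[sel], bins) - 1
    idx = np.clip(idx, 0, n_radial_bins - 1)
    prof = np.bincount(idx, weights=vals[sel], minlength=n_radial_bins)
    cnt = np.bincount(idx, minlength=n_radial_bins)
    good = cnt > 0
    prof = prof[good] / cnt[good]
    rmid = (0.5 * (bins[:-1] + bins[1:]))[good]
    popt, _ = optimize.curve_fit(
        lambda r, K, re: 1.0 - K * np.exp(-2.0 * r**2 / re**2),
        rmid,
        prof,
        p0=[1.0 - prof.min(), r_max / 3.0],
        maxfev=20000,
    )
    K, r_e = float(popt[0]), abs(float(popt[1]))
    if K <= 0:
        raise ValueError("no bleach detected (fitted depth <= 0)")
    resid = prof - (1.0 - K * np.exp(-2.0 * rmid**2 / r_e**2))
    if np.sqrt(np.mean(resid**2)) > 0.1 * K:
        warnings.warn(
            "bleach profile departs from a Gaussian (e.g. hard-edged bleach); "
            "r_e is the least-squares Gaussian radius"
        )
    return r_e, K


def diffusivity_kang(r_nominal: float, r_effective: float, tau_half: float) -> float:
    """D = (r_n^2 + r_e^2) / (8 tau_1/2), in um^2/s for um and s inputs."""
    if r_nominal <= 0 or r_effective <= 0:
        raise ValueError("radii must be positive")
    if tau_half <= 0:
        raise ValueError("tau_half must be positive")
    return (r_nominal**2 + r_effective**2) / (8.0 * tau_half)


def analyze_frap_series(
    series: np.ndarray,
    frame_interval: float,
    pixel_size_um: float,
    bleach_center_px: tuple[float, float],
    r_nominal_um: float,
    control_roi: ROISpec | None = None,
    background_roi: ROISpec | None = None,
    tau_method: str = "crossing",
) -> tuple[FRAPResult, FRAPCurve]:
    """Full pipeline: curve extraction, tau_1/2, r_e, and D.

    The effective radius is estimated on the first post-bleach frame only
    (diffusion broadens the profile in later frames).
    """
    roi = ROISpec(bleach_center_px, r_nominal_um / pixel_size_um)
    curve = extract_frap_curve(
        series,
        frame_interval,
        roi,
        control_roi=control_roi,
        background_roi=background_roi,
        pixel_size=pixel_size_um,
    )
    tau_half, mobile = fit_half_time(curve, method=tau_method)
    post0 = series[curve.bleach_frame]
    pre_mean = series[: curve.bleach_frame].mean(axis=0)
    norm0 = post0 / np.where(pre_mean > 0, pre_mean, 1.0)
    r_e, _ = estimate_effective_radius(norm0, bleach_center_px, pixel_size_um)
    D = diffusivity_kang(r_nominal_um, r_e, tau_half)
    return (
        FRAPResult(
            tau_half=tau_half,
            r_nominal=r_nominal_um,
            r_effective=r_e,
            mobile_fraction=mobile,
            D=D,
        ),
        curve,
    )
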