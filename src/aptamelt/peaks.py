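"""Free/bound melt-peak detection, deconvolution and quantification.

In a TFA melt curve of an aptamer-target mixture, the unbound aptamer melts
at a lower Tm (peak 1, "free") and the target-stabilised aptamer at a higher
Tm (peak 2, "bound"). This module detects those peaks on derivative curves,
fits a two-Gaussian-plus-linear-baseline model, and derives the quantities
used to judge conditions: Tm, peak height, peak area, the bound-aptamer
ratio, cross-condition area heatmaps and linear calibrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize
from scipy.signal import find_peaks, peak_prominences
from scipy.stats import linregress

from .preprocess import DerivativeCurve

#: Detection defaults: prominence in normalized dF/dT units, separation in deg C.
DEFAULT_MIN_PROMINENCE = 5.0
DEFAULT_MIN_SEPARATION = 2.0

#: Fitted components with height below this fraction of the curve maximum are
#: treated as absent (detection floor).
DETECTION_FLOOR_FRACTION = 0.01

SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass
class PeakReport:
    """A single melt peak: position (Tm), height and area."""

    tm: float  # deg C
    height: float  # dF/dT units of the input curve
    area: float  # dF/dT * deg C
    label: str = "unassigned"  # free | bound | unassigned
    condition_id: str | None = None


@dataclass
class TwoPeakFit:
    """Result of the two-component deconvolution of a melt curve."""

    free_peak: PeakReport
    bound_peak: PeakReport
    baseline_slope: float
    baseline_offset: float
    residual_norm: float
    converged: bool
    condition_id: str | None = None
    message: str = ""
    sigma_free: float = float("nan")
    sigma_bound: float = float("nan")


@dataclass
class CalibrationFit:
    """Ordinary least-squares line through (concentration, response) points."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


def gaussian(x, height, center, sigma):
    return height * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def peak_area(height: float, sigma: float) -> float:
    """Analytic area of a Gaussian component: height * sigma * sqrt(2*pi)."""
    return float(height) * float(sigma) * SQRT_2PI


def trapezoid_peak_area(curve: DerivativeCurve, center: float, sigma: float) -> float:
    """Nonparametric area: trapezoidal integral over +/-3 sigma, clipped to the grid."""
    t = curve.temperature
    mask = (t >= center - 3 * sigma) & (t <= center + 3 * sigma)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(curve.dfdt[mask], t[mask]))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def detect_peaks(
    curve: DerivativeCurve,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    max_peaks: int | None = 2,
) -> list[PeakReport]:
    """Local maxima above a prominence threshold, sorted by temperature.

    At most the ``max_peaks`` most prominent peaks are retained (ties broken
    by larger prominence), matching the two-species free/bound signature.
    Returns an empty list for flat or featureless curves.
    """
    t = curve.temperature
    dt = float(t[1] - t[0])
    idx, props = find_peaks(curve.dfdt, prominence=min_prominence, distance=max(1, int(round(min_separation / dt))))
    if len(idx) == 0:
        return []
    order = np.argsort(props["prominences"])[::-1]
    if max_peaks is not None:
        order = order[:max_peaks]
    keep = np.sort(idx[order])
    proms = peak_prominences(curve.dfdt, keep)[0]
    reports = []
    for i, p in zip(keep, proms):
        center = float(t[i])
        height = float(curve.dfdt[i])
        # crude width from half-prominence crossing for a nonparametric area
        sigma = _half_height_sigma(t, curve.dfdt, i)
        reports.append(
            PeakReport(
                tm=center,
                height=height,
                area=trapezoid_peak_area(curve, center, sigma),
                label="unassigned",
                condition_id=curve.condition_id,
            )
        )
    return reports


def _half_height_sigma(t: np.ndarray, y: np.ndarray, i: int) -> float:
    """Estimate a Gaussian sigma from the half-height width around index i."""
    half = y[i] / 2.0
    left = i
    while left > 0 and y[left] > half:
        left -= 1
    right = i
    while right < len(y) - 1 and y[right] > half:
        right += 1
    fwhm = max(t[right] - t[left], 2.0 * (t[1] - t[0]))
    return float(fwhm / 2.3548200450309493)  # FWHM = 2 sqrt(2 ln 2) sigma


# ---------------------------------------------------------------------------
# deconvolution
# ---------------------------------------------------------------------------


def _two_peak_residual(params, t, y):
    model = (
        params["offset"].value
        + params["slope"].value * t
        + gaussian(t, params["h1"].value, params["c1"].value, params["s1"].value)
        + gaussian(t, params["h2"].value, params["c2"].value, params["s2"].value)
    )
    return model - y


def _initial_centers(curve: DerivativeCurve, min_prominence: float) -> tuple[float, float, float, float]:
    """Heuristic (center, height) pairs for the two components.

    Uses detected peaks when two are visible; otherwise places the second
    component at the largest residual after subtracting a Gaussian guess at
    the first, so a shoulder or minor peak still seeds the fit.
    """
    t, y = curve.temperature, curve.dfdt
    found = detect_peaks(curve, min_prominence=min_prominence, max_peaks=2)
    if len(found) >= 2:
        return found[0].tm, found[0].height, found[1].tm, found[1].height
    if len(found) == 1:
        c1, h1 = found[0].tm, found[0].height
    else:
        i = int(np.argmax(y))
        c1, h1 = float(t[i]), float(y[i])
    sigma_guess = _half_height_sigma(t, y, int(np.argmin(np.abs(t - c1))))
    resid = y - gaussian(t, h1, c1, sigma_guess)
    # keep the second guess away from the first center
    far = np.abs(t - c1) > 3 * sigma_guess
    if far.any():
        j = int(np.flatnonzero(far)[np.argmax(resid[far])])
    else:
        j = int(np.argmax(resid))
    return c1, h1, float(t[j]), max(float(resid[j]), 0.0)


def deconvolve_two_peaks(
    curve: DerivativeCurve,
    init: dict | None = None,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> TwoPeakFit:
    """Bounded least-squares fit of two Gaussians plus a linear baseline.

    The component with the lower fitted center is labelled ``free``, the
    higher ``bound`` (target binding stabilises the fold, raising its Tm).
    Non-convergence is reported via ``converged=False`` and ``message``;
    no exception is raised for a failed fit.

    Parameters
    ----------
    curve : DerivativeCurve
        Corrected or normalized derivative curve with >= 10 points.
    init : dict, optional
        Optional overrides for initial values, keys among
        ``c1, h1, s1, c2, h2, s2, slope, offset``.
    """
    t, y = curve.temperature, curve.dfdt
    if len(t) < 10:
        raise ValueError("deconvolution requires at least 10 points")
    dt = float(t[1] - t[0])
    span = float(t[-1] - t[0])
    ymax = float(np.max(y))
    yptp = float(np.ptp(y))

    c1, h1, c2, h2 = _initial_centers(curve, min_prominence)
    guesses = {
        "c1": c1,
        "h1": max(h1, 1e-6),
        "s1": 2.5,
        "c2": c2,
        "h2": max(h2, 1e-6),
        "s2": 2.5,
        "slope": 0.0,
        "offset": float(np.min(y)),
    }
    if init:
        guesses.update(init)

    params = Parameters()
    params.add("h1", value=guesses["h1"], min=0.0, max=max(2 * yptp, 1e-6))
    params.add("c1", value=guesses["c1"], min=float(t[0]), max=float(t[-1]))
    params.add("s1", value=guesses["s1"], min=dt / 2, max=span / 2)
    params.add("h2", value=guesses["h2"], min=0.0, max=max(2 * yptp, 1e-6))
    params.add("c2", value=guesses["c2"], min=float(t[0]), max=float(t[-1]))
    params.add("s2", value=guesses["s2"], min=dt / 2, max=span / 2)
    params.add("slope", value=guesses["slope"])
    params.add("offset", value=guesses["offset"])

    try:
        result = minimize(_two_peak_residual, params, args=(t, y), method="leastsq")
        converged = bool(result.success)
        message = str(result.message)
        p = result.params
    except Exception as exc:  # lmfit failure path: report, never raise
        converged = False
        message = f"fit failed: {exc}"
        p = params

    comps = sorted(
        [
            (p["c1"].value, p["h1"].value, p["s1"].value),
            (p["c2"].value, p["h2"].value, p["s2"].value),
        ],
        key=lambda c: c[0],
    )
    floor = DETECTION_FLOOR_FRACTION * max(ymax, 1e-12)
    labels = ["free", "bound"]
    reports = []
    for (center, height, sigma), label in zip(comps, labels):
        reports.append(
            PeakReport(
                tm=float(center),
                height=float(height),
                area=peak_area(height, sigma),
                label=label if height >= floor else "unassigned",
                condition_id=curve.condition_id,
            )
        )
    resid = _two_peak_residual(p, t, y)
    return TwoPeakFit(
        free_peak=reports[0],
        bound_peak=reports[1],
        baseline_slope=float(p["slope"].value),
        baseline_offset=float(p["offset"].value),
        residual_norm=float(np.sqrt(np.mean(resid**2))),
        converged=converged,
        condition_id=curve.condition_id,
        message=message,
        sigma_free=float(comps[0][2]),
        sigma_bound=float(comps[1][2]),
    )


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def bound_ratio(fit: TwoPeakFit) -> float | None:
    """Bound-aptamer ratio: area_bound / (area_free + area_bound).

    Returns ``None`` (a flagged undefined value, not NaN) when both areas
    are zero. Requires a converged fit.
    """
    if not fit.converged:
        raise ValueError("bound_ratio requires a converged fit")
    a_free = max(fit.free_peak.area, 0.0)
    a_bound = max(fit.bound_peak.area, 0.0)
    total = a_free + a_bound
    if total == 0.0:
        return None
    return a_bound / total


def area_heatmap(
    fits: dict[str, TwoPeakFit],
    concentrations: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Condition x {free, bound} matrix of peak areas.

    Rows are ordered by ascending aptamer concentration when
    ``concentrations`` is given, otherwise by insertion order. A component
    below the detection floor contributes area 0 and is flagged in the
    ``missing`` column.
    """
    if not fits:
        raise ValueError("at least one condition is required")
    rows = []
    for cid, fit in fits.items():
        free_ok = fit.free_peak.label == "free"
        bound_ok = fit.bound_peak.label == "bound"
        rows.append(
            {
                "condition_id": cid,
                "free": fit.free_peak.area if free_ok else 0.0,
                "bound": fit.bound_peak.area if bound_ok else 0.0,
                "missing": ("" if free_ok else "free ") + ("" if bound_ok else "bound"),
            }
        )
    df = pd.DataFrame(rows).set_index("condition_id")
    if concentrations is not None:
        order = sorted(df.index, key=lambda cid: concentrations[cid])
        df = df.loc[order]
        df.insert(0, "aptamer_conc", [concentrations[c] for c in df.index])
    return df


def render_heatmap(matrix: pd.DataFrame, path) -> None:
    """Save a free/bound area heatmap image (matplotlib, Agg backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix[["free", "bound"]].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(4, 0.5 * len(matrix) + 1.5))
    im = ax.imshow(data, aspect="auto", cmap="viridis")
    ax.set_xticks([0, 1], ["free", "bound"])
    ax.set_yticks(range(len(matrix)), matrix.index)
    ax.set_xlabel("peak")
    fig.colorbar(im, ax=ax, label="peak area (dF/dT · °C)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def calibration_fit(x, y) -> CalibrationFit:
    """Ordinary least-squares calibration line with r^2 = 1 - SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if len(x) < 2:
        raise ValueError("calibration requires >= 2 points")
    if np.ptp(x) == 0:
        raise ValueError("x values must not all be equal")
    res = linregress(x, y)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(x),
    )


def fits_to_frame(fits: dict[str, TwoPeakFit]) -> pd.DataFrame:
    """Tidy per-condition summary table (for CSV export)."""
    rows = []
    for cid, fit in fits.items():
        ratio = bound_ratio(fit) if fit.converged else None
        for peak in (fit.free_peak, fit.bound_peak):
            rows.append(
                {
                    "condition_id": cid,
                    "label": peak.label,
                    "tm": peak.tm,
                    "height": peak.height,
                    "area": peak.area,
                    "bound_ratio": ratio,
                    "converged": fit.converged,
                    "residual_norm": fit.residual_norm,
                }
            )
    return pd.DataFrame(rows)
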