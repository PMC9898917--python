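"""Extraction of melting and aggregation-onset temperatures from scans.

Covers the three temperature-ramp read-outs of a combined nanoDSF/DLS
instrument:

* the intrinsic-fluorescence ratio I350/I330 of a melt scan, whose
  first-derivative maximum defines the melting temperature Tm;
* the DLS cumulant hydrodynamic radius, whose departure from the baseline
  defines the aggregation-onset temperature Tagg (first temperature at
  which a full sigmoidal fit and a baseline linear extrapolation differ by
  more than 0.5 percent);
* the back-reflection turbidity of the capillary heat test for free light
  chains (Bence-Jones test), summarised by the temperature of maximal
  turbidity and whether the turbidity partly reverses on further heating.

Concentration dependencies of Tm and Tagg are summarised as the slope of a
linear fit against log10(concentration), in deg C per decade.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

__all__ = [
    "MeltCurve",
    "DlsTrace",
    "TurbidityTrace",
    "OnsetResult",
    "TurbidityResult",
    "NoTransitionError",
    "find_tm",
    "find_tagg",
    "logconc_slope",
    "turbidity_maximum",
]


class NoTransitionError(RuntimeError):
    """Raised when a melt curve shows no resolvable unfolding transition."""


@dataclass
class MeltCurve:
    """One capillary's melt scan: temperature grid and two emission channels."""

    T: np.ndarray
    i330: np.ndarray
    i350: np.ndarray
    conc_uM: float = np.nan
    urea_M: float = 0.0
    capillary_id: str = ""
    sample_id: str = ""
    scan_rate: float = 1.0  # deg C / min

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.i330 = np.asarray(self.i330, dtype=float)
        self.i350 = np.asarray(self.i350, dtype=float)
        if not (len(self.T) == len(self.i330) == len(self.i350)):
            raise ValueError("T, i330 and i350 must have equal length")
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("temperature grid must be strictly increasing")

    @property
    def ratio(self) -> np.ndarray:
        """Fluorescence emission ratio I350/I330."""
        return self.i350 / self.i330


@dataclass
class DlsTrace:
    """Cumulant hydrodynamic radius (nm) vs temperature for one sample."""

    T: np.ndarray
    radius: np.ndarray
    conc_uM: float = np.nan
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if len(self.T) != len(self.radius):
            raise ValueError("T and radius must have equal length")
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("temperature grid must be strictly increasing")


@dataclass
class TurbidityTrace:
    """Back-reflection turbidity vs temperature (heat test scan)."""

    T: np.ndarray
    turbidity: np.ndarray
    conc_uM: float = np.nan
    pH: float = 5.0

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.turbidity = np.asarray(self.turbidity, dtype=float)
        if len(self.T) != len(self.turbidity):
            raise ValueError("T and turbidity must have equal length")


@dataclass
class OnsetResult:
    """Aggregation-onset detection outcome.

    ``T_onset`` is None when no onset was detected (flat trace or
    non-convergent sigmoid fit); ``linear_fit`` is (intercept, slope) of
    the baseline extrapolation and ``sigmoid_fit`` the sigmoidal model's
    parameters (intercept, slope, amplitude, centre, width) — a linear
    baseline plus logistic growth.
    """

    T_onset: float | None
    linear_fit: tuple[float, float] | None = None
    sigmoid_fit: tuple[float, ...] | None = None
    divergence_threshold: float = 0.005
    message: str = ""

    @property
    def detected(self) -> bool:
        return self.T_onset is not None


@dataclass
class TurbidityResult:
    T_max: float | None
    reversible: bool
    detected: bool
    at_scan_end: bool = False

    @property
    def category(self) -> str:
        """Coarse label as used in fingerprint tables."""
        if not self.detected:
            return "No turb."
        if self.at_scan_end:
            return f"> {self.T_max:.0f}"
        return f"{self.T_max:.0f}"


def _smooth(y: np.ndarray, T: np.ndarray, window_degC: float, deriv: int = 0) -> np.ndarray:
    """Local quadratic (Savitzky-Golay) smoothing over a temperature span."""
    dT = float(np.median(np.diff(T)))
    w = max(5, int(round(window_degC / dT)) | 1)  # odd, at least 5 points
    w = min(w, len(y) - (1 - len(y) % 2))  # never exceed data length
    if w <= 3:
        w = min(5, len(y) | 1)
    return savgol_filter(y, window_length=w, polyorder=2, deriv=deriv, delta=dT)


def _robust_noise(y: np.ndarray) -> float:
    """Noise SD estimate from the MAD of first differences."""
    d = np.diff(y)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def find_tm(curve: MeltCurve, smooth_window: float = 2.0) -> float:
    """Melting temperature from the derivative maximum of the I350/I330 ratio.

    The ratio is smoothed with a local quadratic filter spanning
    ``smooth_window`` deg C, differentiated, and the derivative maximum is
    refined by a quadratic interpolation through its three nearest grid
    points.  A flat curve (dynamic range below five times the point-to-point
    noise) raises :class:`NoTransitionError`.
    """
    if len(curve.T) < 20:
        raise ValueError("need at least 20 points across the transition")
    ratio = curve.ratio
    smoothed = _smooth(ratio, curve.T, smooth_window)
    noise = _robust_noise(ratio)
    if smoothed.max() - smoothed.min() < 5.0 * max(noise, 1e-12):
        raise NoTransitionError(
            f"no unfolding transition resolved for {curve.sample_id or 'curve'}"
        )
    deriv = _smooth(ratio, curve.T, smooth_window, deriv=1)
    k = int(np.argmax(deriv))
    if k == 0 or k == len(deriv) - 1:
        return float(curve.T[k])
    # refine by a quadratic over the points within +-smooth_window of the
    # maximum: averages residual noise instead of trusting 3 grid points
    sel = np.abs(curve.T - curve.T[k]) <= smooth_window
    if sel.sum() < 3:
        sel = slice(k - 1, k + 2)
    x = curve.T[sel]
    y = deriv[sel]
    a, b, _ = np.polyfit(x, y, 2)
    if a >= 0:
        return float(curve.T[k])
    vertex = -b / (2.0 * a)
    if not (x[0] <= vertex <= x[-1]):
        return float(curve.T[k])
    return float(vertex)


def _baseline_logistic(T, intercept, slope, amplitude, centre, width):
    """Linear baseline plus logistic growth — the aggregation-trace model."""
    return intercept + slope * T + amplitude / (1.0 + np.exp(-(T - centre) / width))


def find_tagg(
    trace: DlsTrace,
    threshold: float = 0.005,
    baseline_fraction: float = 0.25,
) -> OnsetResult:
    """Aggregation onset from divergence of sigmoid and baseline fits.

    A straight line is fitted to the baseline region (first
    ``baseline_fraction`` of the temperature span) and extrapolated across
    the scan; a sigmoidal model — the same linear baseline form plus a
    logistic growth term — is fitted to the whole trace.  The onset is the
    lowest temperature at which the sigmoidal model first exceeds its own
    baseline component by more than ``threshold`` (relative, default 0.5
    percent), located on a dense temperature grid.  Sharing the baseline
    form between the two fits makes the crossing a property of the fitted
    growth rather than of noise-level offsets between independent fits.
    """
    T, r = trace.T, trace.radius
    if len(T) < 20:
        raise ValueError("need at least 20 points for onset detection")
    span = T[-1] - T[0]
    base_sel = T <= T[0] + baseline_fraction * span
    if base_sel.sum() < 3:
        base_sel = np.zeros_like(base_sel)
        base_sel[:3] = True
    slope, intercept = np.polyfit(T[base_sel], r[base_sel], 1)

    noise = _robust_noise(r)
    baseline_level = float(np.median(r[base_sel]))
    if r.max() - baseline_level < 5.0 * max(noise, 1e-9 * max(baseline_level, 1.0)):
        return OnsetResult(
            None,
            linear_fit=(float(intercept), float(slope)),
            divergence_threshold=threshold,
            message="flat trace: no aggregation growth detected",
        )

    amp0 = r.max() - baseline_level
    centre0 = float(T[np.argmin(np.abs(r - (baseline_level + amp0 / 2.0)))])
    p0 = [float(intercept), float(slope), amp0, centre0, max(span / 20.0, 0.5)]
    try:
        popt, _ = curve_fit(
            _baseline_logistic,
            T,
            r,
            p0=p0,
            maxfev=20000,
            bounds=(
                [-np.inf, -np.inf, 0.0, T[0] - span, 1e-3],
                [np.inf, np.inf, np.inf, T[-1] + span, span],
            ),
        )
    except RuntimeError as exc:
        return OnsetResult(
            None,
            linear_fit=(float(intercept), float(slope)),
            divergence_threshold=threshold,
            message=f"sigmoid fit did not converge: {exc}",
        )

    fine = np.linspace(T[0], T[-1], max(2000, 20 * len(T)))
    lin = popt[0] + popt[1] * fine  # the sigmoidal model's own baseline
    sig = _baseline_logistic(fine, *popt)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(sig - lin) / np.abs(lin)
    crossing = np.nonzero(rel > threshold)[0]
    if len(crossing) == 0:
        return OnsetResult(
            None,
            linear_fit=(float(intercept), float(slope)),
            sigmoid_fit=tuple(float(v) for v in popt),
            divergence_threshold=threshold,
            message="fits never diverge beyond threshold within the scan",
        )
    return OnsetResult(
        float(fine[crossing[0]]),
        linear_fit=(float(intercept), float(slope)),
        sigmoid_fit=tuple(float(v) for v in popt),
        divergence_threshold=threshold,
    )


def logconc_slope(values: Sequence[float], concs: Sequence[float]) -> float:
    """Slope of Tm or Tagg against log10(concentration), deg C per decade.

    The dependence of unfolding and onset temperatures on protein
    concentration is close to linear on a log scale, so a single
    least-squares slope summarises the whole explored range.  Units of the
    concentration cancel (only the decade scale matters).
    """
    values = np.asarray(values, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 concentration points")
    if np.any(concs <= 0):
        raise ValueError("concentrations must be positive")
    slope, _ = np.polyfit(np.log10(concs), values, 1)
    return float(slope)


def turbidity_maximum(
    trace: TurbidityTrace,
    smooth_window: float = 2.0,
    noise_floor_factor: float = 5.0,
) -> TurbidityResult:
    """Temperature of maximal turbidity and reversibility of the heat test.

    Returns the location of the smoothed turbidity maximum.  The result is
    flagged "no turbidity" when the dynamic range stays below
    ``noise_floor_factor`` times a robust noise estimate, and "at scan end"
    (the "> 90" style category) when the turbidity is still rising at the
    final temperature.  Reversibility means the final turbidity dropped
    below half of the maximum rise above the starting baseline.
    """
    T, y = trace.T, trace.turbidity
    if T[-1] - T[0] < 40.0:
        raise ValueError("turbidity scan must span at least 40 deg C")
    smoothed = _smooth(y, T, smooth_window)
    noise = _robust_noise(y)
    baseline = float(np.median(smoothed[: max(3, len(y) // 10)]))
    rng = smoothed.max() - smoothed.min()
    if rng < noise_floor_factor * max(noise, 1e-12):
        return TurbidityResult(None, reversible=False, detected=False)
    k = int(np.argmax(smoothed))
    at_end = k >= len(T) - 2
    rise = smoothed[k] - baseline
    reversible = (not at_end) and (smoothed[-1] - baseline) < 0.5 * rise
    return TurbidityResult(
        float(T[k]), reversible=reversible, detected=True, at_scan_end=at_end
    )
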