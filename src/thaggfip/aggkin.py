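"""Amyloid aggregation kinetics from thioflavin-T (ThT) fluorescence traces.

Each trace is fitted individually with a generic sigmoid with sloped
baselines,

    Y(t) = y_i + m_i*t + (y_f + m_f*t) / (1 + exp(-(t - t50)/k)),

where ``y_i + m_i t`` is the pre-aggregation baseline, ``y_f + m_f t`` the
amplitude of the final plateau (on top of the initial baseline), ``t50``
the halftime at which half of the maximal ThT signal gain is reached and
``k`` the transition time constant.  The equation is phenomenological: it
yields the halftime without claiming anything about the underlying
nucleation/elongation mechanism.

Two scalar summaries accompany the fit: the fold increase of the ThT
signal (final intensity over the trace minimum) and the aggregated
fraction from depletion of soluble protein, measured as A280 of the
supernatant after pelleting and corrected for the absorbance of the ThT
dye itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lmfit import Model

__all__ = [
    "ThtTrace",
    "SigmoidalFit",
    "sigmoid_model",
    "fit_sigmoid",
    "fold_increase",
    "aggregated_fraction",
]


@dataclass
class ThtTrace:
    """One well's ThT fluorescence time course."""

    t: np.ndarray  # hours
    intensity: np.ndarray  # arbitrary fluorescence units
    sample_id: str = ""
    conc_uM: float = np.nan
    pH: float = 3.0
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.t) != len(self.intensity):
            raise ValueError("t and intensity must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


@dataclass
class SigmoidalFit:
    """Fitted sigmoid parameters for one trace.

    ``t50_crossing`` is a diagnostic: the time at which the fitted curve
    crosses halfway between the two baselines, which can differ slightly
    from the fitted ``t50`` parameter when the baselines slope.
    """

    y_i: float
    m_i: float
    y_f: float
    m_f: float
    t50: float
    k: float
    rss: float = np.nan
    t50_crossing: float | None = None

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("transition time constant k must be positive")

    def __call__(self, t):
        return sigmoid_model(t, self.y_i, self.m_i, self.y_f, self.m_f, self.t50, self.k)


def sigmoid_model(t, y_i, m_i, y_f, m_f, t50, k):
    """Sigmoid with sloped baselines; see module docstring."""
    t = np.asarray(t, dtype=float)
    z = np.clip(-(t - t50) / k, -500, 500)
    return y_i + m_i * t + (y_f + m_f * t) / (1.0 + np.exp(z))


def _robust_noise(y: np.ndarray) -> float:
    d = np.diff(y)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def _guesses(t: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Start values from trace geometry.

    Initial baseline from the first tenth of points, plateau from the last
    tenth, t50 from the first crossing of the mid intensity, k as 5 percent
    of the observed span.
    """
    n = len(t)
    head = slice(0, max(2, n // 10))
    tail = slice(n - max(2, n // 10), n)
    m_i, y_i = np.polyfit(t[head], y[head], 1)
    m_tail, y_tail = np.polyfit(t[tail], y[tail], 1)
    t_mid = 0.5 * (t[0] + t[-1])
    y_f = (y_tail + m_tail * t_mid) - (y_i + m_i * t_mid)
    mid = 0.5 * (np.min(y) + np.max(y))
    above = np.nonzero(y >= mid)[0]
    t50 = float(t[above[0]]) if len(above) else t_mid
    span = t[-1] - t[0]
    return {
        "y_i": float(y_i),
        "m_i": float(m_i),
        "y_f": float(y_f),
        "m_f": float(m_tail - m_i),
        "t50": t50,
        "k": max(0.05 * span, 1e-3),
    }


def fit_sigmoid(
    trace: ThtTrace,
    noise_floor_factor: float = 3.0,
    n_restarts: int = 8,
    seed: int = 0,
) -> SigmoidalFit | None:
    """Fit the sigmoid to one trace; ``None`` flags "no aggregation".

    A trace whose dynamic range stays below ``noise_floor_factor`` times a
    robust noise estimate is flagged as non-aggregating and not fitted.
    On failure of the geometric start, up to ``n_restarts`` jittered
    restarts are attempted before raising.
    """
    t, y = trace.t, trace.intensity
    if len(t) < 15:
        raise ValueError("need at least 15 time points")
    # smoothing suppresses the spurious range of pure noise so the dynamic
    # range is compared against the noise floor at the signal's own scale
    width = max(5, len(y) // 20)
    kernel = np.ones(width) / width
    smoothed = np.convolve(y, kernel, mode="valid")
    rng_span = float(np.max(smoothed) - np.min(smoothed))
    if rng_span < noise_floor_factor * max(_robust_noise(y), 1e-12):
        return None

    model = Model(sigmoid_model)
    span = t[-1] - t[0]
    g = _guesses(t, y)
    params = model.make_params(**g)
    params["k"].set(min=1e-6 * span)
    params["t50"].set(min=t[0] - span, max=t[-1] + span)

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(n_restarts + 1):
        p = params.copy()
        if attempt > 0:
            p["t50"].value = g["t50"] + rng.normal(0, 0.2 * span)
            p["k"].value = g["k"] * np.exp(rng.normal(0, 1.0))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(y, p, t=t)
        except Exception:
            continue
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise RuntimeError(
            f"sigmoid fit failed after {n_restarts} restarts for "
            f"{trace.sample_id or 'trace'}"
        )
    v = best.params.valuesdict()
    fit = SigmoidalFit(
        y_i=v["y_i"],
        m_i=v["m_i"],
        y_f=v["y_f"],
        m_f=v["m_f"],
        t50=v["t50"],
        k=abs(v["k"]),
        rss=float(best.chisqr),
    )
    fit.t50_crossing = _half_crossing(fit, t)
    return fit


def _half_crossing(fit: SigmoidalFit, t: np.ndarray) -> float | None:
    """Time where the fitted curve is halfway between its baselines."""
    fine = np.linspace(t[0], t[-1], 4000)
    curve = fit(fine)
    init = fit.y_i + fit.m_i * fine
    amp = fit.y_f + fit.m_f * fine
    frac = np.where(np.abs(amp) > 1e-300, (curve - init) / amp, np.nan)
    above = np.nonzero(frac >= 0.5)[0]
    if len(above) == 0 or above[0] == 0:
        return None
    i = above[0]
    # linear interpolation between bracketing points
    x0, x1 = fine[i - 1], fine[i]
    f0, f1 = frac[i - 1], frac[i]
    if f1 == f0:
        return float(x1)
    return float(x0 + (0.5 - f0) * (x1 - x0) / (f1 - f0))


def fold_increase(trace: ThtTrace) -> float:
    """Final ThT intensity over the trace minimum.

    Deliberately uses the last reading rather than the peak: at high
    protein concentrations large insoluble aggregates sediment out of the
    detection volume and the signal declines after the plateau, and the
    end-of-experiment value is what enters the fingerprint.
    """
    m = float(np.min(trace.intensity))
    if m <= 0:
        raise ValueError("trace minimum must be positive to form a ratio")
    return float(trace.intensity[-1]) / m


def aggregated_fraction(
    a280_initial: float,
    a280_supernatant: float,
    tht_blank_a280: float = 0.0,
    tolerance: float = 0.05,
) -> float:
    """Aggregated protein fraction from soluble-content depletion.

    ``1 - (A280_sup - A280_ThT) / (A280_init - A280_ThT)`` where the blank
    corrects for the absorbance of the ThT dye.  Values slightly outside
    [0, 1] (within ``tolerance`` of the denominator) are clipped with a
    warning; larger violations raise.
    """
    denom = a280_initial - tht_blank_a280
    if denom <= 0:
        raise ValueError("initial A280 must exceed the ThT blank")
    num = a280_supernatant - tht_blank_a280
    frac = 1.0 - num / denom
    if frac < -tolerance or frac > 1.0 + tolerance:
        raise ValueError(
            f"aggregated fraction {frac:.3f} is outside [0, 1] beyond tolerance; "
            "check the blank correction"
        )
    if frac < 0.0 or frac > 1.0:
        warnings.warn(
            f"aggregated fraction {frac:.3f} clipped to [0, 1]", stacklevel=2
        )
        frac = float(np.clip(frac, 0.0, 1.0))
    return float(frac)


def summarize_halftimes(fits: Sequence[SigmoidalFit | None]) -> tuple[float, float, int]:
    """Mean, SD and count of halftimes over per-replicate fits.

    ``None`` entries (non-aggregating replicates) are skipped.
    """
    t50s = np.array([f.t50 for f in fits if f is not None], dtype=float)
    if len(t50s) == 0:
        return np.nan, np.nan, 0
    sd = float(np.std(t50s, ddof=1)) if len(t50s) > 1 else 0.0
    return float(np.mean(t50s)), sd, int(len(t50s))
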