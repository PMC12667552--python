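"""Bioluminescence-assay and enzyme-kinetics calculations.

Incorporation rates are measured through the pyrophosphate (PPi)
by-product of nucleotide addition: a luminescence standard curve converts
intensity to concentration, time courses give initial rates, and the
rates across substrate concentrations are fitted to the Michaelis–Menten
model V = Vmax.[S]/(Km + [S]), either by nonlinear least squares or
through the Lineweaver–Burk double-reciprocal linearization
(1/V = (Km/Vmax).(1/[S]) + 1/Vmax). Scaffold comparisons are summarised
as percentage parameter gains, and donor-quenching FRET efficiency is
E = 1 - I_DA/I_D.

Rates may be left in luminescence units (a.u./s) or converted to uM/s
via the standard curve; Km and the gains are invariant to that choice.
kcat = Vmax / [E] requires a molar enzyme concentration from the caller —
no default conversion from mass concentration is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "StandardCurve",
    "TimeCourse",
    "KineticFit",
    "GainReport",
    "fit_standard_curve",
    "compute_recovery",
    "initial_rate",
    "michaelis_menten",
    "fit_michaelis_menten",
    "parameter_gain",
    "fret_efficiency",
]


@dataclass(frozen=True)
class StandardCurve:
    """Linear luminescence-vs-concentration calibration."""

    slope: float
    intercept: float
    r_squared: float
    valid_range: tuple[float, float]

    def to_concentration(self, intensity: float | np.ndarray) -> float | np.ndarray:
        """Invert the curve: concentration producing a given intensity."""
        return (np.asarray(intensity) - self.intercept) / self.slope


@dataclass(frozen=True)
class TimeCourse:
    """Luminescence readings over time at one substrate concentration."""

    times: tuple[float, ...]
    intensities: tuple[float, ...]
    substrate_conc: float

    def __post_init__(self) -> None:
        if len(self.times) != len(self.intensities):
            raise ValueError("times and intensities must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class KineticFit:
    """Michaelis–Menten parameters for one nucleotide/scaffold condition.

    Km in uM; Vmax in the rate units supplied (a.u./s or uM/s); kcat in
    1/s when an enzyme concentration was given, else None; efficiency is
    kcat/Km (or Vmax/Km when kcat is unavailable, in rate units per uM).
    """

    Km: float
    Vmax: float
    method: str
    kcat: float | None = None
    r_squared: float | None = None

    @property
    def efficiency(self) -> float:
        return (self.kcat if self.kcat is not None else self.Vmax) / self.Km


@dataclass(frozen=True)
class GainReport:
    """Percentage improvement of one kinetic parameter between scaffolds."""

    parameter: str
    baseline_value: float
    improved_value: float
    gain_percent: float


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0  # constant signal fitted exactly
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def fit_standard_curve(
    concentrations: Sequence[float], intensities: Sequence[float]
) -> StandardCurve:
    """Ordinary least-squares line through (concentration, intensity) points."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if x.size < 3:
        raise ValueError("standard curve needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in concentrations")
    res = stats.linregress(x, y)
    yhat = res.slope * x + res.intercept
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=_r_squared(y, yhat),
        valid_range=(float(x.min()), float(x.max())),
    )


def compute_recovery(measured_conc: float, spiked_conc: float) -> float:
    """Spike recovery in percent: 100 x measured / spiked."""
    if spiked_conc <= 0:
        raise ValueError("spiked concentration must be positive")
    return 100.0 * measured_conc / spiked_conc


def initial_rate(tc: TimeCourse, min_points: int = 3, r2_threshold: float = 0.999) -> float:
    """Slope of the initial linear phase of a time course.

    The longest prefix of at least ``min_points`` points whose linear fit
    reaches ``r2_threshold`` is used; if none qualifies the first
    ``min_points`` points are used. The default threshold is strict
    (0.999) so that curvature from substrate depletion does not flatten
    the estimate on saturating courses.
    """
    t = np.asarray(tc.times, dtype=float)
    y = np.asarray(tc.intensities, dtype=float)
    if t.size < min_points:
        raise ValueError(f"time course needs at least {min_points} points")
    best_slope: float | None = None
    for k in range(min_points, t.size + 1):
        res = stats.linregress(t[:k], y[:k])
        r2 = _r_squared(y[:k], res.slope * t[:k] + res.intercept)
        if r2 >= r2_threshold:
            best_slope = float(res.slope)
    if best_slope is None:
        res = stats.linregress(t[:min_points], y[:min_points])
        best_slope = float(res.slope)
    return best_slope


def michaelis_menten(s: np.ndarray | float, Vmax: float, Km: float) -> np.ndarray | float:
    """V = Vmax.[S] / (Km + [S])."""
    s = np.asarray(s, dtype=float)
    return Vmax * s / (Km + s)


def fit_michaelis_menten(
    concentrations: Sequence[float],
    rates: Sequence[float],
    method: str = "nonlinear",
    enzyme_conc: float | None = None,
    rate_sigma: Sequence[float] | None = None,
) -> KineticFit:
    """Fit (Km, Vmax) to rates measured across substrate concentrations.

    ``method`` is ``"nonlinear"`` (least squares on the hyperbola,
    initialized at Km = median([S]), Vmax = max(V)) or
    ``"lineweaver_burk"`` (OLS of 1/V on 1/[S]; slope Km/Vmax, intercept
    1/Vmax). Replicate measurements are passed as repeated concentration
    entries. ``rate_sigma`` supplies per-point rate uncertainties for the
    nonlinear mode; luminescence noise typically scales with the signal,
    so weights proportional to the rate are the usual choice. When
    ``enzyme_conc`` (same concentration units as Km's uM scale is not
    required — any molar unit) is given, kcat = Vmax/[E].
    """
    s = np.asarray(concentrations, dtype=float)
    v = np.asarray(rates, dtype=float)
    if s.size != v.size:
        raise ValueError("concentrations and rates must have equal length")
    if s.size < 4:
        raise ValueError("need rates at >= 4 substrate concentrations")
    if np.any(s <= 0):
        raise ValueError("substrate concentrations must be positive")

    if method == "nonlinear":
        p0 = (float(v.max()), float(np.median(s)))
        sigma = None if rate_sigma is None else np.asarray(rate_sigma, dtype=float)
        try:
            popt, _ = optimize.curve_fit(
                michaelis_menten, s, v, p0=p0, sigma=sigma, maxfev=10000
            )
        except RuntimeError as exc:
            raise RuntimeError(f"Michaelis-Menten fit did not converge: {exc}") from exc
        Vmax, Km = float(popt[0]), float(popt[1])
        if Km <= 0 or Vmax <= 0:
            raise RuntimeError(
                f"non-physical fit (Km={Km:.4g}, Vmax={Vmax:.4g}); "
                "check rate data spans concentrations around Km"
            )
        r2 = _r_squared(v, np.asarray(michaelis_menten(s, Vmax, Km)))
    elif method == "lineweaver_burk":
        if np.any(v <= 0):
            raise ValueError("non-positive rates: reciprocal undefined in LB mode")
        res = stats.linregress(1.0 / s, 1.0 / v)
        if res.intercept <= 0:
            raise RuntimeError(
                f"LB intercept {res.intercept:.4g} <= 0: no physical Vmax"
            )
        Vmax = 1.0 / float(res.intercept)
        Km = float(res.slope) * Vmax
        r2 = _r_squared(1.0 / v, res.slope / s + res.intercept)
    else:
        raise ValueError(f"unknown method {method!r}")

    kcat = Vmax / enzyme_conc if enzyme_conc else None
    return KineticFit(Km=Km, Vmax=Vmax, method=method, kcat=kcat, r_squared=r2)


_HIGHER_IS_BETTER = {"Km": False, "kcat": True, "efficiency": True}


def parameter_gain(ss_value: float, tdn_value: float, parameter: str) -> GainReport:
    """Percentage gain of the scaffolded condition over the baseline.

    For Km (an affinity constant, lower is better) the gain is
    100.(ss - tdn)/ss; for kcat and efficiency (higher is better) it is
    100.(tdn - ss)/ss.
    """
    if parameter not in _HIGHER_IS_BETTER:
        raise ValueError(f"parameter must be one of {sorted(_HIGHER_IS_BETTER)}")
    if ss_value <= 0 or tdn_value <= 0:
        raise ValueError("kinetic parameter values must be positive")
    if _HIGHER_IS_BETTER[parameter]:
        gain = 100.0 * (tdn_value - ss_value) / ss_value
    else:
        gain = 100.0 * (ss_value - tdn_value) / ss_value
    return GainReport(parameter, ss_value, tdn_value, gain)


def fret_efficiency(I_DA: float, I_D: float) -> float:
    """FRET efficiency E = 1 - I_DA/I_D from donor intensities."""
    if I_D <= 0:
        raise ValueError("donor-only intensity I_D must be positive")
    if I_DA < 0:
        raise ValueError("I_DA must be non-negative")
    return 1.0 - I_DA / I_D
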