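"""Kinetic models and fits.

Covers the four analyses used downstream of the gel quantification:

* initial rates normalised per nM of motor protein,
* first-order progress curves ``y0 + A*(1 - exp(-k t))`` with half-times,
* single-exponential nucleosome-sliding fits (same functional form,
  separate model label because the observable differs),
* Michaelis-Menten substrate-saturation fits of ATPase rates with basal
  correction, and relative-rate tables with propagated uncertainty.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import FitFailureError, ParameterError

__all__ = [
    "TimeCourse",
    "KineticFit",
    "InitialRate",
    "MichaelisMentenFit",
    "RelativeRate",
    "initial_rate",
    "fit_first_order",
    "fit_single_exponential",
    "fit_michaelis_menten",
    "relative_rate",
    "first_order_curve",
    "michaelis_menten_curve",
    "round_half_away",
]

LN2 = math.log(2.0)


@dataclass
class TimeCourse:
    """Observable sampled over time.

    ``values`` may be percent supercoiling, a spacing index, or a fraction
    of nucleosomes moved; ``observable`` labels which.
    """

    times: np.ndarray
    values: np.ndarray
    observable: str = ""
    protein_concentration: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ParameterError("times and values must be 1-D and equal length")
        if np.any(self.times < 0):
            raise ParameterError("times must be nonnegative")
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("values must be finite")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class KineticFit:
    """Result of a first-order / single-exponential progress-curve fit."""

    model: str
    k: float
    k_se: float
    amplitude: float
    amplitude_se: float
    y0: float
    y0_se: float
    half_time: float
    r_squared: float
    n_points: int

    def predict(self, t):
        return first_order_curve(np.asarray(t, dtype=float), self.y0, self.amplitude, self.k)


@dataclass
class InitialRate:
    """Least-squares initial slope, normalised per nM protein."""

    rate: float  # observable units / min / nM
    rate_se: float
    slope: float  # observable units / min
    slope_se: float
    n_points: int
    protein_concentration: float


@dataclass
class MichaelisMentenFit:
    kcat: float
    kcat_se: float
    km: float
    km_se: float
    basal_rate: float
    substrate_label: str = ""

    def predict(self, s):
        return michaelis_menten_curve(np.asarray(s, dtype=float), self.kcat, self.km)


@dataclass
class RelativeRate:
    """100 x (numerator / denominator) with quadrature error propagation."""

    numerator: float
    numerator_se: float
    denominator: float
    denominator_se: float
    percent: float = field(init=False)
    percent_se: float = field(init=False)

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ParameterError("denominator rate must be > 0")
        self.percent = 100.0 * self.numerator / self.denominator
        # written to stay finite when numerator == 0
        self.percent_se = math.sqrt(
            (100.0 * self.numerator_se / self.denominator) ** 2
            + (100.0 * self.numerator * self.denominator_se / self.denominator**2) ** 2
        )


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (decimal convention for printed tables).

    numpy rounds half to even, which disagrees with how measured values
    are conventionally reported.
    """
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def first_order_curve(t, y0, amplitude, k):
    return y0 + amplitude * (1.0 - np.exp(-k * np.asarray(t, dtype=float)))


def michaelis_menten_curve(s, kcat, km):
    s = np.asarray(s, dtype=float)
    return kcat * s / (km + s)


def initial_rate(tc: TimeCourse, n_points: int) -> InitialRate:
    """OLS slope over the first ``n_points``, divided by protein concentration."""
    if n_points > len(tc):
        raise ParameterError(f"n_points={n_points} exceeds available points ({len(tc)})")
    if n_points < 3:
        raise ParameterError("need at least 3 points for an initial-rate slope")
    if tc.protein_concentration is None:
        raise ParameterError("time course carries no protein concentration")
    if tc.protein_concentration <= 0:
        raise ParameterError("protein concentration must be > 0")
    t = tc.times[:n_points]
    y = tc.values[:n_points]
    res = stats.linregress(t, y)
    conc = tc.protein_concentration
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return InitialRate(
        rate=float(res.slope) / conc,
        rate_se=se / conc,
        slope=float(res.slope),
        slope_se=se,
        n_points=n_points,
        protein_concentration=conc,
    )


def _k_guesses(t: np.ndarray, y: np.ndarray) -> list[float]:
    """Initial rate-constant guesses: log-linear regression of the
    remaining amplitude, plus 0.5x and 2x perturbations. Deterministic."""
    amp = y.max() - y.min()
    y_inf = y.max() + 0.05 * amp
    w = y_inf - y
    mask = w > 1e-12 * max(amp, 1.0)
    k0 = None
    if mask.sum() >= 2 and np.ptp(t[mask]) > 0:
        slope = stats.linregress(t[mask], np.log(w[mask])).slope
        if np.isfinite(slope) and slope < 0:
            k0 = -float(slope)
    if k0 is None or k0 <= 0:
        # fall back to the reciprocal of the mid-range time
        tmid = t[t > 0]
        k0 = 1.0 / float(np.median(tmid)) if tmid.size else 1.0
    return [k0, 0.5 * k0, 2.0 * k0]


def _fit_rise(tc: TimeCourse, model: str) -> KineticFit:
    t, y = tc.times, tc.values
    if len(tc) < 4:
        raise ParameterError("need at least 4 points to fit a progress curve")
    amp0 = float(y.max() - y.min())
    scale = float(np.max(np.abs(y))) if np.max(np.abs(y)) > 0 else 1.0
    if amp0 <= 1e-12 * scale:
        raise FitFailureError(
            "amplitude is zero: no progress to fit",
            diagnostics={"amplitude_guess": amp0},
        )
    attempts = []
    best = None
    for kg in _k_guesses(t, y):
        p0 = (float(y[0]), amp0, kg)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    first_order_curve, t, y, p0=p0, maxfev=20000
                )
        except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
            attempts.append({"p0": p0, "error": str(exc)})
            continue
        if popt[2] <= 0 or not np.all(np.isfinite(popt)):
            attempts.append({"p0": p0, "error": "nonpositive or nonfinite rate"})
            continue
        ssr = float(np.sum((y - first_order_curve(t, *popt)) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        raise FitFailureError(
            "progress-curve fit did not converge from any start",
            diagnostics={"attempts": attempts},
        )
    ssr, popt, pcov = best
    y0, amplitude, k = (float(v) for v in popt)
    se = np.sqrt(np.abs(np.diag(pcov)))
    se = np.where(np.isfinite(se), se, 0.0)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    return KineticFit(
        model=model,
        k=k,
        k_se=float(se[2]),
        amplitude=amplitude,
        amplitude_se=float(se[1]),
        y0=y0,
        y0_se=float(se[0]),
        half_time=LN2 / k,
        r_squared=r2,
        n_points=len(tc),
    )


def fit_first_order(tc: TimeCourse) -> KineticFit:
    """Fit ``y = y0 + A*(1 - exp(-k t))`` by multi-start nonlinear least squares.

    Returns k and A with standard errors, the half-time ln2/k, and r^2
    against the fitted curve. Raises :class:`FitFailureError` (with the
    attempted starts) rather than returning silent defaults.
    """
    return _fit_rise(tc, "first_order")


def fit_single_exponential(tc: TimeCourse) -> KineticFit:
    """Same functional form as :func:`fit_first_order`; used for sliding
    time courses where the observable is the fraction of nucleosomes moved."""
    return _fit_rise(tc, "single_exponential")


def fit_michaelis_menten(
    substrate_nM,
    kobs_per_min,
    basal: float = 0.0,
    substrate_label: str = "",
) -> MichaelisMentenFit:
    """Fit basal-corrected rates to ``kobs = kcat*[S]/(Km+[S])``.

    ``basal`` (rate with no substrate) is subtracted from each observed
    rate before fitting, so the returned kcat is the stimulated turnover.
    """
    s = np.asarray(substrate_nM, dtype=float)
    v = np.asarray(kobs_per_min, dtype=float)
    if s.shape != v.shape or s.ndim != 1:
        raise ParameterError("substrate and rate arrays must be 1-D and equal length")
    if s.size < 4:
        raise ParameterError("need at least 4 substrate concentrations")
    if np.any(s < 0):
        raise ParameterError("substrate concentrations must be >= 0")
    if basal < 0:
        raise ParameterError("basal rate must be >= 0")
    if np.any(s > 500.0):
        warnings.warn(
            "substrate concentration above 500 nM is beyond the validated assay range",
            stacklevel=2,
        )
    corrected = v - basal
    if np.all(corrected <= 0):
        raise FitFailureError(
            "all basal-corrected rates are <= 0",
            diagnostics={"basal": basal, "kobs": v.tolist()},
        )
    vmax0 = float(corrected.max())
    half = vmax0 / 2.0
    above = s[corrected >= half]
    km0 = float(above.min()) if above.size and above.min() > 0 else float(np.median(s[s > 0]))
    best = None
    attempts = []
    for p0 in [(vmax0 * 1.2, km0), (vmax0 * 1.2, 0.5 * km0), (vmax0 * 2.0, 2.0 * km0)]:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    michaelis_menten_curve, s, corrected, p0=p0, maxfev=20000
                )
        except RuntimeError as exc:  # pragma: no cover
            attempts.append({"p0": p0, "error": str(exc)})
            continue
        if popt[0] <= 0 or popt[1] <= 0 or not np.all(np.isfinite(popt)):
            attempts.append({"p0": p0, "error": "nonpositive parameters"})
            continue
        ssr = float(np.sum((corrected - michaelis_menten_curve(s, *popt)) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        raise FitFailureError(
            "Michaelis-Menten fit did not converge", diagnostics={"attempts": attempts}
        )
    _, popt, pcov = best
    se = np.sqrt(np.abs(np.diag(pcov)))
    se = np.where(np.isfinite(se), se, 0.0)
    return MichaelisMentenFit(
        kcat=float(popt[0]),
        kcat_se=float(se[0]),
        km=float(popt[1]),
        km_se=float(se[1]),
        basal_rate=basal,
        substrate_label=substrate_label,
    )


def relative_rate(
    mutant: float, mutant_se: float, wild_type: float, wild_type_se: float
) -> RelativeRate:
    """Percent rate of a variant relative to wild type.

    SE propagated in quadrature on the relative errors:
    ``SE% = percent * sqrt((SEm/m)^2 + (SEw/w)^2)``.
    """
    return RelativeRate(
        numerator=mutant,
        numerator_se=mutant_se,
        denominator=wild_type,
        denominator_se=wild_type_se,
    )
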