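"""Rhythm quantification and temperature-compensation analysis.

Period, phase and amplitude are estimated by nonlinear least-squares
fitting of a cosine (optionally extended to a Fourier series with up to
three harmonics):

    y(t) = m + sum_{k=1..K} a_k cos(2*pi*k*t/T + phi_k)

with the period T shared across harmonics and initialized from the
dominant discrete-Fourier peak.  Temperature compensation is quantified
on the Arrhenius plot of cycle frequency: ln(24/period) is regressed on
1/T_K, the slope gives the activation energy E_a = -slope * R, and Q10 —
the factor by which the cycle frequency accelerates between 30 and
40 deg C — follows from E_a.  A temperature-compensated clock has Q10
near 1; an uncompensated chemical rate doubles (Q10 = 2, E_a =
13.1 kcal/mol between 30 and 40 deg C).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .containers import AbundanceTimeCourse, PhosphoFractionTrace
from .states import ValidationError

__all__ = [
    "RhythmFit",
    "ArrheniusFit",
    "GAS_CONSTANT_KCAL",
    "phosphorylated_fraction",
    "fit_period",
    "amplitude_minmax",
    "arrhenius_fit",
    "ea_to_q10",
    "q10_to_ea",
]

#: Gas constant in kcal / (mol K).
GAS_CONSTANT_KCAL = 1.987e-3


def _kelvin(t_celsius: float) -> float:
    return t_celsius + 273.15


@dataclass
class RhythmFit:
    """Result of the harmonic cosine fit.

    ``arrhythmic`` is set (and ``period`` is None) when the fundamental
    amplitude is indistinguishable from noise (a_1 < 2 x its SE) or the
    trace carries no variance at all.
    """

    period: Optional[float]          # h
    period_se: Optional[float] = None
    amplitudes: tuple = ()           # a_k per harmonic, signal units
    phases: tuple = ()               # phi_k, rad
    mean_level: float = 0.0
    n_harmonics: int = 1
    residual_sd: float = 0.0
    arrhythmic: bool = False

    def predict(self, times) -> np.ndarray:
        if self.period is None:
            raise ValidationError("arrhythmic fit has no periodic component")
        t = np.asarray(times, dtype=float)
        y = np.full(t.shape, self.mean_level)
        for k, (a, phi) in enumerate(zip(self.amplitudes, self.phases), start=1):
            y = y + a * np.cos(2 * np.pi * k * t / self.period + phi)
        return y


@dataclass
class ArrheniusFit:
    """Arrhenius regression of cycle frequency on reciprocal temperature."""

    e_a: float                       # kcal/mol
    e_a_se: float
    ln_pre_exponential: float
    q10: float
    t1_celsius: float = 30.0
    t2_celsius: float = 40.0
    gas_constant: float = GAS_CONSTANT_KCAL
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = ea_to_q10(self.e_a, self.t1_celsius, self.t2_celsius)
        if not np.isclose(self.q10, expected, rtol=0, atol=1e-9):
            raise ValidationError(
                f"q10 {self.q10} inconsistent with e_a {self.e_a} "
                f"(expected {expected})"
            )


def phosphorylated_fraction(abund: AbundanceTimeCourse) -> PhosphoFractionTrace:
    """Fraction of phosphorylated KaiC: A_SpT + A_pSpT + A_pST = 1 - A_ST
    (ST is the only unphosphorylated state)."""
    frac = 1.0 - abund.state("ST")
    return PhosphoFractionTrace(times=abund.times.copy(), fraction=frac)


def _fft_period_guess(times: np.ndarray, values: np.ndarray) -> float:
    """Dominant non-zero frequency of the detrended signal, assuming a
    near-uniform grid (median spacing)."""
    dt = float(np.median(np.diff(times)))
    y = values - values.mean()
    spec = np.abs(np.fft.rfft(y))
    freqs = np.fft.rfftfreq(values.size, d=dt)
    k = int(np.argmax(spec[1:])) + 1
    return 1.0 / freqs[k]


def _harmonic_model(t, period, mean, *coeffs):
    y = np.full(np.shape(t), mean, dtype=float)
    for k in range(len(coeffs) // 2):
        w = 2 * np.pi * (k + 1) * np.asarray(t) / period
        y = y + coeffs[2 * k] * np.cos(w) + coeffs[2 * k + 1] * np.sin(w)
    return y


def fit_period(
    times,
    values,
    n_harmonics: int = 1,
    detrend: bool = False,
    period_guess: Optional[float] = None,
) -> RhythmFit:
    """Fit the harmonic cosine model and report period +/- SE.

    Requires at least 12 points spanning at least two putative periods.
    ``detrend`` removes a linear trend first.  ``period_guess`` overrides
    the discrete-Fourier initialization.
    """
    if n_harmonics not in (1, 2, 3):
        raise ValidationError("n_harmonics must be 1, 2 or 3")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size != values.size:
        raise ValidationError("times and values must have equal length")
    if times.size < 12:
        raise ValidationError(f"need >= 12 points, got {times.size}")
    if detrend:
        slope, intercept = np.polyfit(times, values, 1)
        values = values - (slope * times + intercept)
    if np.ptp(values) == 0 or np.std(values) < 1e-14 * max(1.0, abs(values.mean())):
        return RhythmFit(period=None, arrhythmic=True,
                         mean_level=float(values.mean()),
                         n_harmonics=n_harmonics)
    span = times[-1] - times[0]
    if period_guess is not None:
        t0 = period_guess
        if span < 2 * t0:
            raise ValidationError(
                f"time span {span:g} h covers fewer than two putative periods "
                f"({t0:g} h each)"
            )
    else:
        # clamp the automatic guess so fewer than two apparent cycles
        # (e.g. a noise-dominated spectrum) flows into the amplitude test
        # rather than aborting
        t0 = min(_fft_period_guess(times, values), span / 2.0)
    # linear init of the harmonic coefficients at the guessed period
    cols = [np.ones_like(times)]
    for k in range(1, n_harmonics + 1):
        w = 2 * np.pi * k * times / t0
        cols += [np.cos(w), np.sin(w)]
    beta0, *_ = np.linalg.lstsq(np.column_stack(cols), values, rcond=None)
    p0 = [t0, beta0[0], *beta0[1:]]
    popt, pcov = optimize.curve_fit(
        _harmonic_model, times, values, p0=p0, maxfev=20000
    )
    period = float(popt[0])
    period_se = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else np.nan
    mean = float(popt[1])
    amps, phis = [], []
    for k in range(n_harmonics):
        c, s = popt[2 + 2 * k], popt[3 + 2 * k]
        amps.append(float(np.hypot(c, s)))
        # a cos(w) + b sin(w) = A cos(w + phi) with phi = atan2(-b, a)
        phis.append(float(np.arctan2(-s, c)))
    resid = values - _harmonic_model(times, *popt)
    dof = times.size - len(popt)
    residual_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else np.nan
    # fundamental amplitude SE by the delta method
    a1 = amps[0]
    arrhythmic = False
    if np.all(np.isfinite(pcov)) and a1 > 0:
        c, s = popt[2], popt[3]
        grad = np.array([c / a1, s / a1])
        var = grad @ pcov[2:4, 2:4] @ grad
        a1_se = float(np.sqrt(max(var, 0.0)))
        if a1 < 2 * a1_se:
            arrhythmic = True
    if arrhythmic:
        return RhythmFit(period=None, arrhythmic=True, mean_level=mean,
                         n_harmonics=n_harmonics, residual_sd=residual_sd)
    return RhythmFit(
        period=period,
        period_se=period_se,
        amplitudes=tuple(amps),
        phases=tuple(phis),
        mean_level=mean,
        n_harmonics=n_harmonics,
        residual_sd=residual_sd,
    )


def amplitude_minmax(times, values, use_fit: bool = False, **fit_kwargs) -> float:
    """Oscillation amplitude as max - min, of the raw trace (default) or
    of the fitted harmonic curve evaluated densely over the span."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("need at least 2 points")
    if not use_fit:
        return float(np.ptp(values))
    fit = fit_period(times, values, **fit_kwargs)
    if fit.arrhythmic:
        return 0.0
    dense = np.linspace(times[0], times[-1], 2001)
    return float(np.ptp(fit.predict(dense)))


def arrhenius_fit(
    periods_by_temperature: Sequence[tuple],
    t1_celsius: float = 30.0,
    t2_celsius: float = 40.0,
) -> ArrheniusFit:
    """Linear regression of ln(24/period) on 1/T_K.

    ``periods_by_temperature`` is a sequence of (temperature deg C,
    period h) pairs at two or more distinct temperatures.  The cycle
    frequency is defined as cycles per day, 24/period.  E_a = -slope * R;
    Q10 is derived from E_a between ``t1_celsius`` and ``t2_celsius``.
    """
    pairs = list(periods_by_temperature)
    if len(pairs) < 2:
        raise ValidationError("need periods at >= 2 temperatures")
    temps = np.array([p[0] for p in pairs], dtype=float)
    periods = np.array([p[1] for p in pairs], dtype=float)
    if np.any(periods <= 0):
        raise ValidationError("periods must be > 0")
    if np.unique(temps).size < 2:
        raise ValidationError("need >= 2 distinct temperatures")
    x = 1.0 / (temps + 273.15)
    y = np.log(24.0 / periods)
    res = stats.linregress(x, y)
    e_a = -float(res.slope) * GAS_CONSTANT_KCAL
    e_a_se = float(res.stderr) * GAS_CONSTANT_KCAL if res.stderr is not None else np.nan
    q10 = ea_to_q10(e_a, t1_celsius, t2_celsius)
    return ArrheniusFit(
        e_a=e_a,
        e_a_se=e_a_se,
        ln_pre_exponential=float(res.intercept),
        q10=q10,
        t1_celsius=t1_celsius,
        t2_celsius=t2_celsius,
        diagnostics={"r_value": float(res.rvalue), "n": len(pairs)},
    )


def ea_to_q10(e_a: float, t1_celsius: float = 30.0, t2_celsius: float = 40.0) -> float:
    """Q10 implied by an activation energy between two temperatures:
    Q10 = exp[(E_a/R)(1/T1_K - 1/T2_K)]."""
    if t1_celsius == t2_celsius:
        raise ValidationError("temperatures must differ")
    inv = 1.0 / _kelvin(t1_celsius) - 1.0 / _kelvin(t2_celsius)
    return float(np.exp(e_a / GAS_CONSTANT_KCAL * inv))


def q10_to_ea(q10: float, t1_celsius: float = 30.0, t2_celsius: float = 40.0) -> float:
    """Activation energy (kcal/mol) implied by a Q10 between two
    temperatures: E_a = R ln(Q10) / (1/T1_K - 1/T2_K)."""
    if q10 <= 0:
        raise ValidationError("q10 must be > 0")
    if t1_celsius == t2_celsius:
        raise ValidationError("temperatures must differ")
    inv = 1.0 / _kelvin(t1_celsius) - 1.0 / _kelvin(t2_celsius)
    return float(GAS_CONSTANT_KCAL * np.log(q10) / inv)
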