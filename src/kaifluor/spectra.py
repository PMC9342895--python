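"""Emission-spectrum processing.

Spectra are normalized against protein concentration and a NATA
(N-acetyl-L-tryptophan amide) standard, band-integrated over 320-370 nm to
give the fluorescence intensity F, and characterized by the wavelength of
their emission maximum (lambda_max, a solvent-exposure proxy for the Trp
environment).  Difference spectra between matched construct pairs isolate
the contribution of an engineered Trp probe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .containers import EmissionSpectrum
from .states import ValidationError

__all__ = [
    "SpectralSummary",
    "LambdaMaxResult",
    "normalize_spectrum",
    "integrate_band",
    "find_lambda_max",
    "difference_spectrum",
    "summarize_f_lambda",
]

BAND_LO = 320.0   # nm, analysis band used for F throughout
BAND_HI = 370.0


@dataclass
class SpectralSummary:
    """Replicate-group summary: integrated intensity F and lambda_max,
    each as mean (+ SD when replicates exist)."""

    label: str
    f: float
    lambda_max: Optional[float]
    f_sd: Optional[float] = None
    lambda_max_sd: Optional[float] = None
    n: int = 1


@dataclass
class LambdaMaxResult:
    """Peak-position estimate.  ``lambda_max`` is None when the maximum
    sits on a window edge (monotone spectrum), in which case ``warning``
    carries the code ``"edge-maximum"``."""

    lambda_max: Optional[float]
    peak_intensity: Optional[float] = None
    warning: Optional[str] = None


def normalize_spectrum(
    raw: EmissionSpectrum, concentration: float, nata_signal: float
) -> EmissionSpectrum:
    """Divide intensities by (concentration x NATA standard signal).

    Raises on non-positive divisors and on attempts to normalize twice.
    """
    if concentration <= 0:
        raise ValidationError(f"concentration must be > 0, got {concentration}")
    if nata_signal <= 0:
        raise ValidationError(f"nata_signal must be > 0, got {nata_signal}")
    if raw.meta.get("normalized"):
        raise ValidationError("spectrum is already normalized")
    meta = dict(raw.meta)
    meta.update(normalized=True, concentration=concentration, nata_signal=nata_signal)
    return EmissionSpectrum(
        wavelengths=raw.wavelengths.copy(),
        intensities=raw.intensities / (concentration * nata_signal),
        meta=meta,
    )


def integrate_band(
    s: EmissionSpectrum, lo: float = BAND_LO, hi: float = BAND_HI
) -> float:
    """Trapezoidal integral of the spectrum over [lo, hi] nm.

    Band edges off the native grid are linearly interpolated so the
    integral covers the band endpoints exactly.
    """
    if lo >= hi:
        raise ValidationError(f"band lower bound {lo} must be < upper bound {hi}")
    wl, inten = s.wavelengths, s.intensities
    if lo < wl[0]:
        raise ValidationError(
            f"band lower bound {lo} nm below spectrum range starting at {wl[0]} nm"
        )
    if hi > wl[-1]:
        raise ValidationError(
            f"band upper bound {hi} nm above spectrum range ending at {wl[-1]} nm"
        )
    inside = (wl > lo) & (wl < hi)
    xs = np.concatenate(([lo], wl[inside], [hi]))
    ys = np.concatenate((
        [np.interp(lo, wl, inten)], inten[inside], [np.interp(hi, wl, inten)]
    ))
    return float(np.trapezoid(ys, xs))


def find_lambda_max(
    s: EmissionSpectrum,
    window: Optional[tuple] = None,
    smooth: bool = False,
) -> LambdaMaxResult:
    """Sub-grid peak position by parabolic interpolation through the
    maximum sample and its two neighbours.

    ``window`` restricts the search to a (lo, hi) nm range.  ``smooth``
    applies a 5-point moving average first (off by default).  A maximum
    on a window edge has no interior parabola and is returned as a
    flagged result rather than a number.
    """
    wl, inten = s.wavelengths, s.intensities
    if window is not None:
        lo, hi = window
        mask = (wl >= lo) & (wl <= hi)
        if mask.sum() < 3:
            raise ValidationError("search window contains fewer than 3 samples")
        wl, inten = wl[mask], inten[mask]
    if smooth:
        kernel = np.ones(5) / 5.0
        inten = np.convolve(inten, kernel, mode="same")
        # the 2 samples at each end are partial averages; exclude them
        wl, inten = wl[2:-2], inten[2:-2]
    i = int(np.argmax(inten))
    if i == 0 or i == inten.size - 1:
        return LambdaMaxResult(lambda_max=None, warning="edge-maximum")
    y0, y1, y2 = inten[i - 1], inten[i], inten[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:  # flat top: take the central sample
        return LambdaMaxResult(lambda_max=float(wl[i]), peak_intensity=float(y1))
    delta = 0.5 * (y0 - y2) / denom
    # local grid may be irregular; use the mean neighbour spacing
    step = 0.5 * (wl[i + 1] - wl[i - 1])
    peak = y1 - 0.25 * (y0 - y2) * delta
    return LambdaMaxResult(
        lambda_max=float(wl[i] + delta * step), peak_intensity=float(peak)
    )


def difference_spectrum(
    a: EmissionSpectrum, b: EmissionSpectrum, interpolate: bool = False
) -> EmissionSpectrum:
    """Pointwise a - b.

    By default the two spectra must share an identical wavelength grid;
    with ``interpolate=True`` both are linearly interpolated onto the
    intersection of their ranges (on a's grid).  Disjoint ranges are an
    error either way.
    """
    meta = {
        "difference": True,
        "minuend": a.meta.get("sample", a.meta.get("construct")),
        "subtrahend": b.meta.get("sample", b.meta.get("construct")),
    }
    if not interpolate:
        if a.wavelengths.shape != b.wavelengths.shape or not np.array_equal(
            a.wavelengths, b.wavelengths
        ):
            raise ValidationError(
                "wavelength grids differ; pass interpolate=True to resample"
            )
        return EmissionSpectrum(
            wavelengths=a.wavelengths.copy(),
            intensities=a.intensities - b.intensities,
            meta=meta,
        )
    lo = max(a.wavelengths[0], b.wavelengths[0])
    hi = min(a.wavelengths[-1], b.wavelengths[-1])
    if lo >= hi:
        raise ValidationError("wavelength ranges are disjoint")
    mask = (a.wavelengths >= lo) & (a.wavelengths <= hi)
    wl = a.wavelengths[mask]
    ya = a.intensities[mask]
    yb = np.interp(wl, b.wavelengths, b.intensities)
    return EmissionSpectrum(wavelengths=wl.copy(), intensities=ya - yb, meta=meta)


def summarize_f_lambda(
    groups: dict[str, Sequence[EmissionSpectrum]],
    lo: float = BAND_LO,
    hi: float = BAND_HI,
    window: Optional[tuple] = None,
) -> list[SpectralSummary]:
    """Per replicate group, mean (and SD for n > 1) of the band-integrated
    intensity F and of lambda_max — the inputs of the F vs lambda_max
    summary plot that separates buried from solvent-exposed Trp probes."""
    out = []
    for label, reps in groups.items():
        reps = list(reps)
        if not reps:
            raise ValidationError(f"replicate group {label!r} is empty")
        fs = np.array([integrate_band(r, lo, hi) for r in reps])
        lams = [find_lambda_max(r, window=window).lambda_max for r in reps]
        lam_ok = np.array([x for x in lams if x is not None], dtype=float)
        n = len(reps)
        out.append(SpectralSummary(
            label=label,
            f=float(fs.mean()),
            lambda_max=float(lam_ok.mean()) if lam_ok.size else None,
            f_sd=float(fs.std(ddof=1)) if n > 1 else None,
            lambda_max_sd=float(lam_ok.std(ddof=1)) if lam_ok.size > 1 else None,
            n=n,
        ))
    return out
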