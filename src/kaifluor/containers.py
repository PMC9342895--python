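"""In-memory containers shared across the pipeline.

These are small validated dataclasses rather than bare arrays because the
analysis chains several measurement modalities (band-integrated
fluorescence, gel-derived phosphostate abundances, emission spectra) whose
metadata — construct, condition, temperature — drives decisions downstream
(e.g. whether an offset term for KaiA fluorescence is fitted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .states import STATES, ValidationError, check_times

logger = logging.getLogger("kaifluor")


@dataclass
class FluorescenceTimeCourse:
    """Apparent Trp fluorescence F_app(t): emission integrated over the
    320-370 nm band, normalized to protein concentration and a NATA
    standard, sampled over hours."""

    times: np.ndarray            # h
    f_app: np.ndarray            # normalized fluorescence units
    temperature: float = 30.0    # deg C
    construct: str = "WT"        # e.g. "WT", "F419W"
    condition: str = "KaiC-alone"  # or "KaiA+KaiB+KaiC"

    def __post_init__(self) -> None:
        self.times = check_times(self.times)
        self.f_app = np.asarray(self.f_app, dtype=float)
        if self.f_app.shape != self.times.shape:
            raise ValidationError("f_app and times must have equal length")
        if not np.all(np.isfinite(self.f_app)):
            raise ValidationError("f_app contains non-finite values")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class AbundanceTimeCourse:
    """Relative abundances of the four phosphostates over time.

    Rows live on the probability simplex.  Gel quantification carries a
    few percent of error, so ingestion renormalizes rows whose sum
    deviates from 1 by at most ``row_sum_tol`` (logged); larger
    deviations are rejected.
    """

    times: np.ndarray           # h
    abundances: np.ndarray      # (n, 4) over (SpT, pSpT, pST, ST)
    row_sum_tol: float = 0.02

    def __post_init__(self) -> None:
        self.times = check_times(self.times)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.shape != (self.times.size, 4):
            raise ValidationError(
                f"abundances must be (n, 4) over {STATES}, got {self.abundances.shape}"
            )
        if not np.all(np.isfinite(self.abundances)):
            raise ValidationError("abundances contain non-finite values")
        if np.any(self.abundances < -1e-9):
            raise ValidationError("abundances contain negative entries")
        sums = self.abundances.sum(axis=1)
        dev = np.abs(sums - 1.0)
        bad = np.nonzero(dev > self.row_sum_tol)[0]
        if bad.size:
            raise ValidationError(
                f"abundance row {bad[0]} sums to {sums[bad[0]]:.4g}; "
                f"deviation exceeds tolerance {self.row_sum_tol:g}"
            )
        off = np.nonzero(dev > 1e-12)[0]
        if off.size:
            logger.info(
                "renormalized %d abundance rows (max row-sum deviation %.3g)",
                off.size, float(dev.max()),
            )
            self.abundances = self.abundances / sums[:, None]

    def __len__(self) -> int:
        return self.times.size

    def state(self, name: str) -> np.ndarray:
        return self.abundances[:, STATES.index(name)]


@dataclass
class EmissionSpectrum:
    """A Trp emission spectrum on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray     # nm
    intensities: np.ndarray     # normalized fluorescence units
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise ValidationError("wavelengths must be a 1-D array of length >= 2")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if self.intensities.shape != self.wavelengths.shape:
            raise ValidationError("intensities and wavelengths must have equal length")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities contain non-finite values")


@dataclass
class StateFluorescence:
    """Per-phosphostate fluorescence intensities F_i — the coefficients of
    the linear model F_app(t) = sum_i F_i A_i(t) (+ offset) — with
    standard errors and fit diagnostics."""

    f_values: dict              # state -> F_i
    f_se: Optional[dict] = None
    offset: Optional[float] = None
    offset_se: Optional[float] = None
    construct: str = "WT"
    condition: str = "KaiC-alone"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in STATES if s not in self.f_values]
        if missing:
            raise ValidationError(f"missing state intensities for {missing}")
        if self.f_se is not None:
            if any(s not in self.f_se for s in STATES):
                raise ValidationError("f_se must cover all four states")
            if any(self.f_se[s] < 0 for s in STATES):
                raise ValidationError("standard errors must be >= 0")

    def vector(self) -> np.ndarray:
        return np.array([float(self.f_values[s]) for s in STATES])


@dataclass
class W419Contribution:
    """Per-state fluorescence attributable to the engineered W419 probe:
    F_i(F419W construct) - F_i(base construct), SEs combined in
    quadrature."""

    f_w419: dict
    se: Optional[dict] = None
    mutant_construct: str = "F419W"
    base_construct: str = "WT"

    def vector(self) -> np.ndarray:
        return np.array([float(self.f_w419[s]) for s in STATES])


@dataclass
class PhosphoFractionTrace:
    """Fraction of phosphorylated KaiC over time (1 - A_ST)."""

    times: np.ndarray
    fraction: np.ndarray
    temperature: float = 30.0

    def __post_init__(self) -> None:
        self.times = check_times(self.times)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.fraction.shape != self.times.shape:
            raise ValidationError("fraction and times must have equal length")
        if np.any(self.fraction < -1e-9) or np.any(self.fraction > 1 + 1e-9):
            raise ValidationError("phosphorylated fraction must lie in [0, 1]")
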