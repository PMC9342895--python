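"""Synthetic data generation for the KaiC fluorescence analysis.

The raw instrument data behind this analysis (plate-reader fluorescence
time courses and SDS-PAGE phosphostate quantifications) are not publicly
deposited, so every downstream stage is exercised on synthetic data with
the same statistical structure:

* **Auto-dephosphorylation** — KaiC alone, shifted from an ice bath to
  30 deg C, relaxes toward the fully dephosphorylated ST state.  Modelled
  as a linear first-order kinetic system dA/dt = K A on the four states.
* **Circadian oscillation** — with KaiA and KaiB present the states cycle
  ST -> SpT -> pSpT -> pST -> ST with period ~24 h.  Modelled
  phenomenologically as phase-staggered periodic pulses renormalized to
  the simplex (no mechanistic KaiABC ODE model is attempted).
* **Emission spectra** — each phosphostate contributes a skewed emission
  band whose amplitude and peak wavelength depend on the state.
* **Apparent fluorescence** — F_app(t) = sum_i F_i A_i(t) + offset + noise,
  the forward form of the linear deconvolution model; the constant offset
  emulates the (non-oscillating) KaiA fluorescence background.

All generators are deterministic given an rng seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize_scalar
from scipy.stats import skewnorm

from .containers import (
    AbundanceTimeCourse,
    EmissionSpectrum,
    FluorescenceTimeCourse,
    StateFluorescence,
)
from .states import STATES, ValidationError, as_state_vector, check_simplex, check_times

__all__ = [
    "PhosphoKineticModel",
    "OscillationModel",
    "SpectralStateModel",
    "generate_autodephos_abundances",
    "generate_oscillation_abundances",
    "synthesize_spectrum",
    "compose_fapp",
]


# --------------------------------------------------------------------------
# kinetic relaxation (auto-dephosphorylation)
# --------------------------------------------------------------------------

@dataclass
class PhosphoKineticModel:
    """First-order interconversion kinetics among the four phosphostates.

    Parameters
    ----------
    rate_constants
        Map from ``(source, sink)`` state pairs to first-order rates in
        1/h.  Any non-negative rate map among the four states is allowed.
        The default is the dephosphorylation chain
        pSpT -> pST -> ST plus SpT -> ST: KaiC alone dephosphorylates and
        ST is absorbing.  The default rates are fixture values chosen to
        relax over roughly a day at 30 deg C; they are not measured
        constants.
    initial_abundances
        State occupancies at t = 0, on the simplex.  The default is a
        largely phosphorylated mix, as after cold storage.
    """

    rate_constants: Mapping[tuple, float] = field(
        default_factory=lambda: {
            ("pSpT", "pST"): 0.15,
            ("pST", "ST"): 0.10,
            ("SpT", "ST"): 0.20,
        }
    )
    initial_abundances: np.ndarray = field(
        default_factory=lambda: np.array([0.25, 0.45, 0.20, 0.10])
    )

    def __post_init__(self) -> None:
        for (src, dst), k in self.rate_constants.items():
            if src not in STATES or dst not in STATES or src == dst:
                raise ValidationError(f"invalid state pair {(src, dst)}")
            if k < 0:
                raise ValidationError(f"negative rate {k} for {src}->{dst}")
        self.initial_abundances = as_state_vector(
            self.initial_abundances, "initial_abundances"
        )
        check_simplex(self.initial_abundances, tol=1e-9, name="initial_abundances")

    def rate_matrix(self) -> np.ndarray:
        """4x4 generator matrix K with columns summing to zero, so that
        dA/dt = K A conserves total abundance."""
        K = np.zeros((4, 4))
        for (src, dst), k in self.rate_constants.items():
            i, j = STATES.index(src), STATES.index(dst)
            K[j, i] += k
            K[i, i] -= k
        return K


def generate_autodephos_abundances(
    model: PhosphoKineticModel, times
) -> AbundanceTimeCourse:
    """Solve dA/dt = K A exactly (matrix exponential) at the requested times.

    Deterministic; each returned row lies on the simplex because the
    generator matrix conserves total abundance and the dynamics preserve
    non-negativity.
    """
    times = check_times(times, nonnegative=True)
    K = model.rate_matrix()
    a0 = model.initial_abundances
    rows = np.empty((times.size, 4))
    for i, t in enumerate(times):
        rows[i] = expm(K * t) @ a0
    rows = np.clip(rows, 0.0, None)  # guard fp dust at machine precision
    return AbundanceTimeCourse(times=times, abundances=rows, row_sum_tol=1e-6)


# --------------------------------------------------------------------------
# circadian oscillation
# --------------------------------------------------------------------------

@dataclass
class OscillationModel:
    """Phenomenological circadian waveform for the four phosphostates.

    Each state receives a periodic bump
    ``floor + exp(kappa * (cos(2*pi*(t - phase)/period) - 1))`` with
    ``kappa = (period / (2*pi*width))**2`` — a von Mises profile that is
    exactly periodic and tends to a wrapped Gaussian of the given width
    for narrow pulses.  The four bumps are renormalized to sum to 1 at
    every time point, giving a smooth simplex-valued trajectory whose
    peaks follow the cycle order ST -> SpT -> pSpT -> pST.

    Default phases stagger the peaks at 6 h intervals over a 24 h cycle,
    as the phase-ordered abundance maxima of the in vitro oscillation
    show.
    """

    period: float = 24.0                     # h
    state_phases: tuple = (6.0, 12.0, 18.0, 0.0)   # peak time per state, h
    state_widths: tuple = (3.0, 3.0, 3.0, 3.0)     # pulse width, h
    state_floors: tuple = (0.05, 0.05, 0.05, 0.05)  # baseline weight
    n_cycles: int = 4
    sampling_interval: float = 0.5           # h

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValidationError("period must be > 0")
        if len(self.state_phases) != 4 or len(self.state_widths) != 4 \
                or len(self.state_floors) != 4:
            raise ValidationError("state_phases/widths/floors must have length 4")
        if any(w <= 0 for w in self.state_widths):
            raise ValidationError("pulse widths must be > 0")
        if any(f < 0 for f in self.state_floors):
            raise ValidationError("floors must be >= 0")
        if self.sampling_interval <= 0:
            raise ValidationError("sampling_interval must be > 0")

    def default_times(self) -> np.ndarray:
        n = int(round(self.n_cycles * self.period / self.sampling_interval))
        return np.arange(n + 1) * self.sampling_interval

    def weights(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)[:, None]
        phases = np.asarray(self.state_phases)[None, :]
        widths = np.asarray(self.state_widths)[None, :]
        floors = np.asarray(self.state_floors)[None, :]
        kappa = (self.period / (2.0 * np.pi * widths)) ** 2
        ang = 2.0 * np.pi * (t - phases) / self.period
        return floors + np.exp(kappa * (np.cos(ang) - 1.0))


def generate_oscillation_abundances(
    model: OscillationModel, times=None
) -> AbundanceTimeCourse:
    """Evaluate the oscillation waveform on ``times`` (default: the
    model's own grid) and renormalize to the simplex at each point."""
    if times is None:
        times = model.default_times()
    times = check_times(times)
    span = times[-1] - times[0]
    if span < model.period:
        raise ValidationError(
            f"times span {span:g} h shorter than one period ({model.period:g} h)"
        )
    w = model.weights(times)
    rows = w / w.sum(axis=1, keepdims=True)
    return AbundanceTimeCourse(times=times, abundances=rows, row_sum_tol=1e-9)


# --------------------------------------------------------------------------
# emission spectra
# --------------------------------------------------------------------------

_DEFAULT_WAVELENGTHS = np.arange(300.0, 401.0, 1.0)


@dataclass
class SpectralStateModel:
    """Per-state emission band model for synthetic Trp spectra.

    Each phosphostate contributes a skew-normal band parameterized by the
    wavelength of its emission maximum (``band_lambda_max``, nm), the peak
    intensity at that maximum (``band_amplitude``), a width scale (nm) and
    a dimensionless skew (skew 0 recovers an exact Gaussian, used by the
    closed-form tests; positive skew gives the red-tailed asymmetry of
    real Trp emission).  Default peak positions span a ~5 nm range and
    default amplitudes mirror the strong/weak alternation of the W419
    probe across states.
    """

    band_lambda_max: tuple = (334.0, 339.0, 337.0, 333.0)  # nm per state
    band_amplitude: tuple = (1.30, 0.30, 0.70, 1.25)       # peak F per state
    band_width: tuple = (12.0, 12.0, 12.0, 12.0)           # nm
    band_skew: tuple = (1.5, 1.5, 1.5, 1.5)
    wavelength_grid: np.ndarray = field(
        default_factory=lambda: _DEFAULT_WAVELENGTHS.copy()
    )
    noise_sigma: float = 0.0
    offset: float = 0.0
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.wavelength_grid = np.asarray(self.wavelength_grid, dtype=float)
        lo, hi = self.wavelength_grid[0], self.wavelength_grid[-1]
        for lmax in self.band_lambda_max:
            if not (lo <= lmax <= hi):
                raise ValidationError(
                    f"band_lambda_max {lmax} nm outside grid [{lo}, {hi}] nm"
                )
        if any(a < 0 for a in self.band_amplitude):
            raise ValidationError("band amplitudes must be >= 0")
        if any(w <= 0 for w in self.band_width):
            raise ValidationError("band widths must be > 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")

    def band(self, state_index: int, wavelengths=None) -> np.ndarray:
        """Emission band of one state, peaking at band_lambda_max with
        peak height band_amplitude."""
        lam = self.wavelength_grid if wavelengths is None else np.asarray(wavelengths)
        lmax = self.band_lambda_max[state_index]
        amp = self.band_amplitude[state_index]
        width = self.band_width[state_index]
        skew = self.band_skew[state_index]
        if skew == 0:
            return amp * np.exp(-0.5 * ((lam - lmax) / width) ** 2)
        mode = _skewnorm_mode(skew)
        loc = lmax - mode * width
        peak = skewnorm.pdf(mode, skew)
        return amp * skewnorm.pdf((lam - loc) / width, skew) / peak


def _skewnorm_mode(a: float) -> float:
    """Mode of the standard skew-normal with shape ``a`` (numeric)."""
    res = minimize_scalar(
        lambda x: -skewnorm.pdf(x, a), bounds=(-3.0, 3.0), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def synthesize_spectrum(
    spec_model: SpectralStateModel,
    abundances,
    rng: Optional[np.random.Generator] = None,
) -> EmissionSpectrum:
    """Abundance-weighted sum of the per-state bands, plus offset and
    (optionally) i.i.d. Gaussian noise per wavelength.

    Reproducible: a fixed ``rng_seed`` on the model (or an explicit
    ``rng``) yields bitwise-identical spectra.
    """
    vec = as_state_vector(abundances)
    check_simplex(vec, tol=1e-6)
    lam = spec_model.wavelength_grid
    intens = np.full(lam.shape, float(spec_model.offset))
    for i in range(4):
        if vec[i] != 0:
            intens = intens + vec[i] * spec_model.band(i)
    if spec_model.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(spec_model.rng_seed)
        intens = intens + rng.normal(0.0, spec_model.noise_sigma, size=lam.shape)
    meta = {"synthetic": True, "abundances": vec.tolist(), "offset": spec_model.offset}
    return EmissionSpectrum(wavelengths=lam.copy(), intensities=intens, meta=meta)


# --------------------------------------------------------------------------
# apparent fluorescence composition (forward model)
# --------------------------------------------------------------------------

def compose_fapp(
    state_f: StateFluorescence,
    abundances: AbundanceTimeCourse,
    noise_sigma: float = 0.0,
    rng_seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> FluorescenceTimeCourse:
    """Forward-compose F_app(t) = sum_i F_i A_i(t) + offset + eps(t).

    ``state_f.offset`` (if set) models the constant background from KaiA
    fluorescence; ``noise_sigma`` adds i.i.d. Gaussian measurement noise.
    Noiseless when ``noise_sigma`` is 0.
    """
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    f = state_f.vector()
    trace = abundances.abundances @ f
    if state_f.offset is not None:
        trace = trace + state_f.offset
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(rng_seed)
        trace = trace + rng.normal(0.0, noise_sigma, size=trace.shape)
    return FluorescenceTimeCourse(
        times=abundances.times.copy(),
        f_app=trace,
        construct=state_f.construct,
        condition=state_f.condition,
    )
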