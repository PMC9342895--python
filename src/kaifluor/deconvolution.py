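"""Linear deconvolution of apparent fluorescence into per-state intensities.

The central model: the apparent (band-integrated) Trp fluorescence of a
KaiC solution is the abundance-weighted sum of intrinsic per-phosphostate
intensities,

    F_app(t) = F_SpT A_SpT(t) + F_pSpT A_pSpT(t) + F_pST A_pST(t)
               + F_ST A_ST(t)  [+ offset],

where A_i(t) are the experimentally determined relative state abundances.
The F_i are recovered by ordinary least squares.  The optional constant
offset models the non-oscillating fluorescence background of KaiA in
reconstituted-oscillator samples; for KaiC-alone relaxations it is
omitted.  Subtracting the fitted F_i of a base construct from those of a
matched F419W construct isolates the contribution of the engineered W419
probe per state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import (
    AbundanceTimeCourse,
    FluorescenceTimeCourse,
    StateFluorescence,
    W419Contribution,
)
from .states import STATES, ValidationError

__all__ = [
    "IdentifiabilityError",
    "FitComparison",
    "fit_state_fluorescence",
    "estimate_offset",
    "extract_w419",
    "simulate_fapp",
    "compare_fit",
]

logger = logging.getLogger("kaifluor")

#: Condition number above which the abundance design is treated as
#: unidentifiable (proportional state trajectories).
CONDITION_LIMIT = 1e6


class IdentifiabilityError(ValueError):
    """Design matrix too ill-conditioned to separate the state intensities."""


@dataclass
class FitComparison:
    """Goodness-of-fit record for an observed vs simulated trace pair."""

    rmsd: float
    pearson_r: float
    times: np.ndarray
    residuals: np.ndarray   # observed - simulated, for phase-resolved inspection


def _align_abundances(
    fluor: FluorescenceTimeCourse, abund: AbundanceTimeCourse
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly interpolate abundances (the sparser, smoother measurement)
    onto the fluorescence timestamps; extrapolation is forbidden, so
    fluorescence points outside the abundance span are dropped."""
    lo, hi = abund.times[0], abund.times[-1]
    keep = (fluor.times >= lo) & (fluor.times <= hi)
    if not np.any(keep):
        raise ValidationError(
            "fluorescence and abundance time ranges do not overlap"
        )
    t = fluor.times[keep]
    y = fluor.f_app[keep]
    A = np.column_stack([
        np.interp(t, abund.times, abund.abundances[:, j]) for j in range(4)
    ])
    if keep.sum() != fluor.times.size:
        logger.info(
            "dropped %d fluorescence points outside the abundance span",
            int(fluor.times.size - keep.sum()),
        )
    return t, y, A


def _collinear_states(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns participating in the near-null singular direction."""
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    v = vt[-1]
    return [n for n, w in zip(names, v) if abs(w) > 0.1]


def fit_state_fluorescence(
    fluor: FluorescenceTimeCourse,
    abund: AbundanceTimeCourse,
    with_offset: bool = False,
    nonnegative: bool = False,
) -> StateFluorescence:
    """Ordinary least-squares fit of the linear state-fluorescence model.

    Parameters
    ----------
    with_offset
        Include a free constant term in the design.  Note that when the
        abundance rows close exactly to 1 (as validated ingestion
        guarantees) the constant column equals the row sum of the four
        abundance columns, the design is singular, and this raises
        :class:`IdentifiabilityError` — a constant background is then
        absorbed into the F_i and cannot be separated by this fit alone.
        For KaiA-containing samples use :func:`estimate_offset` with
        per-state intensities determined from a KaiC-alone relaxation.
    nonnegative
        Constrain F_i >= 0 (and offset >= 0).  Off by default — the
        unconstrained OLS formulation is the primary estimator; the
        constrained mode exists for noisy low-signal data.

    Returns per-state intensities with standard errors from the fit
    covariance, plus diagnostics (residual SD, design condition number,
    number of points used).
    """
    t, y, A = _align_abundances(fluor, abund)
    if t.size < 5:
        raise ValidationError(
            f"only {t.size} overlapping time points; need at least 5"
        )
    names = list(STATES)
    X = A
    if with_offset:
        X = np.column_stack([A, np.ones(t.size)])
        names = names + ["offset"]
    cond = float(np.linalg.cond(X))
    if cond > CONDITION_LIMIT:
        cols = _collinear_states(X, names)
        raise IdentifiabilityError(
            f"design condition number {cond:.3g} exceeds {CONDITION_LIMIT:g}; "
            f"collinear columns: {cols or 'none resolved'}"
        )
    if nonnegative:
        from scipy.optimize import nnls
        beta, _ = nnls(X, y)
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = t.size - X.shape[1]
    sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    f_values = {s: float(beta[i]) for i, s in enumerate(STATES)}
    f_se = {s: float(se[i]) for i, s in enumerate(STATES)}
    offset = float(beta[4]) if with_offset else None
    offset_se = float(se[4]) if with_offset else None
    return StateFluorescence(
        f_values=f_values,
        f_se=f_se,
        offset=offset,
        offset_se=offset_se,
        construct=fluor.construct,
        condition=fluor.condition,
        diagnostics={
            "residual_sd": float(np.sqrt(sigma2)) if dof > 0 else np.nan,
            "condition_number": cond,
            "n_points": int(t.size),
            "dof": int(dof),
        },
    )


def estimate_offset(
    fluor: FluorescenceTimeCourse,
    state_f: StateFluorescence,
    abund: AbundanceTimeCourse,
) -> tuple[float, float]:
    """Estimate the constant fluorescence background of a KaiA-containing
    sample, given per-state intensities determined independently (from a
    KaiC-alone relaxation).

    Because the abundances close to 1, a constant background cannot be
    separated from the F_i within a single fit; with the F_i pinned the
    offset is simply the mean residual
    ``mean(F_app(t) - sum_i F_i A_i(t))``.  Returns ``(offset, SE)``.
    """
    t, y, A = _align_abundances(fluor, abund)
    resid = y - A @ state_f.vector()
    offset = float(resid.mean())
    se = float(resid.std(ddof=1) / np.sqrt(resid.size)) if resid.size > 1 else np.nan
    return offset, se


def extract_w419(
    mutant: StateFluorescence, base: StateFluorescence
) -> W419Contribution:
    """Per-state W419 fluorescence: F_i(F419W construct) - F_i(base),
    standard errors combined in quadrature.

    Both fits must come from the same experimental condition; comparing a
    KaiA-containing oscillation fit with a KaiC-alone relaxation fit
    would confound the probe contribution with the background.
    """
    if mutant.condition != base.condition:
        raise ValidationError(
            f"condition mismatch: {mutant.condition!r} vs {base.condition!r}"
        )
    if mutant.construct == base.construct:
        raise ValidationError(
            f"both fits are from construct {base.construct!r}; need two constructs"
        )
    diff = {s: float(mutant.f_values[s]) - float(base.f_values[s]) for s in STATES}
    se = None
    if mutant.f_se is not None and base.f_se is not None:
        se = {
            s: float(np.hypot(mutant.f_se[s], base.f_se[s])) for s in STATES
        }
    return W419Contribution(
        f_w419=diff,
        se=se,
        mutant_construct=mutant.construct,
        base_construct=base.construct,
    )


def simulate_fapp(
    state_f: StateFluorescence, abund: AbundanceTimeCourse
) -> FluorescenceTimeCourse:
    """Deterministic forward simulation sum_i F_i A_i(t) + offset on the
    abundance time grid, for comparison with an observed trace."""
    trace = abund.abundances @ state_f.vector()
    if state_f.offset is not None:
        trace = trace + state_f.offset
    return FluorescenceTimeCourse(
        times=abund.times.copy(),
        f_app=trace,
        construct=state_f.construct,
        condition=state_f.condition,
    )


def compare_fit(
    observed: FluorescenceTimeCourse, simulated: FluorescenceTimeCourse
) -> FitComparison:
    """RMSD, Pearson r and the residual trace between an observed and a
    simulated F_app time course.

    Exactly matching time grids are used directly; otherwise the
    simulated trace is linearly interpolated onto the observed times
    within the overlap.
    """
    if observed.times.size == simulated.times.size and np.allclose(
        observed.times, simulated.times
    ):
        t = observed.times
        yo, ys = observed.f_app, simulated.f_app
    else:
        lo = max(observed.times[0], simulated.times[0])
        hi = min(observed.times[-1], simulated.times[-1])
        keep = (observed.times >= lo) & (observed.times <= hi)
        t = observed.times[keep]
        yo = observed.f_app[keep]
        ys = np.interp(t, simulated.times, simulated.f_app)
    if t.size < 3:
        raise ValidationError(f"only {t.size} common time points; need at least 3")
    resid = yo - ys
    rmsd = float(np.sqrt(np.mean(resid ** 2)))
    if np.std(yo) == 0 or np.std(ys) == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(yo, ys)[0, 1])
    return FitComparison(rmsd=rmsd, pearson_r=r, times=t, residuals=resid)
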