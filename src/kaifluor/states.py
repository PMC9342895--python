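"""Phosphorylation-state bookkeeping shared by all modules.

KaiC carries two phosphorylation sites, Ser431 (S) and Thr432 (T).  The
four resulting phosphostates are labelled by which residue carries a
phosphoryl group (prefix ``p``), and the circadian cycle visits them in
the fixed order ST -> SpT -> pSpT -> pST -> ST.  Throughout this package
state vectors are ordered ``(SpT, pSpT, pST, ST)`` — the order in which
the linear fluorescence model writes its coefficients.
"""

from __future__ import annotations

import numpy as np

#: Canonical state order used for every 4-vector in the package.
STATES: tuple[str, str, str, str] = ("SpT", "pSpT", "pST", "ST")

#: Index of each state in the canonical order.
STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def as_state_vector(values, name: str = "abundances") -> np.ndarray:
    """Coerce ``values`` (mapping keyed by state, or sequence in canonical
    order) to a float 4-vector in canonical state order."""
    if isinstance(values, dict):
        missing = [s for s in STATES if s not in values]
        if missing:
            raise ValidationError(f"{name}: missing states {missing}")
        vec = np.array([float(values[s]) for s in STATES])
    else:
        vec = np.asarray(values, dtype=float)
        if vec.shape != (4,):
            raise ValidationError(
                f"{name}: expected a 4-vector over {STATES}, got shape {vec.shape}"
            )
    if not np.all(np.isfinite(vec)):
        raise ValidationError(f"{name}: non-finite values")
    return vec


def check_simplex(vec: np.ndarray, tol: float = 1e-9, name: str = "abundances") -> None:
    """Validate that ``vec`` is a probability vector (entries >= 0, sum 1)."""
    if np.any(vec < -tol):
        raise ValidationError(f"{name}: negative entries {vec.tolist()}")
    total = float(vec.sum())
    if abs(total - 1.0) > tol:
        raise ValidationError(
            f"{name}: entries sum to {total:.6g}, not 1 (tolerance {tol:g})"
        )


def check_times(times: np.ndarray, name: str = "times", nonnegative: bool = False) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValidationError(f"{name}: expected a non-empty 1-D array")
    if not np.all(np.isfinite(times)):
        raise ValidationError(f"{name}: non-finite values")
    if np.any(np.diff(times) <= 0):
        raise ValidationError(f"{name}: must be strictly increasing")
    if nonnegative and times[0] < 0:
        raise ValidationError(f"{name}: must start at t >= 0")
    return times
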