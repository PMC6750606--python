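"""Inversion-recovery T1 fitting with Look-Locker correction.

A Look-Locker readout samples the longitudinal magnetization at a series of
inversion times TI.  The recovery of the (signed) signal follows

    S(TI) = A - B * exp(-TI / T1*)

where ``T1*`` is the *apparent* relaxation time, shortened by the repeated
readout pulses.  The true T1 is recovered from the best-fit parameters with
the standard correction

    T1 = T1* * (B/A - 1)

which requires A > 0 and B > A (a physically meaningful recovery from a
(partially) inverted state toward a positive equilibrium).

All times are in seconds; signal units are arbitrary and cancel in the
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DegenerateDataError, DomainError, InsufficientDataError

#: Upper bound on the apparent relaxation time, generous for myocardium and
#: blood at any field strength (physiologic T1* is well under 3 s).
T1_STAR_MAX_S = 10.0

_T1_STAR_MIN_S = 1e-6


@dataclass(frozen=True)
class IRCurve:
    """One inversion-recovery curve: segment-averaged (or blood-pool) signal vs TI.

    Parameters
    ----------
    inversion_times : array-like
        Inversion times in seconds; strictly positive, strictly increasing,
        at least 4 samples.
    signals : array-like
        Measured signed signal intensities, same length, arbitrary units.
    label : str
        Free-text identifier, e.g. an AHA segment name or ``"blood"``.
    """

    inversion_times: np.ndarray
    signals: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        ti = np.asarray(self.inversion_times, dtype=float)
        sig = np.asarray(self.signals, dtype=float)
        if ti.ndim != 1 or sig.ndim != 1 or ti.size != sig.size:
            raise DomainError("inversion_times and signals must be 1-D and equal length")
        if ti.size < 4:
            raise InsufficientDataError(
                f"need at least 4 inversion times, got {ti.size}"
            )
        if not np.all(ti > 0):
            raise DomainError("inversion times must be strictly positive")
        if not np.all(np.diff(ti) > 0):
            raise DomainError("inversion times must be strictly increasing")
        if not np.all(np.isfinite(sig)):
            raise DomainError("signals must be finite")
        object.__setattr__(self, "inversion_times", ti)
        object.__setattr__(self, "signals", sig)

    def __len__(self) -> int:
        return int(self.inversion_times.size)


@dataclass(frozen=True)
class IRFitResult:
    """Best-fit inversion-recovery parameters and the corrected T1.

    ``t1`` is ``t1_star * (b/a - 1)`` whenever the correction domain
    (a > 0, b > a) holds and NaN otherwise.
    """

    a: float
    b: float
    t1_star: float
    t1: float
    residual_sse: float
    converged: bool
    label: str = ""

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "a": self.a,
            "b": self.b,
            "t1_star_s": self.t1_star,
            "t1_s": self.t1,
            "residual_sse": self.residual_sse,
            "converged": self.converged,
        }


def correct_look_locker(a: float, b: float, t1_star: float) -> float:
    """Apply the Look-Locker correction T1 = T1* * (B/A - 1).

    Raises
    ------
    DomainError
        If ``a <= 0``, ``b <= a`` or ``t1_star <= 0`` — a non-physical
        apparent recovery for which the correction is undefined.
    """
    if a <= 0:
        raise DomainError(f"equilibrium signal A must be positive, got {a}")
    if b <= a:
        raise DomainError(
            f"recovery amplitude B ({b}) must exceed A ({a}) for a physical inversion"
        )
    if t1_star <= 0:
        raise DomainError(f"apparent T1* must be positive, got {t1_star}")
    return t1_star * (b / a - 1.0)


def _model(params: np.ndarray, ti: np.ndarray) -> np.ndarray:
    a, b, t1_star = params
    return a - b * np.exp(-ti / t1_star)


def fit_inversion_recovery(
    curve: IRCurve, init: tuple[float, float, float] | None = None
) -> IRFitResult:
    """Least-squares fit of S(TI) = A - B exp(-TI/T1*) to one curve.

    Parameters
    ----------
    curve : IRCurve
    init : (A0, B0, T1*0), optional
        Starting point.  Defaults to A0 = max signal, B0 = max - min signal,
        T1*0 = median TI, which is robust across physiologic T1 values.

    Returns
    -------
    IRFitResult
        With ``converged`` reflecting solver success rather than raising.

    Raises
    ------
    InsufficientDataError
        Fewer than 4 samples (enforced at :class:`IRCurve` construction too).
    DegenerateDataError
        All signals identical, or the optimum collapses to a non-positive
        apparent relaxation time.
    """
    ti = curve.inversion_times
    sig = curve.signals
    if sig.size < 4:
        raise InsufficientDataError("need at least 4 samples to fit 3 parameters")
    if np.ptp(sig) == 0:
        raise DegenerateDataError("signals are all identical; recovery is unobservable")

    if init is None:
        a0 = float(sig.max())
        b0 = float(sig.max() - sig.min())
        t0 = float(np.median(ti))
    else:
        a0, b0, t0 = (float(v) for v in init)
    t0 = min(max(t0, 10 * _T1_STAR_MIN_S), T1_STAR_MAX_S * 0.99)

    scale = max(float(np.max(np.abs(sig))), 1e-12)
    res = least_squares(
        lambda p: _model(p, ti) - sig,
        x0=np.array([a0, b0, t0]),
        bounds=([-np.inf, -np.inf, _T1_STAR_MIN_S], [np.inf, np.inf, T1_STAR_MAX_S]),
        ftol=1e-14,
        xtol=1e-14,
        gtol=1e-14,
        x_scale=[scale, scale, 1.0],
        max_nfev=2000,
    )
    a, b, t1_star = (float(v) for v in res.x)
    if t1_star <= 10 * _T1_STAR_MIN_S:
        raise DegenerateDataError(
            "fit collapsed to a non-positive apparent relaxation time"
        )
    sse = float(np.sum(res.fun**2))
    t1 = t1_star * (b / a - 1.0) if (a > 0 and b > a) else float("nan")
    return IRFitResult(
        a=a,
        b=b,
        t1_star=t1_star,
        t1=t1,
        residual_sse=sse,
        converged=bool(res.success),
        label=curve.label,
    )
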