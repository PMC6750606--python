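"""Extracellular volume fraction (ECV) from serial T1 measurements.

The contrast agent distributes in the extracellular space, so across contrast
states the myocardial relaxation rate R1 = 1/T1 tracks the blood-pool R1
linearly.  The slope of that line is the partition coefficient lambda, and

    ECV = lambda * (1 - HCT)

converts it to a tissue volume fraction using the hematocrit.  R1 pairs whose
blood-pool R1 is high (>= 3.5 1/s, i.e. early after a bolus) are excluded
from the regression: at high contrast concentration the fast-water-exchange
assumption breaks down and ECV would be underestimated.

Segments with late gadolinium enhancement are excluded when averaging ECV to
a global non-infarct value, which estimates diffuse (non-scar) fibrosis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DomainError, InsufficientDataError, NonPhysicalValueWarning

#: Blood-pool R1 (1/s) at or above which a pre/post-contrast pair is excluded
#: from the partition-coefficient regression (fast-water-exchange limit).
R1_BLOOD_EXCLUSION_S1 = 3.5

#: Canonical AHA 16-segment labels (basal 1-6, mid 7-12, apical 13-16).
AHA16_SEGMENTS = (
    "basal_anterior",
    "basal_anteroseptal",
    "basal_inferoseptal",
    "basal_inferior",
    "basal_inferolateral",
    "basal_anterolateral",
    "mid_anterior",
    "mid_anteroseptal",
    "mid_inferoseptal",
    "mid_inferior",
    "mid_inferolateral",
    "mid_anterolateral",
    "apical_anterior",
    "apical_septal",
    "apical_inferior",
    "apical_lateral",
)


@dataclass(frozen=True)
class R1Pair:
    """Simultaneous blood-pool and myocardial relaxation rates (1/s)."""

    r1_blood: float
    r1_myo: float
    timepoint_label: str = ""

    def __post_init__(self) -> None:
        for name, v in (("r1_blood", self.r1_blood), ("r1_myo", self.r1_myo)):
            if not np.isfinite(v) or v <= 0:
                raise DomainError(f"{name} must be positive and finite, got {v}")


@dataclass(frozen=True)
class PartitionFit:
    """OLS fit of myocardial R1 on blood R1 over the retained pairs."""

    slope: float
    intercept: float
    excluded: tuple[R1Pair, ...]
    n_used: int


@dataclass(frozen=True)
class ECVFit:
    """Partition-coefficient regression plus the hematocrit conversion."""

    lambda_: float
    intercept: float
    ecv: float
    hct: float
    n_used: int
    excluded: tuple[R1Pair, ...]
    nonphysical: bool


@dataclass(frozen=True)
class SegmentalECVMap:
    """Per-segment ECV fractions with late-enhancement flags."""

    segment_ids: tuple[str, ...]
    ecv_values: np.ndarray
    lge_positive: np.ndarray

    def __post_init__(self) -> None:
        ecv = np.asarray(self.ecv_values, dtype=float)
        lge = np.asarray(self.lge_positive, dtype=bool)
        if not (len(self.segment_ids) == ecv.size == lge.size):
            raise DomainError("segment_ids, ecv_values and lge_positive must align")
        if np.any((ecv < 0) | (ecv > 1)):
            raise DomainError("ecv_values must be fractions in [0, 1]")
        object.__setattr__(self, "segment_ids", tuple(self.segment_ids))
        object.__setattr__(self, "ecv_values", ecv)
        object.__setattr__(self, "lge_positive", lge)


def compute_r1(t1: float) -> float:
    """Relaxation rate R1 = 1/T1 (1/s) from T1 in seconds."""
    if not np.isfinite(t1) or t1 <= 0:
        raise DomainError(f"T1 must be positive and finite, got {t1}")
    return 1.0 / t1


def fit_partition_coefficient(pairs: list[R1Pair] | tuple[R1Pair, ...]) -> PartitionFit:
    """Estimate lambda as the OLS slope of R1_myo on R1_blood.

    Pairs with ``r1_blood >= 3.5 1/s`` are excluded first (the boundary value
    itself is excluded: only pairs strictly below the limit are kept) and
    returned for audit.

    Raises
    ------
    InsufficientDataError
        Fewer than 2 pairs remain after the exclusion.
    """
    retained = [p for p in pairs if p.r1_blood < R1_BLOOD_EXCLUSION_S1]
    excluded = tuple(p for p in pairs if p.r1_blood >= R1_BLOOD_EXCLUSION_S1)
    if len(retained) < 2:
        raise InsufficientDataError(
            f"need >= 2 R1 pairs below {R1_BLOOD_EXCLUSION_S1} 1/s; "
            f"got {len(retained)} (of {len(pairs)})"
        )
    x = np.array([p.r1_blood for p in retained])
    y = np.array([p.r1_myo for p in retained])
    if np.ptp(x) == 0:
        raise InsufficientDataError("retained blood R1 values are identical; slope undefined")
    fit = stats.linregress(x, y)
    return PartitionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        excluded=excluded,
        n_used=len(retained),
    )


def compute_ecv(lambda_: float, hct: float) -> float:
    """ECV = lambda * (1 - HCT), with HCT a fraction in (0, 1).

    A result outside [0, 1] is non-physical; it is returned unchanged with a
    :class:`NonPhysicalValueWarning` rather than clipped.
    """
    if not (0 < hct < 1):
        raise DomainError(f"hematocrit must be a fraction in (0, 1), got {hct}")
    ecv = lambda_ * (1.0 - hct)
    if not (0.0 <= ecv <= 1.0):
        warnings.warn(
            f"ECV {ecv:.4f} outside [0, 1] (lambda={lambda_}, hct={hct})",
            NonPhysicalValueWarning,
            stacklevel=2,
        )
    return ecv


def ecv_fit(pairs: list[R1Pair] | tuple[R1Pair, ...], hct: float) -> ECVFit:
    """Full ECV estimation: exclusion, lambda regression, hematocrit conversion."""
    part = fit_partition_coefficient(pairs)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", NonPhysicalValueWarning)
        ecv = compute_ecv(part.slope, hct)
        nonphysical = any(issubclass(w.category, NonPhysicalValueWarning) for w in caught)
    if nonphysical:
        warnings.warn(
            f"non-physical ECV {ecv:.4f} flagged", NonPhysicalValueWarning, stacklevel=2
        )
    return ECVFit(
        lambda_=part.slope,
        intercept=part.intercept,
        ecv=ecv,
        hct=hct,
        n_used=part.n_used,
        excluded=part.excluded,
        nonphysical=nonphysical,
    )


def aggregate_noninfarct_ecv(segmap: SegmentalECVMap) -> float:
    """Unweighted mean ECV over LGE-negative segments (global non-infarct ECV)."""
    remote = segmap.ecv_values[~segmap.lge_positive]
    if remote.size == 0:
        raise DomainError("all segments are LGE-positive; no remote myocardium to average")
    return float(remote.mean())
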