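"""Infarct quantification on late-gadolinium-enhancement (LGE) images.

Infarcted myocardium retains gadolinium and appears hyperintense.  A pixel is
classified as infarct when its intensity is at or above

    threshold = mean(remote) + k * SD(remote)

with k = 2 by default, where "remote" is an operator-supplied region of
myocardium away from the infarct.  SD is the sample standard deviation
(n - 1 denominator).  Masses follow from pixel geometry and a myocardial
density of 1.05 g/mL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DegenerateDataError, DomainError

#: Standard myocardial tissue density, g/mL.
MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclass(frozen=True)
class LGESlice:
    """One short-axis LGE slice with myocardial and remote-myocardium masks."""

    pixel_intensities: np.ndarray
    myocardial_mask: np.ndarray
    remote_mask: np.ndarray
    pixel_area_mm2: float
    slice_thickness_mm: float

    def __post_init__(self) -> None:
        img = np.asarray(self.pixel_intensities, dtype=float)
        myo = np.asarray(self.myocardial_mask, dtype=bool)
        rem = np.asarray(self.remote_mask, dtype=bool)
        if img.ndim != 2:
            raise DomainError("pixel_intensities must be a 2-D grid")
        if myo.shape != img.shape or rem.shape != img.shape:
            raise DomainError("masks must match the image shape")
        if np.any(rem & ~myo):
            raise DomainError("remote_mask must be a subset of myocardial_mask")
        if rem.sum() < 2:
            raise DomainError("remote_mask needs at least 2 pixels for an SD")
        if self.pixel_area_mm2 <= 0 or self.slice_thickness_mm <= 0:
            raise DomainError("pixel_area_mm2 and slice_thickness_mm must be positive")
        object.__setattr__(self, "pixel_intensities", img)
        object.__setattr__(self, "myocardial_mask", myo)
        object.__setattr__(self, "remote_mask", rem)


@dataclass(frozen=True)
class InfarctResult:
    """2-SD segmentation output: threshold, mask, and mass summaries."""

    threshold: float
    infarct_mask: np.ndarray
    infarct_mass_g: float
    infarct_pct_lv: float
    lv_mass_g: float
    n_infarct_pixels: int


def _pixel_volume_ml(slc: LGESlice) -> float:
    # mm^2 * mm = mm^3; 1000 mm^3 per mL
    return slc.pixel_area_mm2 * slc.slice_thickness_mm / 1000.0


def segment_infarct(
    slc: LGESlice,
    k_sd: float = 2.0,
    density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> InfarctResult:
    """Threshold the slice at remote mean + ``k_sd`` remote SDs (inclusive >=).

    Raises
    ------
    DegenerateDataError
        If the remote region has zero intensity spread.
    """
    remote = slc.pixel_intensities[slc.remote_mask]
    sd = float(remote.std(ddof=1))
    if sd == 0:
        raise DegenerateDataError("remote myocardium has zero SD; threshold undefined")
    threshold = float(remote.mean()) + k_sd * sd
    mask = slc.myocardial_mask & (slc.pixel_intensities >= threshold)
    vol = _pixel_volume_ml(slc)
    infarct_mass = float(mask.sum()) * vol * density_g_per_ml
    lv = float(slc.myocardial_mask.sum()) * vol * density_g_per_ml
    return InfarctResult(
        threshold=threshold,
        infarct_mask=mask,
        infarct_mass_g=infarct_mass,
        infarct_pct_lv=100.0 * infarct_mass / lv,
        lv_mass_g=lv,
        n_infarct_pixels=int(mask.sum()),
    )


def lv_mass(
    slices: Sequence[LGESlice] | Iterable[LGESlice],
    density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> float:
    """Total LV mass in grams, summed over slices from myocardial pixel counts."""
    slices = list(slices)
    if not slices:
        raise DomainError("need at least one slice")
    total = 0.0
    for slc in slices:
        n_myo = int(slc.myocardial_mask.sum())
        if n_myo == 0:
            raise DomainError("a slice has an empty myocardial mask")
        total += n_myo * _pixel_volume_ml(slc) * density_g_per_ml
    return total
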