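"""Readers and writers for the package's text formats.

IR curves travel as CSV with columns ``label, ti_s, signal``; fit results and
run reports as JSON; LGE slices as long-format pixel CSV (columns ``row, col,
intensity, myocardium, remote``) or, optionally, as NIfTI volumes; cohorts as
CSV using the :data:`~omega3cmr.trialstats.COLUMN_DICT` schema.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .infarct import LGESlice
from .relaxometry import IRCurve, IRFitResult


def write_ir_curves_csv(curves: Iterable[IRCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for ti, s in zip(c.inversion_times, c.signals):
            rows.append({"label": c.label, "ti_s": ti, "signal": s})
    pd.DataFrame(rows, columns=["label", "ti_s", "signal"]).to_csv(path, index=False)


def read_ir_curves_csv(path: str | Path) -> list[IRCurve]:
    df = pd.read_csv(path)
    missing = {"label", "ti_s", "signal"} - set(df.columns)
    if missing:
        raise DomainError(f"IR curve CSV missing columns: {sorted(missing)}")
    curves = []
    for label, grp in df.groupby("label", sort=False):
        grp = grp.sort_values("ti_s")
        curves.append(
            IRCurve(
                inversion_times=grp["ti_s"].to_numpy(float),
                signals=grp["signal"].to_numpy(float),
                label=str(label),
            )
        )
    return curves


def write_fit_results_json(results: Sequence[IRFitResult], path: str | Path) -> None:
    payload = [r.as_dict() for r in results]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_lge_slice_csv(slc: LGESlice, path: str | Path) -> None:
    rows, cols = np.indices(slc.pixel_intensities.shape)
    pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "intensity": slc.pixel_intensities.ravel(),
            "myocardium": slc.myocardial_mask.ravel().astype(int),
            "remote": slc.remote_mask.ravel().astype(int),
        }
    ).to_csv(path, index=False)


def read_lge_slice_csv(
    path: str | Path, pixel_area_mm2: float = 1.0, slice_thickness_mm: float = 8.0
) -> LGESlice:
    df = pd.read_csv(path)
    missing = {"row", "col", "intensity", "myocardium", "remote"} - set(df.columns)
    if missing:
        raise DomainError(f"LGE pixel CSV missing columns: {sorted(missing)}")
    nr, nc = int(df["row"].max()) + 1, int(df["col"].max()) + 1
    img = np.zeros((nr, nc))
    myo = np.zeros((nr, nc), dtype=bool)
    rem = np.zeros((nr, nc), dtype=bool)
    r, c = df["row"].to_numpy(int), df["col"].to_numpy(int)
    img[r, c] = df["intensity"].to_numpy(float)
    myo[r, c] = df["myocardium"].to_numpy(bool)
    rem[r, c] = df["remote"].to_numpy(bool)
    return LGESlice(img, myo, rem, pixel_area_mm2, slice_thickness_mm)


def read_lge_slice_nifti(
    image_path: str | Path,
    myocardial_mask_path: str | Path,
    remote_mask_path: str | Path,
    slice_index: int = 0,
) -> LGESlice:
    """Load an LGE slice plus masks from NIfTI volumes.

    In-plane pixel area and slice thickness come from the image header zooms.
    Volumes with a third dimension are indexed at ``slice_index``.
    """
    import nibabel as nib

    img_nii = nib.load(str(image_path))
    zooms = img_nii.header.get_zooms()

    def _slice(nii) -> np.ndarray:
        data = np.asanyarray(nii.dataobj)
        if data.ndim == 3:
            data = data[:, :, slice_index]
        if data.ndim != 2:
            raise DomainError("expected a 2-D or 3-D NIfTI volume")
        return data

    img = _slice(img_nii).astype(float)
    myo = _slice(nib.load(str(myocardial_mask_path))) > 0
    rem = _slice(nib.load(str(remote_mask_path))) > 0
    pixel_area = float(zooms[0]) * float(zooms[1])
    thickness = float(zooms[2]) if len(zooms) > 2 else 8.0
    return LGESlice(img, myo, rem, pixel_area, thickness)


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_column_map(path: str | Path) -> dict:
    """A JSON object mapping source spreadsheet column names to the cohort schema."""
    mapping = json.loads(Path(path).read_text())
    if not isinstance(mapping, dict):
        raise DomainError("column map must be a JSON object {source: target}")
    return {str(k): str(v) for k, v in mapping.items()}
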