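"""Volume, label-map and cohort I/O.

Conventions used by every other module:

* voxel indexing is 0-based; the axial ("transversal") plane is the plane of
  the first two axes and the slice index runs along the third axis;
* label codes are fixed: 1 LV, 2 RV, 3 LA, 4 RA, 5 LPA, 6 RPA, 7 MPA, 8 AA,
  0 background;
* cohorts are comma-separated UTF-8 CSV with a header row, "." decimal and
  the empty string for a missing cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

#: Fixed label legend shared by every module.
LABEL_LEGEND = {
    0: "background",
    1: "LV",
    2: "RV",
    3: "LA",
    4: "RA",
    5: "LPA",
    6: "RPA",
    7: "MPA",
    8: "AA",
}
#: Structure name -> integer code (background excluded).
STRUCTURE_CODES = {name: code for code, name in LABEL_LEGEND.items() if code != 0}

CHAMBERS = ("LV", "RV", "LA", "RA")
VESSELS = ("MPA", "RPA", "LPA", "AA")

#: Default standardization target (x, y, slices).
DEFAULT_CROP_SHAPE = (512, 512, 480)

#: Pad fill for standardize_crop: air in Hounsfield units.
AIR_HU = -1024.0

#: The 16 morphological feature columns, named as reported.
FEATURE_COLUMNS = [
    "MPAd", "RPAd", "LPAd", "AAd", "LVd", "RVd", "LAd", "RAd",
    "LAa", "RAa", "LVa", "RVa",
    "MPAd/AAd", "RPAd/LPAd", "RVd/LVd", "RAd/LAd",
]
HEMO_COLUMNS = ["mPAP", "sPAP", "dPAP", "TPR", "CO", "PCWP", "PVR"]


class FormatError(ValueError):
    """Malformed on-disk data; the message names the offending field."""


class CohortValidationError(ValueError):
    """Cohort table violates an invariant (e.g. duplicate patient_id)."""


@dataclass
class Volume:
    """A 3D scalar grid in HU with physical voxel spacing (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMap:
    """Integer grid aligned with a :class:`Volume`; codes 0-8."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    legend: dict = field(default_factory=lambda: dict(LABEL_LEGEND))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label map must be 3D, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label map must hold integers")
        codes = np.unique(self.data)
        if codes.size and (codes.min() < 0 or codes.max() > 8):
            raise ValueError(f"label codes outside 0..8: {codes}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def mask(self, structure: str) -> np.ndarray:
        """Binary mask of one named substructure."""
        return self.data == STRUCTURE_CODES[structure]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(vol: Volume, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32),
                          _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def read_volume(path) -> Volume:
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed header / not NIfTI
        raise FormatError(f"cannot read NIfTI volume at {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float32)
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"non-positive voxel spacing in header: {zooms}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return Volume(data=data, spacing=tuple(float(z) for z in zooms), origin=origin)


def write_labels(labels: LabelMap, path) -> None:
    img = nib.Nifti1Image(np.asarray(labels.data, dtype=np.int16),
                          _affine(labels.spacing, labels.origin))
    nib.save(img, str(path))


def read_labels(path) -> LabelMap:
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI label map at {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise FormatError(f"label map at {path} holds non-integer values")
    data = data.astype(np.int16)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return LabelMap(data=data, spacing=tuple(float(z) for z in zooms), origin=origin)


def _crop_pad_1d(n_in: int, n_out: int) -> tuple[slice, tuple[int, int]]:
    """Return (source slice, (pad_low, pad_high)) for one axis.

    Odd remainders put the extra voxel on the low-index side, both when
    cropping and when padding.
    """
    if n_in >= n_out:
        rem = n_in - n_out
        lo = (rem + 1) // 2
        return slice(lo, lo + n_out), (0, 0)
    pad = n_out - n_in
    return slice(0, n_in), ((pad + 1) // 2, pad // 2)


def standardize_crop(vol: Volume, target: tuple[int, int, int] = DEFAULT_CROP_SHAPE) -> Volume:
    """Center-crop / zero-pad (air fill, −1024 HU) a volume to ``target``.

    Per axis the input is center-cropped when larger and symmetrically padded
    when smaller; an odd remainder places the extra voxel on the low-index
    side in both cases.
    """
    target = tuple(int(t) for t in target)
    if any(t < 1 for t in target):
        raise ValueError(f"target dims must be >= 1, got {target}")
    if vol.shape == target:
        return vol
    slices, pads = zip(*(_crop_pad_1d(n, t) for n, t in zip(vol.shape, target)))
    out = vol.data[slices[0], slices[1], slices[2]]
    if any(p != (0, 0) for p in pads):
        out = np.pad(out, pads, mode="constant", constant_values=AIR_HU)
    return replace(vol, data=out)


@dataclass
class CohortTable:
    """Rows of (patient_id, morphological features, hemodynamics).

    Missing cells are carried as NaN; :meth:`column_n` reports the per-column
    count of present values (the "n = 55/54/48" bookkeeping).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if "patient_id" not in self.df.columns:
            raise CohortValidationError("cohort table lacks a patient_id column")
        ids = self.df["patient_id"]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise CohortValidationError(
                f"duplicate patient_id: {sorted(set(dup.astype(str)))}")

    def __len__(self) -> int:
        return len(self.df)

    def column_n(self, column: str) -> int:
        """Number of non-missing values in one column."""
        return int(self.df[column].notna().sum())

    def features(self) -> pd.DataFrame:
        cols = [c for c in FEATURE_COLUMNS if c in self.df.columns]
        return self.df[cols]

    def hemodynamics(self) -> pd.DataFrame:
        cols = [c for c in HEMO_COLUMNS if c in self.df.columns]
        return self.df[cols]


KNOWN_COLUMNS = ["patient_id"] + FEATURE_COLUMNS + HEMO_COLUMNS


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.df.to_csv(str(path), index=False, na_rep="")


def read_cohort(path) -> CohortTable:
    df = pd.read_csv(str(path))
    unknown = [c for c in df.columns if c not in KNOWN_COLUMNS]
    if unknown:
        warnings.warn(f"unknown cohort columns passed through: {unknown}",
                      stacklevel=2)
    return CohortTable(df=df)
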