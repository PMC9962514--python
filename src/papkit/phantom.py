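"""Synthetic thoracic phantom cohort.

Generates (a) hemodynamic records whose mPAP/sPAP moments match the study
cohort (mPAP 42.82 ± 12.74 mmHg, sPAP 68.35 ± 20.62 mmHg, all subjects with
resting mPAP ≥ 25 mmHg), (b) per-patient geometric heart/vessel primitives
whose measurable features carry the reported correlation signs with severity
(left-atrial size shrinking, right-over-left ratios growing with mPAP),
(c) rasterized contrast-CT-like volumes with ground-truth label maps, and
(d) degraded candidate masks emulating a poor pre-segmentation.

The anatomy is deliberately primitive — axis-aligned ellipsoid chambers and
vertical cylindrical vessels — so every downstream measurement has an
analytic oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volio import (
    CHAMBERS,
    CohortTable,
    FEATURE_COLUMNS,
    HEMO_COLUMNS,
    LabelMap,
    STRUCTURE_CODES,
    Volume,
)

# Table-level cohort moments the generator reproduces (mmHg, L/min, dyn·s·cm⁻⁵).
MPAP_MEAN, MPAP_SD = 42.82, 12.74
SPAP_MEAN, SPAP_SD = 68.35, 20.62
CO_MEDIAN, CO_LOG_SD = 4.64, 0.35
PCWP_MEAN, PCWP_SD = 6.86, 4.79
PH_MPAP_FLOOR = 25.0  # PH diagnosis: resting mPAP >= 25 mmHg

# sPAP is regressed on mPAP with this slope; the residual SD is derived at
# runtime so the marginal sPAP variance lands on 20.62².
_SPAP_SLOPE = 1.4

#: Tissue intensities (HU).
HU_CONTRAST = 350.0
HU_MYOCARDIUM = 100.0
HU_LUNG = -800.0
HU_SOFT = 40.0
HU_AIR = -1024.0


class GeometryError(ValueError):
    """A primitive does not fit inside the voxel grid."""


@dataclass
class HemodynamicRecord:
    """Right-heart-catheterization pressures for one patient."""

    patient_id: str
    mPAP: float
    sPAP: float
    dPAP: float
    TPR: float
    CO: float
    PCWP: float
    PVR: float

    def __post_init__(self) -> None:
        for name in ("mPAP", "sPAP", "dPAP", "TPR", "CO", "PCWP", "PVR"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")
        if not (self.dPAP <= self.mPAP <= self.sPAP):
            raise ValueError(
                f"pressure ordering violated: dPAP={self.dPAP} mPAP={self.mPAP} "
                f"sPAP={self.sPAP}")


@dataclass
class PhantomGeometry:
    """Axis-aligned primitives, all in mm.

    ``ellipsoids`` maps structure name -> (center xyz, semi-axes xyz);
    ``tubes`` maps structure name -> (cx, cy, radius, z_low, z_high), a
    cylinder along the slice axis.  ``wall_mm`` is the LV myocardium shell
    thickness (image only, unlabeled).  ``body`` is an optional
    (cx, cy, radius) soft-tissue cylinder; ``lungs`` optional ellipsoids.
    """

    ellipsoids: dict = field(default_factory=dict)
    tubes: dict = field(default_factory=dict)
    wall_mm: float = 8.0
    body: tuple | None = None
    lungs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, (_, semi) in self.ellipsoids.items():
            if any(s <= 0 for s in semi):
                raise ValueError(f"{name}: semi-axes must be positive, got {semi}")
        for name, (_, _, r, z0, z1) in self.tubes.items():
            if r <= 0 or z1 <= z0:
                raise ValueError(f"{name}: bad tube radius/extent")

    def validate_extent(self, shape, spacing) -> None:
        """Raise :class:`GeometryError` if any primitive leaves the grid."""
        extent = [(n - 1) * s for n, s in zip(shape, spacing)]
        for name, (c, semi) in self.ellipsoids.items():
            pad = self.wall_mm if name == "LV" else 0.0
            for ax in range(3):
                if c[ax] - semi[ax] - pad < 0 or c[ax] + semi[ax] + pad > extent[ax]:
                    raise GeometryError(
                        f"{name} ellipsoid exceeds grid along axis {ax}")
        for name, (cx, cy, r, z0, z1) in self.tubes.items():
            if cx - r < 0 or cx + r > extent[0] or cy - r < 0 or cy + r > extent[1]:
                raise GeometryError(f"{name} tube exceeds grid in plane")
            if z0 < 0 or z1 > extent[2]:
                raise GeometryError(f"{name} tube exceeds grid along slices")


def _clipped_normal_params(mean: float, sd: float, floor: float
                           ) -> tuple[float, float]:
    """Pre-clip (mu, sigma) such that max(N(mu, sigma), floor) has the given
    mean and SD, via the closed-form clipped-normal moments."""
    from scipy.optimize import fsolve
    from scipy.stats import norm

    def moments(params):
        mu, sig = params
        a = (floor - mu) / sig
        phi, Phi = norm.pdf(a), norm.cdf(a)
        m1 = floor * Phi + mu * (1 - Phi) + sig * phi
        m2 = (floor ** 2 * Phi + (mu ** 2 + sig ** 2) * (1 - Phi)
              + sig * (mu + floor) * phi)
        return m1 - mean, math.sqrt(max(m2 - m1 ** 2, 1e-12)) - sd

    mu, sig = fsolve(moments, x0=(mean, sd))
    return float(mu), float(sig)


def synth_hemodynamics(n: int, seed: int) -> list[HemodynamicRecord]:
    """Draw ``n`` linked hemodynamic records.

    Generative model: latent severity s ~ N(0,1); mPAP = mu + sigma·s
    clipped to the PH floor of 25 mmHg, with (mu, sigma) calibrated in
    closed form so the clipped distribution has mean 42.82 and SD 12.74;
    sPAP regressed on mPAP with residual noise, kept above mPAP; dPAP from
    the classical mPAP = (sPAP + 2·dPAP)/3 identity plus noise, kept within
    (0, mPAP]; CO lognormal around 4.64 L/min; TPR = 80·mPAP/CO and
    PVR = 80·(mPAP − PCWP)/CO (Wood→metric factor 80).
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    mu, sig = _clipped_normal_params(MPAP_MEAN, MPAP_SD, PH_MPAP_FLOOR)
    spap_resid_sd = math.sqrt(max(SPAP_SD ** 2
                                  - (_SPAP_SLOPE * MPAP_SD) ** 2, 1.0))
    rng = np.random.default_rng(seed)
    s = rng.standard_normal(n)
    mpap = np.maximum(PH_MPAP_FLOOR, mu + sig * s)
    spap = (SPAP_MEAN + _SPAP_SLOPE * (mpap - MPAP_MEAN)
            + spap_resid_sd * rng.standard_normal(n))
    spap = np.maximum(spap, mpap + 2.0)
    dpap = (3.0 * mpap - spap) / 2.0 + 3.0 * rng.standard_normal(n)
    dpap = np.clip(dpap, 1.0, mpap)
    co = np.exp(np.log(CO_MEDIAN) + CO_LOG_SD * rng.standard_normal(n))
    pcwp = np.clip(PCWP_MEAN + PCWP_SD * rng.standard_normal(n), 1.0,
                   np.minimum(dpap, mpap - 1.0))
    tpr = 80.0 * mpap / co
    pvr = 80.0 * (mpap - pcwp) / co
    return [HemodynamicRecord(
        patient_id=f"P{i:04d}", mPAP=float(mpap[i]), sPAP=float(spap[i]),
        dPAP=float(dpap[i]), TPR=float(tpr[i]), CO=float(co[i]),
        PCWP=float(pcwp[i]), PVR=float(pvr[i])) for i in range(n)]


# Base layout for the default 144 mm cube (96 voxels at 1.5 mm spacing).
# Chambers sit in the lower slice range, vessels above; in-plane centers are
# far enough apart that no two labeled structures can touch at the largest
# severity scaling.
_BASE_ELLIPSOIDS = {
    "LV": ((44.0, 44.0, 40.0), (15.0, 13.0, 15.0)),
    "RV": ((100.0, 44.0, 40.0), (17.0, 15.0, 16.0)),
    "LA": ((44.0, 100.0, 42.0), (17.0, 14.0, 13.0)),
    "RA": ((100.0, 100.0, 42.0), (18.0, 15.0, 15.0)),
}
_BASE_TUBES = {
    "MPA": (44.0, 44.0, 13.0, 76.0, 138.0),
    "AA": (100.0, 44.0, 14.0, 76.0, 138.0),
    "LPA": (44.0, 100.0, 9.0, 76.0, 138.0),
    "RPA": (100.0, 100.0, 9.0, 76.0, 138.0),
}
# Severity link slope per structure: scale = 1 + slope·tanh(z/1.2), a smooth,
# strictly monotone, bounded map of standardized severity z.  Signs carry the
# reported correlation structure (left heart shrinks, right heart and
# pulmonary trunk grow with pressure).
_SEVERITY_SLOPE = {
    "LV": -0.10, "RV": +0.12, "LA": -0.15, "RA": +0.12,
    "MPA": +0.08, "AA": 0.0, "LPA": +0.05, "RPA": +0.05,
}
_BODY = (72.0, 72.0, 68.0)
_LUNGS = [((16.0, 72.0, 72.0), (9.0, 55.0, 60.0)),
          ((128.0, 72.0, 72.0), (9.0, 55.0, 60.0))]


def _severity_scale(structure: str, z: float) -> float:
    return 1.0 + _SEVERITY_SLOPE[structure] * math.tanh(z / 1.2)


def synth_geometry(hemo: HemodynamicRecord, seed: int,
                   noise_sd: float = 0.06) -> PhantomGeometry:
    """Geometry for one patient, scaled by standardized severity.

    Each structure's linear scale is the smooth monotone severity link times
    a multiplicative noise term ``1 + N(0, noise_sd)``; with ``noise_sd=0``
    every derived feature is a strictly monotone function of mPAP.
    """
    z = (hemo.mPAP - MPAP_MEAN) / MPAP_SD
    rng = np.random.default_rng(seed)
    ells = {}
    for name, (c, semi) in _BASE_ELLIPSOIDS.items():
        f = _severity_scale(name, z) * (1.0 + noise_sd * rng.standard_normal())
        f = max(f, 0.3)
        ells[name] = (c, tuple(s * f for s in semi))
    tubes = {}
    for name, (cx, cy, r, z0, z1) in _BASE_TUBES.items():
        f = _severity_scale(name, z) * (1.0 + noise_sd * rng.standard_normal())
        f = max(f, 0.3)
        tubes[name] = (cx, cy, r * f, z0, z1)
    return PhantomGeometry(ellipsoids=ells, tubes=tubes, wall_mm=8.0,
                           body=_BODY, lungs=list(_LUNGS))


def render_phantom(geom: PhantomGeometry,
                   shape: tuple[int, int, int] = (96, 96, 96),
                   spacing: tuple[float, float, float] = (1.5, 1.5, 1.5),
                   contrast_hu: float = HU_CONTRAST,
                   noise_sd: float = 10.0,
                   blur_mm: float = 1.5,
                   seed: int = 0) -> tuple[Volume, LabelMap]:
    """Rasterize a phantom into an image volume and its label map.

    Paint order: air → body soft tissue → lungs → LV myocardium shell → the
    eight contrast-filled substructures.  Gaussian blur (``blur_mm``) then
    Gaussian noise (``noise_sd`` HU) are applied to the image only; the label
    map is exact.
    """
    if any(s < 32 for s in shape):
        raise ValueError(f"shape must be >= 32 per axis, got {shape}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive, got {spacing}")
    geom.validate_extent(shape, spacing)

    xs = np.arange(shape[0])[:, None, None] * spacing[0]
    ys = np.arange(shape[1])[None, :, None] * spacing[1]
    zs = np.arange(shape[2])[None, None, :] * spacing[2]

    def ellipsoid_mask(center, semi):
        return ((xs - center[0]) ** 2 / semi[0] ** 2
                + (ys - center[1]) ** 2 / semi[1] ** 2
                + (zs - center[2]) ** 2 / semi[2] ** 2) <= 1.0

    def tube_mask(cx, cy, r, z0, z1):
        inplane = (xs - cx) ** 2 + (ys - cy) ** 2 <= r ** 2
        return inplane & (zs >= z0) & (zs <= z1)

    img = np.full(shape, HU_AIR, dtype=np.float32)
    if geom.body is not None:
        bx, by, br = geom.body
        img[np.broadcast_to((xs - bx) ** 2 + (ys - by) ** 2 <= br ** 2, shape)] = HU_SOFT
    else:
        img[:] = HU_SOFT
    for center, semi in geom.lungs:
        img[ellipsoid_mask(center, semi)] = HU_LUNG
    if "LV" in geom.ellipsoids and geom.wall_mm > 0:
        c, semi = geom.ellipsoids["LV"]
        outer = ellipsoid_mask(c, tuple(s + geom.wall_mm for s in semi))
        img[outer] = HU_MYOCARDIUM

    labels = np.zeros(shape, dtype=np.int16)
    for name, (c, semi) in geom.ellipsoids.items():
        m = ellipsoid_mask(c, semi)
        img[m] = contrast_hu
        labels[m] = STRUCTURE_CODES[name]
    for name, (cx, cy, r, z0, z1) in geom.tubes.items():
        m = tube_mask(cx, cy, r, z0, z1)
        img[m] = contrast_hu
        labels[m] = STRUCTURE_CODES[name]

    if blur_mm > 0:
        sigma = [blur_mm / s for s in spacing]
        img = ndimage.gaussian_filter(img, sigma=sigma)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=shape).astype(np.float32)

    vol = Volume(data=img.astype(np.float32), spacing=spacing)
    lab = LabelMap(data=labels, spacing=spacing)
    return vol, lab


def _ball(radius: int) -> np.ndarray:
    """Binary ball structuring element of the given voxel radius."""
    r = int(radius)
    ax = np.arange(-r, r + 1)
    return (ax[:, None, None] ** 2 + ax[None, :, None] ** 2
            + ax[None, None, :] ** 2) <= r ** 2


def degrade_mask(labels: LabelMap, structure: str, mode: str,
                 magnitude: int, seed: int = 0) -> np.ndarray:
    """Corrupt one structure's ground-truth mask.

    ``erode`` returns a subset of the truth, ``dilate`` a superset, ``jitter``
    a rigid integer translation by up to ``magnitude`` voxels per axis.
    ``magnitude=0`` returns the truth unchanged.
    """
    if magnitude < 0:
        raise ValueError(f"magnitude must be >= 0, got {magnitude}")
    truth = labels.mask(structure)
    if not truth.any():
        raise ValueError(f"structure {structure} absent from label map")
    if magnitude == 0:
        return truth.copy()
    if mode == "erode":
        return ndimage.binary_erosion(truth, structure=_ball(magnitude))
    if mode == "dilate":
        return ndimage.binary_dilation(truth, structure=_ball(magnitude))
    if mode == "jitter":
        rng = np.random.default_rng(seed)
        shift = rng.integers(-magnitude, magnitude + 1, size=3)
        if not shift.any():
            shift[rng.integers(0, 3)] = magnitude
        return np.roll(truth, shift, axis=(0, 1, 2))
    raise ValueError(f"unknown mode {mode!r}")


def synth_cohort(n: int, seed: int,
                 shape: tuple[int, int, int] = (96, 96, 96),
                 spacing: tuple[float, float, float] = (1.5, 1.5, 1.5),
                 noise_sd: float = 10.0, blur_mm: float = 1.5,
                 geometry_noise_sd: float = 0.06,
                 emulate_missingness: bool = False) -> CohortTable:
    """Full measured cohort: hemodynamics → geometry → render → morphometry.

    Features are measured from the rendered label maps with the morphometry
    module (the same path real data would take).  With
    ``emulate_missingness`` the reported per-column n pattern is applied
    (1/55 of sPAP and dPAP cells, 7/55 of TPR cells missing at random).
    """
    from .morphometry import morpho_record  # local import: avoid cycle

    hemos = synth_hemodynamics(n, seed)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for i, h in enumerate(hemos):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        geom = synth_geometry(h, seed=sub_seed, noise_sd=geometry_noise_sd)
        _, lab = render_phantom(geom, shape=shape, spacing=spacing,
                                noise_sd=noise_sd, blur_mm=blur_mm,
                                seed=sub_seed)
        rec = morpho_record(lab)
        row = {"patient_id": h.patient_id}
        row.update({k: rec.get(k) for k in FEATURE_COLUMNS})
        row.update({k: getattr(h, k) for k in HEMO_COLUMNS})
        rows.append(row)
    df = pd.DataFrame(rows, columns=["patient_id"] + FEATURE_COLUMNS + HEMO_COLUMNS)
    if emulate_missingness and n > 0:
        miss_rng = np.random.default_rng(seed + 2)
        n_sp = round(n * 1 / 55)
        n_tpr = round(n * 7 / 55)
        for col, k in (("sPAP", n_sp), ("dPAP", n_sp), ("TPR", n_tpr)):
            if k > 0:
                idx = miss_rng.choice(n, size=k, replace=False)
                df.loc[idx, col] = np.nan
    return CohortTable(df=df)
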