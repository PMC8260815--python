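"""Segmentation and bone traits of a pQCT cross-section.

Implements the standard single-slice pQCT outcome set for the tibia:

* distal (5%) site: total BMC (mg/mm), total CSA (mm^2), total and
  trabecular vBMD (mg/cm^3) and the compressive bone strength index
  BSI_COMP = vBMD_TOT^2 x CSA_TOT (g^2/cm^4);
* shaft (50%) site: total/cortical/medullary CSA, cortical vBMD, marrow-
  excluded total BMC, density-weighted principal second moments of area
  I_max/I_min (mg*cm) and the polar distribution of bone mineral mass in
  5-degree bins aggregated to eight 45-degree anatomical sectors.

Segmentation uses fixed density thresholds: the outer bone border at
169 mg/cm^3 (distal) or 280 mg/cm^3 (shaft), marrow below 100 mg/cm^3, and
a configurable cortical threshold (default 710 mg/cm^3) standing in for the
proprietary contour-detection mode of the original scanner software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .image import MARROW_THRESHOLD, SEGMENTATION_THRESHOLD, DensitySlice

__all__ = [
    "MaskSet",
    "DistalTraits",
    "ShaftTraits",
    "PolarProfile",
    "SECTOR_LABELS",
    "segment_bone",
    "separate_compartments",
    "extract_distal_traits",
    "extract_shaft_traits",
    "polar_mass_distribution",
    "muscle_csa",
    "cv_rms",
    "medullary_area",
    "bsi_comp",
]

#: default density (mg/cm^3) separating cortical from trabecular bone
CORTICAL_THRESHOLD = 710.0

#: anatomical 45-degree sectors, anterior first, proceeding toward medial
SECTOR_LABELS = ("A", "A-M", "M", "P-M", "P", "P-L", "L", "A-L")

N_BINS = 72
BINS_PER_SECTOR = 9


@dataclass
class MaskSet:
    """Boolean compartment masks congruent with the analysed slice."""

    total: np.ndarray
    cortical: np.ndarray
    trabecular: np.ndarray
    medullary: np.ndarray
    low_density_warning: bool = False

    @property
    def empty(self) -> bool:
        return not bool(self.total.any())


@dataclass
class DistalTraits:
    """Distal-tibia outcomes; ``None`` marks a missing (not zero) trait."""

    bmc_tot: float | None = None  # mg/mm
    csa_tot: float | None = None  # mm^2
    vbmd_tot: float | None = None  # mg/cm^3
    vbmd_trab: float | None = None  # mg/cm^3
    bsi_comp: float | None = None  # g^2/cm^4


@dataclass
class PolarProfile:
    """Polar bone-mass distribution around the section centre.

    ``bins`` holds BMC (mg/cm) in 72 half-open 5-degree bins, bin 0 starting
    at the anterior direction and angles increasing toward medial.
    ``sectors`` sums nine consecutive bins per 45-degree sector, each sector
    centred on its anatomical direction; ``None`` when the slice carries no
    orientation tag.
    """

    bins: np.ndarray
    sectors: dict[str, float] | None
    center_mm: tuple[float, float]
    side: str = "right"


@dataclass
class ShaftTraits:
    """Mid-shaft outcomes; ``None`` marks a missing trait."""

    bmc_tot: float | None = None  # mg/mm, marrow excluded
    csa_tot: float | None = None  # mm^2, including marrow
    csa_co: float | None = None  # mm^2
    csa_m: float | None = None  # mm^2, == csa_tot - csa_co
    vbmd_co: float | None = None  # mg/cm^3
    i_max: float | None = None  # mg*cm
    i_min: float | None = None  # mg*cm
    polar: PolarProfile | None = None


def medullary_area(csa_tot: float, csa_co: float) -> float:
    """Medullary CSA from the identity CSA_M = CSA_TOT - CSA_CO (mm^2)."""
    return csa_tot - csa_co


def bsi_comp(vbmd_tot: float, csa_tot: float) -> float:
    """Compressive strength index (g^2/cm^4) from vBMD (mg/cm^3), CSA (mm^2)."""
    return (vbmd_tot / 1000.0) ** 2 * (csa_tot / 100.0)


def _largest_component(binary: np.ndarray) -> np.ndarray:
    """Largest 8-connected component; ties broken by smallest top-left index."""
    labels = measure.label(binary, connectivity=2)
    n = labels.max()
    if n == 0:
        return np.zeros_like(binary, dtype=bool)
    sizes = np.bincount(labels.ravel())[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) == 1:
        keep = best[0]
    else:
        flat = labels.ravel()
        keep = min(best, key=lambda lab: int(np.argmax(flat == lab)))
    return labels == keep


def segment_bone(
    slc: DensitySlice, cortical_threshold: float = CORTICAL_THRESHOLD
) -> MaskSet:
    """Segment a slice into total / cortical / trabecular / medullary masks.

    The total mask is the hole-filled largest 8-connected component of pixels
    at or above the site's segmentation threshold (the periosteal region);
    compartments are then split by :func:`separate_compartments`.  If no
    pixel reaches the threshold an empty (flagged) mask set is returned.
    """
    threshold = SEGMENTATION_THRESHOLD[slc.site]
    binary = slc.values >= threshold
    component = _largest_component(binary)
    if not component.any():
        z = np.zeros_like(binary, dtype=bool)
        return MaskSet(z, z.copy(), z.copy(), z.copy())
    total = ndimage.binary_fill_holes(component)
    return separate_compartments(slc, total, slc.site, cortical_threshold)


def separate_compartments(
    slc: DensitySlice,
    total: np.ndarray,
    site: str,
    cortical_threshold: float = CORTICAL_THRESHOLD,
    clean: bool = True,
) -> MaskSet:
    """Split the periosteal region into cortical/trabecular/medullary masks.

    Cortical bone is taken as pixels at or above ``cortical_threshold``
    (after one pass of binary opening when ``clean``); the medullary mask
    holds pixels below the marrow threshold inside the periosteal boundary;
    trabecular/subcortical bone is the remainder.  At the distal site marrow
    is included with the trabecular compartment, mirroring the convention
    that distal analyses keep bone marrow in the totals.
    """
    if not total.any():
        raise ValueError("total mask is empty")
    cortical = total & (slc.values >= cortical_threshold)
    if clean and cortical.any():
        # 2x2 block opening: removes isolated speckle but leaves any solid
        # rectangle (and hence a clean cortex) untouched
        opened = ndimage.binary_opening(cortical, structure=np.ones((2, 2), dtype=bool))
        if opened.any():  # do not let cleaning erase a thin but real cortex
            cortical = opened & total
    medullary = total & (slc.values < MARROW_THRESHOLD)
    # trabecular/subcortical bone by density window (independent of the
    # cleaning applied to the cortical mask, so a speckle pixel dropped from
    # the cortex is not misread as trabecular bone)
    below_cortex = total & (slc.values < cortical_threshold) & ~cortical
    if site == "shaft":
        trabecular = below_cortex & ~medullary
    else:
        trabecular = below_cortex
    return MaskSet(
        total=total,
        cortical=cortical,
        trabecular=trabecular,
        medullary=medullary,
        low_density_warning=not cortical.any(),
    )


def extract_distal_traits(
    slc: DensitySlice, masks: MaskSet | None = None
) -> DistalTraits:
    """Distal-tibia trait set; marrow is included in all totals."""
    if slc.site != "distal":
        raise ValueError("extract_distal_traits requires a distal-site slice")
    if masks is None:
        masks = segment_bone(slc)
    if masks.empty:
        return DistalTraits()
    area = slc.pixel_area_mm2
    csa_tot = float(masks.total.sum()) * area
    vbmd_tot = float(slc.values[masks.total].mean())
    vbmd_trab = (
        float(slc.values[masks.trabecular].mean()) if masks.trabecular.any() else None
    )
    bmc_tot = vbmd_tot * csa_tot * 1e-3
    return DistalTraits(
        bmc_tot=bmc_tot,
        csa_tot=csa_tot,
        vbmd_tot=vbmd_tot,
        vbmd_trab=vbmd_trab,
        bsi_comp=bsi_comp(vbmd_tot, csa_tot),
    )


def _mass_mask(slc: DensitySlice, masks: MaskSet) -> np.ndarray:
    """Pixels contributing mineral mass at the shaft (marrow excluded)."""
    return masks.total & (slc.values >= MARROW_THRESHOLD)


def extract_shaft_traits(
    slc: DensitySlice,
    masks: MaskSet | None = None,
    side: str = "right",
    compute_polar: bool = True,
) -> ShaftTraits:
    """Mid-shaft trait set including density-weighted principal moments.

    The second-moment tensor sums rho_i * a * [[dy^2, -dx dy], [-dx dy,
    dx^2]] over the cortical mask with coordinates in cm relative to the
    density-weighted cortical centroid and pixel area a in cm^2, so its
    eigenvalues I_max >= I_min carry units of mg*cm.
    """
    if slc.site != "shaft":
        raise ValueError("extract_shaft_traits requires a shaft-site slice")
    if masks is None:
        masks = segment_bone(slc)
    if masks.empty:
        return ShaftTraits()
    area = slc.pixel_area_mm2
    csa_tot = float(masks.total.sum()) * area
    csa_co = float(masks.cortical.sum()) * area
    csa_m = medullary_area(csa_tot, csa_co)
    mass = _mass_mask(slc, masks)
    bmc_tot = float((slc.values[mass]).sum()) * area * 1e-3 if mass.any() else None

    vbmd_co = i_max = i_min = None
    if masks.cortical.any():
        vbmd_co = float(slc.values[masks.cortical].mean())
        i_min, i_max = _principal_moments(slc, masks.cortical)

    polar = None
    if compute_polar and mass.any():
        polar = polar_mass_distribution(slc, masks, side=side)
    return ShaftTraits(
        bmc_tot=bmc_tot,
        csa_tot=csa_tot,
        csa_co=csa_co,
        csa_m=csa_m,
        vbmd_co=vbmd_co,
        i_max=i_max,
        i_min=i_min,
        polar=polar,
    )


def _principal_moments(slc: DensitySlice, mask: np.ndarray) -> tuple[float, float]:
    xx, yy = slc.pixel_coordinates()
    x = xx[mask] / 10.0  # cm
    y = yy[mask] / 10.0
    rho = slc.values[mask]
    a = (slc.pixel_mm / 10.0) ** 2  # cm^2
    w = rho * a
    cx = float((w * x).sum() / w.sum())
    cy = float((w * y).sum() / w.sum())
    dx = x - cx
    dy = y - cy
    ixx = float((w * dy * dy).sum())
    iyy = float((w * dx * dx).sum())
    ixy = float((w * dx * dy).sum())
    eig = np.linalg.eigvalsh(np.array([[ixx, -ixy], [-ixy, iyy]]))
    return float(eig[0]), float(eig[1])


def polar_mass_distribution(
    slc: DensitySlice,
    masks: MaskSet,
    side: str = "right",
    center: str = "mass",
    angular_supersample: int = 1,
) -> PolarProfile:
    """Angular distribution of bone mineral mass in 5-degree bins.

    Each mass-bearing pixel contributes rho_i * a (mg/cm, a in cm^2) to the
    bin containing its angle about the section centre; nine consecutive bins
    are summed per 45-degree sector so that sectors add up to 10 x BMC_TOT.
    Angle zero points anterior and increases toward medial; for the left leg
    the medial axis is mirrored.  ``center`` selects the density-weighted
    (``"mass"``) or geometric (``"geometric"``) centroid.

    ``angular_supersample`` > 1 splits each pixel's mass over an s x s
    subpixel grid before binning, smoothing the jagged assignment of pixels
    that straddle a bin border (bin and sector totals are unchanged).
    """
    if slc.site != "shaft":
        raise ValueError("polar analysis is defined for the shaft site")
    if side not in ("right", "left"):
        raise ValueError("side must be 'right' or 'left'")
    mass = _mass_mask(slc, masks)
    if not mass.any():
        raise ValueError("no mass-bearing pixels inside the bone mask")

    xx, yy = slc.pixel_coordinates()
    rho = slc.values[mass]
    a_cm2 = (slc.pixel_mm / 10.0) ** 2
    contrib = rho * a_cm2  # mg/cm per pixel
    x = xx[mass]
    y = yy[mass]
    if center == "mass":
        cx = float((contrib * x).sum() / contrib.sum())
        cy = float((contrib * y).sum() / contrib.sum())
    elif center == "geometric":
        cx = float(xx[masks.total].mean())
        cy = float(yy[masks.total].mean())
    else:
        raise ValueError("center must be 'mass' or 'geometric'")
    dx = x - cx
    dy = y - cy

    labelled = slc.orientation is not None and {"anterior", "medial"} <= set(
        slc.orientation
    )
    if labelled:
        ant = slc.axis_vector("anterior")
        med = slc.axis_vector("medial")
        if side == "left":
            med = -med
    else:  # unlabeled bins relative to grid axes
        ant = np.array([0.0, 1.0])
        med = np.array([1.0, 0.0])
    s = int(angular_supersample)
    if s < 1:
        raise ValueError("angular_supersample must be >= 1")
    bins = np.zeros(N_BINS)
    offsets = ((np.arange(s) + 0.5) / s - 0.5) * slc.pixel_mm
    for ox in offsets:
        for oy in offsets:
            a_comp = (dx + ox) * ant[0] + (dy + oy) * ant[1]
            m_comp = (dx + ox) * med[0] + (dy + oy) * med[1]
            angle = np.degrees(np.arctan2(m_comp, a_comp)) % 360.0
            # 1e-9 deg snap keeps pixels that sit exactly on a bin border in
            # the upper bin regardless of round-off in the angle computation
            bin_idx = np.floor(angle / 5.0 + 2e-10).astype(int) % N_BINS
            bins += np.bincount(bin_idx, weights=contrib / s**2, minlength=N_BINS)

    sectors = None
    if labelled:
        # sector j spans [45j, 45(j+1)) degrees, i.e. bins 9j .. 9j+8; the
        # "A" sector starts at the anterior axis and runs toward medial
        sectors = {}
        for j, label in enumerate(SECTOR_LABELS):
            start = BINS_PER_SECTOR * j
            sectors[label] = float(bins[start : start + BINS_PER_SECTOR].sum())
    return PolarProfile(bins=bins, sectors=sectors, center_mm=(cx, cy), side=side)


def muscle_csa(slc: DensitySlice, roi: np.ndarray) -> float:
    """Muscle cross-sectional area (mm^2) within an externally drawn ROI.

    Pixels with density in [11, 280) mg/cm^3 count as muscle; below lies
    fat, at or above lies bone, both excluded.  The ROI stands in for the
    manual outline drawn along the outer boundary of the calf.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != slc.values.shape:
        raise ValueError("ROI shape does not match the slice grid")
    sel = roi & (slc.values >= 11.0) & (slc.values < 280.0)
    return float(sel.sum()) * slc.pixel_area_mm2


def cv_rms(repeated_measurements) -> float:
    """Root-mean-square coefficient of variation (percent) across subjects.

    ``repeated_measurements`` maps subject to its repeated values (or is an
    iterable of per-subject sequences).  Each subject needs at least two
    repeats; a subject with zero mean makes the statistic undefined and
    ``nan`` is returned.
    """
    if hasattr(repeated_measurements, "values") and not isinstance(
        repeated_measurements, np.ndarray
    ):
        groups = list(repeated_measurements.values())
    else:
        groups = list(repeated_measurements)
    if not groups:
        raise ValueError("at least one subject is required")
    cvs = []
    for vals in groups:
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError("each subject needs at least two repeats")
        mean = arr.mean()
        if mean == 0:
            return math.nan
        cvs.append(100.0 * arr.std(ddof=1) / mean)
    return float(np.sqrt(np.mean(np.square(cvs))))
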