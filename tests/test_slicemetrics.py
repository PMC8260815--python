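"""Segmentation, trait extraction, polar profile, muscle CSA and CV_RMS."""

import math

import numpy as np
import pytest

from pqctlong.image import DensitySlice
from pqctlong.phantom import PhantomSpec, analytic_phantom_traits, generate_phantom
from pqctlong.slicemetrics import (
    SECTOR_LABELS,
    bsi_comp,
    cv_rms,
    extract_distal_traits,
    extract_shaft_traits,
    medullary_area,
    muscle_csa,
    polar_mass_distribution,
    segment_bone,
    separate_compartments,
)

SHAFT_ANNULUS = PhantomSpec(
    site="shaft", a_mm=18.0, b_mm=18.0, t_mm=7.0, rho_co=1095.0, rho_tr=50.0,
    shape=(67, 67),
)


# ---------------------------------------------------------------- segmentation

def test_all_zero_slice_gives_flagged_empty_masks():
    slc = DensitySlice(np.zeros((20, 20)), site="shaft")
    masks = segment_bone(slc)
    assert masks.empty
    assert not masks.total.any()


def test_annulus_total_mask_matches_periosteal_area():
    slc = generate_phantom(SHAFT_ANNULUS)
    masks = segment_bone(slc)
    area = masks.total.sum() * slc.pixel_area_mm2
    assert area == pytest.approx(math.pi * 18.0**2, rel=0.02)


def test_medullary_mask_matches_inner_ellipse():
    slc = generate_phantom(SHAFT_ANNULUS)  # interior at 50 mg/cm^3 < marrow cut
    masks = segment_bone(slc)
    area = masks.medullary.sum() * slc.pixel_area_mm2
    assert area == pytest.approx(math.pi * 11.0**2, rel=0.02)


def test_cortical_mask_matches_annulus_area():
    spec = PhantomSpec(
        site="shaft", a_mm=18.0, b_mm=18.0, t_mm=7.0, rho_co=1095.0, rho_tr=300.0,
        shape=(67, 67),
    )
    slc = generate_phantom(spec)
    masks = segment_bone(slc)
    area = masks.cortical.sum() * slc.pixel_area_mm2
    assert area == pytest.approx(math.pi * (18.0**2 - 11.0**2), rel=0.02)
    assert not masks.low_density_warning


def test_uniform_high_density_slab_has_empty_trabecular():
    values = np.zeros((20, 20))
    values[5:15, 5:15] = 1095.0
    masks = segment_bone(DensitySlice(values, site="shaft"))
    assert not masks.trabecular.any()
    assert masks.cortical.sum() == 100


def test_subthreshold_cortex_flags_low_density_warning():
    values = np.zeros((20, 20))
    values[5:15, 5:15] = 600.0  # above segmentation, below cortical threshold
    masks = segment_bone(DensitySlice(values, site="shaft"))
    assert masks.total.any()
    assert not masks.cortical.any()
    assert masks.low_density_warning


# ---------------------------------------------------------------- trait values

def test_distal_bsi_hand_arithmetic():
    # vBMD_TOT 360 mg/cm^3 over 1195 mm^2 -> 0.36^2 x 11.95 = 1.549 g^2/cm^4
    assert bsi_comp(360.0, 1195.0) == pytest.approx(1.54872)
    assert bsi_comp(0.0, 500.0) == 0.0


def test_medullary_area_identity_on_printed_values():
    assert medullary_area(599.0, 416.0) == 183.0


def test_distal_phantom_traits():
    spec = PhantomSpec(
        site="distal", a_mm=20.0, b_mm=20.0, t_mm=4.0, rho_co=1095.0, rho_tr=300.0,
        shape=(67, 67),
    )
    traits = extract_distal_traits(generate_phantom(spec))
    assert traits.vbmd_trab == pytest.approx(300.0, rel=1e-6)
    an = analytic_phantom_traits(spec)
    assert traits.csa_tot == pytest.approx(an.csa_tot, rel=0.02)
    assert traits.vbmd_tot == pytest.approx(an.vbmd_tot, rel=0.02)
    assert traits.bsi_comp == pytest.approx(an.bsi_comp, rel=0.05)
    # unit identity BMC = vBMD x CSA x 1e-3
    assert traits.bmc_tot == pytest.approx(traits.vbmd_tot * traits.csa_tot * 1e-3, rel=1e-9)


def test_empty_masks_give_missing_not_zero_traits():
    slc = DensitySlice(np.zeros((16, 16)), site="distal")
    traits = extract_distal_traits(slc)
    assert traits.bmc_tot is None and traits.bsi_comp is None
    shaft = extract_shaft_traits(DensitySlice(np.zeros((16, 16)), site="shaft"))
    assert shaft.bmc_tot is None and shaft.i_max is None


def test_shaft_csa_m_identity_and_moment_isotropy():
    slc = generate_phantom(SHAFT_ANNULUS)
    traits = extract_shaft_traits(slc)
    assert traits.csa_m == traits.csa_tot - traits.csa_co  # exact identity
    assert traits.i_max == pytest.approx(traits.i_min, rel=0.01)  # circular symmetry
    an = analytic_phantom_traits(SHAFT_ANNULUS)
    assert traits.i_max == pytest.approx(an.i_max, rel=0.03)
    assert traits.bmc_tot == pytest.approx(an.bmc_tot, rel=0.02)


def test_rotation_invariance_of_scalar_traits():
    base = PhantomSpec(
        site="shaft", a_mm=18.0, b_mm=13.0, t_mm=5.0, rho_co=1095.0, rho_tr=50.0,
        pixel_mm=0.2, shape=(271, 271),
    )
    t0 = extract_shaft_traits(generate_phantom(base), compute_polar=False)
    for theta in (30.0, 75.0):
        spec = PhantomSpec(
            site="shaft", a_mm=18.0, b_mm=13.0, t_mm=5.0, rho_co=1095.0, rho_tr=50.0,
            theta_deg=theta, pixel_mm=0.2, shape=(271, 271),
        )
        tr = extract_shaft_traits(generate_phantom(spec), compute_polar=False)
        assert tr.csa_tot == pytest.approx(t0.csa_tot, rel=0.01)
        assert tr.bmc_tot == pytest.approx(t0.bmc_tot, rel=0.01)
        assert tr.i_max + tr.i_min == pytest.approx(t0.i_max + t0.i_min, rel=0.01)


# ------------------------------------------------------------------- polar

def test_polar_sectors_sum_to_ten_times_bmc():
    slc = generate_phantom(SHAFT_ANNULUS)
    traits = extract_shaft_traits(slc)
    total = sum(traits.polar.sectors.values())
    assert total == pytest.approx(10.0 * traits.bmc_tot, rel=0.005)
    assert traits.polar.bins.sum() == pytest.approx(10.0 * traits.bmc_tot, rel=0.005)


def test_polar_bins_uniform_for_centred_circle():
    spec = PhantomSpec(
        site="shaft", a_mm=18.0, b_mm=18.0, t_mm=7.0, rho_co=1095.0, rho_tr=50.0,
        pixel_mm=0.2, shape=(271, 271),
    )
    slc = generate_phantom(spec)
    prof = polar_mass_distribution(slc, segment_bone(slc), angular_supersample=4)
    assert prof.bins.max() / prof.bins.min() <= 1.05


def test_rot90_permutes_sectors_by_two_positions():
    spec = PhantomSpec(
        site="shaft", a_mm=18.0, b_mm=13.0, t_mm=5.0, rho_co=1095.0, rho_tr=50.0,
        theta_deg=20.0, shape=(67, 67),
    )
    slc = generate_phantom(spec)
    masks = segment_bone(slc)
    prof = polar_mass_distribution(slc, masks)
    rot = DensitySlice(np.rot90(slc.values), pixel_mm=slc.pixel_mm, site="shaft",
                       orientation=slc.orientation)
    prof_rot = polar_mass_distribution(rot, segment_bone(rot))
    vals = [prof.sectors[k] for k in SECTOR_LABELS]
    vals_rot = [prof_rot.sectors[k] for k in SECTOR_LABELS]
    # CCW image rotation moves anterior mass to where it reads 2 sectors earlier
    shifted = vals_rot[2:] + vals_rot[:2]
    assert np.allclose(vals, shifted, rtol=1e-9)


def test_missing_orientation_returns_unlabeled_bins():
    slc = generate_phantom(SHAFT_ANNULUS)
    slc = DensitySlice(slc.values, pixel_mm=slc.pixel_mm, site="shaft", orientation=None)
    prof = polar_mass_distribution(slc, segment_bone(slc))
    assert prof.sectors is None
    assert prof.bins.shape == (72,)


def test_left_side_mirrors_medial_sectors():
    # offset centre so no pixel sits exactly on a sector border
    spec = PhantomSpec(
        site="shaft", a_mm=18.0, b_mm=13.0, t_mm=5.0, rho_co=1095.0, rho_tr=50.0,
        theta_deg=20.0, offset_mm=(0.31, 0.17), shape=(67, 67),
    )
    slc = generate_phantom(spec)
    masks = segment_bone(slc)
    right = polar_mass_distribution(slc, masks, side="right").sectors
    left = polar_mass_distribution(slc, masks, side="left").sectors
    # mirroring the medial axis reverses the sector order around the circle
    for j, label in enumerate(SECTOR_LABELS):
        assert left[label] == pytest.approx(right[SECTOR_LABELS[7 - j]], rel=1e-9)


# -------------------------------------------------------- brute-force oracle

def _brute_force_traits(slc, masks):
    """Independent per-pixel reimplementation of the shaft trait formulas."""
    nr, nc = slc.values.shape
    p = slc.pixel_mm
    a_mm2 = p * p
    a_cm2 = (p / 10.0) ** 2
    csa_tot = csa_co = 0.0
    bmc = 0.0
    wsum = wx = wy = 0.0
    pix = []
    for r in range(nr):
        for c in range(nc):
            x = (c + 0.5) * p / 10.0
            y = (nr - r - 0.5) * p / 10.0
            rho = slc.values[r, c]
            if masks.total[r, c]:
                csa_tot += a_mm2
                if rho >= 100.0:
                    bmc += rho * a_cm2 * 0.1
            if masks.cortical[r, c]:
                csa_co += a_mm2
                w = rho * a_cm2
                wsum += w
                wx += w * x
                wy += w * y
                pix.append((x, y, w))
    cx, cy = wx / wsum, wy / wsum
    ixx = iyy = ixy = 0.0
    for x, y, w in pix:
        ixx += w * (y - cy) ** 2
        iyy += w * (x - cx) ** 2
        ixy += w * (x - cx) * (y - cy)
    disc = math.sqrt(((ixx - iyy) / 2.0) ** 2 + ixy**2)
    mid = (ixx + iyy) / 2.0
    # polar bins about the mass centroid of marrow-excluded pixels, in mm
    wsum2 = wx2 = wy2 = 0.0
    mass_pix = []
    for r in range(nr):
        for c in range(nc):
            if masks.total[r, c] and slc.values[r, c] >= 100.0:
                x = (c + 0.5) * p
                y = (nr - r - 0.5) * p
                w = slc.values[r, c] * a_cm2
                wsum2 += w
                wx2 += w * x
                wy2 += w * y
                mass_pix.append((x, y, w))
    cx2, cy2 = wx2 / wsum2, wy2 / wsum2
    bins = [0.0] * 72
    for x, y, w in mass_pix:
        ang = math.degrees(math.atan2(x - cx2, y - cy2)) % 360.0
        bins[int(ang // 5.0) % 72] += w
    return csa_tot, csa_co, bmc, mid + disc, mid - disc, bins


def test_brute_force_oracle_agrees_on_random_slices():
    rng = np.random.default_rng(5)
    for _ in range(3):
        values = rng.uniform(0.0, 1300.0, size=(32, 32))
        values[:3, :] = 0.0  # keep a background margin
        slc = DensitySlice(values, site="shaft")
        masks = segment_bone(slc)
        if masks.empty or not masks.cortical.any():
            continue
        traits = extract_shaft_traits(slc, masks)
        csa_tot, csa_co, bmc, imax, imin, bins = _brute_force_traits(slc, masks)
        assert traits.csa_tot == pytest.approx(csa_tot, rel=1e-9)
        assert traits.csa_co == pytest.approx(csa_co, rel=1e-9)
        assert traits.bmc_tot == pytest.approx(bmc, rel=1e-9)
        assert traits.i_max == pytest.approx(imax, rel=1e-9)
        assert traits.i_min == pytest.approx(imin, rel=1e-9)
        assert np.allclose(traits.polar.bins, bins, rtol=1e-9, atol=1e-12)


# --------------------------------------------------------- muscle CSA, CV_RMS

def test_muscle_csa_thresholds():
    values = np.zeros((30, 30))
    values[5:25, 5:25] = 75.0  # muscle-density disk (square, area known)
    slc = DensitySlice(values, site="shaft")
    roi = np.zeros((30, 30), dtype=bool)
    roi[2:28, 2:28] = True
    assert muscle_csa(slc, roi) == pytest.approx(400 * 0.64)
    # fat-only ROI
    assert muscle_csa(DensitySlice(np.full((30, 30), 5.0), site="shaft"), roi) == 0.0
    # inserting bone pixels does not change the result
    values2 = values.copy()
    values2[10:12, 10:12] = 1095.0
    removed = 4 * 0.64
    assert muscle_csa(DensitySlice(values2, site="shaft"), roi) == pytest.approx(
        400 * 0.64 - removed
    )


def test_muscle_csa_shape_mismatch():
    slc = DensitySlice(np.zeros((10, 10)), site="shaft")
    with pytest.raises(ValueError, match="shape"):
        muscle_csa(slc, np.zeros((5, 5), dtype=bool))


def test_cv_rms_examples():
    assert cv_rms([[5.0, 5.0, 5.0], [7.0, 7.0]]) == 0.0
    # subjects {100,102} and {200,202}: CVs 1.4003% and 0.7036% -> 1.108%
    assert cv_rms([[100.0, 102.0], [200.0, 202.0]]) == pytest.approx(1.108, abs=5e-4)
    # scale invariance per subject
    assert cv_rms([[1000.0, 1020.0], [200.0, 202.0]]) == pytest.approx(1.108, abs=5e-4)
    assert math.isnan(cv_rms([[1.0, -1.0]]))
    with pytest.raises(ValueError):
        cv_rms([[1.0]])
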