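"""Hemispherical ischemic regions, zone-factor fields and transmurality.

An ischemic setup is a sphere of total radius r (central ischemic zone CIZ
plus border zone BZ) centered on the endocardial surface — restricted to
myocardium the sphere is effectively a hemisphere. The zone factor ZF grades
severity: 1 inside the CIZ (radius r - bz), 0 outside the total radius, and a
linear ramp across the BZ annulus.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage

from .anatomy import ConfigurationError, VoxelHeart

DEFAULT_BZ_RADII = (2.8, 4.8, 9.6)
#: Per-subject total-radius grids; the thick-walled subject is capped at 30 mm.
DEFAULT_RADII = {
    "VM-like": (10.0, 15.0, 20.0, 25.0, 30.0),
    "K-like": (5.0, 10.0, 15.0, 20.0, 25.0),
    "D-like": (5.0, 10.0, 15.0, 20.0, 25.0),
}


@dataclass
class IschemiaSetup:
    """One ischemic region: location, total radius and border-zone extent.

    When ``total_radius <= bz_radius`` the central ischemic zone is empty and
    the whole region is graded border zone (the smallest study radii with the
    widest border zone); the peak zone factor is then ``total_radius /
    bz_radius`` < 1.
    """

    subject: str
    segment: int
    total_radius: float        # mm, CIZ + BZ
    bz_radius: float           # mm
    center_voxel: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.segment <= 17:
            raise ConfigurationError("segment must be in 1..17")
        if self.total_radius <= 0 or self.bz_radius <= 0:
            raise ConfigurationError("radii must be positive")

    @property
    def setup_id(self) -> str:
        return f"{self.subject}/s{self.segment:02d}/r{self.total_radius:g}/bz{self.bz_radius:g}"


@dataclass
class ZoneFactorField:
    zf: np.ndarray                 # float grid, in [0,1] on myocardium
    setup: IschemiaSetup
    transmural_flag: bool = False


def zone_factor(d: np.ndarray | float, total_radius: float, bz_radius: float):
    """ZF as a function of distance d from the ischemia center (mm).

    1 for d <= r_CIZ, linear ramp (total_radius - d)/bz_radius across the BZ,
    0 beyond the total radius.
    """
    r_ciz = total_radius - bz_radius
    d = np.asarray(d, float)
    zf = np.clip((total_radius - d) / bz_radius, 0.0, 1.0)
    zf = np.where(d <= r_ciz, 1.0, zf)
    return zf if zf.ndim else float(zf)


def segment_center_voxel(heart: VoxelHeart, segment: int) -> tuple[int, int, int]:
    """Endocardial voxel nearest the centroid of an AHA segment."""
    seg_mask = heart.aha_segment == segment
    if not seg_mask.any():
        raise ConfigurationError(f"AHA segment {segment} is empty")
    centroid = np.argwhere(seg_mask).mean(axis=0)
    endo_in_seg = seg_mask & heart.endo_surface
    if not endo_in_seg.any():
        endo_in_seg = heart.endo_surface  # fall back to nearest endo voxel overall
    cand = np.argwhere(endo_in_seg)
    best = cand[np.argmin(np.linalg.norm(cand - centroid, axis=1))]
    return tuple(int(v) for v in best)


def place_ischemia(heart: VoxelHeart, setup: IschemiaSetup) -> ZoneFactorField:
    """Compute the zone-factor field for one hemispherical ischemic setup."""
    center = setup.center_voxel
    if center is None:
        center = segment_center_voxel(heart, setup.segment)
        setup.center_voxel = center
    if not heart.endo_surface[center]:
        raise ConfigurationError("ischemia center must lie on the endocardial surface")
    idx = np.argwhere(heart.occupancy)
    d = np.linalg.norm((idx - np.asarray(center)) * heart.voxel_size, axis=1)
    zf = np.zeros(heart.shape)
    zf[tuple(idx.T)] = zone_factor(d, setup.total_radius, setup.bz_radius)
    field = ZoneFactorField(zf=zf, setup=setup)
    field.transmural_flag = classify_transmurality(field, heart) == "transmural"
    return field


def classify_transmurality(field: ZoneFactorField, heart: VoxelHeart) -> str:
    """'transmural' iff a CIZ voxel lies on, or is 26-adjacent to, the epicardium."""
    ciz = (field.zf >= 1.0) & heart.occupancy
    if not ciz.any():
        return "subendocardial"
    near_epi = ndimage.binary_dilation(heart.epi_surface, np.ones((3, 3, 3), bool))
    return "transmural" if (ciz & near_epi).any() else "subendocardial"


def ischemic_fraction(field: ZoneFactorField, heart: VoxelHeart) -> float:
    """Fraction of LV voxels with any ischemic involvement (zf > 0)."""
    lv = heart.chamber_label == 1
    return float(((field.zf > 0) & lv).sum() / lv.sum())


def enumerate_study_grid(
    subjects: list[str],
    segments: list[int] | None = None,
    radii_per_subject: dict[str, tuple[float, ...]] | None = None,
    bz_radii: tuple[float, ...] = DEFAULT_BZ_RADII,
) -> list[IschemiaSetup]:
    """Cartesian setup grid ordered by (subject, segment, bz, radius).

    The default grids give 17 segments x 3 BZ radii x 15 subject-radius
    combinations = 765 setups.
    """
    if segments is None:
        segments = list(range(1, 18))
    if radii_per_subject is None:
        radii_per_subject = {s: DEFAULT_RADII[s] for s in subjects}
    if not subjects or not segments or not bz_radii:
        raise ConfigurationError("subjects, segments and bz_radii must be nonempty")
    setups = []
    for subj, seg, bz in product(subjects, segments, bz_radii):
        for r in radii_per_subject[subj]:
            setups.append(IschemiaSetup(subject=subj, segment=seg,
                                        total_radius=float(r), bz_radius=float(bz)))
    return setups
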