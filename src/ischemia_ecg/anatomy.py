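"""Parametric voxel ventricles, AHA segmentation and torso electrode sets.

The heart is a truncated half-ellipsoid left-ventricular shell plus a thinner
crescent-shaped right-ventricular shell on a regular voxel grid (mm units).
Three default subjects differ in wall thickness, torso size and heart
placement so that inter-subject feature spread is nonzero.

Local heart coordinates: right-handed, +x = patient left, +y = anterior,
+z = apex-to-base long axis (apex at negative z). Voxel index i maps to the
coordinate ``origin + (i + 0.5) * voxel_size`` along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class ConfigurationError(ValueError):
    """Raised for geometrically inconsistent subject parameters."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SubjectSpec:
    """Parameters of one synthetic subject (ventricle + torso geometry).

    Lengths in mm. ``lv_long_axis`` / ``lv_short_axis`` are the *outer*
    (epicardial) semi-axes of the LV ellipsoid. Wall thickness varies
    linearly from ``wall_thickness_base`` at the base to
    ``wall_thickness_apex`` at the apex.
    """

    name: str
    lv_long_axis: float = 75.0
    lv_short_axis: float = 32.0
    wall_thickness_base: float = 10.0
    wall_thickness_apex: float = 7.0
    rv_wall_thickness: float = 4.0
    torso_radius: float = 165.0
    torso_height: float = 640.0
    heart_center_offset: tuple[float, float, float] = (25.0, 40.0, 90.0)
    heart_orientation: tuple[float, float] = (35.0, 20.0)  # tilt deg about y, x
    voxel_size: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for key in ("lv_long_axis", "lv_short_axis", "wall_thickness_base",
                    "wall_thickness_apex", "rv_wall_thickness",
                    "torso_radius", "torso_height", "voxel_size"):
            if getattr(self, key) <= 0:
                raise ConfigurationError(f"{key} must be positive")
        if self.wall_thickness_base >= self.lv_short_axis:
            raise ConfigurationError(
                "wall_thickness_base must be smaller than lv_short_axis "
                "(epicardium would lie inside the endocardium)")
        if self.wall_thickness_apex >= self.lv_long_axis:
            raise ConfigurationError(
                "wall_thickness_apex must be smaller than lv_long_axis")
        if self.voxel_size > 2.0:
            raise ConfigurationError("voxel_size must be <= 2 mm")

    def rotation_matrix(self) -> np.ndarray:
        """Local-to-global rotation (tilt about y, then about x), degrees."""
        ay, ax = np.deg2rad(self.heart_orientation)
        ry = np.array([[np.cos(ay), 0, np.sin(ay)],
                       [0, 1, 0],
                       [-np.sin(ay), 0, np.cos(ay)]])
        rx = np.array([[1, 0, 0],
                       [0, np.cos(ax), -np.sin(ax)],
                       [0, np.sin(ax), np.cos(ax)]])
        return rx @ ry


@dataclass
class VoxelHeart:
    """Voxelized biventricular myocardium with AHA labels and wall depth."""

    voxel_size: float
    origin: np.ndarray                  # local mm coordinate of grid corner
    occupancy: np.ndarray               # bool (nx, ny, nz): myocardium
    chamber_label: np.ndarray           # uint8: 0 none, 1 LV, 2 RV
    aha_segment: np.ndarray             # uint8: 1..17 on LV voxels, else 0
    transmural_depth: np.ndarray        # float in [0,1] on myocardium
    endo_surface: np.ndarray            # bool mask
    epi_surface: np.ndarray             # bool mask
    lv_cavity: np.ndarray               # bool mask (blood pool)
    apex_base_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    stimulus_sites: list[tuple[tuple[int, int, int], float]] = field(default_factory=list)
    lv_center_xy: tuple[float, float] = (0.0, 0.0)
    base_z: float = 0.0
    subject: SubjectSpec | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Local mm coordinates of voxel centers (for `mask` or all myocardium)."""
        if mask is None:
            mask = self.occupancy
        idx = np.argwhere(mask)
        return self.origin + (idx + 0.5) * self.voxel_size

    def global_voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Voxel centers in global torso coordinates (mm)."""
        local = self.voxel_centers(mask)
        spec = self.subject
        if spec is None:
            return local
        return local @ spec.rotation_matrix().T + np.asarray(spec.heart_center_offset)


@dataclass
class ElectrodeSet:
    """Torso electrodes plus clinical lead definitions.

    ``lead_matrix`` has one row per lead; signal = lead_matrix @ potentials.
    Unipolar rows reference against the Wilson central terminal
    (RA + LA + LL) / 3.
    """

    positions: np.ndarray               # (n_elec, 3) global mm
    names: list[str]
    standard_map: dict[str, int]
    lead_names: list[str]
    lead_matrix: np.ndarray             # (n_leads, n_elec)

    @property
    def n_electrodes(self) -> int:
        return self.positions.shape[0]

    def lead_index(self, name: str) -> int:
        return self.lead_names.index(name)

    def unipolar_lead_name(self, electrode_index: int) -> str:
        return f"U:{self.names[electrode_index]}"


# ---------------------------------------------------------------------------
# ventricle construction
# ---------------------------------------------------------------------------

BASE_TRUNCATION_FRACTION = 0.45   # base plane at z = frac * lv_long_axis
RV_APEX_EXTENT = 0.60             # RV reaches down to z = -frac * lv_long_axis
N_STIMULUS_SITES = 10
STIMULUS_DELAY_MIN_MS = 10.0      # diastolic offset: first frames stay at rest
STIMULUS_DELAY_MAX_MS = 30.0


def _largest_component(mask: np.ndarray) -> np.ndarray:
    structure = np.ones((3, 3, 3), bool)
    labels, n = ndimage.label(mask, structure=structure)
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == np.argmax(counts)


def build_ventricles(spec: SubjectSpec) -> VoxelHeart:
    """Construct the voxelized biventricular shell for one subject.

    The LV is the region between two confocal-center ellipsoids truncated at
    the base plane; the RV is a laterally shifted, thinner shell clipped
    against the LV epicardium, forming a crescent. Transmural depth is
    ``d_endo / (d_endo + d_epi)`` with distances taken to the endocardial and
    epicardial surface voxel sets, so the depth is exactly 0 on the
    endocardium and 1 on the epicardium.
    """
    h = spec.voxel_size
    a = spec.lv_short_axis
    c = spec.lv_long_axis
    wb = spec.wall_thickness_base
    wa = spec.wall_thickness_apex

    a_endo = a - wb
    c_endo = c - wa
    if a_endo <= 0 or c_endo <= 0:
        raise ConfigurationError("endocardial ellipsoid degenerate")

    base_z = BASE_TRUNCATION_FRACTION * c

    # RV ellipsoids (crescent on the patient-right / septal side, -x)
    rv_center = np.array([-0.55 * a, 0.0, 0.08 * c])
    rv_axes_epi = np.array([1.35 * a, 1.05 * a, 0.85 * c])
    rv_axes_endo = rv_axes_epi - spec.rv_wall_thickness

    # grid bounds with 2-voxel margin
    lo = np.minimum([-a, -a, -c], rv_center - rv_axes_epi) - 2 * h
    hi = np.maximum([a, a, base_z], rv_center + rv_axes_epi)
    hi[2] = base_z  # everything truncated at the base plane
    hi = hi + 2 * h
    origin = lo
    shape = np.ceil((hi - lo) / h).astype(int)

    ii = np.arange(shape[0])
    jj = np.arange(shape[1])
    kk = np.arange(shape[2])
    x = origin[0] + (ii + 0.5) * h
    y = origin[1] + (jj + 0.5) * h
    z = origin[2] + (kk + 0.5) * h
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    def inside(center, axes):
        return (((X - center[0]) / axes[0]) ** 2
                + ((Y - center[1]) / axes[1]) ** 2
                + ((Z - center[2]) / axes[2]) ** 2) <= 1.0

    below_base = Z <= base_z
    lv_epi_in = inside((0, 0, 0), (a, a, c)) & below_base
    lv_endo_in = inside((0, 0, 0), (a_endo, a_endo, c_endo)) & below_base
    lv_myo = lv_epi_in & ~lv_endo_in
    lv_cavity = lv_endo_in

    rv_epi_in = inside(rv_center, rv_axes_epi) & below_base & (Z >= -RV_APEX_EXTENT * c)
    rv_endo_in = inside(rv_center, rv_axes_endo) & below_base & (Z >= -RV_APEX_EXTENT * c)
    rv_myo = rv_epi_in & ~rv_endo_in & ~lv_epi_in
    rv_cavity = rv_endo_in & ~lv_epi_in

    lv_myo = _largest_component(lv_myo)
    rv_myo = _largest_component(rv_myo)
    rv_cavity &= ~lv_myo

    occupancy = lv_myo | rv_myo
    if not occupancy.any():
        raise ConfigurationError("empty myocardium for given geometry")
    chamber = np.zeros(shape, np.uint8)
    chamber[lv_myo] = 1
    chamber[rv_myo] = 2

    cavity = (lv_cavity | rv_cavity) & ~occupancy

    # surfaces: myocardial voxels face-adjacent to cavity / to outside below base
    struct6 = ndimage.generate_binary_structure(3, 1)
    cavity_dil = ndimage.binary_dilation(cavity, struct6)
    endo_surface = occupancy & cavity_dil
    exterior = ~occupancy & ~cavity & (Z < base_z - h)  # exclude basal rim cut
    epi_surface = occupancy & ndimage.binary_dilation(exterior, struct6) & ~endo_surface

    # transmural depth from distances to the two surface voxel sets
    d_endo = ndimage.distance_transform_edt(~endo_surface, sampling=h)
    d_epi = ndimage.distance_transform_edt(~epi_surface, sampling=h)
    denom = d_endo + d_epi
    depth = np.zeros(shape)
    ok = occupancy & (denom > 0)
    depth[ok] = (d_endo / np.where(denom > 0, denom, 1.0))[ok]
    depth[endo_surface] = 0.0
    depth[epi_surface] = 1.0

    heart = VoxelHeart(
        voxel_size=h,
        origin=np.asarray(origin, float),
        occupancy=occupancy,
        chamber_label=chamber,
        aha_segment=np.zeros(shape, np.uint8),
        transmural_depth=depth,
        endo_surface=endo_surface,
        epi_surface=epi_surface,
        lv_cavity=lv_cavity & ~occupancy,
        lv_center_xy=(0.0, 0.0),
        base_z=base_z,
        subject=spec,
    )
    _place_stimulus_sites(heart)
    return heart


def _place_stimulus_sites(heart: VoxelHeart) -> None:
    """Deterministic endocardial early-activation sites.

    Farthest-point sampling over the endocardial surface starting at the
    apex-most endocardial voxel emulates a spread-out conduction-system
    breakthrough pattern. Delays increase linearly from apex to base over
    [10, 30] ms so the first sampled frames are diastolic.
    """
    idx = np.argwhere(heart.endo_surface)
    if idx.shape[0] == 0:
        raise ConfigurationError("no endocardial surface")
    coords = heart.origin + (idx + 0.5) * heart.voxel_size
    start = int(np.argmin(coords[:, 2]))
    chosen = [start]
    dmin = np.linalg.norm(coords - coords[start], axis=1)
    for _ in range(min(N_STIMULUS_SITES, idx.shape[0]) - 1):
        nxt = int(np.argmax(dmin))
        chosen.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(coords - coords[nxt], axis=1))
    zs = coords[chosen, 2]
    zspan = max(zs.max() - zs.min(), 1e-9)
    heart.stimulus_sites = []
    for site, zv in zip(chosen, zs):
        delay = STIMULUS_DELAY_MIN_MS + (STIMULUS_DELAY_MAX_MS - STIMULUS_DELAY_MIN_MS) * (
            (zv - zs.min()) / zspan)
        heart.stimulus_sites.append((tuple(int(v) for v in idx[site]), float(delay)))


# ---------------------------------------------------------------------------
# AHA segmentation
# ---------------------------------------------------------------------------


def aha_segment_of(x: float, y: float, z: float, cap_z: float, thirds: tuple[float, float],
                   center_xy: tuple[float, float]) -> int:
    """Classify one LV point into its 17-segment AHA label.

    ``cap_z`` is the top of the apex cap (below the LV cavity), ``thirds``
    are the apical/mid and mid/basal boundary heights. Circumferential
    sectors follow the standard numbering with anterior at +y and the septum
    toward -x.
    """
    if z < cap_z:
        return 17
    ang = np.degrees(np.arctan2(y - center_xy[1], x - center_xy[0])) % 360.0
    if z < thirds[0]:  # apical ring: 4 sectors of 90 deg, anterior centered at 90
        k = int(((ang - 45.0) % 360.0) // 90.0)
        return 13 + k
    base_seg = 7 if z < thirds[1] else 1
    k = int(((ang - 60.0) % 360.0) // 60.0)
    return base_seg + k


def assign_aha_segments(heart: VoxelHeart) -> VoxelHeart:
    """Label every LV voxel with its AHA segment (1-17), in place.

    The apex cap (segment 17) is the LV myocardium below the cavity; the
    remaining long-axis span is split into equal apical/mid/basal thirds with
    4/6/6 circumferential sectors.
    """
    lv = heart.chamber_label == 1
    if not lv.any():
        raise ConfigurationError("no LV voxels")
    idx = np.argwhere(lv)
    coords = heart.origin + (idx + 0.5) * heart.voxel_size
    cavity_idx = np.argwhere(heart.lv_cavity)
    if cavity_idx.shape[0] == 0:
        raise ConfigurationError("no LV cavity; geometry too small")
    cap_z = heart.origin[2] + (cavity_idx[:, 2].min() + 0.5) * heart.voxel_size
    z_top = coords[:, 2].max()
    span = z_top - cap_z
    if span < 3 * heart.voxel_size:
        raise ConfigurationError("LV too short to form three rings")
    thirds = (cap_z + span / 3.0, cap_z + 2.0 * span / 3.0)

    ang = np.degrees(np.arctan2(coords[:, 1] - heart.lv_center_xy[1],
                                coords[:, 0] - heart.lv_center_xy[0])) % 360.0
    seg = np.empty(idx.shape[0], np.uint8)
    cap = coords[:, 2] < cap_z
    apical = ~cap & (coords[:, 2] < thirds[0])
    mid = ~cap & ~apical & (coords[:, 2] < thirds[1])
    basal = ~cap & ~apical & ~mid
    seg[cap] = 17
    seg[apical] = 13 + (((ang[apical] - 45.0) % 360.0) // 90.0).astype(np.uint8)
    seg[mid] = 7 + (((ang[mid] - 60.0) % 360.0) // 60.0).astype(np.uint8)
    seg[basal] = 1 + (((ang[basal] - 60.0) % 360.0) // 60.0).astype(np.uint8)

    heart.aha_segment[:] = 0
    heart.aha_segment[tuple(idx.T)] = seg
    heart._aha_bounds = (float(cap_z), (float(thirds[0]), float(thirds[1])))  # type: ignore[attr-defined]
    return heart


# ---------------------------------------------------------------------------
# electrodes & leads
# ---------------------------------------------------------------------------

STANDARD_LEADS = ["I", "II", "III", "aVR", "aVL", "aVF",
                  "V1", "V2", "V3", "V4", "V5", "V6",
                  "V3R", "V4R", "V5R", "V6R"]

# (angle deg from anterior +y toward patient-left +x, height rel. to torso half-height)
_STANDARD_ANGLES = {
    "RA": (-95.0, 0.88), "LA": (95.0, 0.88), "LL": (35.0, -0.80),
    "V1": (-12.0, None), "V2": (12.0, None), "V3": (27.0, None),
    "V4": (42.0, None), "V5": (60.0, None), "V6": (80.0, None),
}
_PRECORDIAL_DZ = {"V1": 25.0, "V2": 25.0, "V3": 10.0, "V4": 0.0, "V5": 0.0, "V6": 0.0}


def place_electrodes(spec: SubjectSpec, n_bspm: int = 600) -> ElectrodeSet:
    """Quasi-uniform BSPM lattice plus deterministically placed standard electrodes.

    The BSPM electrodes are a Fibonacci lattice mapped onto the lateral torso
    cylinder; standard electrodes sit at fixed anatomical angles/heights.
    Right-sided precordials V3R-V6R mirror V3-V6 across the sagittal plane.
    """
    if n_bspm < 32:
        raise ConfigurationError("n_bspm must be >= 32")
    R, H = spec.torso_radius, spec.torso_height
    golden = (1 + 5 ** 0.5) / 2
    i = np.arange(n_bspm)
    theta = 2 * np.pi * ((i / golden) % 1.0)
    zz = (i + 0.5) / n_bspm * H - H / 2
    pos = np.column_stack([R * np.sin(theta), R * np.cos(theta), zz])
    names = [f"B{k:03d}" for k in range(n_bspm)]

    heart_z = spec.heart_center_offset[2]

    def on_cyl(angle_deg: float, z_mm: float) -> np.ndarray:
        a_ = np.deg2rad(angle_deg)
        return np.array([R * np.sin(a_), R * np.cos(a_), z_mm])

    standard_pos: dict[str, np.ndarray] = {}
    for name, (ang, relh) in _STANDARD_ANGLES.items():
        z_mm = relh * H / 2 if relh is not None else heart_z + _PRECORDIAL_DZ[name]
        standard_pos[name] = on_cyl(ang, z_mm)
    for v in ("V3", "V4", "V5", "V6"):
        p = standard_pos[v].copy()
        p[0] = -p[0]  # mirror across sagittal plane x = 0
        standard_pos[v + "R"] = p

    standard_names = ["RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5", "V6",
                      "V3R", "V4R", "V5R", "V6R"]
    all_pos = np.vstack([pos] + [standard_pos[n][None, :] for n in standard_names])
    all_names = names + standard_names
    standard_map = {n: n_bspm + k for k, n in enumerate(standard_names)}

    n_elec = all_pos.shape[0]
    wct = np.zeros(n_elec)
    for e in ("RA", "LA", "LL"):
        wct[standard_map[e]] = 1.0 / 3.0

    rows: list[np.ndarray] = []
    lead_names: list[str] = []

    def unit(idx: int) -> np.ndarray:
        r = np.zeros(n_elec)
        r[idx] = 1.0
        return r

    ra, la, ll = (unit(standard_map[e]) for e in ("RA", "LA", "LL"))
    bipolar = {
        "I": la - ra, "II": ll - ra, "III": ll - la,
        "aVR": ra - (la + ll) / 2, "aVL": la - (ra + ll) / 2,
        "aVF": ll - (ra + la) / 2,
    }
    for name in ["I", "II", "III", "aVR", "aVL", "aVF"]:
        rows.append(bipolar[name])
        lead_names.append(name)
    for name in STANDARD_LEADS[6:]:
        rows.append(unit(standard_map[name]) - wct)
        lead_names.append(name)
    for k in range(n_elec):
        rows.append(unit(k) - wct)
        lead_names.append(f"U:{all_names[k]}")

    return ElectrodeSet(positions=all_pos, names=all_names,
                        standard_map=standard_map,
                        lead_names=lead_names,
                        lead_matrix=np.array(rows))


def default_subjects() -> list[SubjectSpec]:
    """Three synthetic subjects emulating the study's inter-subject spread.

    "VM-like" has the thickest wall (motivating the 30 mm ischemia-radius
    cap), "K-like" intermediate, "D-like" thin-walled with a smaller torso.
    """
    return [
        SubjectSpec(name="VM-like", lv_long_axis=80.0, lv_short_axis=34.0,
                    wall_thickness_base=12.0, wall_thickness_apex=9.0,
                    torso_radius=172.0, torso_height=680.0,
                    heart_center_offset=(28.0, 45.0, 95.0),
                    heart_orientation=(38.0, 22.0), rng_seed=11),
        SubjectSpec(name="K-like", lv_long_axis=75.0, lv_short_axis=32.0,
                    wall_thickness_base=10.0, wall_thickness_apex=7.0,
                    torso_radius=165.0, torso_height=640.0,
                    heart_center_offset=(25.0, 40.0, 90.0),
                    heart_orientation=(33.0, 18.0), rng_seed=12),
        SubjectSpec(name="D-like", lv_long_axis=72.0, lv_short_axis=30.0,
                    wall_thickness_base=9.0, wall_thickness_apex=6.0,
                    torso_radius=158.0, torso_height=610.0,
                    heart_center_offset=(22.0, 38.0, 85.0),
                    heart_orientation=(30.0, 15.0), rng_seed=13),
    ]


def subject_by_name(name: str, voxel_size: float | None = None) -> SubjectSpec:
    for s in default_subjects():
        if s.name == name:
            if voxel_size is not None:
                s.voxel_size = voxel_size
            return s
    raise KeyError(f"unknown subject {name!r}")
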