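"""Parametric voxel geometry: torso, lungs, blood and the seven-region heart.

The torso and lungs are elliptic cylinders on a regular grid; the heart is a
spherical shell split by the atrioventricular (AV) plane into an atrial and a
ventricular wall, with blood filling the chambers and a ventricular septum
slab dividing the ventricular cavity.  An electrically passive isolation gap
separates atria from ventricles everywhere except at a septal junction
column, which hosts the atrioventricular node (AVN, carved from the bottom of
the atrial septum) and the His bundle (crossing the gap).  The bundle
branches (BNL) continue the column into the ventricular septum, and the
Purkinje layer is the endocardial voxel layer of the ventricular wall (every
ventricular voxel facing blood).  A small sinoatrial node (SAN) patch sits in
the right atrial wall.

Axes: x lateral (+x toward the patient's left), y anterior-posterior
(+y anterior), z caudal-cranial (+z toward the head); origin at the torso
center.  A voxel belongs to the region covering its center.  The same
construction scales from the full default geometry (dx = 4 mm) down to the
coarse test fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .cells import CellParameters, REGIONS, all_region_defaults

__all__ = [
    "Label",
    "HEART_LABELS",
    "LABEL_TO_REGION",
    "GeometryConfig",
    "LabelField",
    "LesionSpec",
    "GeometryError",
    "build_default_geometry",
    "validate_geometry",
    "conductivity_maps",
    "build_tissue",
    "apply_infarct",
    "lesion_preset",
    "face_adjacency_count",
]


class Label(IntEnum):
    OUTSIDE = 0
    TORSO = 1
    LUNGS = 2
    BLOOD = 3
    SAN = 4
    ATRIA = 5
    AVN = 6
    HIS = 7
    BNL = 8
    PURKINJE = 9
    VENTRICLES = 10


HEART_LABELS = (Label.SAN, Label.ATRIA, Label.AVN, Label.HIS,
                Label.BNL, Label.PURKINJE, Label.VENTRICLES)

LABEL_TO_REGION = {
    Label.SAN: "SAN", Label.ATRIA: "Atria", Label.AVN: "AVN",
    Label.HIS: "His", Label.BNL: "BNL", Label.PURKINJE: "Purkinje",
    Label.VENTRICLES: "Ventricles",
}
REGION_TO_LABEL = {v: k for k, v in LABEL_TO_REGION.items()}

PASSIVE_LABELS = (Label.TORSO, Label.LUNGS, Label.BLOOD)

#: Extracellular conductivities of the passive volume conductors (S/m).
DEFAULT_PASSIVE = {"torso": 0.2, "lungs": 0.04, "blood": 0.7, "heart": 0.05}


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class GeometryConfig:
    """All lengths in meters.  Defaults approximate an adult torso."""

    dx: float = 0.004
    torso_rx: float = 0.175
    torso_ry: float = 0.125
    torso_height: float = 0.60
    lung_rx: float = 0.062
    lung_ry: float = 0.095
    lung_xoff: float = 0.092
    lung_yoff: float = 0.0
    lung_zmin: float = -0.06
    lung_zmax: float = 0.21
    cavity_margin: float = 0.008
    heart_center: tuple[float, float, float] = (0.040, 0.020, 0.050)
    heart_outer_radius: float = 0.060
    wall_thickness: float = 0.012
    septum_thickness: float = 0.012
    av_plane_offset: float = 0.015
    gap_thickness: float = 0.009
    san_radius: float = 0.009
    san_direction: tuple[float, float, float] = (-0.55, 0.25, 0.75)
    san_exit: bool = True
    avn_depth: float = 0.008
    bundle_depth: float = 0.080  # cap on the free-running bundle's descent
    junction_radius: float = 0.0065

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise GeometryError("dx must be positive")
        for name in ("wall_thickness", "septum_thickness", "gap_thickness"):
            if getattr(self, name) < 2 * self.dx:
                raise GeometryError(
                    f"{name} = {getattr(self, name)} m is not resolvable at "
                    f"dx = {self.dx} m (needs >= 2*dx)")
        cx, cy, cz = self.heart_center
        reach = self.heart_outer_radius + self.cavity_margin
        if (abs(cx) + reach >= self.torso_rx or abs(cy) + reach >= self.torso_ry
                or abs(cz) + reach >= self.torso_height / 2):
            raise GeometryError("heart (plus cavity margin) does not fit inside the torso")

    @property
    def inner_radius(self) -> float:
        return self.heart_outer_radius - self.wall_thickness

    def replace(self, **kw) -> "GeometryConfig":
        return replace(self, **kw)


@dataclass
class LabelField:
    """3D voxel grid of region labels with physical origin and spacing."""

    labels: np.ndarray  # int8, shape (nx, ny, nz)
    origin: tuple[float, float, float]
    dx: float

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centers along each axis."""
        return tuple(self.origin[i] + (np.arange(self.shape[i]) + 0.5) * self.dx
                     for i in range(3))

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ax = self.axes()
        return np.meshgrid(*ax, indexing="ij")

    def counts(self) -> dict[str, int]:
        out = {}
        for lab in Label:
            n = int(np.count_nonzero(self.labels == lab))
            if n:
                out[lab.name] = n
        return out

    def heart_mask(self) -> np.ndarray:
        return np.isin(self.labels, [int(l) for l in HEART_LABELS])

    def conducting_mask(self) -> np.ndarray:
        return self.labels != int(Label.OUTSIDE)

    def copy(self) -> "LabelField":
        return LabelField(self.labels.copy(), self.origin, self.dx)


# ---------------------------------------------------------------------------

def _face_neighbor_pairs(lab: np.ndarray, a: int, b: int):
    """Index pairs of face-adjacent voxels labelled (a, b), both orders."""
    hits = []
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        m = ((lab[lo] == a) & (lab[hi] == b)) | ((lab[lo] == b) & (lab[hi] == a))
        idx = np.argwhere(m)
        for i in idx:
            j = i.copy()
            j[axis] += 1
            hits.append((tuple(i), tuple(j)))
    return hits


def face_adjacency_count(lab: np.ndarray, a: int, b: int) -> int:
    """Number of face-adjacent voxel pairs with labels a and b."""
    n = 0
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        n += int(np.count_nonzero((lab[lo] == a) & (lab[hi] == b)))
        n += int(np.count_nonzero((lab[lo] == b) & (lab[hi] == a)))
    return n


def build_default_geometry(cfg: GeometryConfig | None = None) -> LabelField:
    """Build the labelled voxel phantom.  Deterministic in the config."""
    if cfg is None:
        cfg = GeometryConfig()
    dx = cfg.dx
    # one padding voxel of OUTSIDE on every side
    nx = int(np.ceil(2 * cfg.torso_rx / dx)) + 2
    ny = int(np.ceil(2 * cfg.torso_ry / dx)) + 2
    nz = int(np.ceil(cfg.torso_height / dx)) + 2
    origin = (-(nx * dx) / 2, -(ny * dx) / 2, -(nz * dx) / 2)
    fld = LabelField(np.zeros((nx, ny, nz), dtype=np.int8), origin, dx)
    X, Y, Z = fld.coordinates()
    lab = fld.labels

    torso = ((X / cfg.torso_rx) ** 2 + (Y / cfg.torso_ry) ** 2 <= 1.0) \
        & (np.abs(Z) <= cfg.torso_height / 2)
    lab[torso] = Label.TORSO

    for sx in (-1.0, 1.0):
        lung = (((X - sx * cfg.lung_xoff) / cfg.lung_rx) ** 2
                + ((Y - cfg.lung_yoff) / cfg.lung_ry) ** 2 <= 1.0) \
            & (Z >= cfg.lung_zmin) & (Z <= cfg.lung_zmax) & torso
        lab[lung] = Label.LUNGS

    cx, cy, cz = cfg.heart_center
    r2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
    cavity = r2 <= (cfg.heart_outer_radius + cfg.cavity_margin) ** 2
    lab[cavity & (lab == Label.LUNGS)] = Label.TORSO

    Ro, Ri = cfg.heart_outer_radius, cfg.inner_radius
    shell = (r2 <= Ro ** 2) & (r2 >= Ri ** 2)
    interior = r2 < Ri ** 2
    z_av = cz + cfg.av_plane_offset
    z0 = z_av - cfg.gap_thickness / 2  # top of the ventricular band
    z1 = z_av + cfg.gap_thickness / 2  # bottom of the atrial band
    vent_band = Z <= z0
    atr_band = Z >= z1
    gap_band = ~vent_band & ~atr_band

    lab[shell & vent_band] = Label.VENTRICLES
    lab[shell & atr_band] = Label.ATRIA
    lab[shell & gap_band] = Label.TORSO  # the AV isolation gap (passive)
    lab[interior] = Label.BLOOD

    septum = (np.abs(X - cx) <= cfg.septum_thickness / 2) & interior
    lab[septum & vent_band] = Label.VENTRICLES
    lab[septum & atr_band] = Label.ATRIA

    # Conduction-system column down the septum.  Low-conductivity regions at
    # voxel resolution suffer severe source-sink mismatch, so every stage is
    # kept one voxel thin and embedded in the tissue that must ignite it:
    # the bundle-branch stem is a single-voxel column through the ventricular
    # septum (it conducts regeneratively and ignites the septum laterally);
    # the His bundle is a single-voxel column crossing the isolation gap plus
    # one voxel into the atrial band, where it is wrapped on five faces by
    # the AVN block; the AVN is a two-layer block at the base of the atrial
    # septum, excited directly by the surrounding atrial wall (whose slow
    # charging of the low-sigma node tissue produces the AV delay).
    ax_x, ax_y, _ = fld.axes()
    x0 = ax_x[np.argmin(np.abs(ax_x - cx))]
    y0 = ax_y[np.argmin(np.abs(ax_y - cy))]
    col_his = (np.abs(X - x0) < dx / 2) & (np.abs(Y - y0) < dx / 2)
    col_avn = (X - cx) ** 2 + (Y - cy) ** 2 <= cfg.junction_radius ** 2

    # Bundle stem and Purkinje trunk, placed before the endocardial Purkinje
    # relabel so it cannot steal them.  The stem is two voxel layers of BNL
    # wrapped in a working-myocardium sheath: without the sheath the stem is
    # glued to the tightly coupled endocardial network whose current sink
    # blocks its ignition by the His bundle.  Below the stem the same column
    # continues as an explicit Purkinje trunk joining the endocardial layer,
    # so the network lights directly from the powered stem bottom; the
    # sheath voxels themselves sit on the Purkinje plates whose sink retards
    # them until the network has fired, keeping the activation order
    # BNL -> Purkinje -> working ventricle.
    # Free-running bundle branch: from the His bundle's lowest gap-level
    # voxel a horizontal BNL bridge crosses the gap blood to a column clear
    # of the septum, which descends through the ventricular cavity without
    # touching any myocardium (like the moderator band) and inserts into the
    # endocardial Purkinje layer near the apex.  Because nothing but blood
    # borders the bundle, the Purkinje network must activate before any
    # working ventricular myocardium -- the physiological order is enforced
    # by topology, not by a race between conduction paths.
    off = cfg.septum_thickness / 2 + dx / 2
    cand = np.flatnonzero(ax_x - cx > off)
    if cand.size == 0:
        raise GeometryError("no room for the free-running bundle branch "
                            "beside the septum")
    x_f = ax_x[cand[0]]
    col_stem = (np.abs(X - x_f) < dx / 2) & (np.abs(Y - y0) < dx / 2)
    gap_z = Z[(Z > z0) & (Z < z1)]
    z_b = gap_z.min() if gap_z.size else z0 + dx / 2
    bridge = (X > x0 + dx / 2) & (X < x_f + dx / 2) & (np.abs(Y - y0) < dx / 2) \
        & (np.abs(Z - z_b) < dx / 2) & (lab == Label.BLOOD)
    stem = col_stem & (Z < z_b) & (lab == Label.BLOOD) \
        & (Z >= z_b - cfg.bundle_depth)
    # A two-voxel Purkinje-fiber segment sits inside the free column (the
    # bundle-to-fiber transition of real anatomy); it fires right after the
    # bundle above it, which guarantees the Purkinje region activates before
    # any ventricular myocardium.  The distal column continues as bundle
    # tissue and ends on a working-myocardium voxel at the apex: excitation
    # at voxel scale can step down in conductivity but not up, so the
    # tightly coupled endocardial plate network is recruited afterwards by
    # the broad myocardial wavefront rather than point ignition.
    fiber = stem & (Z < z_b - 2.5 * dx) & (Z >= z_b - 4.5 * dx)
    lab[bridge | (stem & ~fiber)] = Label.BNL
    lab[fiber] = Label.PURKINJE
    under = np.zeros_like(lab, dtype=bool)
    if stem.any():
        z_under = Z[stem].min() - dx
        under = col_stem & (np.abs(Z - z_under) < dx / 2) \
            & (lab == Label.VENTRICLES)

    # Purkinje: every ventricular voxel with a face neighbour of blood,
    # except the insertion myocardium directly under the bundle tip.
    vent = lab == Label.VENTRICLES
    blood = lab == Label.BLOOD
    near_blood = ndimage.binary_dilation(
        blood, structure=ndimage.generate_binary_structure(3, 1))
    lab[vent & near_blood & ~under] = Label.PURKINJE

    lab[col_his & (Z > z0) & (Z < z1 + dx)
        & np.isin(lab, [int(Label.BLOOD), int(Label.TORSO), int(Label.ATRIA)])] = Label.HIS
    lab[col_avn & (lab == Label.ATRIA) & (Z >= z1)
        & (Z < z1 + cfg.avn_depth)] = Label.AVN

    # SAN patch in the right atrial wall.  The node's conductivity is ~16x
    # below the atrial one, so a convex patch cannot source enough current to
    # excite the surrounding wall (source-sink mismatch).  Like the exit
    # pathways of the real sinoatrial node, a one-voxel-wide atrial pocket is
    # notched into the epicardial half of the patch: pocket voxels see SAN
    # tissue on several faces at once and relay the excitation to the wall.
    d = np.asarray(cfg.san_direction, dtype=float)
    d /= np.linalg.norm(d)
    sc = np.array([cx, cy, cz]) + d * (Ri + Ro) / 2
    san = ((X - sc[0]) ** 2 + (Y - sc[1]) ** 2 + (Z - sc[2]) ** 2
           <= cfg.san_radius ** 2)
    if cfg.san_exit:
        t1 = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(t1) < 1e-9:
            t1 = np.cross(d, [1.0, 0.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(d, t1)
        dX, dY, dZ = X - sc[0], Y - sc[1], Z - sc[2]
        outer_half = r2 >= ((Ri + Ro) / 2) ** 2
        pocket = (np.abs(dX * t1[0] + dY * t1[1] + dZ * t1[2]) <= 0.55 * dx) \
            & (np.abs(dX * t2[0] + dY * t2[1] + dZ * t2[2]) <= 1.1 * dx) \
            & outer_half
        san &= ~pocket
    lab[san & (lab == Label.ATRIA)] = Label.SAN

    # sanity: every region must be resolvable at this dx
    missing = [l.name for l in HEART_LABELS if not np.any(lab == l)]
    if missing:
        raise GeometryError(
            f"regions not resolvable at dx = {dx} m: {', '.join(missing)}")
    return fld


# ---------------------------------------------------------------------------
# Validation.

_CHAIN = [(Label.SAN, Label.ATRIA), (Label.ATRIA, Label.AVN),
          (Label.AVN, Label.HIS), (Label.HIS, Label.BNL),
          (Label.BNL, Label.PURKINJE), (Label.PURKINJE, Label.VENTRICLES)]


@dataclass
class GeometryCheck:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class GeometryReport:
    counts: dict
    checks: list

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def __str__(self) -> str:
        lines = ["voxel counts:"]
        lines += [f"  {k:11s} {v}" for k, v in self.counts.items()]
        lines += ["checks:"]
        lines += [f"  [{'ok' if c.passed else 'FAIL'}] {c.name}"
                  + (f": {c.detail}" if c.detail else "") for c in self.checks]
        return "\n".join(lines)


def validate_geometry(fld: LabelField) -> GeometryReport:
    """Check region presence, conduction-chain adjacency, AV isolation and
    per-region connectedness.  Purely diagnostic: never raises."""
    lab = fld.labels
    checks: list[GeometryCheck] = []

    present = [l for l in HEART_LABELS if np.any(lab == l)]
    checks.append(GeometryCheck(
        "seven-heart-regions", len(present) == 7,
        f"{len(present)}/7 present"))
    for l in (Label.TORSO, Label.LUNGS, Label.BLOOD):
        checks.append(GeometryCheck(f"{l.name.lower()}-present", bool(np.any(lab == l))))

    for a, b in _CHAIN:
        n = face_adjacency_count(lab, a, b)
        checks.append(GeometryCheck(
            f"chain-{a.name}-{b.name}", n > 0,
            f"{n} face-adjacent pairs" if n else f"broken link {a.name}-{b.name}"))

    pairs = _face_neighbor_pairs(lab, Label.ATRIA, Label.VENTRICLES)
    checks.append(GeometryCheck(
        "av-isolation", len(pairs) == 0,
        "" if not pairs else
        f"{len(pairs)} atria-ventricle contacts, e.g. voxels {pairs[0][0]}-{pairs[0][1]}"))

    # Connectedness diagnostic (26-connectivity: a voxelized thin spherical
    # layer such as the Purkinje sheet is one piece through voxel corners even
    # where the 6-neighbour stencil sees islands).  Single-component status is
    # enforced only for the compact conduction structures; for the bulk
    # regions the count is informational -- the working-myocardium sheath
    # around the bundle stem is labelled apart from the free wall but remains
    # electrically continuous with it through the Purkinje lattice.
    struct = ndimage.generate_binary_structure(3, 3)
    # the bundle-branch label is allowed two segments: the proximal bundle
    # and the distal bundle separated by the Purkinje-fiber transition
    max_components = {Label.SAN: 1, Label.AVN: 1, Label.HIS: 1, Label.BNL: 2}
    for l in HEART_LABELS:
        mask = lab == l
        if not mask.any():
            checks.append(GeometryCheck(f"connected-{l.name}", False, "absent"))
            continue
        _, ncomp = ndimage.label(mask, structure=struct)
        checks.append(GeometryCheck(
            f"connected-{l.name}", ncomp <= max_components.get(l, ncomp),
            f"{ncomp} components"))

    return GeometryReport(counts=fld.counts(), checks=checks)


# ---------------------------------------------------------------------------
# Conductivity and tissue maps.

def conductivity_maps(fld: LabelField,
                      params: Mapping[str, CellParameters] | None = None,
                      passive: Mapping[str, float] | None = None):
    """Voxelwise (sigma_i, sigma_e, sigma_o) fields in S/m.

    sigma_i/sigma_e are zero outside the heart; sigma_o is zero outside the
    passive volume conductors (torso, lungs, blood).
    """
    params = params or all_region_defaults()
    passive = dict(DEFAULT_PASSIVE, **(passive or {}))
    lab = fld.labels
    sigma_i = np.zeros(lab.shape)
    sigma_e = np.zeros(lab.shape)
    sigma_o = np.zeros(lab.shape)
    for l in HEART_LABELS:
        region = LABEL_TO_REGION[l]
        if region not in params:
            raise KeyError(f"no CellParameters provided for region {region}")
        m = lab == l
        sigma_i[m] = params[region].sigma_i
        sigma_e[m] = params[region].sigma_e
    for l, key in [(Label.TORSO, "torso"), (Label.LUNGS, "lungs"), (Label.BLOOD, "blood")]:
        if key not in passive:
            raise KeyError(f"no passive conductivity provided for {key}")
        sigma_o[lab == l] = passive[key]
    return sigma_i, sigma_e, sigma_o


@dataclass
class TissueMaps:
    """Per-voxel physical maps the solver consumes.

    ``k`` is the per-voxel rate constant (1/s); an infarct zeroes it together
    with sigma_i.  ``Vi0``/``Ve0``/``u0`` are initial conditions (V).
    """

    sigma_i: np.ndarray
    sigma_e: np.ndarray
    sigma_o: np.ndarray
    k: np.ndarray
    Vi0: np.ndarray
    Ve0: np.ndarray
    u0: np.ndarray
    lesion_mask: np.ndarray  # bool: voxels inside any applied lesion

    def copy(self) -> "TissueMaps":
        return TissueMaps(*(getattr(self, f).copy() for f in (
            "sigma_i", "sigma_e", "sigma_o", "k", "Vi0", "Ve0", "u0", "lesion_mask")))


def build_tissue(fld: LabelField,
                 params: Mapping[str, CellParameters] | None = None,
                 passive: Mapping[str, float] | None = None) -> TissueMaps:
    params = params or all_region_defaults()
    sigma_i, sigma_e, sigma_o = conductivity_maps(fld, params, passive)
    lab = fld.labels
    k = np.zeros(lab.shape)
    Vi0 = np.zeros(lab.shape)
    for l in HEART_LABELS:
        p = params[LABEL_TO_REGION[l]]
        m = lab == l
        k[m] = p.k
        Vi0[m] = -0.060 if p.region == "SAN" else -0.085
    return TissueMaps(sigma_i=sigma_i, sigma_e=sigma_e, sigma_o=sigma_o, k=k,
                      Vi0=Vi0, Ve0=np.zeros(lab.shape), u0=np.zeros(lab.shape),
                      lesion_mask=np.zeros(lab.shape, dtype=bool))


# ---------------------------------------------------------------------------
# Infarct lesions.

@dataclass(frozen=True)
class LesionSpec:
    """Ellipsoidal or box-shaped infarct region (meters)."""

    name: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    shape: str = "ellipsoid"

    def __post_init__(self) -> None:
        if self.shape not in ("ellipsoid", "box"):
            raise ValueError(f"unknown lesion shape {self.shape!r}")


class LesionError(ValueError):
    pass


def lesion_mask(fld: LabelField, lesion: LesionSpec) -> np.ndarray:
    """Boolean mask of heart voxels inside the lesion shape.

    Only myocardial voxels are ever part of the applied mask; a lesion shape
    containing no heart voxel (e.g. centred in the torso) is rejected.
    A zero-radius lesion yields an empty mask without error.
    """
    rx, ry, rz = lesion.radii
    if rx == 0 and ry == 0 and rz == 0:
        return np.zeros(fld.shape, dtype=bool)
    X, Y, Z = fld.coordinates()
    cx, cy, cz = lesion.center
    if lesion.shape == "ellipsoid":
        inside = (((X - cx) / max(rx, 1e-12)) ** 2
                  + ((Y - cy) / max(ry, 1e-12)) ** 2
                  + ((Z - cz) / max(rz, 1e-12)) ** 2) <= 1.0
    else:
        inside = (np.abs(X - cx) <= rx) & (np.abs(Y - cy) <= ry) & (np.abs(Z - cz) <= rz)
    mask = inside & fld.heart_mask()
    if not mask.any():
        raise LesionError(
            f"lesion {lesion.name!r} does not intersect any heart region")
    return mask


def apply_infarct(fld: LabelField, tissue: TissueMaps,
                  lesion: LesionSpec) -> TissueMaps:
    """Return new tissue maps with the infarct applied.

    Inside the lesion the intracellular conductivity and the rate constant k
    are zeroed (electrically silent, unexcitable tissue) and the initial
    potentials are set to Vi = -60 mV, Ve = -20 mV (the injured-tissue state
    whose diastolic current shifts the ECG baseline).  Voxels outside the
    lesion are untouched.
    """
    mask = lesion_mask(fld, lesion)
    out = tissue.copy()
    out.sigma_i[mask] = 0.0
    out.k[mask] = 0.0
    out.Vi0[mask] = -0.060
    out.Ve0[mask] = -0.020
    out.lesion_mask |= mask
    return out


_PRESET_DIRECTIONS = {
    # unit directions from the heart centre toward the lesion centre
    "anterior-MI": (0.05, 0.60, -0.80),   # apical, anterior wall
    # the diaphragmatic wall faces posterior-inferior (~45 degrees)
    "inferior-MI": (0.05, -0.55, -0.84),
}


def lesion_preset(name: str, cfg: GeometryConfig,
                  relative_radius: float = 0.45) -> LesionSpec:
    """Built-in apical transmural infarct positions, scaled to the geometry."""
    if name not in _PRESET_DIRECTIONS:
        raise KeyError(f"unknown lesion preset {name!r}; "
                       f"available: {', '.join(_PRESET_DIRECTIONS)}")
    d = np.asarray(_PRESET_DIRECTIONS[name], dtype=float)
    d /= np.linalg.norm(d)
    rmid = (cfg.inner_radius + cfg.heart_outer_radius) / 2
    center = tuple(np.asarray(cfg.heart_center) + d * rmid)
    r = relative_radius * cfg.heart_outer_radius
    return LesionSpec(name=name, center=center, radii=(r, r, r))
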