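"""Electrode placement and the ECG lead calculus.

Surface electrodes are points snapped to torso-surface voxels.  From the raw
electrode potentials the standard derived channels are computed per sample:

* Einthoven limb leads       I = VL - VR,  II = VF - VR,  III = VF - VL
* Goldberger augmented leads aVR = (2 VR - VL - VF)/2 (and cyclic)
* Wilson precordial leads    V_k - (VL + VR + VF)/3
* Frank orthogonal leads     X = 0.610 A + 0.171 C - 0.781 I
                             Y = 0.655 F + 0.345 M - 1.000 H
                             Z = 0.133 A + 0.736 M - 0.264 I - 0.374 E - 0.231 C
* RMS curves                 VRMS  = sqrt((I^2 + II^2 + III^2)/3)
                             VSAECG = sqrt((X^2 + Y^2 + Z^2)/3)

Each coefficient set of the Frank matrix sums to zero, so the X/Y/Z leads
reject any common-mode offset of the seven electrodes.  Lead traces carry mV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import Label, LabelField

__all__ = [
    "STANDARD_ELECTRODES",
    "FRANK_ELECTRODES",
    "DEFAULT_LAYOUT",
    "ElectrodeSet",
    "LeadTraces",
    "place_electrodes",
    "einthoven",
    "augmented",
    "precordial",
    "frank_xyz",
    "rms_curves",
    "derive_all",
    "CHANNEL_ORDER",
]

STANDARD_ELECTRODES = ("VR", "VL", "VF", "VGND", "V1", "V2", "V3", "V4", "V5", "V6")
FRANK_ELECTRODES = ("A", "C", "E", "F", "H", "I", "M")

#: Fractional positions inside the torso bounding box [0,1]^3
#: (x: right->left, y: posterior->anterior, z: feet->head); all snapped to the
#: nearest torso-surface voxel.  Limb electrodes sit at the torso "corners",
#: V1-V6 along an anterior arc at heart height, the Frank ring at mid-heart
#: height with H near the neck and F low on the left.
DEFAULT_LAYOUT: Mapping[str, tuple[float, float, float]] = {
    "VR": (0.08, 0.50, 0.97), "VL": (0.92, 0.50, 0.97),
    "VGND": (0.08, 0.50, 0.03), "VF": (0.92, 0.50, 0.03),
    "V1": (0.44, 0.92, 0.60), "V2": (0.56, 0.92, 0.60),
    "V3": (0.64, 0.90, 0.58), "V4": (0.72, 0.86, 0.57),
    "V5": (0.80, 0.76, 0.57), "V6": (0.88, 0.62, 0.57),
    "A": (0.95, 0.50, 0.58), "C": (0.78, 0.84, 0.58), "E": (0.50, 0.97, 0.58),
    "I": (0.05, 0.50, 0.58), "M": (0.50, 0.03, 0.58),
    "H": (0.50, 0.85, 0.96), "F": (0.85, 0.50, 0.05),
}


class ElectrodePlacementError(ValueError):
    pass


@dataclass
class ElectrodeSet:
    """Named electrodes resolved to flat voxel indices on the torso surface."""

    nodes: dict            # name -> flat voxel index
    snap_distance: dict    # name -> snapping distance (m)
    field_shape: tuple

    def __getitem__(self, name: str) -> int:
        return self.nodes[name]

    def names(self):
        return list(self.nodes)


def _surface_voxels(fld: LabelField) -> np.ndarray:
    """Flat indices of torso voxels with a face neighbour outside the body."""
    lab = fld.labels
    outside = lab == int(Label.OUTSIDE)
    surf = np.zeros(lab.shape, dtype=bool)
    for axis in range(3):
        for shift in (1, -1):
            surf |= np.roll(outside, shift, axis=axis)
    # voxels on the grid boundary also count as surface
    edge = np.zeros(lab.shape, dtype=bool)
    edge[0, :, :] = edge[-1, :, :] = True
    edge[:, 0, :] = edge[:, -1, :] = True
    edge[:, :, 0] = edge[:, :, -1] = True
    surf = (surf | edge) & (lab == int(Label.TORSO))
    return np.flatnonzero(surf.ravel())


def place_electrodes(fld: LabelField,
                     layout: Mapping[str, tuple[float, float, float]] | None = None
                     ) -> ElectrodeSet:
    """Snap each named fractional position to the nearest torso-surface voxel.

    Raises if any fraction is outside [0, 1].  Warns if two electrodes snap to
    the same voxel (the layout is then too dense for the grid).
    """
    from scipy.spatial import cKDTree

    layout = dict(layout or DEFAULT_LAYOUT)
    for name, frac in layout.items():
        if not all(0.0 <= f <= 1.0 for f in frac):
            raise ElectrodePlacementError(
                f"electrode {name}: layout fractions must lie in [0,1]^3, got {frac}")

    surf_flat = _surface_voxels(fld)
    if surf_flat.size == 0:
        raise ElectrodePlacementError("geometry has no torso-surface voxels")
    ijk = np.array(np.unravel_index(surf_flat, fld.shape)).T
    org = np.asarray(fld.origin)
    pts = org + (ijk + 0.5) * fld.dx
    tree = cKDTree(pts)

    lo = org + 0.5 * fld.dx
    hi = org + (np.asarray(fld.shape) - 0.5) * fld.dx
    nodes, dist = {}, {}
    for name, frac in layout.items():
        target = lo + np.asarray(frac) * (hi - lo)
        d, i = tree.query(target)
        nodes[name] = int(surf_flat[i])
        dist[name] = float(d)

    by_node: dict[int, list[str]] = {}
    for name, node in nodes.items():
        by_node.setdefault(node, []).append(name)
    for node, names in by_node.items():
        if len(names) > 1:
            warnings.warn(f"electrodes {', '.join(names)} snapped to the same "
                          f"voxel (flat index {node})", stacklevel=2)
    return ElectrodeSet(nodes=nodes, snap_distance=dist, field_shape=fld.shape)


# ---------------------------------------------------------------------------
# Lead calculus.  All functions are per-sample and length-checked.

def _check_lengths(**traces):
    lens = {k: len(np.asarray(v)) for k, v in traces.items()}
    if len(set(lens.values())) > 1:
        raise ValueError(f"trace length mismatch: {lens}")


def einthoven(VL, VR, VF):
    """Bipolar limb leads (I, II, III).  II = I + III identically."""
    _check_lengths(VL=VL, VR=VR, VF=VF)
    VL, VR, VF = (np.asarray(x, dtype=float) for x in (VL, VR, VF))
    return VL - VR, VF - VR, VF - VL


def augmented(VL, VR, VF):
    """Goldberger augmented leads (aVR, aVL, aVF); they sum to zero."""
    _check_lengths(VL=VL, VR=VR, VF=VF)
    VL, VR, VF = (np.asarray(x, dtype=float) for x in (VL, VR, VF))
    aVR = (2 * VR - VL - VF) / 2
    aVL = (2 * VL - VR - VF) / 2
    aVF = (2 * VF - VR - VL) / 2
    return aVR, aVL, aVF


def precordial(chest: Mapping[str, np.ndarray], VL, VR, VF) -> dict:
    """Chest leads referenced to the Wilson central terminal (VL+VR+VF)/3."""
    _check_lengths(VL=VL, VR=VR, VF=VF, **chest)
    VL, VR, VF = (np.asarray(x, dtype=float) for x in (VL, VR, VF))
    wct = (VL + VR + VF) / 3.0
    return {name: np.asarray(v, dtype=float) - wct for name, v in chest.items()}


def frank_xyz(A, C, E, F, H, I, M):
    """Orthogonal vectorcardiographic leads from the seven Frank electrodes."""
    _check_lengths(A=A, C=C, E=E, F=F, H=H, I=I, M=M)
    A, C, E, F, H, I, M = (np.asarray(x, dtype=float) for x in (A, C, E, F, H, I, M))
    X = 0.610 * A + 0.171 * C - 0.781 * I
    Y = 0.655 * F + 0.345 * M - 1.000 * H
    Z = 0.133 * A + 0.736 * M - 0.264 * I - 0.374 * E - 0.231 * C
    return X, Y, Z


def rms_curves(I, II, III, X=None, Y=None, Z=None):
    """VRMS over the Einthoven leads; VSAECG over X/Y/Z when given."""
    _check_lengths(I=I, II=II, III=III)
    I, II, III = (np.asarray(x, dtype=float) for x in (I, II, III))
    vrms = np.sqrt((I ** 2 + II ** 2 + III ** 2) / 3.0)
    vsaecg = None
    if X is not None and Y is not None and Z is not None:
        _check_lengths(X=X, Y=Y, Z=Z)
        X, Y, Z = (np.asarray(x, dtype=float) for x in (X, Y, Z))
        vsaecg = np.sqrt((X ** 2 + Y ** 2 + Z ** 2) / 3.0)
    return vrms, vsaecg


#: Fixed CSV channel order for derived traces.
CHANNEL_ORDER = (
    ["time_s"] + list(STANDARD_ELECTRODES) + list(FRANK_ELECTRODES)
    + ["lead_I", "lead_II", "lead_III", "aVR", "aVL", "aVF"]
    + [f"lead_V{i}" for i in range(1, 7)] + ["X", "Y", "Z", "VRMS", "VSAECG"])


@dataclass
class LeadTraces:
    """Time-indexed multichannel traces (mV) on one common time base."""

    data: pd.DataFrame  # column time_s (s) + channels (mV)

    @property
    def dt(self) -> float:
        t = self.data["time_s"].to_numpy()
        return float(t[1] - t[0]) if len(t) > 1 else float("nan")

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.data[channel].to_numpy()

    def channels(self):
        return [c for c in self.data.columns if c != "time_s"]

    def to_csv(self, path) -> None:
        cols = [c for c in CHANNEL_ORDER if c in self.data.columns]
        cols += [c for c in self.data.columns if c not in cols]
        self.data[cols].to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "LeadTraces":
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise ValueError("trace file lacks the time_s column")
        return LeadTraces(df)


def derive_all(electrode_df: pd.DataFrame, in_volts: bool = True) -> LeadTraces:
    """Compute every derivable channel from a raw electrode table.

    ``electrode_df`` must hold ``time_s`` plus electrode columns; potentials
    in volts (``in_volts=True``, the solver's convention) or mV.  Missing
    electrode groups simply skip their derived channels, except the limb
    electrodes which are required.
    """
    df = electrode_df.copy()
    scale = 1e3 if in_volts else 1.0
    for c in df.columns:
        if c != "time_s":
            df[c] = df[c] * scale

    for req in ("VL", "VR", "VF"):
        if req not in df.columns:
            raise ValueError(f"missing required electrode channel {req!r}")

    out = {c: df[c].to_numpy() for c in df.columns}
    VL, VR, VF = df["VL"].to_numpy(), df["VR"].to_numpy(), df["VF"].to_numpy()
    I, II, III = einthoven(VL, VR, VF)
    out["lead_I"], out["lead_II"], out["lead_III"] = I, II, III
    out["aVR"], out["aVL"], out["aVF"] = augmented(VL, VR, VF)

    chest = {c: df[c].to_numpy() for c in ("V1", "V2", "V3", "V4", "V5", "V6")
             if c in df.columns}
    for name, v in precordial(chest, VL, VR, VF).items():
        out[f"lead_{name}"] = v

    X = Y = Z = None
    if all(e in df.columns for e in FRANK_ELECTRODES):
        X, Y, Z = frank_xyz(*(df[e].to_numpy() for e in FRANK_ELECTRODES))
        out["X"], out["Y"], out["Z"] = X, Y, Z

    vrms, vsaecg = rms_curves(I, II, III, X, Y, Z)
    out["VRMS"] = vrms
    if vsaecg is not None:
        out["VSAECG"] = vsaecg

    res = pd.DataFrame(out)
    cols = [c for c in CHANNEL_ORDER if c in res.columns]
    cols += [c for c in res.columns if c not in cols]
    return LeadTraces(res[cols])
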