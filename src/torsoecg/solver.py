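"""Coupled bidomain / volume-conductor solver on the voxel grid.

The heart carries the bidomain pair (intracellular potential ``Vi``,
extracellular potential ``Ve``) plus the recovery variable ``u``; torso,
lungs and blood carry a single passive potential ``V`` obeying the Laplace
equation.  Writing ``Vm = Vi - Ve``, the symmetric bidomain system reduces
to a parabolic equation and an elliptic constraint:

    dVm/dt = -iion + div(sigma_i grad Vi)            (heart)
    div(sigma_i grad Vi) + div(sigma_e grad Ve) = 0  (heart)
    div(sigma_o grad V) = 0                          (passive)

with ``V = Ve`` and extracellular flux continuity at the heart surface,
zero-flux for ``Vi`` at the heart surface, an insulating torso exterior, and
one grounded node pinned to ``V = 0`` exactly (the right-leg electrode).

Discretization: 7-point finite volumes with harmonic face-averaged
conductivities.  Time stepping is operator splitting per step ``dt``:
an explicit (sub-cycled Heun) reaction update of ``(Vm, u)``, an implicit
Euler diffusion solve for ``Vi``, and one elliptic solve for the combined
``Ve``/``V`` field over heart + passive nodes, which enforces both interface
conditions as the transmission conditions of a composite-conductivity
Poisson problem.  Both sparse operators are constant, so they are factorized
once (or solved by preconditioned CG on grids too large to factorize).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from . import cells
from .cells import CellParameters, all_region_defaults
from .geometry import (HEART_LABELS, LABEL_TO_REGION, Label, LabelField,
                       LesionSpec, TissueMaps, build_tissue)

__all__ = [
    "DiscreteSystem",
    "FieldState",
    "SimulationResult",
    "TissueStimulus",
    "assemble",
    "step",
    "simulate",
    "conduction_velocity",
    "make_strip_field",
]

# node counts above this use preconditioned CG instead of a direct factorization
_DIRECT_LIMIT = 200_000


class AssemblyError(ValueError):
    pass


class SolverError(RuntimeError):
    pass


def _weighted_laplacian(mask: np.ndarray, sigma: np.ndarray, dx: float) -> sp.csr_matrix:
    """FV Laplacian L with (L phi)_p = sum_faces w (phi_q - phi_p),
    w = harmonic_mean(sigma_p, sigma_q) / dx^2, over nodes where mask."""
    ids = -np.ones(mask.shape, dtype=np.int64)
    n = int(mask.sum())
    ids[mask] = np.arange(n)
    rows, cols, vals = [], [], []
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        both = mask[lo] & mask[hi]
        s1 = sigma[lo][both]
        s2 = sigma[hi][both]
        ssum = s1 + s2
        w = np.where(ssum > 0, 2.0 * s1 * s2 / np.where(ssum > 0, ssum, 1.0), 0.0) / dx ** 2
        p = ids[lo][both]
        q = ids[hi][both]
        keep = w != 0
        p, q, w = p[keep], q[keep], w[keep]
        rows += [p, q, p, q]
        cols += [q, p, p, q]
        vals += [w, w, -w, -w]
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
    else:  # single-node or fully decoupled domain
        rows = np.array([], dtype=np.int64)
        cols = np.array([], dtype=np.int64)
        vals = np.array([])
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


class _LinearSolver:
    """Direct (factorize once) below _DIRECT_LIMIT, else Jacobi-CG, rtol 1e-8."""

    def __init__(self, A: sp.csr_matrix, rtol: float = 1e-8):
        self.n = A.shape[0]
        self.rtol = rtol
        self.direct = self.n <= _DIRECT_LIMIT
        if self.direct:
            self._lu = spla.splu(A.tocsc())
        else:
            self._A = A
            d = A.diagonal()
            d[d == 0] = 1.0
            self._M = sp.diags(1.0 / d)
            self._x0 = np.zeros(self.n)

    def solve(self, b: np.ndarray) -> np.ndarray:
        if self.direct:
            return self._lu.solve(b)
        x, info = spla.cg(self._A, b, x0=self._x0, rtol=self.rtol, atol=0.0,
                          M=self._M, maxiter=20 * int(np.sqrt(self.n)) + 200)
        if info != 0:
            r = np.linalg.norm(self._A @ x - b)
            raise SolverError(f"CG did not converge (info={info}, residual={r:.3e})")
        self._x0 = x
        return x


@dataclass(frozen=True)
class TissueStimulus:
    """Rectangular current pulse applied to heart voxels near ``center``."""

    center: tuple[float, float, float]
    radius: float
    t_start: float
    duration: float
    amplitude: float  # V/s equivalent, added to dVm/dt


@dataclass
class DiscreteSystem:
    """Assembled operators and per-node parameter vectors for one geometry."""

    field: LabelField
    dt: float
    heart_flat: np.ndarray      # flat voxel indices of heart nodes
    cond_flat: np.ndarray       # flat voxel indices of conducting nodes
    heart_in_cond: np.ndarray   # positions of heart nodes inside cond vector
    Li: sp.csr_matrix           # sigma_i Laplacian on heart nodes (zero-flux)
    A_ell: sp.csr_matrix        # pinned composite elliptic matrix (-Le + pin)
    ground_pos: int             # position of the grounded node in cond vector
    # per-heart-node kinetics
    a: np.ndarray
    b: np.ndarray
    c1: np.ndarray
    c2: np.ndarray
    d: np.ndarray
    e: np.ndarray
    k: np.ndarray
    A: np.ndarray
    B: np.ndarray
    pacemaker: np.ndarray       # bool mask (SAN variant of iion)
    Vi0: np.ndarray
    Ve0: np.ndarray
    u0: np.ndarray
    _vi_solver: _LinearSolver = dc_field(repr=False, default=None)
    _ell_solver: _LinearSolver = dc_field(repr=False, default=None)
    _stim_mask: np.ndarray | None = dc_field(repr=False, default=None)
    stimulus: TissueStimulus | None = None

    @property
    def n_heart(self) -> int:
        return self.heart_flat.size

    @property
    def n_cond(self) -> int:
        return self.cond_flat.size

    def initial_state(self) -> "FieldState":
        return FieldState(Vi=self.Vi0.copy(), u=self.u0.copy(),
                          phi=np.zeros(self.n_cond), t=0.0, sys=self)

    def region_nodes(self, region: str) -> np.ndarray:
        lab = self.field.labels.ravel()[self.heart_flat]
        wanted = [int(l) for l, r in LABEL_TO_REGION.items() if r == region]
        return np.flatnonzero(np.isin(lab, wanted))


@dataclass
class FieldState:
    """Nodal state at one instant: Vi, u over heart; phi = (Ve | V) over all
    conducting nodes.  ``phi`` at the grounded node is exactly 0."""

    Vi: np.ndarray
    u: np.ndarray
    phi: np.ndarray
    t: float
    sys: DiscreteSystem

    @property
    def Ve(self) -> np.ndarray:
        return self.phi[self.sys.heart_in_cond]

    @property
    def Vm(self) -> np.ndarray:
        return self.Vi - self.Ve

    def copy(self) -> "FieldState":
        return FieldState(self.Vi.copy(), self.u.copy(), self.phi.copy(),
                          self.t, self.sys)


def assemble(fld: LabelField, tissue: TissueMaps | None = None,
             params: Mapping[str, CellParameters] | None = None,
             dt: float = 5e-5, ground: int | tuple | None = None,
             stimulus: TissueStimulus | None = None) -> DiscreteSystem:
    """Build sparse operators, factorizations and per-node parameter vectors.

    ``ground`` is a flat voxel index (or 3D voxel index tuple) of the pinned
    node; it must be a conducting voxel.  The conducting domain must be one
    face-connected component (otherwise part of the tissue has no path to the
    ground reference and the elliptic problem splits).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    params = params or all_region_defaults()
    if tissue is None:
        tissue = build_tissue(fld, params)
    lab = fld.labels
    heart_mask = fld.heart_mask()
    cond_mask = fld.conducting_mask()

    _, ncomp = ndimage.label(cond_mask, structure=ndimage.generate_binary_structure(3, 1))
    if ncomp != 1:
        raise AssemblyError(
            f"conducting domain has {ncomp} disconnected components; "
            "no unique path to ground")

    heart_flat = np.flatnonzero(heart_mask.ravel())
    cond_flat = np.flatnonzero(cond_mask.ravel())
    pos_in_cond = -np.ones(lab.size, dtype=np.int64)
    pos_in_cond[cond_flat] = np.arange(cond_flat.size)
    heart_in_cond = pos_in_cond[heart_flat]

    if ground is None:
        ground_flat = int(cond_flat[0])
    elif isinstance(ground, tuple):
        ground_flat = int(np.ravel_multi_index(ground, lab.shape))
    else:
        ground_flat = int(ground)
    gpos = pos_in_cond[ground_flat]
    if gpos < 0:
        raise AssemblyError("ground node is not a conducting voxel")

    Li = _weighted_laplacian(heart_mask, tissue.sigma_i, fld.dx)
    sigma_all = np.where(heart_mask, tissue.sigma_e, tissue.sigma_o)
    Le = _weighted_laplacian(cond_mask, sigma_all, fld.dx)

    # elliptic matrix: -Le with the ground row/column eliminated symmetrically
    A_ell = (-Le).tocoo()
    keep = (A_ell.row != gpos) & (A_ell.col != gpos)
    A_ell = sp.coo_matrix(
        (np.concatenate([A_ell.data[keep], [1.0]]),
         (np.concatenate([A_ell.row[keep], [gpos]]),
          np.concatenate([A_ell.col[keep], [gpos]]))),
        shape=Le.shape).tocsr()
    M_vi = (sp.identity(Li.shape[0], format="csr") - dt * Li).tocsr()

    hv = heart_flat
    def gather(m):
        return m.ravel()[hv].astype(float)

    region_of = lab.ravel()[hv]
    arrs = {name: np.zeros(hv.size) for name in ("a", "b", "c1", "c2", "d", "e", "A", "B")}
    for l in HEART_LABELS:
        p = params[LABEL_TO_REGION[l]]
        m = region_of == int(l)
        for name in arrs:
            arrs[name][m] = getattr(p, name)
    pacemaker = region_of == int(Label.SAN)

    sysm = DiscreteSystem(
        field=fld, dt=dt, heart_flat=heart_flat, cond_flat=cond_flat,
        heart_in_cond=heart_in_cond, Li=Li, A_ell=A_ell, ground_pos=int(gpos),
        k=gather(tissue.k), Vi0=gather(tissue.Vi0), Ve0=gather(tissue.Ve0),
        u0=gather(tissue.u0), pacemaker=pacemaker, stimulus=stimulus, **arrs)
    sysm._vi_solver = _LinearSolver(M_vi)
    sysm._ell_solver = _LinearSolver(A_ell)
    if stimulus is not None:
        X, Y, Z = fld.coordinates()
        d2 = ((X - stimulus.center[0]) ** 2 + (Y - stimulus.center[1]) ** 2
              + (Z - stimulus.center[2]) ** 2).ravel()[heart_flat]
        sysm._stim_mask = d2 <= stimulus.radius ** 2
    return sysm


# ---------------------------------------------------------------------------
# Reaction sub-cycling.
#
# The explicit reaction update is sub-cycled per node with Heun (RK2) steps.
# The sub-step count is fixed at the start of each global step from a bound
# on the reaction Jacobian at the node's current state:
#
#     v    = (Vm - B)/A
#     g(w) = 3 w^2 - 2 (1+a) w + a          (= d/dv [v (a-v)(1-v)])
#     lam  = k * (c1 * max(|g(v-1)|, |g(v+1)|) + c2 * q) + 1000,
#            q = 1 for the pacemaker variant, |u| + 1 otherwise
#     n    = clip(ceil(dt * lam), 1, 100000),    h = dt / n
#
# This rule is deliberately simple so an independent scalar implementation
# can reproduce it bit-for-bit.  Only pacemaker nodes (c1 = 1000 vs 2.6)
# ever need large counts.  A numba-compiled kernel is used when available;
# the pure-numpy path computes identical results.

try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def reaction_substep_counts(sys: "DiscreteSystem", Vm: np.ndarray,
                            u: np.ndarray, dt: float) -> np.ndarray:
    """Per-node Heun sub-cycle counts for one global reaction step."""
    v = (Vm - sys.B) / sys.A
    g_lo = 3 * (v - 1) ** 2 - 2 * (1 + sys.a) * (v - 1) + sys.a
    g_hi = 3 * (v + 1) ** 2 - 2 * (1 + sys.a) * (v + 1) + sys.a
    gmax = np.maximum(np.abs(g_lo), np.abs(g_hi))
    q = np.where(sys.pacemaker, 1.0, np.abs(u) + 1.0)
    lam = sys.k * (sys.c1 * gmax + sys.c2 * q) + 1000.0
    return np.clip(np.ceil(dt * lam), 1, 100000).astype(np.int64)


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _react_kernel(vm, u, a, b, c1, c2, d, e, k, A, B, pace, istim, dt):
        n_nodes = vm.size
        for i in range(n_nodes):
            ki = k[i]
            if ki == 0.0:
                continue
            ai, bi = a[i], b[i]
            c1i, c2i, di, ei = c1[i], c2[i], d[i], e[i]
            Ai, Bi = A[i], B[i]
            pmi = pace[i]
            sti = istim[i]
            x, y = vm[i], u[i]
            v = (x - Bi) / Ai
            glo = 3.0 * (v - 1.0) ** 2 - 2.0 * (1.0 + ai) * (v - 1.0) + ai
            ghi = 3.0 * (v + 1.0) ** 2 - 2.0 * (1.0 + ai) * (v + 1.0) + ai
            gmax = max(abs(glo), abs(ghi))
            q = 1.0 if pmi else abs(y) + 1.0
            lam = ki * (c1i * gmax + c2i * q) + 1000.0
            nsub = int(min(max(np.ceil(dt * lam), 1.0), 100000.0))
            h = dt / nsub
            for _ in range(nsub):
                dv = x - Bi
                w = dv / Ai
                rec = c2i * y if pmi else c2i * y * dv
                f1v = -(ki * c1i * dv * (ai - w) * (1.0 - w) + ki * rec) + sti
                f1u = ki * ei * (w - di * y - bi)
                xp = x + h * f1v
                yp = y + h * f1u
                dv = xp - Bi
                w = dv / Ai
                rec = c2i * yp if pmi else c2i * yp * dv
                f2v = -(ki * c1i * dv * (ai - w) * (1.0 - w) + ki * rec) + sti
                f2u = ki * ei * (w - di * yp - bi)
                x += 0.5 * h * (f1v + f2v)
                y += 0.5 * h * (f1u + f2u)
            vm[i] = x
            u[i] = y


def _react_numpy(sys: "DiscreteSystem", Vm: np.ndarray, u: np.ndarray,
                 istim: np.ndarray, dt: float) -> None:
    """Vectorized fallback, identical arithmetic to the numba kernel."""
    counts = reaction_substep_counts(sys, Vm, u, dt)
    active = sys.k > 0
    counts = np.where(active, counts, 0)
    for n in np.unique(counts):
        if n == 0:
            continue
        idx = np.flatnonzero(counts == n)
        h = dt / n
        a, b = sys.a[idx], sys.b[idx]
        c1, c2 = sys.c1[idx], sys.c2[idx]
        d, e, k = sys.d[idx], sys.e[idx], sys.k[idx]
        A, B = sys.A[idx], sys.B[idx]
        pm = sys.pacemaker[idx]
        stim = istim[idx]
        vm, uu = Vm[idx], u[idx]
        for _ in range(int(n)):
            f1v = -cells.iion_fields(vm, uu, a, b, c1, c2, k, A, B, pm) + stim
            f1u = cells.du_dt_fields(vm, uu, b, d, e, k, A, B)
            vmp = vm + h * f1v
            uup = uu + h * f1u
            f2v = -cells.iion_fields(vmp, uup, a, b, c1, c2, k, A, B, pm) + stim
            f2u = cells.du_dt_fields(vmp, uup, b, d, e, k, A, B)
            vm = vm + 0.5 * h * (f1v + f2v)
            uu = uu + 0.5 * h * (f1u + f2u)
        Vm[idx] = vm
        u[idx] = uu


def _reaction(sys: "DiscreteSystem", Vm: np.ndarray, u: np.ndarray,
              t: float, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Explicit reaction substep over all heart nodes (returns new arrays).

    Infarcted nodes (k = 0) have frozen kinetics and are skipped."""
    Vm = Vm.copy()
    u = u.copy()
    istim = np.zeros(Vm.size)
    if sys.stimulus is not None and sys._stim_mask is not None:
        s = sys.stimulus
        if s.t_start <= t < s.t_start + s.duration:
            istim[sys._stim_mask] = s.amplitude
    if _HAVE_NUMBA:
        _react_kernel(Vm, u, sys.a, sys.b, sys.c1, sys.c2, sys.d, sys.e,
                      sys.k, sys.A, sys.B, sys.pacemaker, istim, dt)
    else:
        _react_numpy(sys, Vm, u, istim, dt)
    return Vm, u


def step(sys: DiscreteSystem, state: FieldState, dt: float | None = None) -> FieldState:
    """Advance one operator-splitting step of length ``sys.dt``.

    Order: reaction (explicit, sub-cycled) -> implicit Vi diffusion ->
    elliptic Ve/V solve with the ground pin.  Raises on non-finite state or
    a failed linear solve.
    """
    if dt is not None and not np.isclose(dt, sys.dt):
        raise ValueError(f"system was assembled for dt={sys.dt}, got {dt}")
    Vm_star, u_new = _reaction(sys, state.Vm, state.u, state.t, sys.dt)
    Vi_new = sys._vi_solver.solve(Vm_star + state.Ve)
    rhs = np.zeros(sys.n_cond)
    rhs[sys.heart_in_cond] = sys.Li @ Vi_new
    rhs[sys.ground_pos] = 0.0
    phi = sys._ell_solver.solve(rhs)
    phi[sys.ground_pos] = 0.0
    new = FieldState(Vi=Vi_new, u=u_new, phi=phi, t=state.t + sys.dt, sys=sys)
    if not (np.all(np.isfinite(Vi_new)) and np.all(np.isfinite(phi))):
        raise SolverError(
            f"non-finite state at t={new.t:.6f}s "
            f"(|Vi|max={np.nanmax(np.abs(Vi_new)):.3g})")
    return new


# ---------------------------------------------------------------------------
# Full runs.

@dataclass
class SimulationResult:
    """Electrode traces (V, one row per output sample), activation times and
    optional field snapshots."""

    times: np.ndarray                    # output sample times (s)
    electrode_traces: "object"           # pandas DataFrame, columns per electrode (V)
    activation: dict                     # region -> first activation time (s) or nan
    activation_nodes: np.ndarray         # per-heart-node first activation time (s)
    snapshots: dict                      # time -> dict of 3D arrays (Vm, Ve, V)
    log: list

    def lead_traces(self):
        """Full derived 12-lead + Frank + RMS channel set, in mV."""
        from .leads import derive_all

        return derive_all(self.electrode_traces)


def simulate(sys: DiscreteSystem, duration: float, output_interval: float = 1e-3,
             electrodes: Mapping[str, int] | None = None,
             snapshot_times: Sequence[float] = (),
             progress: bool = False) -> SimulationResult:
    """Run the assembled system for ``duration`` seconds.

    ``electrodes`` maps channel names to flat voxel indices (see
    :func:`torsoecg.leads.place_electrodes`); their potentials are recorded
    every ``output_interval`` (the grounded channel reads exactly 0).
    First-activation times are the first upward crossing of Vm through
    B + 0.75*A at each node.
    """
    import pandas as pd

    n_per_out = max(1, int(round(output_interval / sys.dt)))
    n_steps = int(round(duration / sys.dt))
    n_out = n_steps // n_per_out + 1

    elec = dict(electrodes or {})
    pos_in_cond = -np.ones(sys.field.labels.size, dtype=np.int64)
    pos_in_cond[sys.cond_flat] = np.arange(sys.n_cond)
    elec_pos = {}
    for name, flat in elec.items():
        p = pos_in_cond[int(flat)]
        if p < 0:
            raise AssemblyError(f"electrode {name} is not on a conducting voxel")
        elec_pos[name] = int(p)

    thr = sys.B + 0.75 * sys.A
    act = np.full(sys.n_heart, np.nan)
    state = sys.initial_state()
    traces = {name: np.zeros(n_out) for name in elec_pos}
    times = np.zeros(n_out)
    snapshots = {}
    log: list[str] = []
    snap_steps = {int(round(t / sys.dt)): t for t in snapshot_times}

    def record(iout, st):
        times[iout] = st.t
        for name, p in elec_pos.items():
            traces[name][iout] = st.phi[p]

    def snap(st):
        shape = sys.field.shape
        out = {}
        for arr_name, vec, flat in (("Vm", st.Vm, sys.heart_flat),
                                    ("Ve", st.Ve, sys.heart_flat),
                                    ("V", st.phi, sys.cond_flat)):
            full = np.full(sys.field.labels.size, np.nan)
            full[flat] = vec
            out[arr_name] = full.reshape(shape)
        return out

    record(0, state)
    if 0 in snap_steps:
        snapshots[0.0] = snap(state)
    iout = 1
    for i in range(1, n_steps + 1):
        state = step(sys, state)
        newly = np.isnan(act) & (state.Vm >= thr)
        act[newly] = state.t
        if i % n_per_out == 0 and iout < n_out:
            record(iout, state)
            iout += 1
        if i in snap_steps:
            snapshots[snap_steps[i]] = snap(state)
        if progress and i % 2000 == 0:
            log.append(f"step {i}/{n_steps} t={state.t:.3f}s "
                       f"Vm range [{state.Vm.min()*1e3:.1f}, {state.Vm.max()*1e3:.1f}] mV")

    lab = sys.field.labels.ravel()[sys.heart_flat]
    activation = {}
    for l in HEART_LABELS:
        m = lab == int(l)
        region_act = act[m]
        activation[LABEL_TO_REGION[l]] = (float(np.nanmin(region_act))
                                          if m.any() and not np.all(np.isnan(region_act))
                                          else float("nan"))
    df = pd.DataFrame({"time_s": times, **traces})
    return SimulationResult(times=times, electrode_traces=df,
                            activation=activation, activation_nodes=act,
                            snapshots=snapshots, log=log)


# ---------------------------------------------------------------------------
# Conduction-velocity strips.

def make_strip_field(n: int, region: str = "Ventricles", dx: float = 5e-4) -> LabelField:
    """1D strip of ``n`` voxels of a single heart region (no passive domain)."""
    from .geometry import REGION_TO_LABEL

    lab = np.full((n, 1, 1), int(REGION_TO_LABEL[region]), dtype=np.int8)
    return LabelField(lab, origin=(0.0, -dx / 2, -dx / 2), dx=dx)


def conduction_velocity(region: str = "Ventricles", n: int = 80, dx: float = 5e-4,
                        dt: float = 2e-5, sigma_scale: float = 1.0,
                        sigma_i_scale: float = 1.0, duration: float = 0.08,
                        params: Mapping[str, CellParameters] | None = None) -> float:
    """Plane-wave conduction velocity (m/s) along a 1D strip.

    The strip is stimulated at one end; velocity is the probe-plane distance
    (at 30% and 70% of the strip) over the activation-time difference.
    ``sigma_scale`` multiplies both conductivities; ``sigma_i_scale`` only the
    intracellular one (``sigma_i_scale=0`` decouples the cells: no wave).
    Returns 0.0 if the wave fails to reach both probes.
    """
    params = dict(params or all_region_defaults())
    p = params[region].replace(
        sigma_e=params[region].sigma_e * sigma_scale,
        sigma_i=params[region].sigma_i * sigma_scale * sigma_i_scale)
    params[region] = p
    fld = make_strip_field(n, region, dx)
    # stimulated end: large/strong enough to out-drive the diffusive sink even
    # when conductivities are scaled up
    stim = TissueStimulus(center=(0.0, 0.0, 0.0), radius=max(4 * dx, 2e-3),
                          t_start=0.002, duration=0.002,
                          amplitude=(p.a + 0.6) * p.A / 0.002)
    sysm = assemble(fld, params=params, dt=dt,
                    ground=(n - 1, 0, 0), stimulus=stim)
    res = simulate(sysm, duration, output_interval=dt)
    i1, i2 = int(0.3 * n), int(0.7 * n)
    t1, t2 = res.activation_nodes[i1], res.activation_nodes[i2]
    if not (np.isfinite(t1) and np.isfinite(t2)) or t2 <= t1:
        return 0.0
    return (i2 - i1) * dx / (t2 - t1)
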