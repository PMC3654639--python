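"""Region-specific membrane kinetics of the heterogeneous whole-heart model.

Every region of the heart (sinoatrial node, atria, atrioventricular node,
His bundle, bundle branches, Purkinje fibers, ventricular myocardium) is
described by the same two-variable modified FitzHugh-Nagumo system, with a
per-region parameter column: a cubic excitation current in the transmembrane
potential ``Vm`` plus a linear recovery variable ``u``,

    iion  = k*c1*(Vm - B) * (a - v) * (1 - v) + k*c2*u * g(Vm)
    du/dt = k*e * (v - d*u - b),            v = (Vm - B) / A

where ``g(Vm) = 1`` in the sinoatrial node and ``g(Vm) = Vm - B`` everywhere
else, ``B`` is the resting potential, ``A`` the action-potential amplitude and
``B + a*A`` the excitation threshold.  The transmembrane potential obeys
``dVm/dt = -iion`` in the space-clamped (single-cell) limit; in tissue the
bidomain diffusion terms are added by :mod:`torsoecg.solver`.

The sinoatrial column has ``a < 0`` and ``b < 0``: its rest state is not an
equilibrium and the cell is a relaxation oscillator (the pacemaker).  All
potentials are carried in volts internally; CSV output is in mV.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "REGIONS",
    "CellParameters",
    "CellState",
    "CellTrace",
    "Stimulus",
    "region_defaults",
    "all_region_defaults",
    "initial_state",
    "iion",
    "du_dt",
    "cubic_roots",
    "default_stimulus",
    "integrate_cell",
    "action_potential_duration",
    "cycle_lengths",
]

#: Canonical region names, in activation order of a normal beat.
REGIONS = ("SAN", "Atria", "AVN", "His", "BNL", "Purkinje", "Ventricles")


@dataclass(frozen=True)
class CellParameters:
    """One region's kinetic constants and bidomain conductivities.

    Units: ``A``/``B`` volts, ``k`` 1/s, ``sigma_e``/``sigma_i`` S/m,
    ``a``/``b``/``d``/``e`` dimensionless, ``c1``/``c2`` in the model's
    current-scaling units (membrane capacitance times surface-to-volume
    ratio is taken as unity, so ``iion`` carries units of V/s).
    """

    region: str
    a: float
    b: float
    c1: float
    c2: float
    d: float
    e: float
    k: float
    A: float
    B: float
    sigma_e: float
    sigma_i: float

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError(f"amplitude A must be positive, got {self.A}")
        for name in ("k", "c1", "c2", "sigma_e", "sigma_i"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {getattr(self, name)}")

    @property
    def is_pacemaker(self) -> bool:
        """True for the SAN variant of the ionic current (recovery term k*c2*u)."""
        return self.region == "SAN"

    @property
    def threshold(self) -> float:
        """Excitation threshold B + a*A (V); the middle root of the cubic."""
        return self.B + self.a * self.A

    def replace(self, **kw) -> "CellParameters":
        return replace(self, **kw)


# Per-region parameter table (A, B in volts; sigma in S/m; k in 1/s).
_TABLE: Mapping[str, dict] = {
    "SAN": dict(a=-0.60, b=-0.30, c1=1000.0, c2=1.0, d=0.0, e=0.0660,
                A=0.033, B=-0.022, k=1000.0, sigma_e=0.0005, sigma_i=0.0005),
    "Atria": dict(a=0.13, b=0.0, c1=2.6, c2=1.0, d=1.0, e=0.0132,
                  A=0.140, B=-0.085, k=1000.0, sigma_e=0.008, sigma_i=0.008),
    "AVN": dict(a=0.13, b=0.0, c1=2.6, c2=1.0, d=1.0, e=0.0132,
                A=0.140, B=-0.085, k=1000.0, sigma_e=0.0005, sigma_i=0.0005),
    "His": dict(a=0.13, b=0.0, c1=2.6, c2=1.0, d=1.0, e=0.0050,
                A=0.140, B=-0.085, k=1000.0, sigma_e=0.010, sigma_i=0.010),
    "BNL": dict(a=0.13, b=0.0, c1=2.6, c2=1.0, d=1.0, e=0.0022,
                A=0.140, B=-0.085, k=1000.0, sigma_e=0.015, sigma_i=0.015),
    "Purkinje": dict(a=0.13, b=0.0, c1=2.6, c2=1.0, d=1.0, e=0.0047,
                     A=0.140, B=-0.085, k=1000.0, sigma_e=0.035, sigma_i=0.035),
    "Ventricles": dict(a=0.13, b=0.0, c1=2.6, c2=1.0, d=1.0, e=0.0060,
                       A=0.140, B=-0.085, k=1000.0, sigma_e=0.008, sigma_i=0.008),
}

# Initial conditions (V): the SAN starts depolarized relative to its own rest.
_INITIAL_VI = {"SAN": -0.060}
_DEFAULT_VI = -0.085


def region_defaults(region: str) -> CellParameters:
    """Return the tabulated parameter column for ``region``.

    Raises ``KeyError`` with the list of valid names for an unknown region.
    """
    try:
        row = _TABLE[region]
    except KeyError:
        raise KeyError(
            f"unknown region {region!r}; valid regions are {', '.join(REGIONS)}"
        ) from None
    return CellParameters(region=region, **row)


def all_region_defaults() -> dict[str, CellParameters]:
    return {r: region_defaults(r) for r in REGIONS}


@dataclass(frozen=True)
class CellState:
    """Pointwise state: intracellular/extracellular potentials (V) and recovery."""

    Vi: float
    Ve: float
    u: float

    @property
    def Vm(self) -> float:
        return self.Vi - self.Ve


def initial_state(region: str) -> CellState:
    """Tabulated initial conditions: Ve = 0, u = 0, Vi region-dependent."""
    region_defaults(region)  # validates the name
    return CellState(Vi=_INITIAL_VI.get(region, _DEFAULT_VI), Ve=0.0, u=0.0)


# ---------------------------------------------------------------------------
# Right-hand sides.  These accept scalars or ndarrays for Vm and u.

def iion(Vm, u, p: CellParameters):
    """Membrane ionic current (model units, acts as V/s on dVm/dt = -iion)."""
    v = (Vm - p.B) / p.A
    cubic = p.k * p.c1 * (Vm - p.B) * (p.a - v) * (1.0 - v)
    if p.is_pacemaker:
        return cubic + p.k * p.c2 * u
    return cubic + p.k * p.c2 * u * (Vm - p.B)


def du_dt(Vm, u, p: CellParameters):
    """Recovery-variable rate k*e*[(Vm-B)/A - d*u - b] (1/s)."""
    v = (Vm - p.B) / p.A
    return p.k * p.e * (v - p.d * u - p.b)


def iion_fields(Vm, u, a, b, c1, c2, k, A, B, pacemaker_mask):
    """Vectorized ionic current for per-node parameter arrays (tissue use)."""
    dV = Vm - B
    v = dV / A
    cubic = k * c1 * dV * (a - v) * (1.0 - v)
    rec = k * c2 * u * np.where(pacemaker_mask, 1.0, dV)
    return cubic + rec


def du_dt_fields(Vm, u, b, d, e, k, A, B):
    v = (Vm - B) / A
    return k * e * (v - d * u - b)


class DegenerateCubicError(ValueError):
    """Raised when c1 = 0 leaves no cubic in the ionic current."""


def cubic_roots(p: CellParameters) -> np.ndarray:
    """The three real Vm roots (V) of iion(Vm, u=0) = 0, ascending.

    The cubic is solved numerically in the normalized variable
    v = (Vm - B)/A; analytically the roots are {B, B + a*A, B + A}.
    """
    if p.c1 == 0:
        raise DegenerateCubicError(f"region {p.region}: c1 = 0, no cubic")
    # v*(a - v)*(1 - v) expanded: v^3 - (1+a) v^2 + a v
    roots_v = np.roots([1.0, -(1.0 + p.a), p.a, 0.0])
    roots_v = np.real(roots_v[np.abs(np.imag(roots_v)) < 1e-12])
    return np.sort(p.B + p.A * roots_v)


# ---------------------------------------------------------------------------
# Single-cell integration.

@dataclass(frozen=True)
class Stimulus:
    """Rectangular current pulse added to dVm/dt (amplitude in V/s)."""

    t_start: float
    duration: float
    amplitude: float

    def current(self, t: float) -> float:
        return self.amplitude if self.t_start <= t < self.t_start + self.duration else 0.0


def default_stimulus(p: CellParameters, t_start: float = 0.010,
                     duration: float = 0.001) -> Stimulus:
    """1 ms pulse sized to lift Vm from rest to just above the threshold B + a*A."""
    lift = (p.a + 0.15) * p.A  # small margin above the threshold
    return Stimulus(t_start=t_start, duration=duration, amplitude=lift / duration)


@dataclass
class CellTrace:
    """Uniformly sampled single-cell trajectory (t in s, Vm in V)."""

    t: np.ndarray
    Vm: np.ndarray
    u: np.ndarray

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_s": self.t, "Vm_mV": self.Vm * 1e3, "u": self.u}
                     ).to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "CellTrace":
        import pandas as pd

        df = pd.read_csv(path)
        return CellTrace(t=df["time_s"].to_numpy(),
                         Vm=df["Vm_mV"].to_numpy() * 1e-3,
                         u=df["u"].to_numpy())


class BlowUpError(RuntimeError):
    pass


def _rhs(t, y, p: CellParameters, stim: Stimulus | None):
    Vm, u = y
    dv = -iion(Vm, u, p)
    if stim is not None:
        dv += stim.current(t)
    return (dv, du_dt(Vm, u, p))


def integrate_cell(p: CellParameters, duration: float, dt: float = 1e-4,
                   stimulus: Stimulus | None = None, method: str = "auto",
                   initial: CellState | None = None) -> CellTrace:
    """Integrate the space-clamped cell and return a uniformly sampled trace.

    ``method`` is ``"rk4"`` (fixed step ``dt``), ``"lsoda"`` (adaptive,
    stiff-capable, resampled onto the ``dt`` grid), or ``"auto"`` which picks
    LSODA when the excitation coefficient makes the kinetics stiff at the
    requested step (the pacemaker column has c1 ~ 400x the myocardial value)
    and RK4 otherwise.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be at least one step")
    if initial is None:
        initial = initial_state(p.region)

    n = int(round(duration / dt))
    t = np.arange(n + 1) * dt
    if method == "auto":
        # crude stiffness estimate: |d iion/dVm| can reach ~10*k*c1*A near the
        # excursion edges; explicit RK4 needs dt below ~2.8/lambda.
        lam = 10.0 * p.k * p.c1 * p.A
        method = "lsoda" if lam * dt > 2.0 else "rk4"

    if method == "lsoda":
        from scipy.integrate import solve_ivp

        sol = solve_ivp(_rhs, (0.0, t[-1]), [initial.Vm, initial.u],
                        t_eval=t, args=(p, stimulus), method="LSODA",
                        rtol=1e-8, atol=1e-10, max_step=5e-3)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise BlowUpError(f"LSODA failed for {p.region}: {sol.message}")
        return CellTrace(t=t, Vm=sol.y[0], u=sol.y[1])

    if method != "rk4":
        raise ValueError(f"unknown method {method!r}")

    Vm = np.empty(n + 1)
    u = np.empty(n + 1)
    Vm[0], u[0] = initial.Vm, initial.u
    y = np.array([initial.Vm, initial.u])
    for i in range(n):
        ti = t[i]
        k1 = np.asarray(_rhs(ti, y, p, stimulus))
        k2 = np.asarray(_rhs(ti + dt / 2, y + dt / 2 * k1, p, stimulus))
        k3 = np.asarray(_rhs(ti + dt / 2, y + dt / 2 * k2, p, stimulus))
        k4 = np.asarray(_rhs(ti + dt, y + dt * k3, p, stimulus))
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise BlowUpError(
                f"state blew up at t={ti + dt:.6f}s for {p.region}: Vm={y[0]}, u={y[1]}")
        Vm[i + 1], u[i + 1] = y
    return CellTrace(t=t, Vm=Vm, u=u)


# ---------------------------------------------------------------------------
# Trace analysis helpers.

def action_potential_duration(trace: CellTrace, p: CellParameters,
                              level: float = 0.9) -> float:
    """APD at ``level`` repolarization: time above B + (1-level)*(peak - B).

    Measured from the upstroke crossing of the threshold to the downstroke
    crossing of the repolarization level.  Returns nan if no AP occurred.
    """
    peak = trace.Vm.max()
    if peak < p.threshold:
        return float("nan")
    repol = p.B + (1.0 - level) * (peak - p.B)
    above_thr = trace.Vm >= p.threshold
    idx_up = int(np.argmax(above_thr))
    after = trace.Vm[idx_up:]
    below = after <= repol
    if not below.any():
        return float("nan")
    idx_down = idx_up + int(np.argmax(below))
    return trace.t[idx_down] - trace.t[idx_up]


def cycle_lengths(trace: CellTrace, p: CellParameters,
                  frac: float = 0.75) -> np.ndarray:
    """Intervals between successive upward crossings of B + frac*A (s)."""
    thr = p.B + frac * p.A
    above = trace.Vm >= thr
    ups = np.flatnonzero(~above[:-1] & above[1:])
    return np.diff(trace.t[ups + 1])
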