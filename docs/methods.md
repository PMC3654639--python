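# Model and methods

`torsoecg` simulates whole-heart electrical activity inside a passive torso
and derives the body-surface electrocardiogram.  This note records the
governing model, the numerical scheme, the geometry design, the parameter
conventions, and the known limitations.

## Governing equations

The heart is a bidomain continuum with intracellular potential `Vi`,
extracellular potential `Ve`, transmembrane potential `Vm = Vi - Ve`, and a
recovery variable `u`:

    dVm/dt = -i_ion + div(sigma_i grad Vi)              (heart)
    div(sigma_i grad Vi) + div(sigma_e grad Ve) = 0     (heart)
    div(sigma_o grad V) = 0                             (torso, lungs, blood)

with modified FitzHugh–Nagumo kinetics per region (`v = (Vm - B)/A`):

    i_ion = k c1 (Vm - B)(a - v)(1 - v) + k c2 u g(Vm)
    du/dt = k e (v - d u - b)

where `g = 1` in the sinoatrial node (SAN) and `g = Vm - B` elsewhere.
Membrane capacitance times surface-to-volume ratio is taken as unity, so
`i_ion` carries units of V/s; all potentials are stored in volts internally
and reported in mV.  The printed grouping "(Vm-B)A" in the source equations
is read as `(Vm-B)/A`: only the division makes the bracket terms
dimensionless and places the cubic's roots at `B`, `B + aA`, `B + A`
(`B + aA` is the excitation threshold, `A` the AP amplitude).  `ke` is the
product of the separately tabulated `k` and `e`.

Region parameters are the tabulated seven columns (SAN, atria, AV node, His
bundle, bundle branches, Purkinje, ventricles).  Two columns matter most:
the SAN has `a < 0, b < 0` (no rest state: a relaxation oscillator with a
~0.84 s cycle in the space-clamped limit) and `c1 = 1000` versus 2.6
elsewhere; `e` sets the APD per region (larger `e`, shorter APD).  Initial
conditions: `Vi = -60 mV` (SAN) / `-85 mV` (elsewhere), `Ve = u = 0`.

Boundary conditions: the torso exterior is insulating; `Vi` has zero flux at
the heart surface; `V = Ve` with extracellular flux continuity at the
heart–torso interface; the right-leg electrode node is pinned to exactly
0 V (the reference for every other potential).

## Numerics

**Discretization.** 7-point finite volumes on a regular voxel grid with
harmonic face-averaged conductivities.  The two interface conditions at the
heart surface are enforced implicitly by assembling one composite elliptic
operator over heart + passive nodes (`sigma_e` inside, `sigma_o` outside):
they are exactly the transmission conditions of a composite-conductivity
Poisson problem.

**Time stepping** (default `dt` = 0.05 ms, the coarse fixture uses 0.1 ms):
operator splitting per step —

1. *Reaction* (explicit): `(Vm, u)` advanced per node by sub-cycled Heun
   steps.  The SAN's `c1 = 1000` makes its reaction Jacobian as large as
   ~5e6 s⁻¹, far beyond any practical global step, so the sub-cycle count is
   chosen per node from a closed-form Jacobian bound at the node's current
   state (documented in `solver.py`; deliberately simple so an independent
   scalar implementation reproduces it).  Only pacemaker nodes ever need
   more than ~2 sub-steps.  A numba kernel executes the loop when numba is
   importable; a pure-numpy path computes identical results.
2. *Intracellular diffusion* (implicit Euler): solve
   `(I - dt L_i) Vi = Vm* + Ve` with the zero-flux `sigma_i` Laplacian.
3. *Elliptic solve*: `-L_sigma phi = L_i Vi` over all conducting nodes with
   the ground row/column eliminated symmetrically; `phi` is `Ve` on heart
   nodes and `V` on passive nodes.

Both sparse operators are constant, so they are LU-factorized once
(SuperLU) and each step costs two triangular solves; above 200k nodes the
solver switches to Jacobi-preconditioned conjugate gradients (relative
residual 1e-8, warm-started).  Single-cell integration uses fixed-step RK4
(`dt` = 0.1 ms) for quiescent regions and LSODA for the stiff SAN column;
the "auto" method picks by a stiffness estimate.

**Infarcts** zero the rate constant `k` and `sigma_i` inside the lesion and
set `Vi = -60 mV`, `Ve = -20 mV` there initially.  A node with `sigma_i = 0`
and `k = 0` holds its `Vi` automatically (its implicit-diffusion row is the
identity and its kinetics are frozen) while its `Ve` still participates in
the passive pathway — the infarcted wall is electrically silent but still
conducts extracellularly.

**Activation times** are the first upward crossing of `Vm` through
`B + 0.75 A` per node; the fraction 0.75 is robust to boundary smoothing.

## Geometry

The torso and lungs are elliptic cylinders; the heart is a spherical shell
(atrial cap above the AV plane, ventricular shell below, blood inside, a
ventricular septum slab) inside a cavity in the lung region.  A passive
isolation gap separates atria from ventricles except at the septal
junction.  Default dimensions (torso 0.35 × 0.25 × 0.60 m, heart outer
radius 6 cm, walls 12 mm, dx = 4 mm) approximate an adult torso; everything
is configurable, and a coarse fixture (torso within 24 voxels per axis,
dx = 6 mm) runs a full beat in about a minute.

The conduction system needed genuine design work.  At tabulated
conductivities a voxel grid suffers severe source–sink mismatch at every
transition from low- to high-conductivity tissue: a small patch of
0.5 mS/m tissue simply cannot charge an 8 mS/m neighbourhood through
harmonic-mean face couplings, and nothing short of a broad wavefront can
ignite the tightly coupled endocardial Purkinje sheet (internal coupling
`sigma/dx^2` ≈ 970 s⁻¹).  Excitation at voxel scale can step *down* in
conductivity but not *up*.  The geometry therefore encodes the same
solutions evolution found:

* **SAN exit pocket** — the SAN patch carries a one-voxel atrial pocket
  notched into its epicardial half; pocket voxels see SAN tissue on several
  faces at once and relay the excitation to the atrial wall each cycle
  (the real node's exit pathways and transitional cells play this role).
* **AVN block with embedded His** — the AV node is a two-layer block at the
  base of the atrial septum, excited directly by the surrounding atrial
  wall; the slow charging of the low-conductivity node tissue produces the
  AV delay.  The His bundle is a single-voxel column wrapped on five faces
  by the AVN block, crossing the isolation gap.
* **Free-running bundle** — from the His bundle a bridge crosses the gap
  blood to a column clear of the septum which descends through the
  ventricular cavity without touching myocardium (as the moderator band
  does).  A two-voxel Purkinje segment inside the column is the
  bundle-to-fiber transition; because nothing but blood borders the column,
  the Purkinje region is guaranteed to activate before any working
  myocardium.  The column ends on an ordinary-myocardium voxel at the apex,
  and the broad myocardial wavefront then recruits the endocardial Purkinje
  sheet from behind.

With these elements the coarse fixture reproduces the full physiological
first-activation order SAN → atria → AVN → His → bundle → Purkinje →
ventricles (0, 18, 53, 79, 98, 107, 121 ms on the fixture) with a clear
AV delay, spontaneously and periodically.

`validate_geometry` checks label presence, the face-adjacency of each
conduction-chain link, the absence of any direct atria–ventricle contact,
and connectedness (strict for the compact conduction structures; the bundle
may be two segments around its fiber transition; component counts of the
bulk regions are informational).

## Leads and features

Electrodes are points snapped to the nearest torso-surface voxel; default
fractional positions put the limb electrodes at the torso corners, V1–V6
on an anterior arc at heart height, and the Frank seven (A, C, E, I
laterally/anteriorly, M posterior, H near the neck, F low on the left).
Derived channels follow the standard lead calculus: Einthoven differences,
Goldberger augmented leads, Wilson central terminal for the precordials,
the Frank coefficient matrix for X/Y/Z (each row sums to zero, so the
orthogonal leads reject common-mode offsets), and the RMS/SAECG curves.

Fiducial detection locates the QRS by slope energy (a moving RMS of dV/dt)
rather than amplitude — in this model the T dome can exceed the R wave —
then takes R as the dominant deflection near the energy burst, QRS bounds
where |dV/dt| stays below 10% of the beat's maximum, P and T as dominant
extrema before/after, and the baseline as the median of the P–Q segment.
The ST level is the baseline-subtracted trace at J + 40 ms.  Infarct
comparisons are by sign and ordering only, never magnitude.

## What the coarse fixture does and does not show

The tiny fixture exercises every code path: spontaneous pacemaking, the
complete conduction chain, volume conduction, all derived leads, and the
infarct experiments.  Its beat is morphologically a real PQRST (the
fixture's 2:1 SAN–atrial capture simply sets a slower effective heart
rate), but with 2–3 voxel walls the repolarization wave is coarse: the T
dome is large relative to the QRS, and absolute intervals follow the
tabulated rate constants rather than any clinically calibrated timing.
Passing tests establish the model's mechanisms and orderings, not clinical
waveform fidelity.

Measured on the fixture, the apical infarcts reproduce the lead II
signature (both infarcts depress the ST segment, the anterior one more
deeply: +0.219 vs +0.223 vs +0.286 mV for anterior/inferior/normal) and
the anterior infarct's relative ST elevation in V1.  The inferior infarct's
relative V1 *depression* is **not** reproduced: with `sigma_i = 0` and
`k = 0` the lesion carries no diastolic injury current at all (run
differences vanish outside the beat), so all ST displacement comes from the
missing contribution of the infarcted wall — and in an upright spherical
heart both apical lesions subtend nearly the same solid angle from V1
(their ST difference there is ~0.001 mV).  Discriminating them requires an
anatomically tilted heart axis, which the voxelized face-coupled conduction
chain cannot support at this resolution.  The corresponding acceptance test
is left failing deliberately.

## Known limitations

* Isotropic conductivities; no fiber architecture.
* Upright spherical heart: no anatomical tilt, hence the V1 limitation
  above; body-surface potential maps are out of scope.
* The conduction-chain ignition margins are established empirically at the
  default and fixture resolutions; radically different voxel sizes may need
  the junction dimensions re-checked with `validate_geometry` plus a test
  beat.
* No restitution/rate-dependence beyond what the kinetics imply; no
  inverse problem.
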