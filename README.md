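# torsoecg

A simplified three-dimensional bidomain simulator of whole-heart electrical
activity inside a human torso, with derivation of the complete 12-lead ECG,
the Frank-lead vectorcardiogram, RMS/SAECG curves, and ST-segment analysis
of myocardial infarction.

The package is for computational electrophysiologists and ECG-methods
researchers who want a desk-scale forward model: adjust cell, tissue or
whole-heart properties — place an ischemic lesion, slow a conduction-system
segment, stretch an action potential — and see the effect on the surface
ECG within minutes, without anatomical meshes or dedicated solvers.

## Model

The heart is a seven-region bidomain continuum (sinoatrial node, atria,
atrioventricular node, His bundle, bundle branches, Purkinje fibers,
ventricular myocardium) embedded, together with blood chambers and lungs,
in a passive torso volume conductor:

    ∂Vm/∂t = −i_ion + ∇·(σᵢ ∇Vᵢ)                    heart
    ∇·(σᵢ ∇Vᵢ) + ∇·(σₑ ∇Vₑ) = 0                     heart
    ∇·(σₒ ∇V) = 0                                   torso, lungs, blood

with `Vm = Vᵢ − Vₑ` and modified FitzHugh–Nagumo kinetics per region
(`v = (Vm − B)/A`):

    i_ion = k c₁ (Vm − B)(a − v)(1 − v) + k c₂ u g(Vm)
    du/dt = k e (v − d u − b)

where `g = 1` in the SAN and `g = Vm − B` elsewhere.  The SAN column
(`a < 0`, `b < 0`) has no rest state and paces the heart spontaneously; a
specialized conduction chain with an electrically isolated atrioventricular
junction carries each beat to the ventricles.  Surface electrodes yield the
Einthoven, Goldberger-augmented, Wilson precordial and Frank X/Y/Z leads by
the standard lead calculus.  Infarcts are modelled by zeroing the rate
constant and intracellular conductivity inside an apical lesion.  See
`docs/methods.md` for the numerics and the voxel anatomy.

## Worked example

One spontaneous beat on the coarse built-in fixture
(`examples/simulate_tiny_ecg.py`):

```python
import dataclasses
from torsoecg.config import make_fixture, run

cfg = make_fixture("tiny-3d")
cfg.solver = dataclasses.replace(cfg.solver, duration=0.6)
result, leads = run(cfg)
print(result.activation)
```

prints the first-activation times of the conduction chain (seconds):

    {'SAN': 0.0002, 'Atria': 0.0175, 'AVN': 0.0533, 'His': 0.0792,
     'BNL': 0.0980, 'Purkinje': 0.1072, 'Ventricles': 0.1205}

— the physiological order SAN → atria → AV node → His → bundle branches →
Purkinje → ventricles, with the AV node holding the wavefront for tens of
milliseconds while the atria finish activating.  `leads["lead_II"]` is the
familiar PQRST (range −1.0 … +1.4 mV on this fixture) and `leads["VGND"]`
is identically zero: the right-leg electrode is the grounded reference.

The infarct experiment (`examples/infarct_st_comparison.py`) runs the
normal heart plus apical anterior and inferior infarcts and measures the
ST level (J + 40 ms minus the PQ baseline) per lead; on lead II it prints

    lead_II ST levels (mV):
      normal        +0.286   shift vs normal  +0.000
      anterior-MI   +0.219   shift vs normal  -0.067
      inferior-MI   +0.223   shift vs normal  -0.063

— both infarcts depress the ST segment and the anterior infarct depresses
it more deeply, the electrocardiographic signature used clinically.

Other entry points: `torsoecg.cells.integrate_cell` (single-cell APs),
`torsoecg.solver.conduction_velocity` (1D strips),
`torsoecg.features.detect_fiducials` / `st_level` (trace analysis), and a
thin CLI (`torsoecg simulate|leads|features|single-cell|fixture|validate`)
for shell use; `examples/` holds one narrative script per capability.

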