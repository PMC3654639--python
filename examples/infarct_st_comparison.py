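"""ST-segment displacement of apical anterior and inferior infarcts.

Simulates one beat on the coarse torso fixture for the normal heart and for
two transmural apical infarcts (rate constant and intracellular conductivity
zeroed inside the lesion, so the infarcted wall never activates).  Measures
the ST level (trace at J + 40 ms minus the PQ baseline) on leads II and V1
and prints the shift of each infarct against the normal heart: both
infarcts depress the ST segment in lead II, the anterior one more deeply.
Runtime: several minutes (three full simulations).
"""

import dataclasses

from torsoecg.config import make_fixture, run
from torsoecg.features import compare_st

runs = {}
for name, lesions in [("normal", []), ("anterior-MI", ["anterior-MI"]),
                      ("inferior-MI", ["inferior-MI"])]:
    cfg = make_fixture("tiny-3d")
    cfg.solver = dataclasses.replace(cfg.solver, duration=0.8)
    cfg.lesions = lesions
    print(f"simulating {name} ...", flush=True)
    _, leads = run(cfg)
    runs[name] = leads

for lead in ("lead_II", "lead_V1"):
    rep = compare_st(runs, lead)
    print(f"\n{lead} ST levels (mV):")
    for name, level in rep["levels"].items():
        shift = rep["shift_vs_normal"][name]
        print(f"  {name:<12} {level:+7.3f}   shift vs normal {shift:+7.3f}")

print("\nNegative shift = ST depression, positive = elevation, relative to")
print("the normal heart's own ST level on that lead.")
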