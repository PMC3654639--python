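import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_cfg():
    from torsoecg.config import make_fixture

    return make_fixture("tiny-3d")


@pytest.fixture(scope="session")
def tiny_field(tiny_cfg):
    from torsoecg.geometry import build_default_geometry

    return build_default_geometry(tiny_cfg.geometry)


@pytest.fixture(scope="session")
def normal_run(tiny_cfg):
    """One full simulated heartbeat cycle on the tiny fixture (shared)."""
    import dataclasses

    from torsoecg.config import run

    cfg = dataclasses.replace(tiny_cfg)
    cfg.solver = dataclasses.replace(cfg.solver, duration=_NORMAL_DURATION)
    result, lead_traces = run(cfg)
    return result, lead_traces


_NORMAL_DURATION = 0.8  # covers one full PQRST cycle on the tiny fixture


@pytest.fixture(scope="session")
def mi_runs(tiny_cfg, normal_run):
    """Lead traces for normal, anterior-MI and inferior-MI tiny runs."""
    import dataclasses

    from torsoecg.config import run

    out = {"normal": normal_run[1]}
    for name in ("anterior-MI", "inferior-MI"):
        cfg = dataclasses.replace(tiny_cfg)
        cfg.solver = dataclasses.replace(cfg.solver, duration=_NORMAL_DURATION)
        cfg.lesions = [name]
        _, lt = run(cfg)
        out[name] = lt
    return out
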