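"""Shared phantom fixtures.

Heavy phantoms and cohort experiments are session-scoped so the whole
suite pays for each of them once.
"""

import numpy as np
import pytest

import tubulometry as tm


@pytest.fixture(scope="session")
def cylinder():
    """Axis-aligned straight cylinder: r = 5 μm, L = 100 μm, spacing 1 μm."""
    cp = np.column_stack([np.zeros(11), np.zeros(11), np.linspace(0, 100, 11)])
    spec = tm.TubePhantomSpec(control_points=cp, tp_arc_length=50.0)
    lumen, truth = tm.synth_tube(spec)
    return lumen, truth


@pytest.fixture(scope="session")
def oblique_cylinder():
    """Same cylinder rotated 45° to the grid (axis along y=x)."""
    d = np.array([0.0, 1.0, 1.0]) / np.sqrt(2)
    cp = np.linspace(0, 100, 11)[:, None] * d
    spec = tm.TubePhantomSpec(control_points=cp, tp_arc_length=50.0)
    lumen, truth = tm.synth_tube(spec)
    return lumen, truth


@pytest.fixture(scope="session")
def hairpin():
    """Default hairpin phantom (neck 100 μm, tail 300 μm) with its truth."""
    lumen, truth = tm.synth_tube(tm.TubePhantomSpec(seed=3))
    return lumen, truth


@pytest.fixture(scope="session")
def hairpin_profiled(hairpin):
    lumen, truth = hairpin
    centerline, profile, summary = tm.profile_tubule(lumen, specimen_id="hp", group="control")
    return lumen, truth, centerline, profile, summary


@pytest.fixture(scope="session")
def recovery_cohort():
    """8 treated (radius ×1.75, 5% jitter) vs 4 control hairpin phantoms."""
    return tm.run_phantom_cohort(seed=0)


@pytest.fixture(scope="session")
def localization_result():
    """Cohort with the treated radius scaled only on s ∈ [−75, 175] μm."""
    return tm.run_localization_experiment(seed=0)
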