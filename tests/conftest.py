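import numpy as np
import pytest

import ddm


def build_cohort(pairs):
    """Cohort from [(time, event), ...] pairs; no design attached."""
    times = np.array([t for t, _ in pairs], dtype=float)
    events = np.array([e for _, e in pairs], dtype=bool)
    return ddm.Cohort(times, events)


@pytest.fixture(scope="session")
def reference_cohort():
    return ddm.make_reference_fixture()


@pytest.fixture(scope="session")
def reference_curve(reference_cohort):
    return ddm.kaplan_meier(reference_cohort)


@pytest.fixture(scope="session")
def lognormal_cohort_10k():
    """10k draws from the fitted log-normal, administratively censored at 24.

    The observation floor is set negligibly small so the latent draws are
    exactly log-normal — the right data-generating process for
    self-consistency checks of model fitting and selection.
    """
    design = ddm.StudyDesign(10_000, censor_horizon=24.0,
                             duration_floor=1e-9, seed=20240901)
    return ddm.generate_cohort(design, ddm.GeneratorSpec.lognormal(1.15, 1.14))
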