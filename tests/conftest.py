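import numpy as np
import pytest

from neurogaze.montage import make_montage
from neurogaze.synth import CohortSpec, make_cohort


@pytest.fixture(scope="session")
def montage64():
    return make_montage(64)


@pytest.fixture(scope="session")
def default_cohort():
    return make_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def study_results():
    """Twenty independent end-to-end study runs on the default cohort.

    Shared by the direction-suite and control-fidelity tests (both summarize
    the same set of runs).
    """
    import logging
    from neurogaze.pipeline import run_study, StudyConfig, check_directions

    logging.disable(logging.WARNING)
    results = []
    for seed in range(1, 21):
        report = run_study(StudyConfig(seed=seed))
        results.append({
            "directions": check_directions(report),
            "controls": report.controls,
            "dfa": report.dfa_summary,
            "iaf": report.iaf,
        })
    logging.disable(logging.NOTSET)
    return results


def tone(freq, fs, duration_s, amplitude=1.0, phase=0.0):
    t = np.arange(int(duration_s * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t + phase)
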