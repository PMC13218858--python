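import dataclasses

import numpy as np
import pytest

import physio
from physio.features import extract_feature_matrix_from_cohort


@pytest.fixture(scope="session")
def profiles():
    return physio.default_profiles()


@pytest.fixture(scope="session")
def small_cohort(profiles):
    """Six-participant, 120 s cohort shared by extraction-level tests."""
    play, watch = profiles
    return physio.simulate_cohort(play, watch, 3, 120.0, seed=11)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return extract_feature_matrix_from_cohort(small_cohort)


@pytest.fixture(scope="session")
def clean_recording(profiles):
    """One 300 s GamePlay-like recording with moderate RR jitter."""
    play, _ = profiles
    prof = dataclasses.replace(play, rr_within_sd=0.05)
    return physio.generate_recording(prof, 300.0, seed=5)


def match_beats(detected: np.ndarray, truth: np.ndarray,
                tol_s: float = 0.05) -> tuple[int, int, int]:
    """Greedy one-to-one matching; returns (tp, n_truth, n_detected)."""
    used = np.zeros(len(detected), bool)
    tp = 0
    for g in truth:
        if len(detected) == 0:
            break
        i = int(np.argmin(np.abs(detected - g)))
        if abs(detected[i] - g) <= tol_s and not used[i]:
            used[i] = True
            tp += 1
    return tp, len(truth), len(detected)
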