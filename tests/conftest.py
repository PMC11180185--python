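import itertools

import numpy as np
import pandas as pd
import pytest

import ordsustain as osn


@pytest.fixture
def tiny_regions():
    return ["A", "B"]


@pytest.fixture
def small_cube():
    """Random 5-subject, 3-region, 2-level probability cube (seeded)."""
    rng = np.random.default_rng(42)
    prob = rng.random((5, 3, 3))
    prob /= prob.sum(axis=2, keepdims=True)
    return osn.ScoreProbabilityCube(prob, [f"s{i}" for i in range(5)], ["A", "B", "C"], 0.5)


@pytest.fixture
def two_subtype_cohort():
    """Well-separated two-subtype cohort at the study noise level."""
    seqs, fractions = osn.preset_two_subtypes()
    table, truth = osn.simulate_cohort(
        seqs, fractions, n_subjects=250, noise_sd=0.5, missing_rate=0.1, seed=7
    )
    return table, truth


def all_valid_sequences(regions, max_level):
    """Exhaustive enumeration of valid orderings (independent of the
    package's samplers): filter all permutations of the event set."""
    events = [(r, z) for r in regions for z in range(1, max_level + 1)]
    out = []
    for perm in itertools.permutations(events):
        ok = True
        for r in regions:
            levels = [z for rr, z in perm if rr == r]
            if levels != sorted(levels):
                ok = False
                break
        if ok:
            out.append(perm)
    return out


@pytest.fixture
def synthetic_assignments():
    """Assignment-like frame with known subtype/stage structure for the
    characterisation statistics (no model fit required)."""
    rng = np.random.default_rng(3)
    n = 400
    subtype = rng.integers(1, 3, n)
    stage = rng.integers(1, 41, n)
    frame = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "subtype": subtype,
            "stage": stage,
            "max_posterior": 0.95,
            "included": True,
            "reason": "",
        }
    )
    covs = pd.DataFrame(
        {
            "subject_id": frame["subject_id"],
            "age_at_death": rng.normal(82, 7, n).round(),
            "sex": rng.choice(["F", "M"], n),
        }
    ).set_index("subject_id")
    return frame, covs
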