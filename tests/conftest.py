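import numpy as np
import pandas as pd
import pytest

from dietbiome.synthetic import SimulationParams, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared across read-only tests."""
    return generate_cohort(SimulationParams(n_subjects=80, seed=11))


@pytest.fixture(scope="session")
def joined_small(small_cohort):
    """Cohort covariates + diet scores + cMetS joined on subject."""
    from dietbiome.clinical import cmets
    from dietbiome.diet import score_all

    c = small_cohort
    scores = score_all(c.intakes, c.cohort["sex"])
    cm = cmets(c.cohort)
    df = (c.cohort.merge(scores, on="subject_id")
          .merge(cm[["subject_id", "cmets"]], on="subject_id")
          .merge(c.intakes[["subject_id", "energy_kcal"]], on="subject_id"))
    return df


def bh_step_up_oracle(pvalues):
    """Brute-force Benjamini-Hochberg step-up: sort, scale by m/rank,
    enforce monotonicity from the largest rank down, cap at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


@pytest.fixture(scope="session")
def bh_oracle():
    return bh_step_up_oracle
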