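"""Shared fixtures: reference parameters and synthetic cohorts.

The heavier objects (simulated cohorts and their diffusion-model fits) are
session-scoped so the acceptance-style checks and the module tests share
one computation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from ansddm.chi2fit import FitConfig, fit_participant
from ansddm.ddm import DiffusionParams
from ansddm.io import collapse_conditions, frame_to_groups
from ansddm.simulate import CohortSpec, generate_cohort
from ansddm.weber import fit_weber

#: Cohort reference values (mean of each parameter across participants).
TABLE_MEANS = dict(a=0.093, s_Z=0.023, v_S=1.163, eta=0.167,
                   T_ER=0.414, s_T=0.219, p_O=0.004)


@pytest.fixture(scope="session")
def table_params() -> DiffusionParams:
    return DiffusionParams(**TABLE_MEANS)


@pytest.fixture(scope="session")
def cohort20():
    """Heterogeneous 20-participant cohort, 768 trials each (seed 11)."""
    return generate_cohort(CohortSpec(n_participants=20), seed=11)


@pytest.fixture(scope="session")
def cohort20_groups(cohort20):
    return frame_to_groups(cohort20[0])


@pytest.fixture(scope="session")
def cohort20_weber(cohort20_groups):
    """log(w) and accuracy per participant of the shared cohort."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pid, recs in cohort20_groups.items():
            fit = fit_weber(collapse_conditions(recs))
            acc = float(np.mean([t.correct for t in recs]))
            out[pid] = (fit.w, acc)
    return out


@pytest.fixture(scope="session")
def cohort20_ddm(cohort20_groups):
    """Diffusion-model fits of the shared cohort (single heuristic start)."""
    cfg = FitConfig(restarts=1, seed=3)
    return {
        pid: fit_participant(collapse_conditions(recs), cfg)
        for pid, recs in sorted(cohort20_groups.items())
    }
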