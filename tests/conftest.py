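import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from deerquant.dipolar_model import DistanceAxis
from deerquant.inversion import fit_global
from deerquant.quantification import assign_states, fit_two_gaussians, populations
from deerquant.synthetic_data import (
    fixture_ground_truth,
    fixture_trace_specs,
    simulate_trace_set,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

N_SEEDS = 20


@pytest.fixture(scope="session")
def default_axis() -> DistanceAxis:
    return DistanceAxis(1.5, 9.0, 0.05)


@pytest.fixture(scope="session")
def population_recovery(default_axis):
    """Full simulate -> global-inversion -> quantification round trips.

    Twenty seeded four-trace replicates per ground-truth fixture; shared by
    the acceptance round-trip checks and the population-recovery property
    tests so the expensive global fits run once per session.
    """
    results = {}
    for fixture in ("exp19C", "exp40C"):
        truth = fixture_ground_truth(fixture, default_axis)
        entries = []
        for seed in range(1, N_SEEDS + 1):
            traces = simulate_trace_set(truth, fixture_trace_specs(seed))
            fit = fit_global(traces, default_axis)
            model = fit_two_gaussians(fit.distribution, seed=seed)
            pops = populations(model, assign_states(model))
            # operative uncertainty: fit covariance or the 1/10-of-p1
            # processing-spread heuristic, whichever is larger
            combined = max(pops.ci95_s, pops.p_ns / 10.0)
            entries.append(
                {
                    "seed": seed,
                    "p_s": pops.p_s,
                    "p_ns": pops.p_ns,
                    "ci95": pops.ci95_s,
                    "combined": combined,
                    "mu1": model.mu1,
                    "mu2": model.mu2,
                    "fit": fit if seed == 1 else None,
                }
            )
        results[fixture] = entries
    return results


@pytest.fixture(scope="session")
def truth_weights():
    return {"exp19C": {"NS": 0.43, "S": 0.57}, "exp40C": {"NS": 0.34, "S": 0.66}}
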