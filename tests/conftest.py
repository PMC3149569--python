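import numpy as np
import pytest

from erpic import (
    CohortParams,
    Deflection,
    SourceSpec,
    default_sources,
    simulate_cohort,
    standard_1020,
)


@pytest.fixture(scope="session")
def montage():
    return standard_1020()


def separated_sources(n=3):
    """Sources with well-separated peaks in both continue conditions.

    Used for ICA identifiability oracles, where temporally overlapping
    sources would confound the recovery check itself.
    """
    centers = ["Fz", "Pz", "C3", "O1", "T4", "F7", "P4", "Cz"][:n]
    specs = []
    for k in range(n):
        lat = 120.0 + 90.0 * k
        specs.append(
            SourceSpec(
                f"src{k}",
                centers[k],
                {
                    "go": (Deflection(+1 if k % 2 == 0 else -1, lat, 28.0, 5.0),),
                    "nogo": (Deflection(-1 if k % 2 == 0 else +1, lat + 45.0, 28.0, 4.0),),
                },
                dominant_conditions=frozenset({"go", "nogo"}),
            )
        )
    return specs


@pytest.fixture(scope="session")
def noiseless_cohort(montage):
    """Deterministic 3-source cohort with no noise or subject variability."""
    specs = separated_sources(3)
    params = CohortParams(
        n_per_group=4, n_sources=3, noise_sd=0.0,
        subject_latency_jitter_sd=0.0, subject_amplitude_sd=0.0, seed=11,
    )
    cohort, truth = simulate_cohort(params, specs, montage)
    return cohort, truth, specs


@pytest.fixture(scope="session")
def default_cohort(montage):
    """Small cohort drawn under the default study conditions."""
    specs = default_sources()
    params = CohortParams(n_per_group=15, seed=7)
    cohort, truth = simulate_cohort(params, specs, montage)
    return cohort, truth, specs


def pair_by_correlation(A, B):
    """Optimal one-to-one pairing of columns of A and B by max total |r|."""
    from scipy.optimize import linear_sum_assignment

    nA, nB = A.shape[1], B.shape[1]
    r = np.zeros((nA, nB))
    for i in range(nA):
        for j in range(nB):
            r[i, j] = np.corrcoef(A[:, i], B[:, j])[0, 1]
    rows, cols = linear_sum_assignment(-np.abs(r))
    return list(zip(rows, cols)), r
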