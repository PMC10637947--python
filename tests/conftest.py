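import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from sarcomsm.msm import DEFAULT_STRUCTURE, PanelDataset, TransitionStructure


@pytest.fixture(scope="session")
def reference_Q():
    from sarcomsm.reference import reference_intensity_matrix
    return reference_intensity_matrix()


@pytest.fixture
def two_state_structure():
    """Progressive 2-state chain with an absorbing end state."""
    return TransitionStructure(n_states=2, transitions=((1, 2),), absorbing=frozenset({2}))


@pytest.fixture
def toy_panel():
    """Three subjects with hand-countable intervals and one death."""
    df = pd.DataFrame({
        "subject_id": ["a", "a", "a", "b", "b", "c", "c", "c"],
        "time": [0.0, 2.0, 4.0, 0.0, 2.0, 0.0, 2.0, 3.0],
        "state": [1, 2, 1, 1, 1, 2, 3, 4],
        "death_exact": [False] * 7 + [True],
    })
    return PanelDataset.from_frame(df, structure=DEFAULT_STRUCTURE)


def random_generator_matrix(rng, n=4, absorbing=(4,), scale=0.5):
    """Random valid generator with the last state(s) absorbing."""
    Q = rng.uniform(0, scale, size=(n, n))
    for a in absorbing:
        Q[a - 1] = 0.0
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def uniformization_probability(Q, t, tol=1e-14, max_terms=1000):
    """Independent P(t) oracle: uniformized Poisson mixture of DTMC powers."""
    n = Q.shape[0]
    lam = max(-np.diag(Q).min(), 1e-12)
    A = np.eye(n) + Q / lam
    term = np.exp(-lam * t)          # Poisson weight at k = 0
    acc = term * np.eye(n)
    Ak = np.eye(n)
    for k in range(1, max_terms):
        Ak = Ak @ A
        term = term * lam * t / k
        acc = acc + term * Ak
        if term < tol and k > lam * t:
            break
    return acc


def brute_force_log_likelihood(params_Q, intervals, exact_death=False, absorbing=(4,)):
    """Reference panel log-likelihood: one expm per interval, plain loop."""
    total = 0.0
    for _, row in intervals.iterrows():
        P = expm(params_Q * row["dt"])
        r, s = int(row["from_state"]) - 1, int(row["to_state"]) - 1
        if exact_death and row["to_exact"] and int(row["to_state"]) in absorbing:
            transient = [i for i in range(params_Q.shape[0]) if i + 1 not in absorbing]
            dens = sum(P[r, j] * params_Q[j, s] for j in transient)
            total += np.log(dens)
        else:
            total += np.log(P[r, s])
    return total
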