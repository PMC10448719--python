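import numpy as np
import pytest
from hypothesis import settings

import msmuq

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def chain4():
    """Default 4-state metastable chain (stay 0.995)."""
    return msmuq.build_metastable_chain(4, 0.995)


@pytest.fixture(scope="session")
def chain2_fast():
    """2-state chain with stay probability 0.5 (fast mixing)."""
    return msmuq.build_metastable_chain(2, 0.5)


@pytest.fixture(scope="session")
def long_path(chain4):
    """A 1e6-step hidden path from the default chain."""
    return msmuq.sample_discrete_path(chain4, 10**6, 0, seed=7)


def brute_force_counts(dtrajs, tau):
    """Naive double-loop sliding-window transition counting (test oracle)."""
    n = max(int(np.max(d)) for d in dtrajs if len(d)) + 1
    C = np.zeros((n, n))
    for d in dtrajs:
        d = np.asarray(d)
        if len(d) <= tau:
            continue
        for t in range(len(d) - tau):
            C[d[t], d[t + tau]] += 1
    return C


def whitening_tica_oracle(C00, C0t_sym):
    """Dense whitening-based generalized eigensolver (test oracle).

    Computes C00^{-1/2} C0t C00^{-1/2} explicitly and diagonalizes it.
    """
    w, U = np.linalg.eigh(C00)
    inv_sqrt = U @ np.diag(1.0 / np.sqrt(w)) @ U.T
    M = inv_sqrt @ C0t_sym @ inv_sqrt
    evals = np.linalg.eigvalsh(M)
    return np.sort(evals)[::-1]
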