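import dataclasses

import numpy as np
import pytest

import ohcengage as oe


@pytest.fixture(scope="session")
def small_cohort():
    """A 250-user cohort from the packaged scenario (fixed seed)."""
    cfg = dataclasses.replace(oe.default_scenario(n_users=250), seed=2024)
    return oe.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_X(small_cohort):
    return small_cohort.engagement_matrix()


@pytest.fixture(scope="session")
def recovery_fit():
    """One n=1000 fit of the packaged scenario, shared by recovery checks."""
    cfg = oe.default_scenario(n_users=1000)
    cohort = oe.generate_cohort(cfg)
    X = cohort.engagement_matrix()
    est = oe.MarkovChainMixture(n_components=4, random_state=0).fit(X)
    return cfg, cohort, X, est


def match_labels(true_labels, pred_labels, K):
    """Optimal component-label matching by maximum agreement (Hungarian)."""
    from scipy.optimize import linear_sum_assignment

    conf = np.zeros((K, K))
    for t, p in zip(true_labels, pred_labels):
        conf[t, p] += 1
    rows, cols = linear_sum_assignment(-conf)
    return rows, cols, conf


def enumeration_loglik(engaged, A, b):
    """Exhaustive-path oracle for the sequence log-likelihood.

    Sums probability over all 3^(T-1) hidden-state paths: day 1 is state
    "high" and engaged with probability 1; each later day contributes a
    transition factor and a Bernoulli emission factor.
    """
    engaged = np.asarray(engaged, dtype=bool)
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    T = len(engaged)
    if not engaged[0]:
        return -np.inf
    if T == 1:
        return 0.0
    import itertools

    total = 0.0
    for path in itertools.product(range(3), repeat=T - 1):
        prob = 1.0
        prev = 0
        for t, s in enumerate(path, start=1):
            e = b[s] if engaged[t] else 1.0 - b[s]
            prob *= A[prev, s] * e
            prev = s
        total += prob
    return np.log(total) if total > 0 else -np.inf
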