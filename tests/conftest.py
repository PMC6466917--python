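"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities by enumeration or
naive arithmetic, independent of the package's vectorised code paths.
"""

import itertools
import math

import numpy as np
import pytest

from varpool import (
    AssaySpec,
    CovariateMatrix,
    GroupTestData,
    LOGIT,
    PoolAssignment,
)


@pytest.fixture(scope="session")
def assay95():
    return AssaySpec(0.95, 0.95)


@pytest.fixture(scope="session")
def assay_perfect():
    return AssaySpec(1.0, 1.0)


@pytest.fixture(scope="session")
def six_specimen_cohort():
    """Six specimens whose working risks under beta=(0,1) are exactly
    (0.30, 0.25, 0.20, 0.10, 0.05, 0.02)."""
    risks = np.array([0.30, 0.25, 0.20, 0.10, 0.05, 0.02])
    X = CovariateMatrix.from_raw(LOGIT.inverse(risks)[:, None],
                                 column_names=["x1"])
    return X, np.array([0.0, 1.0]), risks


@pytest.fixture(scope="session")
def three_pool_data():
    """Three pools of two with printed covariates, for likelihood checks."""
    x1 = np.array([0.5, 1.8, 2.2, 3.1, 0.2, 4.0])
    X = CovariateMatrix.from_raw(x1[:, None], column_names=["x1"])
    asn = PoolAssignment(np.arange(6), [2, 2, 2])
    z = np.array([1, 0, 1])
    return GroupTestData(asn, z, X)


def random_group_data(rng, n_groups=5, k_lo=1, k_hi=4, d=2):
    """A small random cohort with random pools and outcomes."""
    sizes = rng.integers(k_lo, k_hi + 1, n_groups)
    n = int(sizes.sum())
    raw = rng.normal(0.0, 1.5, (n, d - 1))
    X = CovariateMatrix.from_raw(raw)
    perm = rng.permutation(n)
    z = rng.integers(0, 2, n_groups)
    if z.min() == z.max():  # keep both outcomes present
        z[0] = 1 - z[0]
    return GroupTestData(PoolAssignment(perm, sizes), z, X)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def enumeration_log_likelihood(beta, data, assay, link=LOGIT):
    """Exhaustive-enumeration log-likelihood.

    Marginalises every pool's outcome probability over all 2^k member
    infection configurations.
    """
    beta = np.asarray(beta, float)
    se, sp = assay.sensitivity, assay.specificity
    ll = 0.0
    for l in range(data.assignment.m):
        rows = data.covariates.values[data.assignment.group_members(l)]
        p = link.evaluate(rows @ beta)
        p1 = 0.0
        for status in itertools.product((0, 1), repeat=len(p)):
            w = math.prod(pj if s else 1 - pj for pj, s in zip(p, status))
            p1 += w * (se if any(status) else 1 - sp)
        z = data.outcomes[l]
        ll += math.log(p1 if z == 1 else 1 - p1)
    return ll


def naive_pool_cost(beta, rows, assay, link=LOGIT):
    """Information cost by direct arithmetic (no shared code)."""
    p = link.evaluate(np.asarray(rows) @ np.asarray(beta, float))
    q = math.prod(1 - pj for pj in p)
    k = len(p)
    r = assay.sensitivity + assay.specificity - 1
    p1 = assay.sensitivity - r * q
    return p1 * (1 - p1) / (r**2 * k**2 * q**2)


def brute_force_psv_sizes(risks_sorted, assay, k_max, phi0=1.8414):
    """Step-by-step sequential sizing by naive evaluation of the same
    cap and argmin rules: W from the leading specimen, k = k_max when
    k_max <= phi0/W, else the cost-minimising k (ties to smaller k)."""
    r = assay.sensitivity + assay.specificity - 1
    se = assay.sensitivity
    sizes = []
    t = 0
    n = len(risks_sorted)
    while t < n:
        remaining = n - t
        k_adm = min(k_max, remaining)
        w = -math.log(1 - risks_sorted[t])
        if w == 0 or k_max <= phi0 / w:
            k = k_adm
        else:
            best_k, best_c = None, None
            for k_try in range(1, k_adm + 1):
                q = math.prod(1 - p for p in risks_sorted[t:t + k_try])
                p1 = se - r * q
                c = p1 * (1 - p1) / (r**2 * k_try**2 * q**2)
                if best_c is None or c < best_c:
                    best_k, best_c = k_try, c
            k = best_k
        sizes.append(k)
        t += k
    return sizes
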