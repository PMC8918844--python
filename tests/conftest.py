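"""Shared fixtures and independent brute-force oracles.

The oracle functions recompute every bank quantity with explicit Python
loops and nothing from :mod:`ckbank.bank` except raw arrays, so they
stay independent of the vectorized implementation they check.
"""

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# -- brute-force oracles ------------------------------------------------------

def oracle_cosine(u, r):
    num = sum(a * b for a, b in zip(u, r))
    nu = math.sqrt(sum(a * a for a in u))
    nr = math.sqrt(sum(b * b for b in r))
    return num / (nu * nr)


def oracle_logits(units, r):
    """Per-class mean cosine by explicit double loop over classes and units."""
    out = []
    for class_units in units:
        total = 0.0
        for u in class_units:
            total += oracle_cosine(u, r)
        out.append(total / len(class_units))
    return np.array(out)


def oracle_contrastive(units, r, y):
    n = len(units)
    m = len(units[y])
    pos = sum(oracle_cosine(u, r) for u in units[y]) / m
    neg = 0.0
    for i in range(n):
        if i == y:
            continue
        neg += sum(oracle_cosine(u, r) for u in units[i]) / len(units[i])
    return -pos + neg / (n - 1)


def oracle_combined(units, r, y):
    s = oracle_logits(units, r)
    p = np.exp(s) / np.exp(s).sum()
    cel = -math.log(p[y])
    con = oracle_contrastive(units, r, y)
    return con, cel, con + cel


# -- fixtures ----------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_instances(rng):
    """Random (units, r, y) triples with N <= 5, M <= 8, D <= 16."""
    instances = []
    for _ in range(120):
        n = int(rng.integers(2, 6))
        m = int(rng.integers(1, 9))
        d = int(rng.integers(2, 17))
        units = rng.standard_normal((n, m, d))
        r = rng.standard_normal(d)
        y = int(rng.integers(0, n))
        instances.append((units, r, y))
    return instances


@pytest.fixture
def separable_features():
    """Well-separated 2-class Gaussian features (delta/sigma = 4)."""
    from ckbank.synthetic import SyntheticSpec, generate_features

    spec = SyntheticSpec.gaussian(separation=4.0, dispersion=1.0,
                                  feature_dim=8, seed=0)
    X_train, y_train = generate_features(spec, 2000, seed=11)
    X_test, y_test = generate_features(spec, 2000, seed=12)
    return X_train, y_train, X_test, y_test
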