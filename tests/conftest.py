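"""Shared fixtures and independent reference implementations (oracles)."""

import math

import numpy as np
import pandas as pd
import pytest

from gebvnet import ExpressionMatrix, GEBVMatrix, SimConfig, simulate_dataset

PERFECT = 1.0 - 1e-12


def brute_force_pcit(r: np.ndarray) -> np.ndarray:
    """Literal triple-loop reference for the trio significance test.

    Kept deliberately naive and scalar so it shares no code path with the
    vectorized implementation.
    """
    n = r.shape[0]
    sig = np.zeros((n, n), dtype=bool)
    for x in range(n):
        for y in range(x + 1, n):
            rxy = r[x, y]
            if abs(rxy) >= PERFECT:
                sig[x, y] = sig[y, x] = True
                continue
            if rxy == 0:
                continue
            rejected = False
            for z in range(n):
                if z == x or z == y:
                    continue
                rxz, ryz = r[x, z], r[y, z]
                if abs(rxz) >= PERFECT or abs(ryz) >= PERFECT:
                    continue
                terms = []
                p1 = (rxy - rxz * ryz) / math.sqrt((1.0 - rxz**2) * (1.0 - ryz**2))
                p2 = (rxz - rxy * ryz) / math.sqrt((1.0 - rxy**2) * (1.0 - ryz**2))
                p3 = (ryz - rxy * rxz) / math.sqrt((1.0 - rxy**2) * (1.0 - rxz**2))
                if rxy != 0:
                    terms.append(p1 / rxy)
                if rxz != 0:
                    terms.append(p2 / rxz)
                if ryz != 0:
                    terms.append(p3 / ryz)
                if not terms:
                    continue
                eps = sum(terms) / len(terms)
                if abs(rxy) <= abs(eps * rxz) and abs(rxy) <= abs(eps * ryz):
                    rejected = True
                    break
            sig[x, y] = sig[y, x] = not rejected
    return sig


def partial_corr_by_inversion(r_xy, r_xz, r_yz):
    """Partial correlation via the inverse of the 3x3 correlation matrix."""
    R = np.array([[1.0, r_xy, r_xz], [r_xy, 1.0, r_yz], [r_xz, r_yz, 1.0]])
    P = np.linalg.inv(R)
    return -P[0, 1] / math.sqrt(P[0, 0] * P[1, 1])


def random_correlation_matrix(rng, n, m):
    """Sample correlation matrix of n independent Gaussian series, m samples."""
    X = rng.standard_normal((n, m))
    r = np.clip(np.corrcoef(X), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


@pytest.fixture(scope="session")
def small_dataset():
    """Small seeded dataset shared by fast integration-style tests."""
    cfg = SimConfig(n_samples=60, n_genes=40, n_mirnas=8, n_traits=4,
                    block_traits=3, n_planted_assoc=4, n_planted_regulators=1,
                    seed=11)
    gebv, genes, mirnas, truth = simulate_dataset(cfg)
    return cfg, gebv, genes, mirnas, truth


@pytest.fixture
def tiny_expr():
    rng = np.random.default_rng(5)
    samples = [f"s{i}" for i in range(20)]
    df = pd.DataFrame(rng.standard_normal((6, 20)),
                      index=[f"g{i}" for i in range(6)], columns=samples)
    return ExpressionMatrix(df, "gene")


@pytest.fixture
def tiny_gebv():
    rng = np.random.default_rng(6)
    samples = [f"s{i}" for i in range(20)]
    df = pd.DataFrame(rng.standard_normal((20, 3)), index=samples,
                      columns=["ca", "fe", "zn"])
    return GEBVMatrix(df)
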