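"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by exhaustive enumeration
(triple loops over voxels, the literal step-up definition of the FDR, the
normal equations) so the package implementations are checked against a
second, independent route.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from neoclaustrum.synthetic import CohortSpec, PhantomSpec, generate_cohort, generate_phantom


# ---------------------------------------------------------------------------
# Brute-force voxel oracles (small grids only)
# ---------------------------------------------------------------------------

def brute_dilate_chebyshev(mask: np.ndarray, radius: int) -> np.ndarray:
    """Literal definition: a voxel is in the dilation iff some True voxel
    lies within Chebyshev distance `radius`."""
    out = np.zeros_like(mask, dtype=bool)
    pts = np.argwhere(mask)
    for idx in np.ndindex(mask.shape):
        for p in pts:
            if max(abs(idx[0] - p[0]), abs(idx[1] - p[1]), abs(idx[2] - p[2])) <= radius:
                out[idx] = True
                break
    return out


def brute_neighbour_count_26(mask: np.ndarray) -> np.ndarray:
    """Per-voxel 26-neighbourhood count by explicit offset loop;
    out-of-bounds neighbours count as False."""
    out = np.zeros(mask.shape, dtype=int)
    shape = mask.shape
    for idx in np.ndindex(shape):
        c = 0
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if di == dj == dk == 0:
                        continue
                    i, j, k = idx[0] + di, idx[1] + dj, idx[2] + dk
                    if 0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]:
                        c += bool(mask[i, j, k])
        out[idx] = c
    return out


def brute_bh_fdr(p: np.ndarray) -> np.ndarray:
    """Step-up definition: q_(i) = min_{j >= i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def normal_equations_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.solve(X.T @ X, X.T @ y)


def exact_correlation_columns(n: int, rhos, rng) -> tuple[np.ndarray, np.ndarray]:
    """A claustrum column and region columns whose *sample* Pearson
    correlations equal the requested values exactly (built from an
    orthonormal basis)."""
    raw = rng.normal(size=(n, len(rhos) + 1))
    raw -= raw.mean(axis=0)
    qmat, _ = np.linalg.qr(raw)
    x = qmat[:, 0]
    regions = np.column_stack(
        [r * x + np.sqrt(1 - r**2) * qmat[:, j + 1] for j, r in enumerate(rhos)]
    )
    return x, regions


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def small_phantom():
    spec = PhantomSpec(shape=(48, 48, 40), md_noise_sd=0.0, fa_noise_sd=0.0)
    return generate_phantom(spec, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
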