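"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _cs_dijkstra

from optofurrow.core import PhotoactivationProtocol, Rect
from optofurrow.synthetic import NoiseModel, SyntheticParams, make_tissue


@pytest.fixture(scope="session")
def noiseless_params() -> SyntheticParams:
    return SyntheticParams(noise=NoiseModel(gaussian_sd=0.0), n_z=1)


@pytest.fixture(scope="session")
def tissue(noiseless_params):
    return make_tissue(noiseless_params)


@pytest.fixture(scope="session")
def activation_protocol() -> PhotoactivationProtocol:
    return PhotoactivationProtocol(regions=(Rect(120, 180, 60, 150),))


def interior_labels(labels: np.ndarray) -> list[int]:
    """Labels whose region does not touch the field border."""
    border = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    return [int(l) for l in np.unique(labels) if l > 0 and l not in border]


def dijkstra_voronoi_oracle(seed_arr: np.ndarray, guide: np.ndarray, lam: float) -> np.ndarray:
    """Brute-force seeded geodesic Voronoi via per-seed shortest paths.

    Builds the full 4-neighbour graph with step cost
    sqrt((dI)^2 + lam), runs scipy's Dijkstra from each seed's pixels,
    and assigns each pixel the label with minimal distance (ties to the
    smaller label id).  Independent of the package's own propagation.
    """
    h, w = seed_arr.shape
    n = h * w
    g = np.asarray(guide, dtype=np.float64).ravel()
    rows, cols, vals = [], [], []
    for i in range(n):
        y, x = divmod(i, w)
        for j in (
            i - w if y > 0 else -1,
            i + w if y < h - 1 else -1,
            i - 1 if x > 0 else -1,
            i + 1 if x < w - 1 else -1,
        ):
            if j >= 0:
                rows.append(i)
                cols.append(j)
                vals.append(np.sqrt((g[j] - g[i]) ** 2 + lam))
    graph = csr_matrix((vals, (rows, cols)), shape=(n, n))
    labs = np.unique(seed_arr[seed_arr > 0])
    dist = np.full((len(labs), n), np.inf)
    for k, lab in enumerate(labs):
        idx = np.nonzero(seed_arr.ravel() == lab)[0]
        dist[k] = _cs_dijkstra(graph, indices=idx).min(axis=0)
    best = np.argmin(dist, axis=0)  # np.argmin: smallest index on ties
    return labs[best].reshape(h, w).astype(np.int32)


def random_voronoi_instance(rng: np.random.Generator, shape=(15, 15)):
    """One random propagation problem (seeds, guide, lambda)."""
    guide = rng.uniform(0.0, 10.0, shape)
    n_seeds = int(rng.integers(2, 6))
    seed_arr = np.zeros(shape, dtype=np.int32)
    pos = rng.choice(shape[0] * shape[1], n_seeds, replace=False)
    for k, p in enumerate(pos):
        seed_arr[divmod(int(p), shape[1])] = k + 1
    lam = float(rng.uniform(0.0, 2.0))
    return seed_arr, guide, lam
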