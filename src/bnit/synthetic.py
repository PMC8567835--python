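"""Synthetic structural and functional data with known ground truth.

Every generator is fully determined by an integer seed through NumPy's
``default_rng`` (PCG64); the RNG algorithm is part of the public contract so
fixtures are reproducible across runs and platforms.

The structural generator emulates a fiber-length connectome as a random
geometric graph: regions are points in a 3-D box (coordinates in mm) and
connected when closer than a radius, with the Euclidean distance as the edge
length. Euclidean lengths satisfy the triangle inequality, so direct edges
are their own geodesics and hand verification is easy; a ``length_noise``
"violation mode" perturbs lengths multiplicatively to exercise multi-edge
geodesics between structurally adjacent regions.

The functional generator produces zero-mean Gaussian time series with a
prescribed correlation matrix, for which the mutual information is known in
closed form: MI = -1/2 log2(1 - rho^2) bits. Gaussian chains with fixed
hop correlation give corr(S, K_j) = rho^j, a Markov chain on which the data
processing inequality holds exactly in population.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.sparse.csgraph import connected_components

from bnit.io import Parcellation, RegionalTimeSeries, StructuralConnectome
from bnit.mi import FunctionalConnectome


def gaussian_mi_bits(rho: float | np.ndarray) -> float | np.ndarray:
    """Closed-form MI of a bivariate Gaussian: -1/2 log2(1 - rho^2)."""
    return -0.5 * np.log2(1.0 - np.asarray(rho) ** 2)


def make_structural(
    n_regions: int,
    radius: float = 60.0,
    box_size: float = 100.0,
    seed: int = 0,
    length_noise: float = 0.0,
    max_retries: int = 20,
) -> StructuralConnectome:
    """Random geometric fiber-length connectome in a 3-D box.

    Regions are placed uniformly in a ``box_size``-mm cube and connected when
    within ``radius`` mm; the edge weight is the Euclidean distance.
    ``length_noise > 0`` multiplies each length by an independent
    ``1 + U(0, length_noise)`` factor, breaking metricity. If the graph comes
    out disconnected, placement is retried (with a warning) up to
    ``max_retries`` times before erroring.
    """
    if n_regions < 3:
        raise ValueError("need at least 3 regions")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries + 1):
        pos = rng.uniform(0.0, box_size, size=(n_regions, 3))
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
        adj = (dist <= radius) & ~np.eye(n_regions, dtype=bool)
        lengths = np.where(adj, dist, 0.0)
        if length_noise > 0:
            factor = 1.0 + rng.uniform(0.0, length_noise, size=dist.shape)
            factor = np.triu(factor, 1)
            factor = factor + factor.T
            lengths = lengths * np.where(adj, factor, 0.0)
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp == 1:
            return StructuralConnectome(lengths)
        warnings.warn(
            f"random geometric graph disconnected (attempt {attempt + 1}); retrying"
        )
    raise ValueError(
        f"could not generate a connected graph with n={n_regions}, "
        f"radius={radius}, box={box_size}; increase the radius or region density"
    )


def make_gaussian_timeseries(
    target_corr: np.ndarray, n_timepoints: int, seed: int = 0
) -> RegionalTimeSeries:
    """Zero-mean Gaussian series with a prescribed correlation matrix.

    The target matrix must be symmetric positive semidefinite (checked via
    its smallest eigenvalue); sampling uses the Cholesky factor of the
    (slightly ridged) correlation. Empirical correlations converge to the
    target at the usual O(T^-1/2) rate.
    """
    corr = np.asarray(target_corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("target correlation must be a square matrix")
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < -1e-10:
        raise ValueError(
            f"target correlation is not positive semidefinite "
            f"(smallest eigenvalue {eigmin:.3e})"
        )
    rng = np.random.default_rng(seed)
    n = corr.shape[0]
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(n))
    values = chol @ rng.standard_normal((n, n_timepoints))
    return RegionalTimeSeries(values)


def make_markov_chain_series(
    n_nodes: int, hop_rho: float, n_timepoints: int, seed: int = 0
) -> RegionalTimeSeries:
    """Gaussian Markov chain S -> K1 -> ... with fixed hop correlation.

    Node j+1 is ``hop_rho * node_j + sqrt(1 - hop_rho^2) * noise``, so every
    node has unit variance and corr(S, K_j) = hop_rho^j. Along this chain the
    data processing inequality holds in population: MI(S; K_j) is
    nonincreasing in j.
    """
    if not abs(hop_rho) < 1:
        raise ValueError("|hop_rho| must be below 1")
    rng = np.random.default_rng(seed)
    values = np.empty((n_nodes, n_timepoints))
    values[0] = rng.standard_normal(n_timepoints)
    scale = np.sqrt(1.0 - hop_rho**2)
    for j in range(1, n_nodes):
        values[j] = hop_rho * values[j - 1] + scale * rng.standard_normal(n_timepoints)
    return RegionalTimeSeries(values)


def toy_fixture() -> tuple[StructuralConnectome, FunctionalConnectome, Parcellation]:
    """Fixed 5-region instance with hand-computable path scores.

    Regions A..E (indices 0..4). Structural edges (mm): A-B 10, B-C 10,
    C-E 15, A-D 30, D-E 10, B-E 40. The A->E geodesic is therefore
    (A, B, C, E) at 35 mm (vs A-D-E at 40 and A-B-E at 50).

    MI values (bits) are dyadic rationals so logs are exact:
    AB 1.0, AC 0.5, AD 0.25, AE 0.25, BC 1.0, BD 0.5, BE 0.5, CD 0.25,
    CE 0.5, DE 1.0; the diagonal carries a nominal entropy of 3.0 bits.
    Masked strengths: W = (1.25, 2.5, 1.5, 1.25, 2.0). The documented answer
    sheet (verified in the test suite): PPS(A->E) = 1.25 bits and
    raw PBS(A->E) = log2(9.375) bits, normalized by 35 mm.
    """
    ids = ["A", "B", "C", "D", "E"]
    sc = np.zeros((5, 5))
    for i, j, length in [(0, 1, 10), (1, 2, 10), (2, 4, 15), (0, 3, 30), (3, 4, 10), (1, 4, 40)]:
        sc[i, j] = sc[j, i] = length
    mi = np.full((5, 5), 0.0)
    vals = {
        (0, 1): 1.0, (0, 2): 0.5, (0, 3): 0.25, (0, 4): 0.25,
        (1, 2): 1.0, (1, 3): 0.5, (1, 4): 0.5,
        (2, 3): 0.25, (2, 4): 0.5,
        (3, 4): 1.0,
    }
    for (i, j), v in vals.items():
        mi[i, j] = mi[j, i] = v
    np.fill_diagonal(mi, 3.0)
    parc = Parcellation(
        region_ids=ids,
        network=["default_mode", "default_mode", "visual", "subcortical", "subcortical"],
        hemisphere=["L", "L", "R", "L", "R"],
    )
    return (
        StructuralConnectome(sc, ids),
        FunctionalConnectome(mi, None, ids),
        parc,
    )
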