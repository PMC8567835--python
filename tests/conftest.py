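"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (exhaustive enumeration, direct
product-form evaluation) and share no code with the implementation paths
they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from bnit import toy_fixture


# ---------------------------------------------------------------------------
# toy 5-region fixture answer sheet (hand-computed, see synthetic.toy_fixture)
#
# Regions A..E = 0..4. SC edges (mm): A-B 10, B-C 10, C-E 15, A-D 30,
# D-E 10, B-E 40. Geodesics of interest:
#   A->E: (A,B,C,E), 35 mm      A->C: (A,B,C), 20 mm
# MI (bits): AB 1, AC 1/2, AD 1/4, AE 1/4, BC 1, BD 1/2, BE 1/2,
#            CD 1/4, CE 1/2, DE 1.
# Masked strengths: W_A = 1+1/4 = 1.25, W_B = 1+1+1/2 = 2.5,
#                   W_C = 1+1/2 = 1.5, W_D = 1/4+1 = 1.25, W_E = 1/2+1+1/2 = 2.
# PPS(A->E) over {B, C, E} anchored at MI(A,B)=1:
#   (1-1) + (1-1/2) + (1-1/4) = 1.25 bits.
# PPS(A->C) (2-edge) = MI(A,B) - MI(A,C) = 1/2 bit.
# raw PBS(A->E) = -log2[(1/1.25) * (1/2.5) * (0.5/1.5)] = log2(9.375) bits,
#   normalized by 35 mm.
# ---------------------------------------------------------------------------

TOY_PATH_AE = (0, 1, 2, 4)
TOY_LEN_AE = 35.0
TOY_PPS_AE = 1.25
TOY_PPS_AC = 0.5
TOY_RAW_PBS_AE = math.log2(9.375)
TOY_W = np.array([1.25, 2.5, 1.5, 1.25, 2.0])


@pytest.fixture(scope="session")
def toy():
    return toy_fixture()


# ---------------------------------------------------------------------------
# independent oracles


def enumerate_shortest(lengths: np.ndarray, s: int, t: int):
    """Exhaustive DFS over all simple paths; returns (best_length, best_paths).

    best_paths is the set of node tuples attaining the minimum length.
    Returns (inf, set()) when s and t are disconnected.
    """
    n = lengths.shape[0]
    best = [math.inf, set()]

    def walk(node: int, visited: set[int], path: list[int], acc: float) -> None:
        if node == t:
            if acc < best[0] - 1e-12:
                best[0], best[1] = acc, {tuple(path)}
            elif abs(acc - best[0]) <= 1e-12:
                best[1].add(tuple(path))
            return
        for nxt in range(n):
            if nxt in visited or lengths[node, nxt] <= 0:
                continue
            visited.add(nxt)
            path.append(nxt)
            walk(nxt, visited, path, acc + lengths[node, nxt])
            path.pop()
            visited.remove(nxt)

    walk(s, {s}, [s], 0.0)
    return best[0], best[1]


def pbs_product_form(nodes: tuple[int, ...], mi: np.ndarray, w: np.ndarray) -> float:
    """Raw PBS via the literal product form: -log2 prod(MI_i / W_i)."""
    prod = 1.0
    for a, b in zip(nodes[:-1], nodes[1:]):
        prod *= mi[a, b] / w[a]
    return -math.log2(prod)


def pps_resummation(nodes: tuple[int, ...], mi: np.ndarray) -> float:
    """PPS via (m+1) * MI(S,K1) - sum_i MI(S,i) over post-source nodes."""
    s = nodes[0]
    post = nodes[1:]
    return len(post) * mi[s, post[0]] - sum(mi[s, i] for i in post)


def random_connected_lengths(n: int, density: float, rng) -> np.ndarray:
    """Random symmetric positive length matrix, guaranteed connected.

    Edges are sampled at the given density, then a random spanning chain is
    added so the graph is always connected.
    """
    lengths = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                lengths[i, j] = lengths[j, i] = rng.uniform(1.0, 10.0)
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        if lengths[a, b] == 0:
            lengths[a, b] = lengths[b, a] = rng.uniform(1.0, 10.0)
    return lengths


def random_mi_matrix(n: int, rng) -> np.ndarray:
    """Random symmetric positive MI-like matrix with entropy-like diagonal."""
    mi = rng.uniform(0.05, 1.5, size=(n, n))
    mi = (mi + mi.T) / 2.0
    np.fill_diagonal(mi, 3.0)
    return mi
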