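"""Path broadcasting strength (PBS) and nodal broadcasting strengths.

PBS is search information evaluated on functional (mutual-information)
weights superimposed on the structural geodesic: for a path from S through
K1..Km to T,

    PBS_raw(s->t) = -log2 prod over i in {S, K1, ..., Km} of MI_i / W_i

where MI_i is the MI of the edge leaving node i along the path and W_i is
node i's structurally masked MI strength (sum of MI over its structural
neighbors). Each ratio is the "probability" that a greedy broadcast at node
i picks the path edge, so PBS is the information (bits) needed to keep the
signal on the path: low PBS means routing, high PBS means the signal also
spreads to edges adjacent to the path (broadcasting). Longer paths
accumulate more terms, so the reported PBS is normalized by the geodesic
length in millimeters (bits/mm).

Nodal (weighted) broadcasting strengths aggregate normalized PBS per region
and regime: WBS_sender(k) sums over pairs with k as source, WBS_receiver(k)
over pairs with k as target, and WBS(k) is their average.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bnit.io import StructuralConnectome, ValidationError
from bnit.mi import FunctionalConnectome
from bnit.paths import PathTable, ShortestPath
from bnit.pps import RegimeLabels

logger = logging.getLogger(__name__)

_BROADCASTABLE_REGIMES = ("direct", "relay", "transducted")


def structural_strength(
    fc: FunctionalConnectome, sc: StructuralConnectome
) -> np.ndarray:
    """Structurally masked MI nodal strength W_i = sum_j MI(i, j) over SC edges.

    Only pairs with a present structural connection contribute; the diagonal
    (self-information) is excluded because the SC diagonal is zero.
    """
    if fc.n_regions != sc.n_regions:
        raise ValidationError(
            f"FC has {fc.n_regions} regions but SC has {sc.n_regions}"
        )
    return (fc.mi * sc.adjacency).sum(axis=1)


def compute_pbs(
    path: ShortestPath,
    fc: FunctionalConnectome,
    w: np.ndarray,
    mode: str = "full_strength",
) -> tuple[float, float]:
    """(raw bits, normalized bits/mm) broadcasting strength of one geodesic.

    Defined for any path with >= 1 edge, including direct single-edge
    geodesics. ``mode="full_strength"`` divides every path-edge MI by the
    full nodal strength W_i; ``mode="exclude_arrival"`` is the classical
    search-information variant that subtracts the arrival edge's MI from the
    strength of each intermediate node. A zero MI on a path edge (or an
    empty strength) yields an infinite PBS, which downstream sums exclude.
    """
    if mode not in ("full_strength", "exclude_arrival"):
        raise ValueError(f"mode must be full_strength|exclude_arrival, got {mode!r}")
    mi = fc.mi
    raw = 0.0
    nodes = path.nodes
    for k in range(len(nodes) - 1):
        i, j = nodes[k], nodes[k + 1]
        edge_mi = mi[i, j]
        denom = w[i]
        if mode == "exclude_arrival" and k > 0:
            denom = denom - mi[nodes[k - 1], i]
        if edge_mi <= 0 or denom <= 0:
            logger.warning(
                "infinite PBS on path %s: edge (%d, %d) has MI %.3g / strength %.3g",
                nodes,
                i,
                j,
                edge_mi,
                denom,
            )
            return math.inf, math.inf
        raw += -math.log2(edge_mi / denom)
    return raw, raw / path.total_length


@dataclass
class PBSMatrix:
    """Per-ordered-pair broadcasting strengths.

    ``raw`` is in bits and ``norm`` in bits/mm; NaN marks undefined entries
    (diagonal, disconnected pairs) and inf marks paths with a zero-MI edge.
    """

    raw: np.ndarray
    norm: np.ndarray
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.region_ids:
            self.region_ids = [f"region_{i}" for i in range(self.raw.shape[0])]

    @property
    def n_regions(self) -> int:
        return self.raw.shape[0]


@dataclass
class BroadcastStrengths:
    """Per-region sender/receiver/symmetric broadcasting strengths (bits/mm).

    ``wbs`` is exactly (``wbs_sender`` + ``wbs_receiver``) / 2. ``regime``
    records which communication regime the sums were restricted to, and
    ``n_excluded`` how many infinite/undefined pair values were left out.
    """

    wbs_sender: np.ndarray
    wbs_receiver: np.ndarray
    wbs: np.ndarray
    regime: str
    n_excluded: int = 0
    region_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region_ids
                or [f"region_{i}" for i in range(len(self.wbs))],
                "wbs_sender": self.wbs_sender,
                "wbs_receiver": self.wbs_receiver,
                "wbs": self.wbs,
            }
        )


def pbs_matrix(
    paths: PathTable,
    fc: FunctionalConnectome,
    w: np.ndarray | None = None,
    sc: StructuralConnectome | None = None,
    mode: str = "full_strength",
) -> PBSMatrix:
    """Raw and length-normalized PBS for every ordered pair.

    Either precomputed strengths ``w`` or the structural connectome ``sc``
    (from which they are derived) must be given.
    """
    if w is None:
        if sc is None:
            raise ValidationError("either nodal strengths w or an SC is required")
        w = structural_strength(fc, sc)
    w = np.asarray(w, dtype=float)
    if paths.n != fc.n_regions or w.shape != (paths.n,):
        raise ValidationError("path table, FC and strengths have mismatched sizes")
    raw = np.full((paths.n, paths.n), np.nan)
    norm = np.full((paths.n, paths.n), np.nan)
    for s, t, p in paths.pairs():
        raw[s, t], norm[s, t] = compute_pbs(p, fc, w, mode)
    return PBSMatrix(raw, norm, list(paths.region_ids))


def broadcast_strengths(
    pbs: PBSMatrix, regimes: RegimeLabels, regime: str
) -> BroadcastStrengths:
    """Aggregate normalized PBS into per-region strengths for one regime.

    ``wbs_sender(k)`` sums PBS over pairs (k -> t) labelled ``regime``;
    ``wbs_receiver(k)`` over pairs (s -> k). Undefined (NaN) and infinite
    pair values are excluded from the sums and counted in ``n_excluded``.
    """
    if regime not in _BROADCASTABLE_REGIMES:
        raise ValidationError(
            f"regime must be one of {_BROADCASTABLE_REGIMES}, got {regime!r}"
        )
    if pbs.n_regions != regimes.n_regions:
        raise ValidationError("PBS matrix and regime labels have mismatched sizes")
    mask = regimes.mask(regime)
    finite = np.isfinite(pbs.norm)
    n_excluded = int((mask & ~finite).sum())
    if n_excluded:
        logger.warning(
            "%d %s-regime pair(s) excluded from WBS sums (undefined/infinite PBS)",
            n_excluded,
            regime,
        )
    vals = np.where(mask & finite, pbs.norm, 0.0)
    sender = vals.sum(axis=1)
    receiver = vals.sum(axis=0)
    return BroadcastStrengths(
        wbs_sender=sender,
        wbs_receiver=receiver,
        wbs=(sender + receiver) / 2.0,
        regime=regime,
        n_excluded=n_excluded,
        region_ids=list(pbs.region_ids),
    )


def top_regions(bs: BroadcastStrengths, k: int) -> pd.DataFrame:
    """Top-``k`` regions by symmetric WBS, descending; ties by region index."""
    n = len(bs.wbs)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available regions")
    order = np.lexsort((np.arange(n), -bs.wbs))[:k]
    frame = bs.to_frame().iloc[order].reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, k + 1))
    return frame
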