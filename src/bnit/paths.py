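"""All-pairs shortest paths on the fiber-length structural connectome.

Edge weights are millimeter streamline lengths and are minimized directly
(smaller = closer; no inverse transform). Ties between equal-length paths are
broken deterministically — fewer hops first, then the lexicographically
smallest node-index sequence as seen from the lower-indexed endpoint — because
downstream path scores depend on the exact node sequence. Each unordered pair
is solved once from its lower-indexed endpoint and the opposite direction is
the reversal, so the s->t and t->s sequences are always mutual reverses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from heapq import heappop, heappush
from pathlib import Path

import numpy as np

from bnit.io import StructuralConnectome, ValidationError


@dataclass(frozen=True)
class ShortestPath:
    """A geodesic on the structural connectome.

    ``nodes`` is the ordered region-index sequence (source, intermediates,
    target); ``total_length`` is the summed fiber length in millimeters.
    """

    nodes: tuple[int, ...]
    total_length: float

    @property
    def source(self) -> int:
        return self.nodes[0]

    @property
    def target(self) -> int:
        return self.nodes[-1]

    @property
    def edge_count(self) -> int:
        return len(self.nodes) - 1

    @property
    def intermediates(self) -> tuple[int, ...]:
        return self.nodes[1:-1]

    def reversed(self) -> "ShortestPath":
        return ShortestPath(self.nodes[::-1], self.total_length)


class PathTable:
    """All-pairs geodesics; absent entries mark disconnected pairs.

    ``get(s, t)`` returns the :class:`ShortestPath` for the ordered pair or
    ``None`` when the pair is disconnected. The diagonal is undefined.
    """

    def __init__(
        self,
        n: int,
        paths: dict[tuple[int, int], ShortestPath],
        region_ids: list[str] | None = None,
    ) -> None:
        self.n = n
        self._paths = paths  # keyed by (min_idx, max_idx)
        self.region_ids = region_ids or [f"region_{i}" for i in range(n)]

    def get(self, s: int, t: int) -> ShortestPath | None:
        if s == t:
            raise ValueError("shortest path is undefined for a region and itself")
        stored = self._paths.get((min(s, t), max(s, t)))
        if stored is None:
            return None
        return stored if stored.source == s else stored.reversed()

    def is_connected(self, s: int, t: int) -> bool:
        return (min(s, t), max(s, t)) in self._paths

    def pairs(self):
        """Iterate over all ordered connected pairs (s, t, path)."""
        for (a, b), p in self._paths.items():
            yield a, b, p
            yield b, a, p.reversed()

    def lengths(self) -> np.ndarray:
        """Matrix of geodesic lengths; inf for disconnected, 0 on the diagonal."""
        out = np.full((self.n, self.n), np.inf)
        np.fill_diagonal(out, 0.0)
        for (a, b), p in self._paths.items():
            out[a, b] = out[b, a] = p.total_length
        return out

    # -- JSON-lines persistence (one record per ordered pair) ---------------

    def to_jsonl(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for s in range(self.n):
                for t in range(self.n):
                    if s == t:
                        continue
                    p = self.get(s, t)
                    rec: dict = {
                        "source": self.region_ids[s],
                        "target": self.region_ids[t],
                    }
                    if p is None:
                        rec["disconnected"] = True
                    else:
                        rec["nodes"] = [self.region_ids[i] for i in p.nodes]
                        rec["length_mm"] = p.total_length
                    fh.write(json.dumps(rec) + "\n")
        return path

    @classmethod
    def from_jsonl(cls, path: str | Path, region_ids: list[str]) -> "PathTable":
        index = {r: i for i, r in enumerate(region_ids)}
        paths: dict[tuple[int, int], ShortestPath] = {}
        with open(path) as fh:
            for line in fh:
                rec = json.loads(line)
                s, t = index[rec["source"]], index[rec["target"]]
                if rec.get("disconnected"):
                    continue
                if s < t:  # each unordered pair stored once, from the low index
                    nodes = tuple(index[r] for r in rec["nodes"])
                    paths[(s, t)] = ShortestPath(nodes, float(rec["length_mm"]))
        return cls(len(region_ids), paths, list(region_ids))


def _dijkstra_from(
    adjacency: list[list[tuple[int, float]]], source: int
) -> dict[int, tuple[float, int, tuple[int, ...]]]:
    """Single-source Dijkstra with (length, hops, sequence) lexicographic keys."""
    final: dict[int, tuple[float, int, tuple[int, ...]]] = {}
    best: dict[int, tuple[float, int, tuple[int, ...]]] = {}
    heap: list[tuple[float, int, tuple[int, ...]]] = [(0.0, 0, (source,))]
    while heap:
        entry = heappop(heap)
        node = entry[2][-1]
        if node in final:
            continue
        final[node] = entry
        dist, hops, seq = entry
        for nb, w in adjacency[node]:
            if nb in final:
                continue
            cand = (dist + w, hops + 1, seq + (nb,))
            cur = best.get(nb)
            if cur is None or cand < cur:
                best[nb] = cand
                heappush(heap, cand)
    return final


def all_pairs_shortest_paths(
    sc: StructuralConnectome, edge_mask: np.ndarray | None = None
) -> PathTable:
    """Compute the geodesic node sequence and mm length for every region pair.

    Parameters
    ----------
    sc
        Structural connectome; weights are used as-is (unthresholded,
        unbinarized mean streamline lengths).
    edge_mask
        Optional boolean matrix marking which entries are edges. Defaults to
        ``sc.lengths > 0``. A masked-present edge with length 0 between
        distinct regions is invalid and raises.
    """
    lengths = sc.lengths
    n = sc.n_regions
    if edge_mask is None:
        edge_mask = lengths > 0
    else:
        edge_mask = np.asarray(edge_mask, dtype=bool)
        if edge_mask.shape != lengths.shape:
            raise ValidationError("edge mask shape does not match the connectome")
        zero_edges = edge_mask & ~np.eye(n, dtype=bool) & (lengths <= 0)
        if zero_edges.any():
            i, j = np.argwhere(zero_edges)[0]
            raise ValidationError(
                f"edge ({sc.region_ids[i]}, {sc.region_ids[j]}) has nonpositive "
                "length; a zero-length connection between distinct regions is invalid"
            )
    adjacency: list[list[tuple[int, float]]] = [
        [(int(j), float(lengths[i, j])) for j in np.flatnonzero(edge_mask[i]) if j != i]
        for i in range(n)
    ]
    paths: dict[tuple[int, int], ShortestPath] = {}
    for s in range(n):
        final = _dijkstra_from(adjacency, s)
        for t, (dist, _hops, seq) in final.items():
            if t > s:
                paths[(s, t)] = ShortestPath(seq, dist)
    return PathTable(n, paths, list(sc.region_ids))


def path_view(table: PathTable, s: int, t: int, variant: str = "full") -> tuple[int, ...]:
    """Return the path node sequence, optionally dropping source or target.

    ``variant="drop_source"`` gives (K1, ..., Km, T) — the nodes the score sum
    runs over in the path processing score; ``"drop_target"`` gives
    (S, K1, ..., Km) — the nodes whose outgoing edges enter the path
    broadcasting strength.
    """
    p = table.get(s, t)
    if p is None:
        raise ValidationError(
            f"regions {table.region_ids[s]} and {table.region_ids[t]} are "
            "structurally disconnected"
        )
    if variant == "full":
        return p.nodes
    if variant == "drop_source":
        return p.nodes[1:]
    if variant == "drop_target":
        return p.nodes[:-1]
    raise ValueError(f"variant must be full|drop_source|drop_target, got {variant!r}")
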