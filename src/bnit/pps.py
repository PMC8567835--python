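"""Path processing score (PPS) and communication-regime classification.

The PPS of a multi-edge geodesic from source S through intermediates
K1..Km to target T is

    PPS(s->t) = sum over i in {K1, ..., Km, T} of [MI(S; K1) - MI(S; i)]

i.e. every post-source node is compared against the first hop. The measure is
a relaxed form of the data processing inequality: along a Markov chain the
information about the source can only decay, so a clearly negative PPS is
evidence that the path is not the one carrying the communication ("absent"),
a PPS near zero means the signal arrives nearly intact ("relay"), and a
large positive PPS means the signal was transformed en route ("transducted").
PPS is undefined for single-edge geodesics ("direct" regime) and is generally
nonsymmetric: PPS(s->t) != PPS(t->s).

Relay boundaries default to the range obtained from the [5, 95] percentiles
of within-default-mode-network PPS values at rest, (-0.04, 0.07) bits;
:func:`estimate_boundaries` recomputes them for any reference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bnit.io import Parcellation, ValidationError
from bnit.mi import FunctionalConnectome
from bnit.paths import PathTable, ShortestPath

#: Default relay-regime boundaries (bits).
DEFAULT_LOWER = -0.04
DEFAULT_UPPER = 0.07

# regime codes used in RegimeLabels.codes
UNDEFINED = -1  # diagonal
DISCONNECTED = 0
DIRECT = 1
ABSENT = 2
RELAY = 3
TRANSDUCTED = 4

REGIME_NAMES: dict[int, str] = {
    UNDEFINED: "undefined",
    DISCONNECTED: "disconnected",
    DIRECT: "direct",
    ABSENT: "absent",
    RELAY: "relay",
    TRANSDUCTED: "transducted",
}
REGIME_CODES: dict[str, int] = {v: k for k, v in REGIME_NAMES.items()}


class PPSUndefinedError(ValidationError):
    """PPS requested for a pair whose geodesic has a single edge."""


@dataclass(frozen=True)
class RegimeBoundaries:
    """Lower/upper PPS bounds of the relay regime, in bits."""

    lower: float = DEFAULT_LOWER
    upper: float = DEFAULT_UPPER
    provenance: str = "package default"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValidationError(
                f"relay boundaries must satisfy lower < upper, got "
                f"({self.lower}, {self.upper})"
            )


@dataclass
class RegimeLabels:
    """Per-ordered-pair communication regime, as integer codes.

    Codes map to {undefined, disconnected, direct, absent, relay,
    transducted}; the diagonal is always undefined.
    """

    codes: np.ndarray
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if not self.region_ids:
            self.region_ids = [f"region_{i}" for i in range(self.codes.shape[0])]

    @property
    def n_regions(self) -> int:
        return self.codes.shape[0]

    def names(self) -> np.ndarray:
        out = np.empty(self.codes.shape, dtype=object)
        for code, name in REGIME_NAMES.items():
            out[self.codes == code] = name
        return out

    def counts(self) -> dict[str, int]:
        return {
            name: int((self.codes == code).sum()) for code, name in REGIME_NAMES.items()
        }

    def mask(self, regime: str) -> np.ndarray:
        if regime not in REGIME_CODES:
            raise ValidationError(
                f"unknown regime {regime!r}; expected one of {sorted(REGIME_CODES)}"
            )
        return self.codes == REGIME_CODES[regime]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.names(), index=self.region_ids, columns=self.region_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegimeLabels":
        names = df.to_numpy(dtype=object)
        codes = np.empty(names.shape, dtype=np.int8)
        for name, code in REGIME_CODES.items():
            codes[names == name] = code
        unknown = set(names.ravel()) - set(REGIME_CODES)
        if unknown:
            raise ValidationError(f"unknown regime label(s) {sorted(unknown)}")
        return cls(codes, [str(c) for c in df.columns])


def compute_pps(
    path: ShortestPath, fc: FunctionalConnectome, mode: str = "anchor"
) -> float:
    """PPS of one geodesic, in bits.

    ``mode="anchor"`` (default) is the definition above, with every summand
    anchored at MI(S; K1). ``mode="telescoping"`` instead sums consecutive
    differences MI(S; prev) - MI(S; node), which telescopes to
    MI(S; K1) - MI(S; T); the two agree exactly on 2-edge paths.
    """
    if path.edge_count < 2:
        raise PPSUndefinedError(
            "PPS is not defined for a single-edge shortest path "
            f"({path.source} -> {path.target})"
        )
    mi = fc.mi
    s = path.source
    post = path.nodes[1:]  # K1, ..., Km, T
    if mode == "anchor":
        anchor = mi[s, post[0]]
        return float(sum(anchor - mi[s, i] for i in post))
    if mode == "telescoping":
        return float(mi[s, post[0]] - mi[s, path.target])
    raise ValueError(f"mode must be anchor|telescoping, got {mode!r}")


def pps_matrix(
    paths: PathTable, fc: FunctionalConnectome, mode: str = "anchor"
) -> np.ndarray:
    """PPS for every ordered pair; NaN marks undefined entries.

    Undefined: the diagonal, disconnected pairs, and pairs whose geodesic is
    a single edge (the direct regime).
    """
    if paths.n != fc.n_regions:
        raise ValidationError(
            f"path table has {paths.n} regions but FC has {fc.n_regions}"
        )
    out = np.full((paths.n, paths.n), np.nan)
    for s, t, p in paths.pairs():
        if p.edge_count >= 2:
            out[s, t] = compute_pps(p, fc, mode)
    return out


def estimate_boundaries(
    pps: np.ndarray | None = None,
    parcellation: Parcellation | None = None,
    network: str = "default_mode",
    percentiles: tuple[float, float] = (5.0, 95.0),
) -> RegimeBoundaries:
    """Relay boundaries from the PPS distribution of a reference network.

    With no data the packaged defaults (-0.04, 0.07) are returned. Otherwise
    ``pps`` is either the full N x N PPS matrix (the defined values over
    ordered within-``network`` pairs are used, requiring ``parcellation``) or
    an already-pooled 1-D array of PPS values — pooling across subjects is the
    caller's concatenation. At least 20 defined values are required for a
    stable percentile.
    """
    if pps is None:
        return RegimeBoundaries()
    pps = np.asarray(pps, dtype=float)
    if pps.ndim == 1:
        values = pps[np.isfinite(pps)]
        source = "pooled values"
    else:
        if parcellation is None:
            raise ValidationError("a parcellation is required to mask a PPS matrix")
        labels = parcellation.network_array()
        if network not in labels:
            raise ValidationError(
                f"network {network!r} absent from the parcellation "
                f"(present: {parcellation.networks_present})"
            )
        members = np.flatnonzero(labels == network)
        sub = pps[np.ix_(members, members)]
        values = sub[np.isfinite(sub)]
        source = f"within-{network} pairs"
    if values.size < 20:
        raise ValidationError(
            f"only {values.size} defined PPS values in the reference mask; "
            "at least 20 are needed for a stable percentile estimate"
        )
    lo, hi = np.percentile(values, percentiles)
    return RegimeBoundaries(
        float(lo),
        float(hi),
        provenance=f"percentiles {percentiles} of {values.size} {source}",
    )


def classify_regimes(
    pps: np.ndarray, paths: PathTable, boundaries: RegimeBoundaries | None = None
) -> RegimeLabels:
    """Assign every ordered pair to a communication regime.

    Single-edge geodesics are *direct* regardless of PPS; multi-edge pairs are
    *absent* below the lower boundary, *relay* inside the closed interval
    [lower, upper], *transducted* above the upper boundary. Disconnected pairs
    and the diagonal get their own markers.
    """
    b = boundaries or RegimeBoundaries()
    pps = np.asarray(pps, dtype=float)
    if pps.shape != (paths.n, paths.n):
        raise ValidationError(
            f"PPS matrix shape {pps.shape} does not match {paths.n} regions"
        )
    codes = np.full((paths.n, paths.n), DISCONNECTED, dtype=np.int8)
    np.fill_diagonal(codes, UNDEFINED)
    for s, t, p in paths.pairs():
        if p.edge_count == 1:
            codes[s, t] = DIRECT
        else:
            v = pps[s, t]
            if np.isnan(v):
                raise ValidationError(
                    f"PPS undefined for connected multi-edge pair ({s}, {t})"
                )
            if v < b.lower:
                codes[s, t] = ABSENT
            elif v <= b.upper:
                codes[s, t] = RELAY
            else:
                codes[s, t] = TRANSDUCTED
    return RegimeLabels(codes, list(paths.region_ids))
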