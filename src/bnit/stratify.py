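"""Functional-network stratification of regimes and sender-receiver asymmetry.

Because both path scores are nonsymmetric, stratification uses ordered
(source network, target network) pairs by default; the within/between reading
over unordered network pairs is available via ``ordered=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bnit.io import Parcellation, ValidationError
from bnit.pbs import BroadcastStrengths
from bnit.pps import RegimeLabels


def regime_by_network(
    regimes: RegimeLabels,
    parcellation: Parcellation,
    regime: str,
    ordered: bool = True,
) -> pd.DataFrame:
    """Percentage of one regime's paths per (source, target) network pair.

    Rows index the source network and columns the target network (canonical
    network order, restricted to networks present in the parcellation).
    Entries are percentages of that regime's defined paths and sum to 100.
    With ``ordered=False`` the (A, B) and (B, A) counts are pooled into the
    upper triangle before converting to percentages.
    """
    if regimes.n_regions != parcellation.n_regions:
        raise ValidationError(
            f"regime labels cover {regimes.n_regions} regions but the "
            f"parcellation has {parcellation.n_regions}"
        )
    nets = parcellation.networks_present
    net_index = {name: i for i, name in enumerate(nets)}
    node_net = np.array([net_index[n] for n in parcellation.network])
    mask = regimes.mask(regime)
    counts = np.zeros((len(nets), len(nets)))
    src, tgt = np.nonzero(mask)
    np.add.at(counts, (node_net[src], node_net[tgt]), 1)
    if not ordered:
        counts = np.triu(counts + counts.T) - np.diag(np.diagonal(counts))
    total = counts.sum()
    if total == 0:
        raise ValidationError(f"no paths carry the {regime!r} regime")
    return pd.DataFrame(100.0 * counts / total, index=nets, columns=nets)


def network_regime_summary(
    regimes: RegimeLabels,
    parcellation: Parcellation,
    which: tuple[str, ...] = ("absent", "relay", "transducted"),
    ordered: bool = True,
) -> dict[str, pd.DataFrame]:
    """Per-regime network-pair percentage tables (skipping empty regimes)."""
    out: dict[str, pd.DataFrame] = {}
    for regime in which:
        if regimes.mask(regime).any():
            out[regime] = regime_by_network(regimes, parcellation, regime, ordered)
    return out


@dataclass
class AsymmetrySummary:
    """Per-region sender-minus-receiver broadcasting differences (bits/mm)."""

    table: pd.DataFrame  # region, wbs_sender, wbs_receiver, delta
    median: float
    iqr: float
    mean: float
    regime: str


def asymmetry_summary(bs: BroadcastStrengths) -> AsymmetrySummary:
    """Sender-receiver asymmetry of nodal broadcasting, with summary stats.

    Emits the per-node delta vector (sender minus receiver) plus its median,
    interquartile range and mean; no hypothesis testing is performed, the
    vectors are the input any external test would need.
    """
    delta = bs.wbs_sender - bs.wbs_receiver
    table = bs.to_frame()
    table["delta"] = delta
    q75, q25 = np.percentile(delta, [75, 25])
    return AsymmetrySummary(
        table=table,
        median=float(np.median(delta)),
        iqr=float(q75 - q25),
        mean=float(delta.mean()),
        regime=bs.regime,
    )
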