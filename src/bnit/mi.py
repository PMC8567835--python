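"""Mutual-information functional connectomes by uniform binning.

The functional connectome is estimated as the pairwise mutual information
(in bits) between z-scored regional time series, using the plug-in
joint-histogram estimator on a uniform binning of the z-score axis
(default: bin width 0.5 SD spanning [-3.5, 3.5], i.e. 14 bins).

MI is computed as H(X) + H(Y) - H(X, Y) with plug-in (maximum-likelihood)
entropies, which is algebraically identical to the sum over occupied joint
cells of p(x, y) log2[p(x, y) / (p(x) p(y))] and makes MI(X; X) = H(X) exact.
No small-sample bias correction is applied; :func:`bin_sensitivity`
quantifies robustness to the bin width instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bnit.io import RegionalTimeSeries, ValidationError, _default_ids

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class BinningScheme:
    """Uniform binning of the z-score axis used for MI estimation.

    ``bin_width`` is in z-score units; bins are anchored at the lower bound,
    half-open ``[lo, hi)`` with the last bin closed. Values outside the range
    are clipped into the boundary bins. A width that does not evenly divide
    the range (e.g. 0.75 or 2 over [-3.5, 3.5]) is allowed: the top bin is
    truncated at the upper bound.
    """

    bin_width: float = 0.5
    lower: float = -3.5
    upper: float = 3.5

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValidationError("bin width must be positive")
        if self.lower >= self.upper:
            raise ValidationError("binning range lower bound must be below upper")

    @property
    def n_bins(self) -> int:
        return int(np.ceil((self.upper - self.lower) / self.bin_width - 1e-9))


@dataclass
class FunctionalConnectome:
    """Pairwise mutual information matrix in bits.

    Symmetric with nonnegative off-diagonal entries; the diagonal stores each
    region's binned entropy H(i) (MI of a signal with itself) and is excluded
    from all nodal-strength and path computations. ``scheme`` records the
    binning used, or ``None`` for matrices loaded from disk.
    """

    mi: np.ndarray
    scheme: BinningScheme | None = None
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mi = np.asarray(self.mi, dtype=float)
        if self.mi.ndim != 2 or self.mi.shape[0] != self.mi.shape[1]:
            raise ValidationError(
                f"functional connectome must be square, got shape {self.mi.shape}"
            )
        if not self.region_ids:
            self.region_ids = _default_ids(self.mi.shape[0])
        if len(self.region_ids) != self.mi.shape[0]:
            raise ValidationError("region ids do not match matrix size")
        if not np.all(np.isfinite(self.mi)):
            raise ValidationError("MI matrix contains non-finite entries")
        asym = np.max(np.abs(self.mi - self.mi.T), initial=0.0)
        if asym > _SYMMETRY_TOL:
            raise ValidationError(f"MI matrix asymmetric (max |A - A.T| = {asym:.3e})")
        off = self.mi[~np.eye(self.mi.shape[0], dtype=bool)]
        if off.size and off.min() < -1e-12:
            raise ValidationError("mutual information must be nonnegative")

    @property
    def n_regions(self) -> int:
        return self.mi.shape[0]


def zscore(ts: RegionalTimeSeries) -> RegionalTimeSeries:
    """Z-score each regional time course (population SD, i.e. divide by T).

    Raises if any region's signal is constant, naming the region.
    """
    values = ts.values
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population SD
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValidationError(
            f"constant time series for region(s) {[ts.region_ids[i] for i in flat]}"
        )
    return RegionalTimeSeries((values - mean) / sd, list(ts.region_ids))


def discretize(ts: RegionalTimeSeries, scheme: BinningScheme | None = None) -> np.ndarray:
    """Map z-scored samples to integer bin codes in {0, ..., n_bins - 1}.

    Bin edges are half-open ``[lo, hi)`` with the last bin closed; values
    outside the range are clipped into the boundary bins, preserving T.
    """
    scheme = scheme or BinningScheme()
    values = ts.values
    if np.isnan(values).any():
        bad = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"NaN sample at region {ts.region_ids[bad[0]]}, time point {bad[1]}"
        )
    codes = np.floor((values - scheme.lower) / scheme.bin_width).astype(np.int64)
    return np.clip(codes, 0, scheme.n_bins - 1)


def _entropy_bits(counts: np.ndarray, total: int) -> float:
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def pairwise_mi(
    codes: np.ndarray,
    scheme: BinningScheme | None = None,
    region_ids: list[str] | None = None,
) -> FunctionalConnectome:
    """Plug-in mutual information between every pair of code sequences.

    ``codes`` is the N x T integer matrix from :func:`discretize`. Off-diagonal
    entries hold MI(i; j) = H(i) + H(j) - H(i, j) in bits; the diagonal holds
    the binned entropies H(i). The matrix is symmetric by construction (each
    pair is computed once).
    """
    scheme = scheme or BinningScheme()
    codes = np.asarray(codes)
    n, t = codes.shape
    if t < 2:
        raise ValidationError("need at least 2 time points to estimate MI")
    b = scheme.n_bins
    marg = np.stack([np.bincount(codes[i], minlength=b) for i in range(n)])
    h = np.array([_entropy_bits(marg[i], t) for i in range(n)])
    mi = np.zeros((n, n))
    np.fill_diagonal(mi, h)
    for i in range(n):
        base = codes[i] * b
        for j in range(i + 1, n):
            joint = np.bincount(base + codes[j], minlength=b * b)
            hij = _entropy_bits(joint, t)
            # clamp tiny negative round-off; plug-in MI is nonnegative
            mi[i, j] = mi[j, i] = max(h[i] + h[j] - hij, 0.0)
    return FunctionalConnectome(mi, scheme, list(region_ids or []))


def mi_connectome(
    ts: RegionalTimeSeries, scheme: BinningScheme | None = None
) -> FunctionalConnectome:
    """Convenience pipeline: z-score, discretize, pairwise MI."""
    scheme = scheme or BinningScheme()
    codes = discretize(zscore(ts), scheme)
    return pairwise_mi(codes, scheme, list(ts.region_ids))


def average_runs(
    fc_a: FunctionalConnectome, fc_b: FunctionalConnectome
) -> FunctionalConnectome:
    """Elementwise mean of two MI connectomes from repeat acquisitions.

    Used to average the two phase-encoding runs of the same session; the
    matrices must share region count and binning.
    """
    if fc_a.n_regions != fc_b.n_regions:
        raise ValidationError(
            f"cannot average {fc_a.n_regions}- and {fc_b.n_regions}-region connectomes"
        )
    if fc_a.scheme != fc_b.scheme:
        raise ValidationError("cannot average connectomes with different binning")
    return FunctionalConnectome(
        (fc_a.mi + fc_b.mi) / 2.0, fc_a.scheme, list(fc_a.region_ids)
    )


def bin_sensitivity(
    ts: RegionalTimeSeries,
    widths: list[float] = (0.5, 0.75, 1.0, 2.0),
    lower: float = -3.5,
    upper: float = 3.5,
) -> tuple[dict[float, FunctionalConnectome], pd.DataFrame]:
    """MI connectomes at several bin widths and their pairwise agreement.

    Agreement is the Pearson correlation between the upper-triangle MI values
    of every pair of widths, returned as a widths-by-widths DataFrame (1.0 on
    the diagonal).
    """
    widths = list(widths)
    schemes = [BinningScheme(w, lower, upper) for w in widths]
    zs = zscore(ts)
    fcs = {
        s.bin_width: pairwise_mi(discretize(zs, s), s, list(ts.region_ids))
        for s in schemes
    }
    n = ts.n_regions
    iu = np.triu_indices(n, k=1)
    vecs = np.stack([fcs[w].mi[iu] for w in widths])
    if len(widths) == 1:
        agree = np.ones((1, 1))
    else:
        agree = np.corrcoef(vecs)
    summary = pd.DataFrame(agree, index=widths, columns=widths)
    return fcs, summary
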