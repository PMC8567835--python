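"""Delimited-text I/O for connectome matrices, time series and parcellations.

All on-disk formats are plain text: connectivity matrices and regional time
series are delimited numeric tables (comma, tab or whitespace separated,
auto-detected on read; tab-separated on write), and the parcellation is a TSV
table with columns ``region``, ``network``, ``hemisphere``.

Region order is authoritative from the parcellation table; matrices are never
re-sorted on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: The seven cortical resting-state networks plus the subcortical set.
ALLOWED_NETWORKS: tuple[str, ...] = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
    "subcortical",
)

_SYMMETRY_TOL = 1e-9


class MatrixParseError(ValueError):
    """A delimited text file contained a malformed (non-numeric) cell."""


class ValidationError(ValueError):
    """Loaded data violates a connectome/time-series invariant."""


def _default_ids(n: int) -> list[str]:
    return [f"region_{i}" for i in range(n)]


@dataclass
class StructuralConnectome:
    """Symmetric matrix of mean streamline lengths between region pairs.

    ``lengths[i, j]`` is the mean white-matter fiber length between regions
    *i* and *j* in millimeters; an off-diagonal zero means *no structural
    connection* (never "length zero"). The matrix is the fixed topology on
    which all shortest paths are computed; it is used unthresholded and
    unbinarized.
    """

    lengths: np.ndarray
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.lengths.ndim != 2 or self.lengths.shape[0] != self.lengths.shape[1]:
            raise ValidationError(
                f"structural connectome must be square, got shape {self.lengths.shape}"
            )
        if not self.region_ids:
            self.region_ids = _default_ids(self.lengths.shape[0])
        if len(self.region_ids) != self.lengths.shape[0]:
            raise ValidationError(
                f"{len(self.region_ids)} region ids for a "
                f"{self.lengths.shape[0]}-row matrix"
            )
        if not np.all(np.isfinite(self.lengths)):
            raise ValidationError("structural connectome contains non-finite entries")
        asym = np.max(np.abs(self.lengths - self.lengths.T), initial=0.0)
        if asym > _SYMMETRY_TOL:
            raise ValidationError(
                f"structural connectome asymmetric (max |A - A.T| = {asym:.3e})"
            )
        if np.max(np.abs(np.diagonal(self.lengths)), initial=0.0) > 1e-12:
            raise ValidationError("structural connectome diagonal must be zero")
        if np.min(self.lengths, initial=0.0) < 0:
            raise ValidationError("streamline lengths must be nonnegative")

    @property
    def n_regions(self) -> int:
        return self.lengths.shape[0]

    @property
    def adjacency(self) -> np.ndarray:
        """Boolean mask of present structural edges (nonzero off-diagonal)."""
        return self.lengths > 0


@dataclass
class RegionalTimeSeries:
    """Regional activity signals: one row per region, one column per time point."""

    values: np.ndarray
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(
                f"time series must be a 2-D region x time array, got {self.values.ndim}-D"
            )
        if self.values.shape[1] < 2:
            raise ValidationError("time series needs at least 2 time points")
        if not self.region_ids:
            self.region_ids = _default_ids(self.values.shape[0])
        if len(self.region_ids) != self.values.shape[0]:
            raise ValidationError(
                f"{len(self.region_ids)} region ids for {self.values.shape[0]} rows"
            )

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class Parcellation:
    """Region metadata: functional-network label and hemisphere per region.

    Labels are restricted to the seven cortical resting-state networks plus
    ``subcortical`` (see :data:`ALLOWED_NETWORKS`). The row order of the table
    defines the authoritative region order for all matrices.
    """

    region_ids: list[str]
    network: list[str]
    hemisphere: list[str]

    def __post_init__(self) -> None:
        if not (len(self.region_ids) == len(self.network) == len(self.hemisphere)):
            raise ValidationError("parcellation columns have mismatched lengths")
        bad = sorted(set(self.network) - set(ALLOWED_NETWORKS))
        if bad:
            raise ValidationError(
                f"unknown network label(s) {bad}; allowed: {list(ALLOWED_NETWORKS)}"
            )

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def networks_present(self) -> list[str]:
        """Allowed networks that actually occur, in canonical order."""
        present = set(self.network)
        return [n for n in ALLOWED_NETWORKS if n in present]

    def network_array(self) -> np.ndarray:
        return np.asarray(self.network, dtype=object)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region_ids,
                "network": self.network,
                "hemisphere": self.hemisphere,
            }
        )


# ---------------------------------------------------------------------------
# reading / writing


def _detect_delimiter(line: str) -> str | None:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # whitespace


def _parse_numeric_table(path: Path) -> tuple[np.ndarray, list[str] | None]:
    """Parse a delimited numeric file, returning (matrix, optional header ids)."""
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise MatrixParseError(f"{path}: empty file")
    delim = _detect_delimiter(lines[0])
    rows = [ln.split(delim) if delim else ln.split() for ln in lines]
    header: list[str] | None = None
    try:
        float(rows[0][0])
    except ValueError:
        header = [tok.strip() for tok in rows[0]]
        rows = rows[1:]
    width = len(rows[0])
    data = np.empty((len(rows), width), dtype=float)
    for i, row in enumerate(rows):
        if len(row) != width:
            raise MatrixParseError(
                f"{path}: row {i} has {len(row)} cells, expected {width}"
            )
        for j, tok in enumerate(row):
            try:
                data[i, j] = float(tok)
            except ValueError:
                raise MatrixParseError(
                    f"{path}: non-numeric value {tok.strip()!r} at row {i}, column {j}"
                ) from None
    return data, header


def read_matrix(path: str | Path, expected_kind: str):
    """Read a delimited numeric file as a typed connectome object.

    Parameters
    ----------
    path
        Delimited text file; an optional first row of region identifiers is
        accepted for square matrices.
    expected_kind
        One of ``"structural"``, ``"functional"``, ``"timeseries"``. The
        corresponding type invariants (symmetry, nonnegativity, zero
        diagonal, ...) are validated on load.

    Returns
    -------
    StructuralConnectome, FunctionalConnectome or RegionalTimeSeries.
    """
    path = Path(path)
    data, header = _parse_numeric_table(path)
    ids = header or []
    if expected_kind == "structural":
        return StructuralConnectome(data, list(ids))
    if expected_kind == "functional":
        from bnit.mi import FunctionalConnectome

        return FunctionalConnectome(data, region_ids=list(ids))
    if expected_kind == "timeseries":
        return RegionalTimeSeries(data, list(ids))
    raise ValueError(
        f"expected_kind must be structural|functional|timeseries, got {expected_kind!r}"
    )


def write_matrix(
    matrix, path: str | Path, region_ids: Sequence[str] | None = None
) -> Path:
    """Write a matrix (or typed connectome) as tab-delimited text.

    Floats are written with 17 significant digits so that a write/read
    round-trip reproduces the array exactly.
    """
    path = Path(path)
    if isinstance(matrix, StructuralConnectome):
        data, ids = matrix.lengths, matrix.region_ids
    elif hasattr(matrix, "mi") and hasattr(matrix, "region_ids"):  # FunctionalConnectome
        data, ids = matrix.mi, matrix.region_ids
    elif isinstance(matrix, RegionalTimeSeries):
        data, ids = matrix.values, None  # row count != column count: no header
    else:
        data, ids = np.asarray(matrix, dtype=float), region_ids
    lines = []
    if ids is not None and len(ids) == data.shape[1]:
        lines.append("\t".join(ids))
    for row in data:
        lines.append("\t".join(f"{v:.17g}" for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_parcellation_table(path: str | Path) -> Parcellation:
    """Read a TSV parcellation with header ``region<TAB>network<TAB>hemisphere``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"region", "network", "hemisphere"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    return Parcellation(
        region_ids=df["region"].tolist(),
        network=df["network"].tolist(),
        hemisphere=df["hemisphere"].tolist(),
    )


def write_parcellation_table(parc: Parcellation, path: str | Path) -> Path:
    path = Path(path)
    parc.to_frame().to_csv(path, sep="\t", index=False)
    return path


def default_parcellation() -> Parcellation:
    """The packaged 374-region atlas: 360 cortical + 14 subcortical regions.

    Region counts per network and hemisphere are realistic for a 360-region
    cortical parcellation augmented with 14 subcortical structures, but the
    region-to-network assignment itself is synthetic (constructed for this
    package), as flagged by the data file name.
    """
    with resources.as_file(
        resources.files("bnit.data") / "atlas374_synthetic.tsv"
    ) as p:
        return read_parcellation_table(p)


# ---------------------------------------------------------------------------
# group averaging


def group_average_structural(
    connectomes: Sequence[StructuralConnectome], min_present: int = 1
) -> StructuralConnectome:
    """Average streamline lengths over subjects, ignoring absent edges.

    For each region pair the output length is the mean over the subjects in
    which the edge is present (nonzero); a zero entry encodes absence, not a
    zero-millimeter fiber, so it never dilutes the mean. An edge is retained
    only if present in at least ``min_present`` subjects (default 1).
    """
    if not connectomes:
        raise ValueError("need at least one structural connectome")
    ref = connectomes[0]
    for sc in connectomes[1:]:
        if sc.region_ids != ref.region_ids:
            raise ValidationError("connectomes have mismatched region sets/order")
    stack = np.stack([sc.lengths for sc in connectomes])
    present = stack > 0
    count = present.sum(axis=0)
    total = (stack * present).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    mean[count < max(min_present, 1)] = 0.0
    return StructuralConnectome(mean, list(ref.region_ids))
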