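"""Electrode-grid geometry and simulated-shift channel partitions.

A high-density surface-EMG grid is a regular ``n_rows x n_cols`` array of
monopolar electrodes with a common inter-electrode distance (IED).  Channels
are numbered row-major: channel ``i`` sits at row ``i // n_cols``,
column ``i % n_cols``, with physical coordinates ``x = col * ied_mm`` (the
transversal axis, across muscle fibers) and ``y = row * ied_mm`` (the
longitudinal axis, along the fibers).

Electrode shift is simulated by interleaved half-grid partitions: training on
every other column (or row) and testing on the complementary set displaces the
montage by exactly one electrode pitch while keeping the sub-grid geometry of
the two partitions congruent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError

__all__ = [
    "ElectrodeGrid",
    "ShiftScheme",
    "SHIFT_SCHEME_NAMES",
    "build_grid",
    "make_shift_scheme",
    "pair_distance_lags",
]

#: Valid shift-scheme identifiers.  ST*/SL* shift transversal/longitudinal to
#: the muscle-fiber direction; ST and SL are the matching half-grid controls
#: (train and test on the same channels); NONE uses the full grid.
SHIFT_SCHEME_NAMES = ("ST", "SL", "ST1", "ST2", "SL1", "SL2", "NONE")


@dataclass(frozen=True)
class ElectrodeGrid:
    """Regular electrode grid with row-major channel order.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions (rows run longitudinal, columns transversal).
    ied_mm
        Inter-electrode distance in millimeters, identical along both axes.
    """

    n_rows: int
    n_cols: int
    ied_mm: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidArgumentError(
                f"grid dimensions must be >= 1, got {self.n_rows}x{self.n_cols}"
            )
        if not self.ied_mm > 0:
            raise InvalidArgumentError(f"ied_mm must be > 0, got {self.ied_mm}")

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    def channel_index(self, row: int, col: int) -> int:
        """Row-major channel index of electrode at ``(row, col)``."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise InvalidArgumentError(f"(row={row}, col={col}) outside grid")
        return row * self.n_cols + col

    def row_col(self, channel: int) -> tuple[int, int]:
        """Inverse of :meth:`channel_index`."""
        if not 0 <= channel < self.n_channels:
            raise InvalidArgumentError(f"channel {channel} outside grid")
        return divmod(channel, self.n_cols)

    @property
    def positions(self) -> np.ndarray:
        """Per-channel ``(x, y)`` coordinates in millimeters, shape (c, 2)."""
        rows, cols = np.divmod(np.arange(self.n_channels), self.n_cols)
        return np.column_stack([cols * self.ied_mm, rows * self.ied_mm])


@dataclass(frozen=True)
class ShiftScheme:
    """Channel partition realizing one simulated-shift configuration.

    ``train_channels`` and ``test_channels`` are row-major-sorted channel
    indices.  For the shifted schemes (ST1/ST2/SL1/SL2) the i-th test channel
    is the i-th train channel displaced by one electrode pitch along the
    scheme's axis, so a model trained on the first partition sees, at test
    time, the same montage shifted by ``ied_mm``.
    """

    name: str
    axis: str  # "transversal" (columns), "longitudinal" (rows), or "none"
    train_channels: tuple[int, ...]
    test_channels: tuple[int, ...]
    grid: ElectrodeGrid = field(repr=False)

    @property
    def is_control(self) -> bool:
        """True when train and test partitions coincide (no shift)."""
        return self.train_channels == self.test_channels


def build_grid(n_rows: int, n_cols: int, ied_mm: float) -> ElectrodeGrid:
    """Construct an :class:`ElectrodeGrid`.

    The experimental montage this package targets is 8 rows x 24 columns at
    10 mm IED (192 monopolar channels wrapped around the forearm), but any
    positive dimensions are accepted.
    """
    return ElectrodeGrid(int(n_rows), int(n_cols), float(ied_mm))


def _axis_partition(grid: ElectrodeGrid, axis: str, parity: int) -> tuple[int, ...]:
    rows, cols = np.divmod(np.arange(grid.n_channels), grid.n_cols)
    key = cols if axis == "transversal" else rows
    return tuple(int(i) for i in np.flatnonzero(key % 2 == parity))


def make_shift_scheme(grid: ElectrodeGrid, name: str) -> ShiftScheme:
    """Build the channel partition for a named shift configuration.

    ST1 trains on even-index columns and tests on odd-index columns
    (shift by one column pitch transversal to the fibers); ST2 is the
    reverse.  SL1/SL2 do the same with rows (longitudinal shift).  ST and SL
    are controls: both roles use the even-index half.  NONE uses the full
    grid for both roles.  Within a half-grid partition the spacing along the
    shift axis is ``2 * ied_mm`` and the orthogonal spacing stays ``ied_mm``.
    """
    name = name.upper()
    if name not in SHIFT_SCHEME_NAMES:
        raise InvalidArgumentError(
            f"unknown shift scheme {name!r}; expected one of {SHIFT_SCHEME_NAMES}"
        )
    if name == "NONE":
        full = tuple(range(grid.n_channels))
        return ShiftScheme("NONE", "none", full, full, grid)

    axis = "transversal" if name.startswith("ST") else "longitudinal"
    count = grid.n_cols if axis == "transversal" else grid.n_rows
    if count % 2 != 0:
        raise InvalidArgumentError(
            f"scheme {name} needs an even number of "
            f"{'columns' if axis == 'transversal' else 'rows'}, got {count}"
        )
    even = _axis_partition(grid, axis, 0)
    odd = _axis_partition(grid, axis, 1)
    if name in ("ST", "SL"):
        return ShiftScheme(name, axis, even, even, grid)
    if name in ("ST1", "SL1"):
        return ShiftScheme(name, axis, even, odd, grid)
    return ShiftScheme(name, axis, odd, even, grid)  # ST2 / SL2


def pair_distance_lags(
    grid: ElectrodeGrid,
    channels: "list[int] | tuple[int, ...] | np.ndarray",
    max_lag_mm: float,
) -> dict[float, list[tuple[int, int]]]:
    """Group channel pairs by planar Euclidean distance (spatial lag).

    Distances are rounded to the nearest 0.1 mm so that lag grouping is
    deterministic under floating-point arithmetic.  Only lags with at least
    one pair at or below ``max_lag_mm`` appear.  The grid is treated as
    planar (no wrap-around), and pairs are returned as ``(i, j)`` with
    ``i < j`` in the order given by ``channels``.

    Returns
    -------
    dict
        Mapping ``lag_mm -> list of (channel_i, channel_j)`` with lags in
        ascending order.
    """
    channels = [int(c) for c in np.asarray(channels).ravel()]
    if len(channels) == 0:
        raise InvalidArgumentError("channel list is empty")
    if not max_lag_mm > 0:
        raise InvalidArgumentError(f"max_lag_mm must be > 0, got {max_lag_mm}")
    for c in channels:
        if not 0 <= c < grid.n_channels:
            raise InvalidArgumentError(f"channel {c} outside grid")

    pos = grid.positions[channels]
    lags: dict[float, list[tuple[int, int]]] = {}
    for a in range(len(channels)):
        for b in range(a + 1, len(channels)):
            d = float(np.hypot(*(pos[a] - pos[b])))
            lag = round(d, 1)
            if lag <= max_lag_mm:
                lags.setdefault(lag, []).append((channels[a], channels[b]))
    return dict(sorted(lags.items()))
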