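"""Array geometry: spot addressing, replicate mapping and nearest-spot search.

A kinome profiling slide carries ``n_sets`` identical replicate sets of
substrates, each a ``set_rows x set_cols`` grid spotted at a fixed pitch,
stacked vertically on the slide.  Every substrate therefore occurs once per
set at the same (row, col) position, which is what both the intra-slide
gradient correction and the interarray normalization exploit.

Distances are Euclidean in physical micrometres between *nominal* grid
centers; normalization never depends on sub-pixel center refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ArrayLayout",
    "SpotAddress",
    "AddressError",
    "replicate_addresses",
    "NeighborFinder",
    "nearest_spots",
]


class AddressError(ValueError):
    """Raised when a spot address is not valid for a layout."""


@dataclass(frozen=True)
class ArrayLayout:
    """Physical and logical geometry of one slide.

    Parameters
    ----------
    n_sets:
        Number of replicate sets stacked vertically (default 3).
    set_rows, set_cols:
        Grid size of one set (default 32 x 32 = 1024 substrates).
    block_size:
        Edge of the square sub-grid deposited by a single spotting pin
        (default 8, i.e. 8 x 8 blocks).
    spot_pitch:
        Center-to-center spot distance in micrometres (default 560).
    spot_diameter:
        Nominal spot diameter in micrometres (default 250).
    """

    n_sets: int = 3
    set_rows: int = 32
    set_cols: int = 32
    block_size: int = 8
    spot_pitch: float = 560.0
    spot_diameter: float = 250.0

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.set_rows % self.block_size or self.set_cols % self.block_size:
            raise ValueError("set_rows and set_cols must be divisible by block_size")
        if not self.spot_pitch > self.spot_diameter:
            raise ValueError("spot_pitch must exceed spot_diameter")

    @property
    def n_substrates(self) -> int:
        return self.set_rows * self.set_cols

    @property
    def n_spots(self) -> int:
        return self.n_sets * self.n_substrates

    @property
    def total_rows(self) -> int:
        """Rows of the full logical grid (sets stacked vertically)."""
        return self.n_sets * self.set_rows

    def substrate_id(self, row: int, col: int) -> int:
        return row * self.set_cols + col

    def spot_center(self, set_index: int, row: int, col: int) -> tuple[float, float]:
        """(x, y) in micrometres; origin at the top-left spot center.

        x grows with columns, y with rows; sets continue the row axis.
        """
        y = (set_index * self.set_rows + row) * self.spot_pitch
        x = col * self.spot_pitch
        return (x, y)

    def set_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Nominal (x, y) center grids of one set, shape (set_rows, set_cols)."""
        r = np.arange(self.set_rows)[:, None] * self.spot_pitch
        c = np.arange(self.set_cols)[None, :] * self.spot_pitch
        y = np.broadcast_to(r, (self.set_rows, self.set_cols)).copy()
        x = np.broadcast_to(c, (self.set_rows, self.set_cols)).copy()
        return x, y

    def addresses(self):
        """Iterate over every SpotAddress of the layout, set-major."""
        for s in range(self.n_sets):
            for r in range(self.set_rows):
                for c in range(self.set_cols):
                    yield SpotAddress(s, r, c, self.substrate_id(r, c))


class SpotAddress(NamedTuple):
    """Logical position of one spot: set, row and column, plus the
    substrate identity shared by its replicate counterparts."""

    set_index: int
    row: int
    col: int
    substrate_id: int


def _check_address(addr: SpotAddress, layout: ArrayLayout) -> None:
    if not (0 <= addr.set_index < layout.n_sets):
        raise AddressError(f"set_index {addr.set_index} outside 0..{layout.n_sets - 1}")
    if not (0 <= addr.row < layout.set_rows and 0 <= addr.col < layout.set_cols):
        raise AddressError(f"(row, col) = ({addr.row}, {addr.col}) outside the set grid")
    if addr.substrate_id != layout.substrate_id(addr.row, addr.col):
        raise AddressError("substrate_id inconsistent with (row, col)")


def replicate_addresses(addr: SpotAddress, layout: ArrayLayout) -> list[SpotAddress]:
    """Addresses of the same substrate in the other replicate sets.

    Returns ``n_sets - 1`` addresses in ascending set order; empty for a
    single-set layout.
    """
    _check_address(addr, layout)
    return [
        SpotAddress(s, addr.row, addr.col, addr.substrate_id)
        for s in range(layout.n_sets)
        if s != addr.set_index
    ]


class NeighborFinder:
    """Stepped-radius nearest-spot search on one replicate set.

    A circle centered on the query spot is grown in steps of one spot pitch
    until it holds at least ``n_min`` eligible spots; all eligible spots
    inside the final radius are returned (ties at the boundary included),
    ordered by distance.  The query spot itself is always excluded.

    Distance order and per-spot sorted neighbour tables are computed once
    per layout and reused across eligibility masks, which is what makes the
    per-spot local medians cheap enough to run inside iterative loops.
    """

    def __init__(self, layout: ArrayLayout):
        self.layout = layout
        x, y = layout.set_centers()
        pts = np.column_stack([x.ravel(), y.ravel()])  # index = row*cols + col
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        self._order = np.argsort(d, axis=1, kind="stable")
        self._sorted_d = np.take_along_axis(d, self._order, axis=1)
        self._pitch = layout.spot_pitch

    def neighbors(self, flat_index: int, eligible: np.ndarray, n_min: int,
                  warn: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Eligible neighbour flat indices and distances for one query spot.

        ``eligible`` is a boolean mask over the ``set_rows*set_cols`` flat
        grid.  Fewer than ``n_min`` eligible spots on the whole set returns
        everything eligible with a warning.
        """
        order = self._order[flat_index]
        dists = self._sorted_d[flat_index]
        keep = eligible[order]
        keep[0] = False  # self (distance 0 sorts first)
        elig_pos = np.nonzero(keep)[0]
        if elig_pos.size < n_min:
            if warn and elig_pos.size < n_min:
                warnings.warn(
                    f"only {elig_pos.size} eligible spots available "
                    f"(requested {n_min}); returning all of them",
                    stacklevel=2,
                )
            return order[elig_pos], dists[elig_pos]
        # radius of the n_min-th eligible spot, rounded up to a pitch step
        r_need = dists[elig_pos[n_min - 1]]
        radius = self._pitch * np.ceil(r_need / self._pitch - 1e-9)
        inside = elig_pos[dists[elig_pos] <= radius + 1e-9]
        return order[inside], dists[inside]


def nearest_spots(
    addr: SpotAddress,
    table,
    n: int = 20,
    eligible: Callable | None = None,
) -> list:
    """The >= ``n`` nearest eligible spots around ``addr`` in its own set.

    ``table`` is a :class:`kinorm.spots.SpotTable`; ``eligible`` is an
    optional predicate over its per-spot records.  Returns SpotRecord-like
    rows ordered by distance (boundary ties all included).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    layout = table.layout
    _check_address(addr, layout)
    records = [table.record(SpotAddress(addr.set_index, r, c, layout.substrate_id(r, c)))
               for r in range(layout.set_rows) for c in range(layout.set_cols)]
    mask = np.ones(layout.n_substrates, dtype=bool)
    if eligible is not None:
        mask = np.array([bool(eligible(rec)) for rec in records])
    finder = table.neighbor_finder()
    flat = addr.row * layout.set_cols + addr.col
    idx, _ = finder.neighbors(flat, mask, n)
    return [records[i] for i in idx]
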