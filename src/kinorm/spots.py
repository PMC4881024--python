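"""Per-slide spot tables: net log2 intensities plus quality flags.

The canonical on-disk form is a TSV with one row per spot and columns
``slide_id, condition, set, row, col, substrate_id, x_um, y_um, net_log2``
followed by one 0/1 column per quality flag.  In memory the same data are
held as dense ``(n_sets, set_rows, set_cols)`` arrays, which is what the
normalization code operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .layout import ArrayLayout, NeighborFinder, SpotAddress

__all__ = ["FLAG_NAMES", "FlagSet", "SpotRecord", "SpotTable", "read_spot_table", "write_spot_table"]

# the seven component flags; "overall" is their logical OR
FLAG_NAMES = (
    "artifact",
    "overshine",
    "ks",
    "no_contrast",
    "saturated",
    "shape",
    "position",
)


class FlagSet(NamedTuple):
    """The eight binary quality flags of one spot (0 reliable, 1 unreliable)."""

    artifact: int = 0
    overshine: int = 0
    ks: int = 0
    no_contrast: int = 0
    saturated: int = 0
    shape: int = 0
    position: int = 0

    @property
    def overall(self) -> int:
        return int(any(self))


class SpotRecord(NamedTuple):
    address: SpotAddress
    center: tuple[float, float]  # (x, y) in micrometres
    net_log2: float  # NaN when missing
    flags: FlagSet

    @property
    def unflagged(self) -> bool:
        return not self.flags.overall and np.isfinite(self.net_log2)


_FINDER_CACHE: dict[tuple, NeighborFinder] = {}


def _finder_for(layout: ArrayLayout) -> NeighborFinder:
    key = (layout.set_rows, layout.set_cols, layout.spot_pitch)
    if key not in _FINDER_CACHE:
        _FINDER_CACHE[key] = NeighborFinder(layout)
    return _FINDER_CACHE[key]


@dataclass
class SpotTable:
    """All spots of one slide.

    ``values`` holds net log2 intensities with shape
    ``(n_sets, set_rows, set_cols)``; NaN marks a missing measurement
    (which coincides with the No-Contrast flag).  ``flags`` maps each flag
    name to a boolean array of the same shape.
    """

    layout: ArrayLayout
    values: np.ndarray
    flags: dict[str, np.ndarray] = field(default_factory=dict)
    slide_id: str = "slide"
    condition: str = ""

    def __post_init__(self) -> None:
        shape = (self.layout.n_sets, self.layout.set_rows, self.layout.set_cols)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != shape:
            raise ValueError(f"values shape {self.values.shape} != layout shape {shape}")
        for name in FLAG_NAMES:
            arr = self.flags.get(name)
            if arr is None:
                arr = np.zeros(shape, dtype=bool)
            self.flags[name] = np.asarray(arr, dtype=bool)
            if self.flags[name].shape != shape:
                raise ValueError(f"flag '{name}' has shape {self.flags[name].shape}")

    # ---------------------------------------------------------------- basics
    @classmethod
    def blank(cls, layout: ArrayLayout, slide_id: str = "slide",
              condition: str = "") -> "SpotTable":
        shape = (layout.n_sets, layout.set_rows, layout.set_cols)
        return cls(layout, np.zeros(shape), slide_id=slide_id, condition=condition)

    def copy(self) -> "SpotTable":
        return SpotTable(
            self.layout,
            self.values.copy(),
            {k: v.copy() for k, v in self.flags.items()},
            self.slide_id,
            self.condition,
        )

    @property
    def overall_flag(self) -> np.ndarray:
        """Boolean OR over the seven component flags, per spot."""
        out = np.zeros_like(self.values, dtype=bool)
        for name in FLAG_NAMES:
            out |= self.flags[name]
        return out

    @property
    def unflagged(self) -> np.ndarray:
        """Reliable spots: no flag set and a finite intensity."""
        return ~self.overall_flag & np.isfinite(self.values)

    def record(self, addr: SpotAddress) -> SpotRecord:
        s, r, c = addr.set_index, addr.row, addr.col
        flags = FlagSet(**{n: int(self.flags[n][s, r, c]) for n in FLAG_NAMES})
        return SpotRecord(addr, self.layout.spot_center(s, r, c),
                          float(self.values[s, r, c]), flags)

    def neighbor_finder(self) -> NeighborFinder:
        return _finder_for(self.layout)

    # ------------------------------------------------------------------- IO
    def to_frame(self) -> pd.DataFrame:
        lay = self.layout
        s, r, c = np.meshgrid(
            np.arange(lay.n_sets), np.arange(lay.set_rows), np.arange(lay.set_cols),
            indexing="ij",
        )
        s, r, c = s.ravel(), r.ravel(), c.ravel()
        overall = self.overall_flag
        df = pd.DataFrame(
            {
                "slide_id": self.slide_id,
                "condition": self.condition,
                "set": s,
                "row": r,
                "col": c,
                "substrate_id": r * lay.set_cols + c,
                "x_um": c * lay.spot_pitch,
                "y_um": (s * lay.set_rows + r) * lay.spot_pitch,
                "net_log2": self.values.ravel(),
            }
        )
        for name in FLAG_NAMES:
            df[f"flag_{name}"] = self.flags[name].ravel().astype(int)
        df["flag_overall"] = overall.ravel().astype(int)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, layout: ArrayLayout | None = None) -> "SpotTable":
        if layout is None:
            layout = ArrayLayout(
                n_sets=int(df["set"].max()) + 1,
                set_rows=int(df["row"].max()) + 1,
                set_cols=int(df["col"].max()) + 1,
                block_size=_infer_block(int(df["row"].max()) + 1, int(df["col"].max()) + 1),
            )
        shape = (layout.n_sets, layout.set_rows, layout.set_cols)
        if len(df) != np.prod(shape):
            raise ValueError("spot table does not cover every grid position exactly once")
        idx = (df["set"].to_numpy(), df["row"].to_numpy(), df["col"].to_numpy())
        values = np.full(shape, np.nan)
        values[idx] = df["net_log2"].to_numpy()
        flags = {}
        for name in FLAG_NAMES:
            arr = np.zeros(shape, dtype=bool)
            col = f"flag_{name}"
            if col in df:
                arr[idx] = df[col].to_numpy().astype(bool)
            flags[name] = arr
        slide_id = str(df["slide_id"].iloc[0]) if "slide_id" in df else "slide"
        condition = str(df["condition"].iloc[0]) if "condition" in df else ""
        return cls(layout, values, flags, slide_id, condition)

    @classmethod
    def from_tsv(cls, path, layout: ArrayLayout | None = None) -> "SpotTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"), layout)


def _infer_block(rows: int, cols: int) -> int:
    for b in (8, 4, 2, 1):
        if rows % b == 0 and cols % b == 0:
            return b
    return 1


def read_spot_table(path, layout: ArrayLayout | None = None) -> SpotTable:
    return SpotTable.from_tsv(path, layout)


def write_spot_table(table: SpotTable, path) -> None:
    table.to_tsv(path)
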