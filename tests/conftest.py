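"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from kinorm.layout import ArrayLayout
from kinorm.spots import SpotTable


@pytest.fixture(scope="session")
def small_layout() -> ArrayLayout:
    """Three replicate sets of 8x8 spots: fast but fully structured."""
    return ArrayLayout(n_sets=3, set_rows=8, set_cols=8, block_size=8)


@pytest.fixture(scope="session")
def mid_layout() -> ArrayLayout:
    return ArrayLayout(n_sets=3, set_rows=16, set_cols=16, block_size=8)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def random_table(layout: ArrayLayout, rng: np.random.Generator,
                 flag_fraction: float = 0.0, **kwargs) -> SpotTable:
    """A spot table with N(10, 1.5) intensities and optional random flags."""
    shape = (layout.n_sets, layout.set_rows, layout.set_cols)
    t = SpotTable(layout, rng.normal(10, 1.5, size=shape), **kwargs)
    if flag_fraction > 0:
        t.flags["artifact"] = rng.uniform(size=shape) < flag_fraction
    return t


# ------------------------------------------------------------------ oracles

def brute_force_nearest(layout: ArrayLayout, flat_query: int,
                        eligible: np.ndarray, n_min: int) -> np.ndarray:
    """Stepped-radius nearest-spot reference: full distance sort, radius
    grown in whole pitch steps until >= n_min eligible spots, boundary ties
    included.  Independent of the package's NeighborFinder."""
    x, y = layout.set_centers()
    pts = np.column_stack([x.ravel(), y.ravel()])
    d = np.hypot(*(pts - pts[flat_query]).T)
    cand = [i for i in np.argsort(d, kind="stable")
            if i != flat_query and eligible[i]]
    if len(cand) < n_min:
        return np.asarray(cand, dtype=int)
    radius = layout.spot_pitch
    while True:
        inside = [i for i in cand if d[i] <= radius + 1e-9]
        if len(inside) >= n_min:
            return np.asarray(inside, dtype=int)
        radius += layout.spot_pitch


def brute_force_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the fraction of concordant (positive, negative) pairs, ties
    counted half — the Mann-Whitney definition, by exhaustive enumeration."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins / (len(pos) * len(neg)))
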