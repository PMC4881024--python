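"""Intra-slide gradient correction from on-slide replicate sets.

Uneven kinase or peptide concentration produces smooth intensity gradients
across a slide.  Because every substrate is spotted once per replicate set,
a spot sitting in a depressed region is systematically weaker than its two
counterparts; the local median of those replicate deviations estimates the
gradient at each position, and subtracting one third of the summed local
gradients equalizes the sets exactly in the uniform-offset case.

Only unflagged spots contribute deviations and local medians; flagged spots
pass through uncorrected (they are excluded downstream anyway).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spots import SpotTable

__all__ = ["replicate_deviations", "local_gradients", "gradient_correct", "GradientCorrection"]


def replicate_deviations(table: SpotTable) -> np.ndarray:
    """Log2 deviation of every spot against its replicate counterparts.

    Returns an array of shape ``(n_sets, set_rows, set_cols, n_sets - 1)``;
    entry ``[s, r, c, k]`` is ``value[s] - value[other_k]`` where
    ``other_k`` runs over the other sets in ascending order.  NaN whenever
    either spot of the pair is flagged or missing.
    """
    lay = table.layout
    ok = table.unflagged
    vals = np.where(ok, table.values, np.nan)
    out = np.full((lay.n_sets, lay.set_rows, lay.set_cols, lay.n_sets - 1), np.nan)
    for s in range(lay.n_sets):
        others = [t for t in range(lay.n_sets) if t != s]
        for k, t in enumerate(others):
            out[s, :, :, k] = vals[s] - vals[t]
    return out


def local_gradients(
    table: SpotTable,
    deviations: np.ndarray | None = None,
    n_neighbors: int = 20,
) -> np.ndarray:
    """Per-spot local gradient estimates, shape ``(n_sets, R, C, n_sets-1)``.

    ``gradient[s, r, c, k]`` is the median deviation-against-replicate-set-k
    over the ``n_neighbors`` nearest eligible spots in set ``s`` (stepped
    circular search, self excluded).  Eligible means unflagged with all
    replicate deviations defined.  Spots with no eligible neighbour get
    gradient 0 with a warning.
    """
    lay = table.layout
    if deviations is None:
        deviations = replicate_deviations(table)
    finder = table.neighbor_finder()
    n_dev = lay.n_sets - 1
    out = np.zeros((lay.n_sets, lay.set_rows, lay.set_cols, n_dev))
    starved = 0
    for s in range(lay.n_sets):
        dev_flat = deviations[s].reshape(-1, n_dev)
        eligible = np.isfinite(dev_flat).all(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # starvation reported once below
            for i in range(lay.n_substrates):
                idx, _ = finder.neighbors(i, eligible, n_neighbors, warn=False)
                if idx.size == 0:
                    starved += 1
                    continue
                r, c = divmod(i, lay.set_cols)
                out[s, r, c] = np.median(dev_flat[idx], axis=0)
    if starved:
        warnings.warn(f"{starved} spots had no eligible neighbours; gradient set to 0",
                      stacklevel=2)
    return out


@dataclass
class GradientCorrection:
    """Corrected table plus the per-spot correction map (log2)."""

    table: SpotTable
    correction: np.ndarray  # (n_sets, R, C); 0 for flagged spots
    gradients: np.ndarray  # (n_sets, R, C, n_sets - 1)


def gradient_correct(table: SpotTable, n_neighbors: int = 20) -> GradientCorrection:
    """Subtract the local replicate-gradient correction from every spot.

    correction = (gradient_1 + ... + gradient_{n_sets-1}) / n_sets; for the
    three-set slide this is the (g1 + g2)/3 rule whose divisor makes the
    uniform-offset case equalize the sets exactly.
    """
    grads = local_gradients(table, n_neighbors=n_neighbors)
    correction = grads.sum(axis=-1) / table.layout.n_sets
    correction = np.where(table.unflagged, correction, 0.0)
    out = table.copy()
    out.values = table.values - correction
    return GradientCorrection(out, correction, grads)
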