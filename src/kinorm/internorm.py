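"""Interarray normalization: repetitive signal enhancement (RSE) and baselines.

Treatment can shift the whole intensity distribution of a kinome array, so
normalizers that force equal distributions (global median-centering,
quantile normalization) over-correct and manufacture spurious repressions.
RSE instead normalizes a control/treatment slide pair on a data-selected
*invariant set*:

1. local median-centering across the two conditions over QC-passing
   substrates, using the N nearest substrates per location;
2. quasi-stringent per-substrate t-testing (p < 0.1 on the on-slide
   triplicates) to identify substrates plausibly affected by treatment;
3. re-centering on the QC-passing, unaffected substrates only.

Steps 2-3 iterate until the exclusion set stabilizes; substrates excluded
early may re-enter later.  The converged normalization set is typically
70-90% of all substrates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .spots import SpotTable

__all__ = [
    "RSEParams",
    "RSEResult",
    "spot_means",
    "local_median_center_pair",
    "detect_affected",
    "rse_normalize",
    "median_center",
    "quantile_normalize",
]


@dataclass(frozen=True)
class RSEParams:
    """Tuning knobs of the RSE iteration.

    n_neighbors: substrates in each local-median window (default 20).
    exclusion_alpha: two-sided t-test threshold for the affected set
        (default 0.1, deliberately permissive so real effects are kept out
        of the normalization set).
    max_iterations: hard cap on test/re-center rounds.
    anchor: "symmetric" moves each slide by half the offset; "a" keeps the
        control slide fixed and moves only the treatment slide.
    """

    n_neighbors: int = 20
    exclusion_alpha: float = 0.1
    max_iterations: int = 50
    anchor: str = "symmetric"

    def __post_init__(self):
        if not 0 < self.exclusion_alpha < 1:
            raise ValueError("exclusion_alpha must be in (0, 1)")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.anchor not in ("symmetric", "a"):
            raise ValueError("anchor must be 'symmetric' or 'a'")


@dataclass
class RSEResult:
    """Outcome of one pairwise RSE run."""

    table_a: SpotTable
    table_b: SpotTable
    offsets: np.ndarray            # (R, C): local-median offset m(s) = B - A scale
    normalization_set: np.ndarray  # (R, C) bool: converged invariant set
    excluded: np.ndarray           # (R, C) bool: affected set at convergence
    iterations: int
    set_sizes: list[int] = field(default_factory=list)
    converged: bool = True


class NormalizationError(RuntimeError):
    """No usable substrates to normalize on."""


# --------------------------------------------------------------- primitives

def spot_means(table: SpotTable) -> np.ndarray:
    """Per-substrate mean of the unflagged replicate net log2 values.

    Shape ``(set_rows, set_cols)``; NaN when every replicate is flagged.
    """
    ok = table.unflagged
    vals = np.where(ok, table.values, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(vals, axis=0)


def _local_median_offsets(
    table_a: SpotTable,
    d: np.ndarray,
    eligible: np.ndarray,
    n_neighbors: int,
) -> np.ndarray:
    """m(s): median of d over the N nearest eligible substrates, self included."""
    lay = table_a.layout
    finder = table_a.neighbor_finder()
    d_flat = d.ravel()
    elig_flat = eligible.ravel()
    m = np.zeros(lay.n_substrates)
    for i in range(lay.n_substrates):
        self_in = elig_flat[i]
        need = n_neighbors - 1 if self_in else n_neighbors
        if need > 0:
            idx, _ = finder.neighbors(i, elig_flat, need, warn=False)
        else:
            idx = np.empty(0, dtype=int)
        pool = np.concatenate([[i], idx]) if self_in else idx
        if pool.size == 0:
            m[i] = 0.0
        else:
            m[i] = np.median(d_flat[pool.astype(int)])
    return m.reshape(lay.set_rows, lay.set_cols)


def local_median_center_pair(
    table_a: SpotTable,
    table_b: SpotTable,
    eligible: np.ndarray | None = None,
    n_neighbors: int = 20,
    anchor: str = "symmetric",
) -> tuple[SpotTable, SpotTable, np.ndarray]:
    """Center a slide pair on the local median cross-condition difference.

    For each substrate s, ``d(s) = meanB(s) - meanA(s)`` over eligible
    substrates and ``m(s)`` is the median of d over the ``n_neighbors``
    nearest eligible substrates (the substrate itself included when
    eligible).  Symmetric application adds ``+m/2`` to every replicate of s
    on slide A and ``-m/2`` on slide B, so the local median of B - A is
    driven to ~0 without moving the pair mean.
    """
    mean_a, mean_b = spot_means(table_a), spot_means(table_b)
    both = np.isfinite(mean_a) & np.isfinite(mean_b)
    if eligible is None:
        eligible = both
    else:
        eligible = eligible & both
    if not eligible.any():
        raise NormalizationError("no eligible substrates shared by both conditions")
    d = mean_b - mean_a
    m = _local_median_offsets(table_a, np.where(both, d, 0.0), eligible, n_neighbors)
    out_a, out_b = table_a.copy(), table_b.copy()
    if anchor == "symmetric":
        out_a.values = table_a.values + m[None, :, :] / 2.0
        out_b.values = table_b.values - m[None, :, :] / 2.0
    else:  # anchor slide A, move only B
        out_b.values = table_b.values - m[None, :, :]
    return out_a, out_b, m


def _replicate_stats(table: SpotTable):
    """Count, mean and sum of squared deviations of unflagged replicates."""
    ok = table.unflagged
    vals = np.where(ok, table.values, np.nan)
    n = ok.sum(axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals, axis=0)
        ss = np.nansum((vals - mean[None]) ** 2, axis=0)
    return n, mean, ss


def substrate_pvalues(table_a: SpotTable, table_b: SpotTable) -> np.ndarray:
    """Two-sided pooled-variance two-sample t-test per substrate.

    Uses the <= n_sets unflagged replicate values in each condition; NaN for
    substrates with fewer than 2 usable replicates on either slide.  Zero
    pooled variance resolves to p = 1 for equal means and p = 0 otherwise.
    """
    na, ma, ssa = _replicate_stats(table_a)
    nb, mb, ssb = _replicate_stats(table_b)
    testable = (na >= 2) & (nb >= 2)
    p = np.full(ma.shape, np.nan)
    if not testable.any():
        return p
    na_, nb_ = na[testable], nb[testable]
    diff = mb[testable] - ma[testable]
    df = na_ + nb_ - 2
    sp2 = (ssa[testable] + ssb[testable]) / df
    se = np.sqrt(sp2 * (1.0 / na_ + 1.0 / nb_))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    pt = 2.0 * stats.t.sf(np.abs(t), df)
    pt[se == 0] = np.where(diff[se == 0] == 0, 1.0, 0.0)
    p[testable] = pt
    return p


def detect_affected(
    table_a: SpotTable, table_b: SpotTable, alpha: float = 0.1
) -> np.ndarray:
    """Substrates whose replicate t-test indicates a condition difference.

    Returns a boolean ``(set_rows, set_cols)`` mask; substrates that cannot
    be tested (fewer than 2 unflagged replicates in either condition) are
    treated as unaffected for normalization purposes.
    """
    p = substrate_pvalues(table_a, table_b)
    return np.where(np.isnan(p), False, p < alpha)


# ----------------------------------------------------------------- RSE loop

def rse_normalize(
    table_a: SpotTable,
    table_b: SpotTable,
    params: RSEParams = RSEParams(),
) -> RSEResult:
    """Run the full RSE iteration on one gradient-corrected slide pair.

    Iteration 0 centers on every QC-passing substrate; each round then
    re-tests the currently centered pair, rebuilds the centering *from the
    original tables* with the new exclusion set (so early exclusions can
    re-enter), and stops when the exclusion set repeats.  A cycle longer
    than one state returns the union of the cycling sets with a warning.
    """
    mean_a, mean_b = spot_means(table_a), spot_means(table_b)
    qc_pass = np.isfinite(mean_a) & np.isfinite(mean_b)
    if not qc_pass.any():
        raise NormalizationError("no QC-passing substrates shared by both slides")

    def center(norm_set: np.ndarray):
        return local_median_center_pair(
            table_a, table_b, eligible=norm_set,
            n_neighbors=params.n_neighbors, anchor=params.anchor,
        )

    cur_a, cur_b, offsets = center(qc_pass)
    history: list[frozenset] = [frozenset()]  # iteration-0 exclusion set
    set_sizes: list[int] = [int(qc_pass.sum())]
    excluded = np.zeros_like(qc_pass)
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        affected = detect_affected(cur_a, cur_b, params.exclusion_alpha) & qc_pass
        key = frozenset(np.flatnonzero(affected.ravel()).tolist())
        if history and key == history[-1]:
            excluded, converged = affected, True
            break
        if key in history:  # cycle: normalize on the union of the cycling sets
            cyc = history[history.index(key):] + [key]
            union = np.zeros_like(qc_pass).ravel()
            for k in cyc:
                union[list(k)] = True
            excluded = union.reshape(qc_pass.shape) & qc_pass
            warnings.warn(
                f"RSE exclusion set cycles with period {len(cyc) - 1}; "
                "normalizing on the complement of the union", stacklevel=2)
            cur_a, cur_b, offsets = center(qc_pass & ~excluded)
            set_sizes.append(int((qc_pass & ~excluded).sum()))
            converged = True
            break
        history.append(key)
        excluded = affected
        norm_set = qc_pass & ~excluded
        if not norm_set.any():
            raise NormalizationError("every QC-passing substrate tested as affected")
        cur_a, cur_b, offsets = center(norm_set)
        set_sizes.append(int(norm_set.sum()))
    else:
        warnings.warn("RSE did not converge within max_iterations; "
                      "returning the last state", stacklevel=2)

    norm_set = qc_pass & ~excluded
    cur_a, cur_b, offsets = center(norm_set)
    return RSEResult(
        table_a=cur_a,
        table_b=cur_b,
        offsets=offsets,
        normalization_set=norm_set,
        excluded=excluded,
        iterations=iterations,
        set_sizes=set_sizes,
        converged=converged,
    )


# ---------------------------------------------------------------- baselines

def median_center(tables: list[SpotTable]) -> list[SpotTable]:
    """Global median-centering over ALL spots, quality flags ignored.

    Each slide is shifted so its overall median net log2 equals the grand
    median of the slide medians.  This is the naive baseline the invariant-
    set approach is measured against.
    """
    if len(tables) < 2:
        raise ValueError("median centering needs at least 2 tables")
    meds = [float(np.nanmedian(t.values)) for t in tables]
    grand = float(np.median(meds))
    out = []
    for t, med in zip(tables, meds):
        c = t.copy()
        c.values = t.values - med + grand
        out.append(c)
    return out


def quantile_normalize(tables: list[SpotTable]) -> list[SpotTable]:
    """Order-statistic (Bolstad-style) quantile normalization across slides.

    Every finite value is replaced by the across-slide mean of its rank's
    order statistics; ties receive the mean of their tied quantile values.
    Missing values are left untouched and excluded from quantile estimation;
    slides with unequal finite counts are handled by interpolating each
    slide's empirical quantile function on a common probability grid.
    """
    if len(tables) < 2:
        raise ValueError("quantile normalization needs at least 2 tables")
    finite_vals = [t.values[np.isfinite(t.values)] for t in tables]
    counts = [v.size for v in finite_vals]
    if min(counts) == 0:
        raise ValueError("a table has no finite values")
    sorted_vals = [np.sort(v) for v in finite_vals]
    if len(set(counts)) == 1:
        reference = np.mean(sorted_vals, axis=0)  # mean of order statistics
        n = counts[0]
        probs = None
    else:
        n = max(counts)
        probs = np.linspace(0, 1, n)
        reference = np.mean(
            [np.interp(probs, np.linspace(0, 1, c), sv)
             for c, sv in zip(counts, sorted_vals)],
            axis=0,
        )
    out = []
    for t, vals, c in zip(tables, finite_vals, counts):
        new = t.copy()
        ranks = stats.rankdata(vals, method="average") - 1.0  # 0-based, ties averaged
        if c != n:
            ranks = ranks * (n - 1) / (c - 1) if c > 1 else ranks
        repl = np.interp(ranks, np.arange(n), reference)
        new.values = t.values.copy()
        new.values[np.isfinite(t.values)] = repl
        out.append(new)
    return out
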