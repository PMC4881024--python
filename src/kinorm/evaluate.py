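"""Truth-based evaluation: per-spot t-tests, ROC/AUC, pathway-level tests.

Because the simulator controls which substrates are induced, every
per-substrate t-test outcome can be classified as TP/FP/TN/FN, and the
p-values swept into a ROC curve whose area summarizes how well an analysis
(normalization included) separates induced from unaffected substrates.
Pathway-level tests aggregate all substrates annotated to one pathway with
a paired t-test, which is more sensitive than single-spot testing but also
more easily misled by normalization bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics

from .internorm import (
    RSEParams,
    median_center,
    quantile_normalize,
    rse_normalize,
    spot_means,
    substrate_pvalues,
)
from .intranorm import gradient_correct
from .simulate import SimulationConfig, simulate_experiment
from .spots import SpotTable

__all__ = [
    "EvaluationResult",
    "spot_tests",
    "classify_and_roc",
    "pathway_tests",
    "benchmark",
    "NORMALIZERS",
]


@dataclass
class EvaluationResult:
    """Classification of per-substrate calls against the simulated truth."""

    pvalues: np.ndarray          # per tested substrate
    truth: np.ndarray            # bool, aligned with pvalues
    calls: np.ndarray            # bool: p < alpha
    tp: int
    fp: int
    tn: int
    fn: int
    fpr: np.ndarray              # ROC curve points
    tpr: np.ndarray
    auc: float


def spot_tests(table_a: SpotTable, table_b: SpotTable) -> np.ndarray:
    """Per-substrate two-sided pooled t-test p-values (NaN = untestable).

    Same test variant as the RSE exclusion step: two-sample Student t on the
    unflagged replicate triplets of the two conditions.
    """
    return substrate_pvalues(table_a, table_b)


def classify_and_roc(
    pvals: np.ndarray, truth: np.ndarray, alpha: float = 0.05
) -> EvaluationResult:
    """Confusion counts at ``alpha`` plus the ROC over all p-value thresholds.

    Substrates with NaN p-values are omitted.  The ROC score is ``-p``
    (smaller p = more positive); the trapezoidal AUC then equals the
    Mann-Whitney statistic of the p-values against the truth labels.
    """
    pvals = np.asarray(pvals, dtype=float).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    ok = np.isfinite(pvals)
    p, y = pvals[ok], truth[ok]
    if y.all() or not y.any():
        raise ValueError("truth labels contain a single class; AUC undefined")
    calls = p < alpha
    tp = int(np.sum(calls & y))
    fp = int(np.sum(calls & ~y))
    fn = int(np.sum(~calls & y))
    tn = int(np.sum(~calls & ~y))
    fpr, tpr, _ = metrics.roc_curve(y.astype(int), -p)
    auc = float(metrics.auc(fpr, tpr))
    return EvaluationResult(p, y, calls, tp, fp, tn, fn, fpr, tpr, auc)


def pathway_tests(
    table_a: SpotTable,
    table_b: SpotTable,
    annotation: pd.DataFrame,
    min_substrates: int = 3,
    level: str = "pathway",
) -> pd.DataFrame:
    """Paired t-test per pathway (or kinase) across its substrates.

    Each substrate contributes one pair: its triplicate mean in condition A
    vs condition B.  Substrates missing in either condition are dropped;
    groups with fewer than ``min_substrates`` usable substrates are skipped.
    Returns a frame with columns group, n_substrates, p_value, direction
    (sign of the mean paired difference) and mean_diff.
    """
    if level not in ("pathway", "kinase"):
        raise ValueError("level must be 'pathway' or 'kinase'")
    mean_a = spot_means(table_a).ravel()
    mean_b = spot_means(table_b).ravel()
    rows = []
    for group, sub in annotation.groupby(level):
        sids = sub["substrate_id"].to_numpy()
        a, b = mean_a[sids], mean_b[sids]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < min_substrates:
            warnings.warn(f"{level} '{group}' has fewer than {min_substrates} "
                          "usable substrates; skipped", stacklevel=2)
            continue
        diff = b[ok] - a[ok]
        if np.allclose(diff, diff[0]):
            p = 0.0 if diff[0] != 0 else 1.0
        else:
            p = float(stats.ttest_rel(b[ok], a[ok]).pvalue)
        rows.append((group, int(ok.sum()), p,
                     int(np.sign(diff.mean())), float(diff.mean())))
    return pd.DataFrame(rows, columns=[level, "n_substrates", "p_value",
                                       "direction", "mean_diff"])


# ---------------------------------------------------------------- benchmark

def _norm_raw(a, b, params):
    return a, b


def _norm_median(a, b, params):
    return tuple(median_center([a, b]))


def _norm_quantile(a, b, params):
    return tuple(quantile_normalize([a, b]))


def _norm_rse(a, b, params):
    res = rse_normalize(a, b, params)
    return res.table_a, res.table_b


NORMALIZERS = {
    "raw": _norm_raw,
    "median": _norm_median,
    "quantile": _norm_quantile,
    "rse": _norm_rse,
}


def benchmark(
    configs: list[SimulationConfig],
    normalizers: list[str],
    gradient_correction: bool = True,
    alpha: float = 0.05,
    rse_params: RSEParams = RSEParams(),
    n_neighbors: int = 20,
) -> pd.DataFrame:
    """AUC of substrate classification per config cell and normalizer.

    For each config: simulate, optionally gradient-correct every slide,
    apply each normalizer per control/treatment pair, t-test, and compute
    the per-patient AUC against the simulated truth.  Returns a tidy frame
    with one row per (cell, normalizer): mean AUC over patients and SEM.
    """
    unknown = set(normalizers) - set(NORMALIZERS)
    if unknown:
        raise ValueError(f"unknown normalizer(s): {sorted(unknown)}")
    rows = []
    for cell, config in enumerate(configs):
        exp = simulate_experiment(config)
        pairs = exp.pairs
        if gradient_correction:
            pairs = [
                (gradient_correct(a, n_neighbors).table, gradient_correct(b, n_neighbors).table)
                for a, b in pairs
            ]
        for name in normalizers:
            fn = NORMALIZERS[name]
            aucs = []
            for a, b in pairs:
                na, nb = fn(a, b, rse_params)
                res = classify_and_roc(spot_tests(na, nb).ravel(),
                                       exp.induced.ravel(), alpha)
                aucs.append(res.auc)
            aucs = np.asarray(aucs)
            sem = aucs.std(ddof=1) / np.sqrt(len(aucs)) if len(aucs) > 1 else 0.0
            rows.append((cell, config.seed, name, float(aucs.mean()), float(sem),
                         len(aucs)))
    return pd.DataFrame(rows, columns=["cell", "seed", "normalizer",
                                       "mean_auc", "sem", "n_patients"])
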