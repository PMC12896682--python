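"""Forecast metrics, confusion-matrix risk policies, correlation and
significance testing.

Confusion-matrix conventions: rows are true classes, columns predictions;
macro scores are unweighted means over classes; a class never predicted
gets precision 0 with an explicit flag (the conservative choice when a
missed deterioration costs more than a false alarm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# regression metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForecastMetricReport:
    mse: float
    mae: float
    rmse: float
    r2: float | None
    r2_reason: str | None = None


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray
                       ) -> ForecastMetricReport:
    """MSE/MAE/RMSE and R^2 (1 - SS_res/SS_tot about the mean of y_true)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    err = y_pred - y_true
    mse = float((err**2).mean())
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt(mse))
    ss_tot = float(((y_true - y_true.mean())**2).sum())
    if y_true.size < 2 or ss_tot == 0.0:
        return ForecastMetricReport(mse, mae, rmse, None,
                                    "constant y_true: R^2 undefined")
    r2 = 1.0 - float((err**2).sum()) / ss_tot
    return ForecastMetricReport(mse, mae, rmse, r2)


def relative_reduction(baseline: float, value: float) -> dict[str, float]:
    """Absolute and percentage reduction of ``value`` below ``baseline``."""
    absolute = baseline - value
    return {"absolute": absolute, "percent": 100.0 * absolute / baseline}


# ---------------------------------------------------------------------------
# confusion matrices
# ---------------------------------------------------------------------------

def confusion_from_labels(true: np.ndarray, pred: np.ndarray,
                          K: int) -> np.ndarray:
    """K x K count matrix; C[i, j] = #(true i predicted j)."""
    true = np.asarray(true, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if true.shape != pred.shape:
        raise ValueError("label arrays must have equal length")
    if len(true) and (true.min() < 0 or pred.min() < 0
                      or true.max() >= K or pred.max() >= K):
        raise ValueError(f"labels out of range 0..{K - 1}")
    C = np.zeros((K, K), dtype=int)
    np.add.at(C, (true, pred), 1)
    return C


@dataclass(frozen=True)
class ClassMetricReport:
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    undefined_precision: np.ndarray  # True where TP+FP == 0 (reported as 0)
    undefined_recall: np.ndarray     # True where TP+FN == 0 (reported as 0)


def class_metrics(C: np.ndarray) -> ClassMetricReport:
    """Per-class and macro precision/recall/F1 from a confusion matrix."""
    C = np.asarray(C)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (C < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    total = C.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(C).astype(float)
    fp = C.sum(axis=0) - tp
    fn = C.sum(axis=1) - tp
    tn = total - tp - fp - fn
    undef_p = (tp + fp) == 0
    undef_r = (tp + fn) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(undef_p, 0.0, tp / np.where(undef_p, 1, tp + fp))
        recall = np.where(undef_r, 0.0, tp / np.where(undef_r, 1, tp + fn))
        pr = precision + recall
        f1 = np.where(pr == 0, 0.0, 2 * precision * recall / np.where(pr == 0, 1, pr))
    return ClassMetricReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        precision=precision, recall=recall, f1=f1,
        accuracy=float(tp.sum() / total),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        undefined_precision=undef_p, undefined_recall=undef_r)


def merge_classes(C: np.ndarray, groups: list[list[int]]
                  ) -> tuple[np.ndarray, ClassMetricReport]:
    """Merge class groups (summing rows and columns) and re-score.

    ``groups`` must partition 0..K-1; group order defines the merged class
    order.
    """
    C = np.asarray(C)
    K = C.shape[0]
    flat = sorted(i for g in groups for i in g)
    if flat != list(range(K)):
        raise ValueError("groups must partition the class index range")
    M = np.zeros((len(groups), len(groups)), dtype=C.dtype)
    for a, ga in enumerate(groups):
        for b, gb in enumerate(groups):
            M[a, b] = C[np.ix_(ga, gb)].sum()
    return M, class_metrics(M)


def alert_threshold_policy(C: np.ndarray, cutoff_label: int,
                           high_risk: tuple[int, ...] = (3, 4)
                           ) -> dict[str, float]:
    """Conservative alert policy on a confusion matrix.

    A sample is alerted when its predicted label is >= ``cutoff_label``;
    misses are true high-risk samples left un-alerted.
    """
    C = np.asarray(C)
    K = C.shape[0]
    if not 0 <= cutoff_label <= K:
        raise ValueError("cutoff outside label range")
    hr = list(high_risk)
    n_high = int(C[hr, :].sum())
    misses = int(C[np.ix_(hr, list(range(min(cutoff_label, K))))].sum())
    miss_rate = misses / n_high if n_high else 0.0
    return {"misses": misses, "n_high_risk": n_high,
            "miss_rate": miss_rate, "recall": 1.0 - miss_rate}


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def pearson_matrix(table: pd.DataFrame | np.ndarray,
                   features: list[str] | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r with BH-adjusted two-tailed p-values.

    Benjamini-Hochberg runs across the D(D-1)/2 upper-triangle tests.
    Zero-variance columns give missing (NaN) entries.
    """
    if isinstance(table, pd.DataFrame):
        frame = table[features] if features else table.select_dtypes("number")
    else:
        X = np.asarray(table, dtype=float)
        names = features or [f"f{i}" for i in range(X.shape[1])]
        frame = pd.DataFrame(X, columns=names)
    if len(frame) < 3:
        raise ValueError("need at least 3 rows for correlation tests")
    cols = list(frame.columns)
    D = len(cols)
    R = np.eye(D)
    P = np.zeros((D, D))
    raw_p, pairs = [], []
    for i in range(D):
        for j in range(i + 1, D):
            x, y = frame[cols[i]].to_numpy(), frame[cols[j]].to_numpy()
            if x.std() == 0 or y.std() == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, y)
            R[i, j] = R[j, i] = r
            raw_p.append(p)
            pairs.append((i, j))
    valid = ~np.isnan(raw_p)
    adj = np.full(len(raw_p), np.nan)
    if valid.any():
        adj[valid] = multipletests(np.asarray(raw_p)[valid],
                                   method="fdr_bh")[1]
    for (i, j), p in zip(pairs, adj):
        P[i, j] = P[j, i] = p
    np.fill_diagonal(P, 0.0)
    for i in range(D):
        if frame[cols[i]].std() == 0:
            R[i, i] = np.nan
    return (pd.DataFrame(R, index=cols, columns=cols),
            pd.DataFrame(P, index=cols, columns=cols))


# ---------------------------------------------------------------------------
# paired significance tests over the seed set
# ---------------------------------------------------------------------------

def significance_mark(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def paired_seed_tests(runs_a: np.ndarray, runs_b: np.ndarray,
                      config_names: list[str] | None = None) -> pd.DataFrame:
    """Paired two-tailed t-tests per configuration, Holm-adjusted across them.

    ``runs_a``/``runs_b`` are (n_configs, n_seeds) paired metric arrays from
    identical seeds and splits.  Zero-variance differences are degenerate:
    p is reported as 1 with a flag, and no significance mark is given.
    """
    A = np.atleast_2d(np.asarray(runs_a, dtype=float))
    B = np.atleast_2d(np.asarray(runs_b, dtype=float))
    if A.shape != B.shape:
        raise ValueError("paired runs must have identical shape")
    if A.shape[1] < 2:
        raise ValueError("need at least 2 paired runs per configuration")
    names = config_names or [f"config_{i}" for i in range(A.shape[0])]
    rows = []
    for name, a, b in zip(names, A, B):
        diff = a - b
        if np.allclose(diff.std(), 0.0):
            rows.append({"config": name, "t": np.nan, "p": 1.0,
                         "degenerate": True})
        else:
            t, p = stats.ttest_rel(a, b)
            rows.append({"config": name, "t": float(t), "p": float(p),
                         "degenerate": False})
    table = pd.DataFrame(rows)
    table["p_holm"] = multipletests(table["p"].to_numpy(), method="holm")[1]
    table["mark"] = [
        "" if d else significance_mark(p)
        for d, p in zip(table["degenerate"], table["p_holm"])]
    return table


def seed_set_report(per_seed: dict[str, dict[str, list[float]]],
                    proposed: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean +/- std metric table over the seed set with significance marks.

    ``per_seed[model][metric]`` holds one value per seed.  Each baseline is
    compared with the ``proposed`` model by paired t-tests on every metric,
    Holm-adjusted across baselines, and the baseline rows carry the marks.
    """
    models = list(per_seed)
    metrics = list(per_seed[proposed])
    summary = pd.DataFrame({
        metric: {
            m: f"{np.mean(per_seed[m][metric]):.4f} ± "
               f"{np.std(per_seed[m][metric]):.4f}"
            for m in models
        } for metric in metrics
    })
    tests = []
    baselines = [m for m in models if m != proposed]
    for metric in metrics:
        if not baselines:
            continue
        A = np.array([per_seed[m][metric] for m in baselines])
        B = np.array([per_seed[proposed][metric]] * len(baselines))
        t = paired_seed_tests(A, B, config_names=baselines)
        t.insert(0, "metric", metric)
        tests.append(t)
    tests = pd.concat(tests, ignore_index=True) if tests else pd.DataFrame()
    return summary, tests
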