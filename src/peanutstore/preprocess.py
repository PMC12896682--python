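"""Standardization, leakage-safe chronological splitting, sliding windows.

The supervised layout follows the usual long-horizon forecasting protocol:
z-score features with statistics fitted on the training span only, split the
series chronologically 8:1:1, then slide a 16-day window with stride 1
inside each partition so no window straddles a split boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import ENV_FEATURES, INDICATORS

#: Model feature columns: six quality indicators then the two environment
#: features, so targets are always the first six output dimensions.
FEATURES = INDICATORS + ENV_FEATURES

_EPS = 1e-12


class ConstantFeatureWarning(UserWarning):
    """A feature had zero variance on the training rows."""


@dataclass
class ScalerParams:
    """Per-feature z-score parameters (population sigma by default)."""

    mean: np.ndarray
    std: np.ndarray
    features: list[str]
    constant: np.ndarray = field(default=None)

    def transform(self, X: np.ndarray) -> np.ndarray:
        safe_std = np.where(self.std < _EPS, _EPS, self.std)
        out = (np.asarray(X, dtype=float) - self.mean) / safe_std
        if self.constant.any():
            out[..., self.constant] = 0.0
        return out

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        safe_std = np.where(self.std < _EPS, _EPS, self.std)
        return np.asarray(X, dtype=float) * safe_std + self.mean


def fit_scaler(train_rows: np.ndarray | pd.DataFrame,
               features: list[str] | None = None,
               ddof: int = 0) -> ScalerParams:
    """Fit z-score parameters on training rows only.

    ``ddof=0`` is the population convention; pass ``ddof=1`` for the sample
    convention.  Constant features are flagged and transformed to zeros.
    """
    if isinstance(train_rows, pd.DataFrame):
        features = features or [f for f in FEATURES if f in train_rows.columns]
        X = train_rows[features].to_numpy(dtype=float)
    else:
        X = np.asarray(train_rows, dtype=float)
        features = features or [f"f{i}" for i in range(X.shape[-1])]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows to fit a scaler")
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=ddof)
    constant = std < _EPS
    if constant.any():
        names = [f for f, c in zip(features, constant) if c]
        warnings.warn(f"constant feature(s) {names}: sigma=0, transform "
                      "returns zeros", ConstantFeatureWarning, stacklevel=2)
    return ScalerParams(mean=mean, std=std, features=list(features),
                        constant=constant)


@dataclass(frozen=True)
class SplitIndex:
    """Contiguous day ranges (1-based, inclusive) for train/val/test."""

    train: tuple[int, int]
    val: tuple[int, int]
    test: tuple[int, int]
    ratios: tuple[float, float, float]

    def counts(self) -> tuple[int, int, int]:
        return tuple(hi - lo + 1 for lo, hi in (self.train, self.val, self.test))

    def partition_days(self, name: str) -> np.ndarray:
        lo, hi = getattr(self, name)
        return np.arange(lo, hi + 1)


def chronological_split(n_days: int,
                        ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                        ) -> SplitIndex:
    """Split ``n_days`` consecutive days into train/val/test blocks.

    Validation and test sizes are floored; the remainder goes to training,
    so 630 days at 8:1:1 gives 504/63/63.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ValueError("need three positive ratios")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    if n_days < 3:
        raise ValueError("need at least 3 days to split three ways")
    n_val = int(np.floor(n_days * ratios[1]))
    n_test = int(np.floor(n_days * ratios[2]))
    n_train = n_days - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("a partition would be empty")
    return SplitIndex(
        train=(1, n_train),
        val=(n_train + 1, n_train + n_val),
        test=(n_train + n_val + 1, n_days),
        ratios=ratios,
    )


def split_table(table: pd.DataFrame, split: SplitIndex) -> dict[str, pd.DataFrame]:
    """Partition a storage table by day membership."""
    out = {}
    for name in ("train", "val", "test"):
        lo, hi = getattr(split, name)
        out[name] = table[(table["day"] >= lo) & (table["day"] <= hi)].copy()
    return out


def fill_missing(frame: pd.DataFrame,
                 columns: list[str] | None = None) -> pd.DataFrame:
    """Forward-fill then mean-fill within one partition (leakage-safe)."""
    frame = frame.copy()
    columns = columns or [c for c in FEATURES if c in frame.columns]
    frame[columns] = frame[columns].ffill()
    frame[columns] = frame[columns].fillna(frame[columns].mean())
    return frame


@dataclass(frozen=True)
class WindowSample:
    """One supervised instance: L-day input block plus its target."""

    X: np.ndarray          # (L, D) standardized features
    y: np.ndarray | float  # (h, D) horizon block or scalar end label
    t: int                 # end-day index of the window


def window_count(t_part: int, L: int = 16, horizon: int = 0) -> int:
    """Closed-form number of stride-1 windows in a partition of t_part steps."""
    return max(t_part - L - horizon + 1, 0)


def make_windows(series: np.ndarray, L: int = 16, stride: int = 1,
                 horizon: int = 0, labels: np.ndarray | None = None,
                 partition_name: str = "partition",
                 day_offset: int = 0):
    """Slide an L-step window over one partition's series.

    In end-label mode (``horizon=0``) the target is the label (or feature
    row) of the window's last day; in horizon mode it is the next
    ``horizon`` rows.  Returns ``(X, y, t_end)`` arrays; ``t_end`` holds
    1-based end-day indices offset by ``day_offset``.
    """
    series = np.asarray(series, dtype=float)
    t_part = series.shape[0]
    needed = L if horizon == 0 else L + horizon
    if t_part < needed:
        raise ValueError(
            f"{partition_name} has {t_part} steps, needs >= {needed} for "
            f"L={L}" + (f", horizon={horizon}" if horizon else ""))
    starts = np.arange(0, t_part - needed + 1, stride)
    X = np.stack([series[s:s + L] for s in starts])
    ends = starts + L - 1
    if horizon == 0:
        if labels is not None:
            y = np.asarray(labels)[ends]
        else:
            y = series[ends]
    else:
        y = np.stack([series[e + 1:e + 1 + horizon] for e in ends])
    return X, y, ends + 1 + day_offset


def window_dataset(table: pd.DataFrame, split: SplitIndex, L: int = 16,
                   horizon: int = 0, stride: int = 1,
                   scaler: ScalerParams | None = None,
                   features: list[str] | None = None):
    """Build pooled per-condition window sets for each partition.

    Windows are built independently within each condition's series and each
    chronological partition, then pooled, so windows never mix conditions
    nor cross split boundaries.  Returns ``(datasets, scaler)`` where
    ``datasets[name]`` holds stacked ``X`` (n, L, D), ``y``, end days and
    condition ids.
    """
    features = features or [f for f in FEATURES if f in table.columns]
    parts = {k: fill_missing(v, features) for k, v in split_table(table, split).items()}
    if scaler is None:
        scaler = fit_scaler(parts["train"], features)
    datasets = {}
    for name, part in parts.items():
        xs, ys, ts, cs = [], [], [], []
        for cond, group in part.groupby("condition_id", sort=True):
            group = group.sort_values("day")
            std = scaler.transform(group[features].to_numpy(dtype=float))
            lo = int(group["day"].min())
            X, y, t = make_windows(std, L=L, stride=stride, horizon=horizon,
                                   partition_name=f"{name}/condition {cond}",
                                   day_offset=lo - 1)
            xs.append(X)
            ys.append(y)
            ts.append(t)
            cs.append(np.full(len(t), cond))
        datasets[name] = {
            "X": np.concatenate(xs),
            "y": np.concatenate(ys),
            "t": np.concatenate(ts),
            "condition": np.concatenate(cs),
        }
    return datasets, scaler
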