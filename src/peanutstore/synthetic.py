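"""Synthetic peanut storage-degradation data.

Real storage trials take months of chamber time; this module generates
daily multivariate records with the statistical structure such trials show:
monotone saturating hydrolysis/oxidation indicators whose rates grow with
temperature, declining flavour volatile and moisture, and strong
cross-indicator correlation induced by the shared time-temperature drive.

The trajectory of each indicator follows a saturating exponential

    x(t) = A - (A - x0) * exp(-r * t),        r = base_rate * multiplier(T)

with additive Gaussian observation noise truncated at physical bounds.
Asymptotes ``A`` sit beyond the worst published grade profile so a full
210-day run traverses the whole quality range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import DECREASING, GRADE_PROFILES, INCREASING, INDICATORS

#: CSV header names for on-disk storage tables, in column order.
CSV_COLUMNS = {
    "day": "day index",
    "condition_id": "condition id",
    "temperature": "temperature (°C)",
    "humidity": "relative humidity (%)",
    "fatty_acid": "fatty acid content (%)",
    "carbonyl": "carbonyl content (μmol/g)",
    "peroxide_value": "peroxide value (mmol/kg)",
    "acid_value": "acid value (mg/g)",
    "phenylacetaldehyde": "phenylacetaldehyde (μg/kg)",
    "moisture": "moisture content (%)",
}


@dataclass(frozen=True)
class ConditionSpec:
    """One constant temperature/humidity storage chamber."""

    condition_id: int
    temperature: float  # deg C
    humidity: float     # % RH
    rate_multiplier: float  # scales degradation kinetics, >= 0

    def __post_init__(self):
        if not np.isfinite(self.temperature):
            raise ValueError("temperature must be finite")
        if not 0.0 < self.humidity <= 100.0:
            raise ValueError("humidity must be in (0, 100]")
        if self.rate_multiplier < 0:
            raise ValueError("rate_multiplier must be >= 0")


@dataclass
class KineticParams:
    """Per-indicator saturating-exponential kinetics and noise levels.

    ``temperature_sensitivity`` is a Q10-style factor: the default condition
    rate multipliers scale by this factor per 10 deg C away from 25 deg C.
    """

    initial: dict[str, float] = field(default_factory=lambda: {
        ind: GRADE_PROFILES[1][i] for i, ind in enumerate(INDICATORS)})
    asymptote: dict[str, float] = field(default_factory=lambda: {
        "fatty_acid": 90.0, "carbonyl": 130.0, "peroxide_value": 4.5,
        "acid_value": 2.0, "phenylacetaldehyde": 3.0, "moisture": 4.5})
    base_rate: dict[str, float] = field(default_factory=lambda: {
        "fatty_acid": 0.004, "carbonyl": 0.004, "peroxide_value": 0.005,
        "acid_value": 0.0045, "phenylacetaldehyde": 0.012, "moisture": 0.006})
    noise_sd: dict[str, float] = field(default_factory=lambda: {
        "fatty_acid": 1.0, "carbonyl": 2.0, "peroxide_value": 0.08,
        "acid_value": 0.03, "phenylacetaldehyde": 2.0, "moisture": 0.05})
    temperature_sensitivity: float = 2.0
    seed: int = 2021

    def __post_init__(self):
        for ind in INDICATORS:
            if self.base_rate[ind] < 0:
                raise ValueError(f"negative base rate for {ind}")
            if ind in INCREASING and self.asymptote[ind] <= self.initial[ind]:
                raise ValueError(
                    f"increasing indicator {ind} needs asymptote > initial")
            if ind in DECREASING and self.asymptote[ind] >= self.initial[ind]:
                raise ValueError(
                    f"decreasing indicator {ind} needs asymptote < initial")

    def to_dict(self) -> dict:
        return {
            "initial": dict(self.initial),
            "asymptote": dict(self.asymptote),
            "base_rate": dict(self.base_rate),
            "noise_sd": dict(self.noise_sd),
            "temperature_sensitivity": self.temperature_sensitivity,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        return cls(**d)


#: Physical lower bounds used to truncate observation noise.
_LOWER_BOUND = {ind: 0.0 for ind in INDICATORS}
_LOWER_BOUND["moisture"] = 1e-6


def default_conditions(params: KineticParams | None = None) -> list[ConditionSpec]:
    """The three standard chambers: 15/65, 25/70, 35/75 (deg C / % RH)."""
    q10 = (params or KineticParams()).temperature_sensitivity
    return [
        ConditionSpec(1, 15.0, 65.0, q10 ** (-1.0)),
        ConditionSpec(2, 25.0, 70.0, 1.0),
        ConditionSpec(3, 35.0, 75.0, q10 ** (1.0)),
    ]


def _trajectory(ind: str, params: KineticParams, mult: float,
                days: np.ndarray) -> np.ndarray:
    x0 = params.initial[ind]
    a = params.asymptote[ind]
    r = params.base_rate[ind] * mult
    return a - (a - x0) * np.exp(-r * days)


def simulate_storage(conditions: list[ConditionSpec] | None = None,
                     params: KineticParams | None = None,
                     n_days: int = 210,
                     n_replicates: int = 1) -> pd.DataFrame:
    """Simulate daily storage records for every condition.

    Returns a tidy table with one row per (day, condition[, replicate]);
    days run 1..n_days.  Deterministic given ``params.seed``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    params = params or KineticParams()
    conditions = conditions if conditions is not None else default_conditions(params)
    if not conditions:
        raise ValueError("at least one condition required")

    rng = np.random.default_rng(params.seed)
    days = np.arange(1, n_days + 1, dtype=float)
    frames = []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            rec = {
                "day": days.astype(int),
                "condition_id": cond.condition_id,
                "temperature": cond.temperature,
                "humidity": cond.humidity,
            }
            for ind in INDICATORS:
                clean = _trajectory(ind, params, cond.rate_multiplier, days)
                if np.any(clean < _LOWER_BOUND[ind]):
                    raise ValueError(
                        f"kinetics for {ind} violate physical bounds; "
                        "check initial/asymptote configuration")
                noisy = clean + rng.normal(0.0, params.noise_sd[ind], n_days)
                rec[ind] = np.maximum(noisy, _LOWER_BOUND[ind])
            frame = pd.DataFrame(rec)
            if n_replicates > 1:
                frame["replicate"] = rep
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def grade_reference_profiles() -> dict[int, np.ndarray]:
    """Mean six-indicator vector of each quality grade (1..5)."""
    return {g: np.asarray(v, dtype=float) for g, v in GRADE_PROFILES.items()}


def standardized_grade_profiles() -> np.ndarray:
    """Grade profiles z-scored per indicator across the five grades."""
    profiles = np.stack([GRADE_PROFILES[g] for g in range(1, 6)]).astype(float)
    mu = profiles.mean(axis=0)
    sd = profiles.std(axis=0)
    return (profiles - mu) / sd


def make_blob_fixture(k: int, n_per_cluster: int, separation: float = 8.0,
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian clusters centred on standardized grade profiles.

    ``separation`` is the ratio of unit centre scale to cluster spread: the
    point scatter around each centre has standard deviation 1/separation.
    """
    if k < 1 or n_per_cluster < 1:
        raise ValueError("k and n_per_cluster must be >= 1")
    if k > 5:
        raise ValueError("only 5 grade reference profiles available as centres")
    rng = np.random.default_rng(seed)
    centres = standardized_grade_profiles()[:k]
    X = np.concatenate([
        c + rng.normal(0.0, 1.0 / separation, (n_per_cluster, centres.shape[1]))
        for c in centres
    ])
    labels = np.repeat(np.arange(k), n_per_cluster)
    return X, labels


def write_table(table: pd.DataFrame, path) -> None:
    """Write a storage table as CSV with the descriptive header names."""
    out = table.rename(columns=CSV_COLUMNS)
    out.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a storage table CSV written by :func:`write_table`."""
    inverse = {v: k for k, v in CSV_COLUMNS.items()}
    table = pd.read_csv(path).rename(columns=inverse)
    missing = [c for c in CSV_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"storage table is missing columns: {missing}")
    return table
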