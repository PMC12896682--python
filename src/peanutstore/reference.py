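"""Published reference values for peanut storage-quality grading.

These constants are inputs to the package: per-grade indicator means, the
grade score thresholds, the per-grade classification counts of the published
five-grade confusion study, and the published forecaster comparison metrics.
They seed synthetic fixtures, orient the quality score, and feed the
evaluation arithmetic; nothing here is a computed result of this package.
"""

from __future__ import annotations

import numpy as np

#: Indicator column order used throughout the package.
INDICATORS = [
    "fatty_acid",        # fatty acid content, %
    "carbonyl",          # carbonyl content, umol/g
    "peroxide_value",    # mmol/kg
    "acid_value",        # mg/g
    "phenylacetaldehyde",  # ug/kg
    "moisture",          # %
]

#: Environmental feature columns (fixed per storage condition).
ENV_FEATURES = ["temperature", "humidity"]

#: Indicators that rise during storage (hydrolysis/oxidation products).
INCREASING = ["fatty_acid", "carbonyl", "peroxide_value", "acid_value"]
#: Indicators that fall during storage (flavour volatile, water).
DECREASING = ["phenylacetaldehyde", "moisture"]

#: Mean six-indicator profile of each quality grade (1 = premium ... 5 =
#: severely deteriorated), in the INDICATORS order.
GRADE_PROFILES: dict[int, tuple[float, ...]] = {
    1: (36.80, 4.1, 0.47, 0.63, 96.1, 6.21),
    2: (50.10, 7.2, 1.25, 0.84, 24.2, 4.95),
    3: (59.88, 14.7, 2.10, 1.07, 10.7, 4.75),
    4: (68.79, 59.0, 3.20, 1.39, 6.26, 4.71),
    5: (80.47, 111.0, 3.90, 1.75, 5.63, 4.67),
}

#: Quality-score lower bounds of grades 1..5 (half-open intervals; grade 5 is
#: everything below 0.04).
GRADE_SCORE_BOUNDS = (0.42, 0.22, 0.11, 0.04)

#: Warehouse action attached to each grade.
GRADE_ACTIONS = {
    1: "routine storage",
    2: "routine monitoring",
    3: "enhanced monitoring, priority outbound",
    4: "early warning, restricted circulation",
    5: "retirement",
}

#: Published per-grade true/false positive/negative counts of the five-grade
#: classifier (grades indexed 0..4 = grades 1..5).
PUBLISHED_TP = np.array([781, 798, 1355, 818, 891])
PUBLISHED_FP = np.array([135, 402, 892, 1379, 1765])
PUBLISHED_FN = np.array([1661, 290, 1347, 491, 784])
#: Published per-grade sample counts (row totals).
PUBLISHED_SUPPORT = np.array([2442, 1088, 2702, 1309, 1675])

#: SYNTHETIC completion of the five-grade confusion matrix.  Only the
#: marginals above plus two merged-policy totals (high-risk cross-grade
#: confusion 89 between grades 4 and 5; 396 high-risk samples predicted
#: below grade 3) were published, which do not pin down every cell; this
#: matrix is one integer solution consistent with every published count and
#: is used as the worked-example input for the risk-policy arithmetic.
PUBLISHED_CONFUSION = np.array([
    [781,  80,   70,  640, 871],
    [10,  798,   32,  100, 148],
    [15,   36, 1355,  600, 696],
    [60,  140,  241,  818,  50],
    [50,  146,  549,   39, 891],
])

#: Published test metrics (MSE, MAE, RMSE, R^2) of the forecaster comparison.
FORECAST_COMPARISON = {
    "LSTM":        (0.6173, 0.6078, 0.7809, 0.9992),
    "FD-Net":      (0.6116, 0.5981, 0.7862, 0.9990),
    "FEDformer":   (0.5647, 0.4971, 0.7067, 0.9996),
    "MSDformer":   (0.5289, 0.5789, 0.6838, 0.9993),
    "Autoformer":  (0.5116, 0.5792, 0.6723, 0.9993),
    "Crossformer": (0.4775, 0.4467, 0.6653, 0.9996),
    "D-SCSformer": (0.2012, 0.2884, 0.4387, 0.9998),
}

#: Published ablation metrics (MSE, MAE): backbone alone, backbone+DSW
#: (Model 1), backbone+statistical fusion (Model 2), full model.
ABLATION_COMPARISON = {
    "SCSformer":   (0.30086862146638544, 0.3685976541042328),
    "Model 1":     (0.25244804322719574, 0.3390711915490115),
    "Model 2":     (0.28954741954803467, 0.3556258857250136),
    "D-SCSformer": (0.20124180614948273, 0.2884479761123657),
}

#: Storage phase boundaries in days per condition temperature:
#: (end of premium phase, end of good phase).
STORAGE_PHASES = {15: (100, 150), 25: (60, 100), 35: (40, 90)}

#: Default seed and stability seed set of the training protocol.
DEFAULT_SEED = 2021
SEED_SET = (2021, 2026, 2031, 2036, 2041)
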