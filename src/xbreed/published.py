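"""Published estimates from the motivating two-breed tropical beef study.

The across-breed methodology implemented here was developed on a field
dataset of 1829 Brahman (BB) and 1973 Tropical Composite (TC) cattle
with five tropical-adaptation traits and 71,726 SNPs; the raw data are
not public, but the published parameter tables are, and they serve two
purposes in this package: internal-consistency checks of the reported
arithmetic (C_miss against the reported variance proportions, column
averages of the validation tables) and as the reference point for the
qualitative behaviour the synthetic-data studies reproduce.

All numbers below are transcribed as printed (2 d.p.); recomputing a
quantity from other printed quantities can therefore differ by up to
~0.01 through input rounding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TRAITS = (
    "Navel score",
    "Coat score",
    "Coat colour",
    "Body condition",
    "Yearling weight",
)

BREEDS = ("BB", "TC")

#: panel size and the de-overlapped list sizes of the published study
PANEL_SIZE = 71726
PER_TRAIT_QUOTA = 7173  # 10 % of the panel
LIST_OF_SAME_SIZE = 16207
LIST_OF_DIFFERENT_SIZE = 16951


def _bivariate(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        index=list(TRAITS),
        columns=[
            "h2_P_BB",
            "h2_G_BB",
            "C_miss_BB",
            "h2_P_TC",
            "h2_G_TC",
            "C_miss_TC",
            "r_G",
        ],
    )


#: bi-variate estimates with the whole-panel GRM (G_W)
BIVARIATE_GW = _bivariate(
    [
        [0.34, 0.38, 0.48, 0.29, 0.50, 0.37, 0.12],
        [0.36, 0.39, 0.48, 0.32, 0.44, 0.42, 0.07],
        [0.33, 0.38, 0.47, 0.34, 0.39, 0.46, 0.07],
        [0.21, 0.57, 0.27, 0.18, 0.58, 0.24, 0.63],
        [0.39, 0.42, 0.48, 0.36, 0.39, 0.48, 0.04],
    ]
)

#: bi-variate estimates with the same-direction GRM (G_S)
BIVARIATE_GS = _bivariate(
    [
        [0.08, 0.88, 0.08, 0.09, 0.86, 0.10, 0.93],
        [0.16, 0.77, 0.18, 0.14, 0.79, 0.15, 0.83],
        [0.09, 0.84, 0.10, 0.06, 0.91, 0.06, 0.92],
        [0.10, 0.85, 0.10, 0.08, 0.88, 0.08, 0.92],
        [0.06, 0.92, 0.06, 0.08, 0.88, 0.08, 0.96],
    ]
)

#: bi-variate estimates with the different-direction GRM (G_D)
BIVARIATE_GD = _bivariate(
    [
        [0.10, 0.85, 0.11, 0.07, 0.89, 0.08, -0.91],
        [0.12, 0.83, 0.13, 0.11, 0.83, 0.12, -0.89],
        [0.08, 0.87, 0.08, 0.06, 0.91, 0.06, -0.93],
        [0.08, 0.88, 0.08, 0.10, 0.84, 0.10, -0.95],
        [0.07, 0.90, 0.07, 0.08, 0.88, 0.08, -0.95],
    ]
)

#: within-breed pedigree-based two-sex estimates (h2 cows, h2 bulls, r_g)
WITHIN_BREED_H2 = pd.DataFrame(
    {
        ("BB", "h2_cows"): [0.52, 0.66, 0.57, 0.56, 0.45],
        ("BB", "h2_bulls"): [0.53, 0.32, 0.59, 0.46, 0.61],
        ("BB", "r_g"): [0.94, 0.81, 0.95, 0.83, 0.71],
        ("TC", "h2_cows"): [0.57, 0.54, 0.57, 0.47, 0.55],
        ("TC", "h2_bulls"): [0.72, 0.62, 0.52, 0.41, 0.68],
        ("TC", "r_g"): [0.88, 0.88, 0.94, 0.62, 0.96],
    },
    index=list(TRAITS),
)


def _validation(accuracy_rows, bias_rows, directions) -> pd.DataFrame:
    """Long-form validation table: trait x direction x GRM, accuracy & bias."""
    grms = ("G_W", "G_S", "G_D")
    rows = []
    for metric, block in (("accuracy", accuracy_rows), ("bias", bias_rows)):
        for trait, vals in zip(TRAITS + ("Average",), block):
            for j, (direction, grm) in enumerate(
                [(d, g) for d in directions for g in grms]
            ):
                rows.append((trait, direction, grm, metric, vals[j]))
    df = pd.DataFrame(rows, columns=["trait", "direction", "grm", "metric", "value"])
    return df.pivot_table(
        index=["trait", "direction", "grm"], columns="metric", values="value"
    ).reset_index()


#: cows of one breed predicting cows of the other breed
VALIDATION_CROSS_BREED_COWS = _validation(
    accuracy_rows=[
        [0.40, 0.70, -0.47, 0.14, 0.58, -0.60],
        [0.11, 0.64, -0.54, 0.07, 0.53, -0.57],
        [0.05, 0.65, -0.62, 0.13, 0.67, -0.66],
        [0.20, 0.55, -0.48, 0.20, 0.65, -0.57],
        [0.07, 0.45, -0.43, 0.09, 0.43, -0.38],
        [0.17, 0.60, -0.51, 0.13, 0.57, -0.56],
    ],
    bias_rows=[
        [1.65, 1.48, -2.00, 0.61, 1.12, -2.03],
        [0.92, 3.77, -3.16, 0.28, 0.76, -1.01],
        [0.42, 2.29, -2.49, 0.83, 1.24, -1.38],
        [1.42, 1.46, -1.85, 1.22, 2.04, -2.27],
        [0.57, 1.61, -1.72, 0.73, 1.56, -1.70],
        [1.00, 2.12, -2.24, 0.73, 1.35, -1.68],
    ],
    directions=("BB cows : TC cows", "TC cows : BB cows"),
)

#: cows predicting bulls of the same breed
VALIDATION_WITHIN_BREED = _validation(
    accuracy_rows=[
        [0.23, 0.25, 0.21, 0.56, 0.56, 0.33],
        [0.04, 0.05, 0.05, 0.29, 0.29, 0.28],
        [0.40, 0.40, 0.37, 0.31, 0.30, 0.28],
        [0.15, 0.17, 0.11, 0.11, 0.16, 0.06],
        [0.20, 0.20, 0.17, 0.20, 0.23, 0.18],
        [0.21, 0.21, 0.18, 0.30, 0.31, 0.22],
    ],
    bias_rows=[
        [0.78, 0.69, 0.62, 1.26, 1.07, 1.45],
        [0.78, 0.66, 0.64, 0.65, 0.56, 0.61],
        [1.65, 1.40, 1.42, 1.17, 0.98, 0.96],
        [0.39, 0.32, 0.30, 0.40, 0.39, 0.31],
        [0.90, 0.67, 0.60, 1.21, 1.14, 0.99],
        [0.90, 0.75, 0.72, 0.94, 0.83, 0.87],
    ],
    directions=("BB cows : BB bulls", "TC cows : TC bulls"),
)

#: cows predicting bulls of the other breed
VALIDATION_CROSS_BREED_BULLS = _validation(
    accuracy_rows=[
        [0.32, 0.46, -0.09, 0.14, 0.20, -0.12],
        [0.08, 0.23, -0.20, 0.09, 0.05, 0.03],
        [-0.06, 0.13, -0.17, 0.05, 0.27, -0.26],
        [0.22, 0.18, 0.07, 0.10, 0.15, -0.02],
        [0.09, 0.18, -0.04, 0.10, 0.21, -0.05],
        [0.13, 0.24, -0.09, 0.10, 0.18, -0.08],
    ],
    bias_rows=[
        [1.95, 1.93, -0.71, 0.43, 0.45, -0.49],
        [0.82, 0.93, -1.25, 0.41, 0.26, 0.10],
        [-0.50, 0.84, -1.24, 0.46, 1.04, -1.15],
        [1.04, 0.44, -0.07, 0.47, 0.39, -0.07],
        [1.32, 1.00, -0.25, 0.70, 0.91, -0.29],
        [1.13, 1.03, -0.71, 0.49, 0.61, -0.45],
    ],
    directions=("BB cows : TC bulls", "TC cows : BB bulls"),
)


# ---------------------------------------------------------------------------
# Internal-consistency arithmetic
# ---------------------------------------------------------------------------


def cmiss_consistency(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute C_miss = h2_P / (h2_P + h2_G) from the printed proportions.

    The identity follows from C_miss = 1 - sigma2_u/(sigma2_u + sigma2_a)
    when both proportions share the same phenotypic-variance denominator.
    Returns printed vs recomputed values and their deviation per breed.
    """
    rows = []
    for breed in BREEDS:
        h2p = table[f"h2_P_{breed}"]
        h2g = table[f"h2_G_{breed}"]
        printed = table[f"C_miss_{breed}"]
        recomputed = h2p / (h2p + h2g)
        for trait in table.index:
            rows.append(
                {
                    "trait": trait,
                    "breed": breed,
                    "printed": printed[trait],
                    "recomputed": float(recomputed[trait]),
                    "deviation": float(abs(recomputed[trait] - printed[trait])),
                }
            )
    return pd.DataFrame(rows)


def validation_averages(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute the per-column Average rows from the per-trait cells."""
    cells = table[table.trait != "Average"]
    printed = table[table.trait == "Average"].set_index(["direction", "grm"])
    recomputed = cells.groupby(["direction", "grm"])[["accuracy", "bias"]].mean()
    out = printed[["accuracy", "bias"]].join(
        recomputed, lsuffix="_printed", rsuffix="_recomputed"
    )
    out["accuracy_deviation"] = (
        out["accuracy_printed"] - out["accuracy_recomputed"]
    ).abs()
    out["bias_deviation"] = (out["bias_printed"] - out["bias_recomputed"]).abs()
    return out.reset_index()
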