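"""GBLUP prediction on merged two-breed data with masked validation phenotypes.

The prediction model is the uni-variate GBLUP ``y = X b + M u + e`` with
``u ~ N(0, G sigma2_u)`` on the merged two-breed, two-sex dataset: only
the calibration selection (cows of one breed) keeps its phenotypes;
everything else is masked before the variance components are
re-estimated, and every animal covered by the GRM receives a GEBV
through its genomic relationships.  Accuracy is the product-moment
correlation between GEBV and the validation animals' phenotypes
adjusted for fixed effects estimated in the within-breed analyses; bias
is the regression slope of adjusted phenotype on GEBV (slope 1 =
unbiased).  Three calibration-to-validation schemes are supported:
cows of one breed predicting cows of the other breed, bulls of the same
breed, or bulls of the other breed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinship import ConfigurationError, RelationshipMatrix
from .mixedmodel import (
    ModelSpec,
    RandomTerm,
    VarianceComponents,
    reml_fit,
    solve_mme,
)

logger = logging.getLogger(__name__)

SCHEME_LABELS = (
    "cross-breed within-sex",
    "within-breed cross-sex",
    "cross-breed cross-sex",
)


@dataclass(frozen=True)
class ValidationScheme:
    """One calibration -> validation split by breed and sex."""

    label: str
    calibration_breed: str
    calibration_sex: str
    validation_breed: str
    validation_sex: str

    def __post_init__(self):
        same_cell = (
            self.calibration_breed == self.validation_breed
            and self.calibration_sex == self.validation_sex
        )
        if same_cell:
            raise ConfigurationError(
                "calibration and validation selectors must not overlap"
            )

    @property
    def name(self) -> str:
        return (
            f"{self.calibration_breed} {self.calibration_sex} -> "
            f"{self.validation_breed} {self.validation_sex}"
        )


def standard_schemes(breeds=("BB", "TC"), cow_sex="F", bull_sex="M") -> list:
    """The three cow-calibrated schemes, in both breed directions."""
    out = []
    for cal in breeds:
        other = [b for b in breeds if b != cal][0]
        out.append(ValidationScheme("cross-breed within-sex", cal, cow_sex, other, cow_sex))
        out.append(ValidationScheme("within-breed cross-sex", cal, cow_sex, cal, bull_sex))
        out.append(ValidationScheme("cross-breed cross-sex", cal, cow_sex, other, bull_sex))
    return out


# ---------------------------------------------------------------------------
# Adjusted phenotypes
# ---------------------------------------------------------------------------


def within_breed_fixed_solutions(
    data: pd.DataFrame,
    nrm: RelationshipMatrix,
    response: str,
    factors=(),
    covariates=(),
    animal_column: str = "animal",
    breed_column: str = "breed",
    sex_column: str = "sex",
    components: dict | None = None,
) -> dict:
    """Per-breed two-sex bi-variate pedigree fits; returns fitted fixed parts.

    For each breed the trait is treated as a different trait in each sex
    (pedigree relationship only), giving per-sex heritabilities, the
    between-sex genetic correlation and the BLUE fixed-effect solutions
    used to adjust validation phenotypes.  Returns a dict
    ``breed -> {"components", "solution", "fitted": Series by animal}``.
    ``components`` (breed -> VarianceComponents) skips the REML step and
    solves the BLUEs at the supplied values.
    """
    out = {}
    for breed, sub in data.groupby(breed_column):
        spec = ModelSpec(
            response=response,
            trait_column=sex_column,
            traits=tuple(sorted(sub[sex_column].unique())),
            factors=tuple(factors),
            covariates=tuple(covariates),
            animal_column=animal_column,
            random_terms=(RandomTerm("pedigree", nrm, "full"),),
        )
        if components is not None and breed in components:
            vc = components[breed]
        else:
            vc = reml_fit(spec, sub)
        sol = solve_mme(spec, sub, vc)
        fitted = pd.Series(
            sol.fitted_fixed.to_numpy(),
            index=sub.loc[sol.fitted_fixed.index, animal_column].to_numpy(),
        )
        out[breed] = {"components": vc, "solution": sol, "fitted": fitted}
    return out


def adjusted_phenotypes(
    data: pd.DataFrame,
    fixed_fits: dict,
    response: str,
    animal_column: str = "animal",
    breed_column: str = "breed",
) -> pd.Series:
    """Observed phenotype minus the within-breed fitted fixed effects.

    Records whose fixed-effect cell was absent from the within-breed fit
    (an unseen factor level, so no BLUE exists for it) are dropped with
    a logged count.
    """
    parts = []
    n_dropped = 0
    for breed, sub in data.groupby(breed_column):
        if breed not in fixed_fits:
            n_dropped += len(sub)
            continue
        fitted = fixed_fits[breed]["fitted"]
        y = pd.Series(sub[response].to_numpy(), index=sub[animal_column].to_numpy())
        common = y.index.intersection(fitted.index)
        n_dropped += len(y) - len(common)
        parts.append(y.loc[common] - fitted.loc[common])
    if n_dropped:
        logger.info("adjusted_phenotypes: dropped %d records without usable BLUEs", n_dropped)
    if not parts:
        raise ConfigurationError("no records could be adjusted")
    return pd.concat(parts)


# ---------------------------------------------------------------------------
# GBLUP
# ---------------------------------------------------------------------------


def gblup_predict(
    data: pd.DataFrame,
    grm: RelationshipMatrix,
    scheme: ValidationScheme,
    response: str,
    factors=(),
    covariates=(),
    animal_column: str = "animal",
    breed_column: str = "breed",
    sex_column: str = "sex",
    components: VarianceComponents | None = None,
) -> tuple[pd.Series, VarianceComponents]:
    """GEBV for every animal in the GRM under one masking scheme.

    Phenotypes outside the calibration selection are masked (set
    missing); unless ``components`` is supplied, the genomic and
    residual variances are re-estimated by REML on the masked data.
    Returns ``(gebv, components)`` with ``gebv`` indexed by GRM animal id.
    """
    observed = (data[breed_column] == scheme.calibration_breed) & (
        data[sex_column] == scheme.calibration_sex
    )
    if not observed.any():
        raise ConfigurationError(
            f"calibration set empty for scheme {scheme.name!r}"
        )
    masked = data.copy()
    masked.loc[~observed, response] = np.nan
    spec = ModelSpec(
        response=response,
        random_terms=(RandomTerm("genomic", grm),),
        factors=tuple(factors),
        covariates=tuple(covariates),
        animal_column=animal_column,
    )
    if components is None:
        components = reml_fit(spec, masked)
    solution = solve_mme(spec, masked, components)
    gebv = solution.random["genomic"].iloc[:, 0]
    gebv.name = "GEBV"
    return gebv, components


def accuracy_and_bias(
    gebv: pd.Series, adjusted: pd.Series, validation_animals
) -> dict:
    """Correlation (accuracy) and regression slope (bias) over validation animals.

    ``bias`` is the OLS slope of adjusted phenotype on GEBV -- 1 means
    the spread of the GEBV matches the spread of realised performance.
    A zero-variance GEBV vector leaves both undefined (NaN, flagged).
    """
    ids = pd.Index(validation_animals)
    ids = ids.intersection(gebv.index).intersection(adjusted.index)
    if len(ids) < 3:
        raise ConfigurationError("need at least 3 validation animals with GEBV and phenotype")
    g = gebv.loc[ids].to_numpy(dtype=float)
    a = adjusted.loc[ids].to_numpy(dtype=float)
    if np.std(g) == 0.0 or np.std(a) == 0.0:
        logger.warning("accuracy_and_bias: zero-variance input, metrics undefined")
        return {"accuracy": np.nan, "bias": np.nan, "n": len(ids), "defined": False}
    acc = float(np.corrcoef(g, a)[0, 1])
    slope = float(np.cov(a, g, ddof=1)[0, 1] / np.var(g, ddof=1))
    return {"accuracy": acc, "bias": slope, "n": len(ids), "defined": True}


def run_validation_grid(
    data: pd.DataFrame,
    grms: dict,
    adjusted: pd.Series,
    schemes=None,
    response: str = "trait",
    trait_label: str | None = None,
    factors=(),
    covariates=(),
    animal_column: str = "animal",
    breed_column: str = "breed",
    sex_column: str = "sex",
    reuse_components: bool = True,
) -> pd.DataFrame:
    """Accuracy/bias for every trait x scheme x GRM cell, plus Average rows.

    ``grms`` maps variant name (e.g. ``G_W, G_S, G_D``) to a
    RelationshipMatrix.  Schemes sharing a calibration selection also
    share the REML fit and GEBV under each GRM (the masking depends only
    on the calibration cell).  The trailing ``Average`` rows are the
    arithmetic means of the per-trait cells per (scheme, GRM, direction).
    """
    schemes = list(schemes) if schemes is not None else standard_schemes(
        breeds=tuple(sorted(data[breed_column].unique()))
    )
    trait_label = trait_label or response
    rows = []
    cache: dict = {}
    for grm_name, grm in grms.items():
        for scheme in schemes:
            key = (grm_name, scheme.calibration_breed, scheme.calibration_sex)
            if key not in cache or not reuse_components:
                cache[key] = gblup_predict(
                    data,
                    grm,
                    scheme,
                    response=response,
                    factors=factors,
                    covariates=covariates,
                    animal_column=animal_column,
                    breed_column=breed_column,
                    sex_column=sex_column,
                )
            gebv, comp = cache[key]
            val_ids = data.loc[
                (data[breed_column] == scheme.validation_breed)
                & (data[sex_column] == scheme.validation_sex),
                animal_column,
            ]
            metrics = accuracy_and_bias(gebv, adjusted, val_ids)
            rows.append(
                {
                    "trait": trait_label,
                    "scheme": scheme.label,
                    "direction": scheme.name,
                    "grm": grm_name,
                    "n_calibration": int(
                        (
                            (data[breed_column] == scheme.calibration_breed)
                            & (data[sex_column] == scheme.calibration_sex)
                            & data[response].notna()
                        ).sum()
                    ),
                    **metrics,
                }
            )
    report = pd.DataFrame(rows)
    averages = (
        report.groupby(["scheme", "direction", "grm"], as_index=False)[["accuracy", "bias"]]
        .mean()
        .assign(trait="Average")
    )
    return pd.concat([report, averages], ignore_index=True)
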