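"""Phenotype preprocessing: two-factor ANOVA, broad-sense heritability,
year-adjusted accession means, trait transforms, trait correlations."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .datatypes import PhenotypeTable


@dataclass
class AnovaResult:
    """Sequential (type-I) decomposition value ~ accession + year."""

    table: pd.DataFrame  # index: accession, year, residual
    ms_accession: float
    ms_residual: float

    @property
    def msc(self) -> float:
        return self.ms_accession

    @property
    def mse(self) -> float:
        return self.ms_residual


@dataclass
class HeritabilityResult:
    sigma_g2: float  # raw (may be negative)
    sigma_e2: float
    h2: float  # computed with sigma_g2 clamped at 0
    divisor: int


def _trait_frame(phenos: PhenotypeTable, trait: str) -> pd.DataFrame:
    df = phenos.trait_values(trait)
    if df.empty:
        raise ValueError(f"no records for trait {trait!r}")
    return df


def two_factor_anova(phenos: PhenotypeTable, trait: str,
                     ss_type: int = 1) -> AnovaResult:
    """Fixed-effects ANOVA of trait ~ accession + year.

    Sequential (type-I) sums of squares with accession fitted first;
    ``ss_type=2`` is available for unbalanced designs. Requires >= 2 levels
    of each factor.
    """
    df = _trait_frame(phenos, trait)
    if "year" not in df.columns:
        raise ValueError("two_factor_anova needs raw records with a year column")
    for factor in ("accession", "year"):
        if df[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has a single level")
    fit = smf.ols("value ~ C(accession) + C(year)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=ss_type)
    table = table.rename(index={"C(accession)": "accession", "C(year)": "year",
                                "Residual": "residual"})
    table["mean_sq"] = table["sum_sq"] / table["df"]
    return AnovaResult(
        table=table,
        ms_accession=float(table.loc["accession", "mean_sq"]),
        ms_residual=float(table.loc["residual", "mean_sq"]),
    )


def heritability(anova: AnovaResult, divisor: int) -> HeritabilityResult:
    """Broad-sense heritability from ANOVA mean squares.

    sigma_g^2 = (MSc - MSe) / divisor (reported raw, clamped to 0 inside
    h^2), sigma_e^2 = MSe, h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).
    The conventional divisor is the per-accession replicate count
    (years x reps in a balanced design); see :func:`replicate_divisor`.
    """
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    sigma_g2 = (anova.ms_accession - anova.ms_residual) / divisor
    sigma_e2 = anova.ms_residual
    g = max(sigma_g2, 0.0)
    h2 = g / (g + sigma_e2) if (g + sigma_e2) > 0 else 0.0
    return HeritabilityResult(sigma_g2, sigma_e2, h2, divisor)


def replicate_divisor(phenos: PhenotypeTable, trait: str) -> int:
    """Mean number of records per accession (the expected-replicates divisor)."""
    df = _trait_frame(phenos, trait)
    return int(round(df.groupby("accession").size().mean()))


def adjusted_means(phenos: PhenotypeTable, trait: str) -> PhenotypeTable:
    """Per-accession least-squares means adjusted for the year effect.

    Fits the additive model and predicts each accession averaged over the
    year levels, so a year with extra replication does not shift accession
    comparisons. Single-year data reduces to raw accession means.
    """
    df = _trait_frame(phenos, trait)
    if "year" not in df.columns or df["year"].nunique() < 2:
        means = df.groupby("accession", sort=False)["value"].mean().reset_index()
        means["trait"] = trait
        return PhenotypeTable(means[["accession", "trait", "value"]])
    fit = smf.ols("value ~ C(accession) + C(year)", data=df).fit()
    accessions = df["accession"].unique()
    years = df["year"].unique()
    grid = pd.DataFrame(
        [(a, y) for a in accessions for y in years], columns=["accession", "year"]
    )
    grid["pred"] = fit.predict(grid)
    means = grid.groupby("accession", sort=False)["pred"].mean().reset_index()
    means = means.rename(columns={"pred": "value"})
    means["trait"] = trait
    return PhenotypeTable(means[["accession", "trait", "value"]])


def transform_trait(values: pd.Series, transform: str = "none") -> pd.Series:
    """Elementwise trait transform; ``log`` is the natural log and requires
    strictly positive values."""
    if transform == "none":
        return values.copy()
    if transform != "log":
        raise ValueError(f"unknown transform {transform!r}")
    bad = values <= 0
    if bad.any():
        name = bad[bad].index[0]
        raise ValueError(f"log transform requires positive values (offender: {name})")
    out = np.log(values)
    out.attrs["transform"] = "log"
    return out


def trait_correlations(means: dict[str, pd.Series] | pd.DataFrame,
                       traits: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations among per-accession trait means.

    Accepts a wide DataFrame (accessions x traits) or a dict of Series
    indexed by accession; needs >= 3 shared accessions per pair. Constant
    traits yield NaN with a warning.
    """
    if isinstance(means, dict):
        means = pd.DataFrame(means)
    if traits is not None:
        means = means[list(traits)]
    for t in means.columns:
        col = means[t].dropna()
        if col.nunique() <= 1:
            warnings.warn(f"trait {t!r} is constant; correlations undefined")
    for ta in means.columns:
        for tb in means.columns:
            if ta < tb and (means[[ta, tb]].dropna().shape[0] < 3):
                raise ValueError(f"traits {ta}/{tb}: fewer than 3 shared accessions")
    return means.corr(method="pearson", min_periods=3)
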