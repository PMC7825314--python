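"""Dual-luciferase reporter statistics.

RLU (relative luciferase units) is the firefly/renilla ratio per well,
normalised to the mean ratio of the empty-vector wells, so the empty
vector averages exactly 1.  Allele comparisons run the full test battery:
Welch's two-sample t-test (two-sided, Welch-Satterthwaite degrees of
freedom), Bartlett's test for homogeneity of variances and a Shapiro-Wilk
normality test per group.  All three are reported; none gates another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

EMPTY_CONSTRUCT = "empty"


@dataclass(frozen=True)
class ReporterSample:
    construct: str
    experiment: int
    firefly: float
    renilla: float

    def __post_init__(self):
        if self.firefly < 0:
            raise ValidationError("firefly luminescence must be non-negative")
        if self.renilla <= 0:
            raise ValidationError("renilla luminescence must be positive")


@dataclass
class AlleleComparisonResult:
    welch_t: float
    welch_df: float
    welch_p: float
    bartlett_p: float
    shapiro_p_per_group: tuple[float, float]
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.welch_p < self.alpha

    def to_dict(self) -> dict:
        return {
            "welch_t": self.welch_t,
            "welch_df": self.welch_df,
            "welch_p": self.welch_p,
            "bartlett_p": self.bartlett_p,
            "shapiro_p_group_a": self.shapiro_p_per_group[0],
            "shapiro_p_group_b": self.shapiro_p_per_group[1],
            "alpha": self.alpha,
            "significant": self.significant,
        }


def compute_rlu(samples: pd.DataFrame) -> pd.Series:
    """Per-well RLU normalised to the empty-vector mean.

    ``samples`` needs columns ``construct``, ``firefly``, ``renilla`` and at
    least one ``empty`` row; after normalisation the empty-vector group mean
    is exactly 1.  Scaling both luminescence channels by a common factor
    leaves the result unchanged.
    """
    if np.any(samples["renilla"] <= 0):
        raise ValidationError("renilla luminescence must be positive in every well")
    if np.any(samples["firefly"] < 0):
        raise ValidationError("firefly luminescence must be non-negative")
    ratio = samples["firefly"] / samples["renilla"]
    empty = ratio[samples["construct"] == EMPTY_CONSTRUCT]
    if empty.empty:
        raise ValidationError("no empty-vector samples to normalise against")
    return ratio / empty.mean()


def compare_alleles(group_a, group_b, alpha: float = 0.05) -> AlleleComparisonResult:
    """Welch t-test plus Bartlett and per-group Shapiro-Wilk on two RLU groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValidationError("each group needs at least 3 values (Shapiro-Wilk minimum)")
    welch = stats.ttest_ind(a, b, equal_var=False)
    bartlett = stats.bartlett(a, b)
    shapiro_a = stats.shapiro(a)
    shapiro_b = stats.shapiro(b)
    return AlleleComparisonResult(
        welch_t=float(welch.statistic),
        welch_df=float(welch.df),
        welch_p=float(welch.pvalue),
        bartlett_p=float(bartlett.pvalue),
        shapiro_p_per_group=(float(shapiro_a.pvalue), float(shapiro_b.pvalue)),
        alpha=alpha,
    )


def allele_comparison_from_table(
    table: pd.DataFrame,
    allele_a: str = "major_allele",
    allele_b: str = "minor_allele",
    mode: str = "pooled",
    alpha: float = 0.05,
) -> AlleleComparisonResult:
    """End-to-end allele comparison from a replicate table.

    ``mode='pooled'`` tests all wells of each allele (the default, n =
    experiments x replicates per group); ``mode='experiment_means'`` first
    averages replicates within each experiment (n = experiments per group).
    """
    rlu = compute_rlu(table)
    df = table.assign(rlu=rlu)

    def group(construct):
        g = df[df["construct"] == construct]
        if g.empty:
            raise ValidationError(f"no samples for construct {construct!r}")
        if mode == "pooled":
            return g["rlu"].to_numpy()
        if mode == "experiment_means":
            return g.groupby("experiment")["rlu"].mean().to_numpy()
        raise ValidationError(f"unknown mode {mode!r}")

    return compare_alleles(group(allele_a), group(allele_b), alpha=alpha)
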