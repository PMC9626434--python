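"""Agreement statistics between kinematic methods.

Bland–Altman analysis quantifies systematic (bias) and random (limits of
agreement) differences between two methods measuring the same angle; under
normally distributed differences about 95% of points fall within
bias ± 2·SD. The ΔROM multi-linear regression explains the range-of-motion
difference between two model types from the participant's sex, BMI and the
three anatomical (inter-joint-distance) errors:

    ΔROM = intercept + β1·sex + β2·BMI + β3·Δ‖clavicle‖ + β4·Δ‖scapula‖ + β5·Δ‖humerus‖

with sex coded 1 (male) / 1.1 (female), BMI in kg/m² and the anatomical
errors in cm. A model is called significant when its overall F-test
p-value is at most 0.05; a predictor when |t| is at least 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import CollinearityError, ValidationError

__all__ = [
    "BlandAltmanResult",
    "RegressionResult",
    "bland_altman",
    "loa_coverage",
    "fit_delta_rom_regression",
    "significance_report",
    "PREDICTORS",
    "COHORT_COLUMNS",
]

PREDICTORS = ("sex_code", "bmi", "delta_clavicle", "delta_scapula", "delta_humerus")
COHORT_COLUMNS = ("id", "task", "delta_rom") + PREDICTORS

#: LOA multiplier: two-fold the SD of the differences (exactly 2, not 1.96)
LOA_MULTIPLIER = 2.0


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and limits of agreement between two paired methods (degrees)."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    means: np.ndarray
    differences: np.ndarray
    multiplier: float = LOA_MULTIPLIER

    def summary(self) -> dict:
        return {
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n": self.n,
            "multiplier": self.multiplier,
        }


def bland_altman(method_a, method_b, multiplier: float = LOA_MULTIPLIER) -> BlandAltmanResult:
    """Bland–Altman agreement of paired samples (differences a − b).

    Inputs are arrays (or lists of arrays, pooled) on a common grid — one
    value per normalized time point per repetition. LOA are
    bias ± multiplier·SD with SD the sample standard deviation.
    """
    def pool(x):
        if isinstance(x, (list, tuple)):
            return np.concatenate([np.ravel(np.asarray(xi, float)) for xi in x])
        return np.ravel(np.asarray(x, float))

    a, b = pool(method_a), pool(method_b)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValidationError("Bland-Altman needs at least 2 paired samples")
    diff = a - b
    mean = 0.5 * (a + b)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        bias=bias, sd_diff=sd,
        loa_low=bias - multiplier * sd, loa_high=bias + multiplier * sd,
        n=int(a.size), means=mean, differences=diff, multiplier=multiplier,
    )


def loa_coverage(differences, multiplier: float = LOA_MULTIPLIER) -> float:
    """Fraction of differences inside bias ± multiplier·SD.

    For normal differences and multiplier 2 this approaches
    Φ(2) − Φ(−2) ≈ 0.9545 as n grows. Degenerate all-equal samples have
    SD 0 with every point at the bias, giving 1.0.
    """
    d = np.ravel(np.asarray(differences, dtype=float))
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValidationError("no finite differences")
    bias = d.mean()
    sd = d.std(ddof=1) if d.size > 1 else 0.0
    lo, hi = bias - multiplier * sd, bias + multiplier * sd
    return float(np.mean((d >= lo) & (d <= hi)))


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of the ΔROM model for one task."""

    task: str
    coefficients: dict    # intercept + the five β, in ° per predictor unit
    std_errors: dict
    t_stats: dict
    r_squared: float
    adj_r_squared: float
    model_p_value: float  # overall F-test of the five slopes
    n: int

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "coefficients": dict(self.coefficients),
            "std_errors": dict(self.std_errors),
            "t_stats": dict(self.t_stats),
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "model_p_value": self.model_p_value,
            "n": self.n,
        }


def _check_rank(X: pd.DataFrame):
    """Raise CollinearityError naming columns that are linearly dependent."""
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank >= mat.shape[1]:
        return
    offending = []
    kept: list[int] = []
    for j in range(mat.shape[1]):
        trial = mat[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            offending.append(X.columns[j])
    raise CollinearityError(offending)


def fit_delta_rom_regression(table: pd.DataFrame, task: str) -> RegressionResult:
    """Fit the five-predictor ΔROM regression for one task by OLS.

    ``table`` is a cohort table with one row per participant per task and
    the columns ``delta_rom, sex_code, bmi, delta_clavicle, delta_scapula,
    delta_humerus`` (plus ``task`` if several tasks are stacked).
    """
    df = table
    if "task" in df.columns:
        df = df[df["task"] == task]
    missing = [c for c in ("delta_rom",) + PREDICTORS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort table lacks column(s): {missing}")
    df = df.dropna(subset=["delta_rom", *PREDICTORS])
    if len(df) < 7:
        raise ValidationError(
            f"need at least 7 rows to fit 5 predictors + intercept, got {len(df)}"
        )
    X = sm.add_constant(df[list(PREDICTORS)].astype(float), has_constant="add")
    _check_rank(X)
    fit = sm.OLS(df["delta_rom"].astype(float), X).fit()
    names = ["intercept", *PREDICTORS]
    keys = list(X.columns)  # 'const' + predictors
    return RegressionResult(
        task=task,
        coefficients={n: float(fit.params[k]) for n, k in zip(names, keys)},
        std_errors={n: float(fit.bse[k]) for n, k in zip(names, keys)},
        t_stats={n: float(fit.tvalues[k]) for n, k in zip(names, keys)},
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        model_p_value=float(fit.f_pvalue),
        n=int(fit.nobs),
    )


def significance_report(result: RegressionResult,
                        p_threshold: float = 0.05,
                        t_threshold: float = 2.0) -> dict:
    """Label the model and each predictor per the study's significance rules.

    The model counts as significant when its overall p-value is at most
    ``p_threshold``; a predictor when |t| is at least ``t_threshold``.
    """
    predictors = {
        name: {
            "coefficient": result.coefficients[name],
            "t_stat": result.t_stats[name],
            "significant": abs(result.t_stats[name]) >= t_threshold,
        }
        for name in PREDICTORS
    }
    return {
        "task": result.task,
        "model_p_value": result.model_p_value,
        "model_significant": result.model_p_value <= p_threshold,
        "r_squared": result.r_squared,
        "adj_r_squared": result.adj_r_squared,
        "predictors": predictors,
    }
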