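"""Multiplicative-null predictions, epistasis scores and significance tests.

Under the multiplicative null, a combination of substitutions confers the
product of the single-substitution fold-effects: R = prod(X_i). The error
on R propagates as dR = R * sqrt(sum((dX_i/X_i)^2)), treating the singles
as independent. Observed deviations are scored on the natural-log scale,
epsilon = ln(observed / R): zero under exact multiplicativity, positive for
synergy, negative for antagonism. Pairwise interactions are further
classified as magnitude, sign, or reciprocal-sign epistasis depending on
whether a substitution's effect direction flips across backgrounds.

Group comparisons of EC50 measurements use the unpaired two-sample t-test
(pooled-variance Student by default, Welch on request) computed from
summary statistics, with the conventional star labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .landscape import (
    FitnessLandscape,
    FitnessMeasurement,
    Substitution,
    format_genotype,
    parse_genotype,
)

__all__ = [
    "EpistasisPrediction",
    "TTestResult",
    "predict_multiplicative",
    "epistasis_score",
    "classify_pair",
    "unpaired_t_test",
    "significance_stars",
]


@dataclass(frozen=True)
class EpistasisPrediction:
    """Multiplicative expectation for a multi-substitution genotype."""

    genotype: tuple[Substitution, ...]
    predicted: float  # R = product of single-substitution mean folds
    delta_predicted: float  # dR from error propagation
    components: tuple[float, ...]  # X_i, single-substitution means
    component_errors: tuple[float, ...]  # dX_i
    observed: FitnessMeasurement | None = None


def predict_multiplicative(
    landscape: FitnessLandscape, genotype: str | Sequence[Substitution]
) -> EpistasisPrediction:
    """Predicted fold R and propagated error dR for a genotype.

    R multiplies the single-substitution mean folds; dR generalises the
    three-term propagation formula to k terms:
    dR = R * sqrt(sum_i (dX_i / X_i)^2). The wild-type reference enters as
    the fixed value 1 and contributes no error term. Requires every
    constituent single-substitution genotype to be measured.
    """
    subs = parse_genotype(genotype) if isinstance(genotype, str) else tuple(sorted(genotype))
    if not subs:
        raise ValueError("prediction needs at least one substitution")
    components, errors = [], []
    for s in subs:
        try:
            meas = landscape.measurement(format_genotype([s]))
        except KeyError:
            raise KeyError(f"single-substitution measurement for {s} is missing") from None
        components.append(meas.mean)
        errors.append(meas.sd)
    r = math.prod(components)
    dr = r * math.sqrt(sum((dx / x) ** 2 for x, dx in zip(components, errors)))
    observed = None
    try:
        observed = landscape.measurement(format_genotype(subs))
    except KeyError:
        pass
    return EpistasisPrediction(
        genotype=subs,
        predicted=r,
        delta_predicted=dr,
        components=tuple(components),
        component_errors=tuple(errors),
        observed=observed,
    )


def epistasis_score(
    observed: FitnessMeasurement | float, predicted: EpistasisPrediction | float
) -> float:
    """epsilon = ln(observed / predicted): log-scale deviation from multiplicativity."""
    obs = observed.mean if isinstance(observed, FitnessMeasurement) else float(observed)
    pred = predicted.predicted if isinstance(predicted, EpistasisPrediction) else float(predicted)
    if not (obs > 0 and pred > 0):
        raise ValueError("observed and predicted folds must be positive")
    return math.log(obs / pred)


def _direction(log_effect: float, tol: float) -> int:
    """-1/0/+1 effect direction, with |log effect| <= tol treated as neutral."""
    if log_effect > tol:
        return 1
    if log_effect < -tol:
        return -1
    return 0


def classify_pair(
    f_wt: float,
    f_a: float,
    f_b: float,
    f_ab: float,
    tol: float = 0.05,
) -> Literal["none", "magnitude", "sign", "reciprocal_sign"]:
    """Classify the interaction between two substitutions.

    The four fitness values are wild type, each single, and the double.
    With |epsilon| <= tol (on the log scale) the pair is "none"
    (indistinguishable from multiplicative). Otherwise the effect of each
    substitution is compared between the wild-type background and the
    other-substitution background: no direction flip is "magnitude"
    epistasis, one flip is "sign", two flips "reciprocal_sign". Effects
    within tol of zero are treated as directionless and cannot flip.
    """
    for v in (f_wt, f_a, f_b, f_ab):
        if not v > 0:
            raise ValueError("fitness values must be positive")
    eps = math.log(f_ab * f_wt / (f_a * f_b))
    if abs(eps) <= tol:
        return "none"
    a_alone = _direction(math.log(f_a / f_wt), tol)
    a_in_b = _direction(math.log(f_ab / f_b), tol)
    b_alone = _direction(math.log(f_b / f_wt), tol)
    b_in_a = _direction(math.log(f_ab / f_a), tol)
    flips = sum(
        1 for alone, other in ((a_alone, a_in_b), (b_alone, b_in_a)) if alone * other == -1
    )
    return ("magnitude", "sign", "reciprocal_sign")[flips]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    method: Literal["pooled", "welch"]

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def unpaired_t_test(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    method: Literal["pooled", "welch"] = "pooled",
) -> TTestResult:
    """Unpaired two-sample t-test from summary statistics.

    Defaults to the pooled-variance Student form; ``method="welch"`` drops
    the equal-variance assumption. Two groups with zero spread and equal
    means are reported as t=0, p=1 (no evidence of difference) rather than
    0/0.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("t-test needs at least 2 observations per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        df = n1 + n2 - 2 if method == "pooled" else float(min(n1, n2) - 1)
        if mean1 == mean2:
            return TTestResult(t=0.0, df=float(df), p=1.0, method=method)
        return TTestResult(t=math.copysign(math.inf, mean1 - mean2), df=float(df), p=0.0, method=method)
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(method == "pooled")
    )
    if method == "pooled":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TTestResult(t=float(t), df=df, p=float(p), method=method)


def significance_stars(p: float) -> str:
    """Conventional star label: *** p<=0.001, ** p<=0.01, * p<=0.05, else ns."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"
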