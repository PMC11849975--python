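"""Dose-response models for blast-TBI phenotypes.

The injury dose delivered by the weight-drop rig is summarized by the
maximal pressure (kPa) of the drop and the number of drops administered.
Continuous responses (locomotor activity) regress linearly on dose; binary
phenotypes (behavioural seizure, tau pathology, stimulus response) are fit
by maximum-likelihood logistic regression.  Each covariate's effect is
reported as an odds ratio OR = exp(beta) with a Wald 95% CI on the
log-odds scale, and model discrimination as the area under the ROC curve.

Because per-kPa odds ratios are numerically close to 1, effects are
communicated per k units: OR_per_k = OR^k, e.g. OR 1.005 per kPa is a
64.7% increase in odds per 100 kPa.  Group comparisons against the shared
uninjured control use one-way ANOVA followed by Dunnett's multiple
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "PhenotypeRecord",
    "RegressionFit",
    "CovariateEffect",
    "DoseResponseFit",
    "GroupComparison",
    "SeparationError",
    "fit_linear",
    "fit_logistic",
    "scale_odds_ratio",
    "roc_auc",
    "anova_dunnett",
    "records_from_arrays",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


class SeparationError(ValueError):
    """Raised when a logistic fit is degenerate due to complete separation."""


@dataclass(frozen=True)
class PhenotypeRecord:
    """One larva's binary outcome with its injury-dose covariates."""

    larva_id: str
    group: str
    outcome: int
    max_pressure_kpa: float
    n_drops: int = 1
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1):
            raise ValueError(f"outcome must be 0 or 1, got {self.outcome}")
        if self.max_pressure_kpa < 0:
            raise ValueError("max_pressure_kpa must be >= 0")
        if self.n_drops < 0:
            raise ValueError("n_drops must be >= 0")


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares line fit with slope inference."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class CovariateEffect:
    """Per-unit effect of one covariate in a logistic model."""

    name: str
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted logistic dose-response model.

    ``effects`` maps covariate name to its :class:`CovariateEffect`;
    ``auc`` is the ROC area of the fitted probabilities against the
    observed outcomes.
    """

    effects: dict[str, CovariateEffect]
    intercept: float
    auc: float
    n: int
    model_spec: str
    log_likelihood: float

    def odds_ratio(self, covariate: str) -> float:
        return self.effects[covariate].odds_ratio


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA plus Dunnett's comparisons against a shared control."""

    control_label: str
    group_means: dict[str, float]
    group_ns: dict[str, int]
    f_statistic: float
    anova_p: float
    adjusted_p: dict[str, float]
    significant: dict[str, bool]
    alpha: float


def fit_linear(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Simple linear regression of a response on one dose metric.

    Ordinary least squares; ``p_value`` is the two-sided test of zero
    slope.  Requires n >= 3 and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError(f"need n >= 3 points, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )


def records_from_arrays(
    max_pressure_kpa: Sequence[float],
    outcome: Sequence[int],
    n_drops: Sequence[int] | None = None,
    group: str = "g",
) -> list[PhenotypeRecord]:
    """Convenience constructor: parallel arrays -> phenotype records."""
    if n_drops is None:
        n_drops = np.ones(len(outcome), dtype=int)
    return [
        PhenotypeRecord(
            larva_id=f"L{i}",
            group=group,
            outcome=int(y),
            max_pressure_kpa=float(x),
            n_drops=int(d),
        )
        for i, (x, y, d) in enumerate(zip(max_pressure_kpa, outcome, n_drops))
    ]


def _records_frame(records: Sequence[PhenotypeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "larva_id": r.larva_id,
            "group": r.group,
            "outcome": r.outcome,
            "max_pressure_kpa": r.max_pressure_kpa,
            "n_drops": r.n_drops,
        }
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    # monotone-likelihood screen: a covariate whose ranges for the two
    # outcome classes do not overlap separates the data completely
    for name in X.columns:
        v = X[name].to_numpy(dtype=float)
        v0, v1 = v[y == 0], v[y == 1]
        if np.ptp(v) == 0:
            continue
        if v0.max() < v1.min() or v1.max() < v0.min():
            raise SeparationError(
                f"complete separation on covariate {name!r}: outcome classes "
                "do not overlap; the MLE does not exist"
            )


def fit_logistic(
    records: Sequence[PhenotypeRecord],
    covariates: Sequence[str] = ("max_pressure_kpa",),
) -> DoseResponseFit:
    """Maximum-likelihood logistic regression of outcome on dose covariates.

    Covariates are used on their natural scales (kPa, drop count) so the
    reported odds ratios are per-unit.  Wald 95% CI: exp(beta +/- 1.96 SE).
    Requires both outcome classes and n >= 10 observations per covariate.

    Raises
    ------
    SeparationError
        If an outcome class is missing or a covariate completely separates
        the classes (monotone likelihood, no MLE).
    """
    df = _records_frame(records)
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise ValueError(f"unknown covariates {missing}")
    y = df["outcome"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise SeparationError("outcome has a single class; logistic fit undefined")
    if len(df) < 10 * len(covariates):
        raise ValueError(
            f"need >= {10 * len(covariates)} observations for "
            f"{len(covariates)} covariate(s), got {len(df)}"
        )
    X = df[list(covariates)]
    _check_separation(X, y)
    model = sm.Logit(y, sm.add_constant(X.astype(float), has_constant="add"))
    res = model.fit(disp=0, maxiter=200)
    if not np.all(np.isfinite(res.bse)) or np.any(np.abs(res.params) > 50):
        raise SeparationError(
            "logistic fit diverged (quasi-separation); standard errors unreliable"
        )
    effects = {}
    for name in covariates:
        beta = float(res.params[name])
        se = float(res.bse[name])
        effects[name] = CovariateEffect(
            name=name,
            beta=beta,
            se=se,
            odds_ratio=float(np.exp(beta)),
            ci_low=float(np.exp(beta - _Z95 * se)),
            ci_high=float(np.exp(beta + _Z95 * se)),
            p_value=float(res.pvalues[name]),
        )
    auc = roc_auc(res.predict(), y.astype(int))
    return DoseResponseFit(
        effects=effects,
        intercept=float(res.params["const"]),
        auc=auc,
        n=len(df),
        model_spec="outcome ~ " + " + ".join(covariates),
        log_likelihood=float(res.llf),
    )


def scale_odds_ratio(or_per_unit: float, k: float) -> tuple[float, float]:
    """Re-express a per-unit odds ratio per ``k`` units.

    Returns ``(or_per_k, percent_change)`` with ``or_per_k = or_per_unit**k``
    and ``percent_change = 100 * (or_per_k - 1)``, at full precision
    (reports round to one decimal).  E.g. OR 1.005 per kPa is OR 1.647 per
    100 kPa, a +64.7% change in odds.
    """
    if or_per_unit <= 0:
        raise ValueError(f"odds ratio must be > 0, got {or_per_unit}")
    or_per_k = or_per_unit**k
    return or_per_k, 100.0 * (or_per_k - 1.0)


def roc_auc(scores: Sequence[float], outcomes: Sequence[int]) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    The probability that a random positive outscores a random negative,
    ties counted 1/2; invariant under strictly increasing transforms of
    the scores.  Requires both classes.
    """
    outcomes = np.asarray(outcomes)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(outcomes)) < 2:
        raise ValueError("both outcome classes must be present for ROC AUC")
    if np.ptp(scores) == 0:
        return 0.5  # all tied: chance discrimination
    return float(roc_auc_score(outcomes, scores))


def anova_dunnett(
    groups: Mapping[str, Sequence[float]],
    control: str,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> GroupComparison:
    """One-way ANOVA followed by Dunnett's comparisons versus control.

    Each treatment group is compared two-sided against the shared control
    with the family-wise error held at ``alpha`` under the equicorrelated
    multivariate-t reference (pooled variance).  ``rng`` seeds the
    numerical evaluation of the multivariate-t distribution so p-values
    are reproducible.

    Degenerate input (zero pooled variance, all group means equal) returns
    adjusted p of 1 for every group: no detectable difference.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} not among groups {list(groups)}")
    if len(groups) < 2:
        raise ValueError("need at least one treatment group besides control")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {name!r} needs n >= 2, got {len(arr)}")
    treatment_names = [k for k in arrays if k != control]
    samples = [arrays[k] for k in treatment_names]
    control_data = arrays[control]

    pooled_var = np.concatenate(list(arrays.values())).var(ddof=1)
    means = {k: float(np.mean(v)) for k, v in arrays.items()}
    if pooled_var == 0:
        # all observations identical: nothing to compare
        adjusted = {k: 1.0 for k in treatment_names}
        return GroupComparison(
            control_label=control,
            group_means=means,
            group_ns={k: len(v) for k, v in arrays.items()},
            f_statistic=float("nan"),
            anova_p=1.0,
            adjusted_p=adjusted,
            significant={k: False for k in treatment_names},
            alpha=alpha,
        )

    f_statistic, anova_p = stats.f_oneway(*arrays.values())
    dunnett_res = stats.dunnett(
        *samples, control=control_data, alternative="two-sided", rng=rng
    )
    adjusted = {
        name: float(min(p, 1.0))
        for name, p in zip(treatment_names, dunnett_res.pvalue)
    }
    return GroupComparison(
        control_label=control,
        group_means=means,
        group_ns={k: len(v) for k, v in arrays.items()},
        f_statistic=float(f_statistic),
        anova_p=float(anova_p),
        adjusted_p=adjusted,
        significant={k: p < alpha for k, p in adjusted.items()},
        alpha=alpha,
    )
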