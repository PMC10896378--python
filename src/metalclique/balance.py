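"""Propensity-score subclassification to balance covariates across groups.

Membership in the microbe-present group is not randomized; covariates may
confound it.  A logistic propensity model on all covariates assigns each
participant a probability of group membership; participants are cut into
subclasses at propensity quantiles; and marginal-mean-weighting-through-
stratification weights — ``(n_s / N) * (N_g / n_{s,g})`` for a member of
group ``g`` in subclass ``s`` — reweight each group to the subclass mix of
the whole sample (an ATE-style estimand).  Balance is judged by per-covariate
standardized mean differences before and after weighting (love plot).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import COVARIATES
from .screen import build_design

logger = logging.getLogger(__name__)


@dataclass
class BalanceResult:
    propensity: np.ndarray          # in (0, 1)
    subclass: np.ndarray            # 1..S per participant
    weight: np.ndarray              # positive, group totals preserved
    smd_before: pd.Series
    smd_after: pd.Series
    merges: list[str] = field(default_factory=list)

    def love_plot_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": self.smd_before.index,
            "smd_before": self.smd_before.to_numpy(),
            "smd_after": self.smd_after.reindex(self.smd_before.index).to_numpy(),
        })


def estimate_propensity(
    table: pd.DataFrame,
    covariates: Sequence[str] = COVARIATES,
    group: str = "microbe_present",
) -> np.ndarray:
    """Fitted probabilities from a logistic model of group on all covariates."""
    g = table[group].to_numpy(dtype=float)
    if len(np.unique(g)) < 2:
        raise ValueError("both groups must be nonempty")
    X = build_design(table, covariates)
    if np.isnan(X.to_numpy()).any():
        raise ValueError("complete covariates required (impute first)")
    try:
        res = sm.GLM(g, X, family=sm.families.Binomial()).fit(maxiter=200)
        p = np.asarray(res.predict(X))
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(
            "propensity model failed (perfect separation or singular design); "
            "consider fewer covariates or penalization"
        ) from exc
    # quasi-separation of a sparse cell pushes a few fitted probabilities to
    # the boundary; that is tolerable, but widespread separation is not
    boundary = (p < 1e-8) | (p > 1 - 1e-8)
    if boundary.mean() > 0.1:
        raise ValueError(
            "propensity model shows separation (fitted probabilities at 0/1); "
            "consider fewer covariates or penalization"
        )
    if boundary.any():
        logger.warning(
            "%d fitted propensities at the boundary (sparse cell); clipped",
            int(boundary.sum()),
        )
    return np.clip(p, 1e-12, 1 - 1e-12)


def subclassify(
    propensity: np.ndarray,
    group: np.ndarray,
    n_subclasses: int = 6,
    table: pd.DataFrame | None = None,
    covariates: Sequence[str] = COVARIATES,
) -> BalanceResult:
    """Cut at propensity quantiles and compute stratification weights.

    Subclasses in which either group is unrepresented are merged into the
    adjacent subclass toward the median propensity (logged).  When a table
    is supplied, standardized mean differences before/after weighting are
    attached.
    """
    if n_subclasses < 2:
        raise ValueError("n_subclasses must be >= 2")
    ps = np.asarray(propensity, dtype=float)
    g = np.asarray(group).astype(int)
    n = len(ps)
    edges = np.quantile(ps, np.linspace(0, 1, n_subclasses + 1)[1:-1])
    sub = np.searchsorted(edges, ps, side="left")  # 0..S-1

    merges: list[str] = []
    def usable(labels: np.ndarray) -> bool:
        for s in np.unique(labels):
            m = labels == s
            if len(np.unique(g[m])) < 2:
                return False
        return True

    while not usable(sub):
        labels = np.unique(sub)
        if len(labels) < 2:
            raise ValueError("after merging, fewer than 2 usable subclasses")
        # merge the first offending subclass toward the median label
        med = np.median(labels)
        for s in labels:
            m = sub == s
            if len(np.unique(g[m])) < 2:
                others = labels[labels != s]
                toward = others[others > s] if s < med else others[others < s][::-1]
                target = toward[0] if len(toward) else others[np.argmin(np.abs(others - s))]
                merges.append(f"merged subclass {s} into {target} (missing a group)")
                sub[m] = target
                break
    labels = np.unique(sub)
    if len(labels) < 2:
        raise ValueError("after merging, fewer than 2 usable subclasses")

    weight = np.empty(n)
    n_g = np.array([(g == 0).sum(), (g == 1).sum()], dtype=float)
    for s in labels:
        m = sub == s
        n_s = m.sum()
        for gv in (0, 1):
            mg = m & (g == gv)
            weight[mg] = (n_s / n) * (n_g[gv] / mg.sum())
    for msg in merges:
        logger.info(msg)

    # relabel 1..S in propensity order
    relabel = {s: i + 1 for i, s in enumerate(sorted(labels))}
    sub_out = np.array([relabel[s] for s in sub])

    smd_before = smd_after = pd.Series(dtype=float)
    if table is not None:
        smd_before = standardized_mean_differences(table, g, None, covariates)
        smd_after = standardized_mean_differences(table, g, weight, covariates)
    return BalanceResult(
        propensity=ps, subclass=sub_out, weight=weight,
        smd_before=smd_before, smd_after=smd_after, merges=merges,
    )


def standardized_mean_differences(
    table: pd.DataFrame,
    group: np.ndarray | str = "microbe_present",
    weights: np.ndarray | None = None,
    covariates: Sequence[str] = COVARIATES,
) -> pd.Series:
    """Per-covariate (weighted mean difference) / pooled SD.

    Categorical covariates expand to indicators.  The denominator is the
    unweighted pooled SD sqrt((s0^2 + s1^2) / 2) from the full sample, fixed
    so before/after comparisons share a scale; zero pooled SD yields SMD 0
    with a logged flag.
    """
    g = (
        table[group].to_numpy(dtype=int) if isinstance(group, str)
        else np.asarray(group).astype(int)
    )
    w = np.ones(len(g)) if weights is None else np.asarray(weights, dtype=float)
    X = build_design(table, covariates).drop(columns="const")
    out = {}
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        m0, m1 = (g == 0), (g == 1)
        mean0 = np.average(x[m0], weights=w[m0])
        mean1 = np.average(x[m1], weights=w[m1])
        s0 = x[m0].std(ddof=1) if m0.sum() > 1 else 0.0
        s1 = x[m1].std(ddof=1) if m1.sum() > 1 else 0.0
        pooled = np.sqrt((s0**2 + s1**2) / 2)
        if pooled == 0:
            logger.warning("zero pooled SD for %s; SMD reported as 0", col)
            out[col] = 0.0
        else:
            out[col] = (mean1 - mean0) / pooled
    return pd.Series(out)


def balance_cohort(
    table: pd.DataFrame,
    covariates: Sequence[str] = COVARIATES,
    group: str = "microbe_present",
    n_subclasses: int = 6,
) -> BalanceResult:
    """Propensity estimation + subclassification in one step."""
    ps = estimate_propensity(table, covariates, group)
    return subclassify(
        ps, table[group].to_numpy(), n_subclasses, table, covariates
    )
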