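"""Covariate-adjusted single-exposure associations with the log outcome.

Each of the 22 exposures (and the microbe-presence flag) is entered one at a
time into a linear model of log t-CDI on the term plus the standard covariate
set; 95% CIs come from the t distribution, and the 22 exposure p-values are
adjusted by the Benjamini-Hochberg step-up procedure (the FDR family is the
22 exposure tests).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cliques import EXPOSURE_KEYS
from .cohort import CATEGORICAL_COVARIATES, COVARIATES


@dataclass
class AssociationResult:
    """A fitted association: effect, CI, model p, optional FDR/permutation p."""

    term: str
    beta: float
    ci_low: float
    ci_high: float
    p_model: float
    n: int
    p_fdr: float | None = None
    p_rand: float | None = None
    subgroup_prevalence: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")
        for p in (self.p_model, self.p_fdr, self.p_rand):
            if p is not None and not (0.0 <= p <= 1.0 or np.isnan(p)):
                raise ValueError(f"p-value outside [0, 1]: {p}")

    def as_row(self) -> dict:
        return {
            "term": self.term, "beta": self.beta,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_model": self.p_model, "p_fdr": self.p_fdr,
            "p_rand": self.p_rand, "n": self.n,
            "subgroup_prevalence": self.subgroup_prevalence,
        }


def build_design(
    df: pd.DataFrame, covariates: Sequence[str] = COVARIATES
) -> pd.DataFrame:
    """Intercept + covariate design matrix, categoricals as indicator contrasts."""
    cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
    for c in covariates:
        if c in CATEGORICAL_COVARIATES:
            vals = df[c].to_numpy()
            for level in sorted(pd.unique(vals))[1:]:
                cols[f"{c}_{level}"] = (vals == level).astype(float)
        else:
            cols[c] = df[c].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def fit_adjusted(
    df: pd.DataFrame,
    term: str | np.ndarray,
    outcome: str = "log_tcdi",
    covariates: Sequence[str] = COVARIATES,
    weights: np.ndarray | None = None,
    per_sd: bool = False,
    term_name: str | None = None,
) -> AssociationResult:
    """OLS (or weighted LS) of the outcome on one term plus covariates.

    ``term`` is a column name or a numeric vector; with ``per_sd`` the term
    is scaled to unit SD for interpretability.  Raises on a rank-deficient
    design (e.g. a constant term column).
    """
    y = df[outcome].to_numpy(dtype=float)
    if isinstance(term, str):
        x = df[term].to_numpy(dtype=float)
        name = term_name or term
    else:
        x = np.asarray(term, dtype=float)
        name = term_name or "term"
    if np.isnan(y).any() or np.isnan(x).any():
        raise ValueError("missing cells present; impute before fitting")
    if per_sd:
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"term {name} is constant; cannot scale per SD")
        x = x / sd
    X = build_design(df, covariates)
    X.insert(1, name, x)
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise np.linalg.LinAlgError(
            f"singular design matrix fitting term {name!r} "
            "(constant or collinear column)"
        )
    if weights is None:
        model = sm.OLS(y, X)
    else:
        w = np.asarray(weights, dtype=float)
        if (w < 0).any() or not np.isfinite(w).all():
            raise ValueError("weights must be finite and non-negative")
        model = sm.WLS(y, X, weights=w)
    res = model.fit()
    ci = res.conf_int().loc[name]
    return AssociationResult(
        term=name,
        beta=float(res.params[name]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_model=float(res.pvalues[name]),
        n=len(df),
    )


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def screen_all(
    df: pd.DataFrame,
    covariates: Sequence[str] = COVARIATES,
    weights: np.ndarray | None = None,
    per_sd: bool = False,
) -> pd.DataFrame:
    """Fit every exposure (plus microbe presence) one at a time; BH-adjust.

    The FDR family is the 22 exposure tests; the microbe row carries no
    adjusted p.  Returns a forest-plot-ready table.
    """
    results: list[AssociationResult] = []
    for key in EXPOSURE_KEYS:
        try:
            results.append(
                fit_adjusted(df, key, covariates=covariates, weights=weights,
                             per_sd=per_sd)
            )
        except Exception as exc:
            raise RuntimeError(f"fit failed for exposure {key}") from exc
    adj = bh_fdr([r.p_model for r in results])
    for r, a in zip(results, adj):
        r.p_fdr = float(a)
    results.append(
        fit_adjusted(df, "microbe_present", covariates=covariates,
                     weights=weights)
    )
    return pd.DataFrame([r.as_row() for r in results])


def forest_plot(results: pd.DataFrame, path=None, title: str = ""):
    """Minimal forest plot of screen results (beta with 95% CI per term)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.3 * len(results) + 1.5))
    ypos = np.arange(len(results))[::-1]
    ax.errorbar(
        results["beta"], ypos,
        xerr=[results["beta"] - results["ci_low"],
              results["ci_high"] - results["beta"]],
        fmt="o", color="k", ecolor="gray", capsize=2,
    )
    ax.axvline(0.0, ls=":", color="gray")
    ax.set_yticks(ypos)
    ax.set_yticklabels(results["term"])
    ax.set_xlabel("beta (log outcome) with 95% CI")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
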