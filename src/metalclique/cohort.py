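"""Cohort table I/O, validation, imputation and descriptive statistics.

The cohort rectangle has one row per participant: 22 exposure columns
(``<metal>_<T2|T3>``, maternal blood concentrations in ug/L), a binary
microbe-presence flag, a continuous t-scored depression outcome (``tcdi``,
normalized to [0, 100]), six covariates and a binary negative-control outcome
(``pet``).  The outcome is modelled on the natural-log scale (``log_tcdi``).

Missing covariate values (by design confined to maternal age and child age,
each under 5%) are imputed by predictive mean matching within a
chained-equations loop: fit a predictive regression on observed rows, match
each missing row to the ``k`` observed donors with the nearest predicted
values, and draw one donor's observed value at random.  Imputed values are
therefore always members of the observed support of the column.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cliques import EXPOSURE_KEYS

logger = logging.getLogger(__name__)

#: Covariates adjusted for in every regression model.
COVARIATES = ("sex", "ses", "maternal_age", "maternal_bmi", "child_age", "batch")
#: The 3-level socioeconomic-status covariate is expanded to indicator contrasts.
CATEGORICAL_COVARIATES = ("ses",)
CONTINUOUS_COVARIATES = ("maternal_age", "maternal_bmi", "child_age")
#: Covariates in which missing values may occur (imputed by PMM).
IMPUTABLE_COVARIATES = ("maternal_age", "child_age")

MANDATORY_COLUMNS = ("participant_id", "microbe_present", "tcdi", "pet") + COVARIATES


class SchemaError(ValueError):
    """A cohort file does not match the expected column schema."""


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table, drop rows with missing outcome, add log_tcdi.

    Rows with a missing outcome are dropped with a logged count (the analysis
    sample is participants with complete outcome data).  Raises
    :class:`SchemaError` for missing columns, non-numeric exposures or
    outcomes outside [0, 100].
    """
    missing_cols = [
        c for c in MANDATORY_COLUMNS + EXPOSURE_KEYS if c not in df.columns
    ]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing_cols)}")
    df = df.copy()
    for col in EXPOSURE_KEYS:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"non-numeric exposure column {col}") from exc
    n_before = len(df)
    df = df[df["tcdi"].notna()].reset_index(drop=True)
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info(
            "dropped %d of %d rows with missing outcome; %d remain",
            n_dropped, n_before, len(df),
        )
    tcdi = pd.to_numeric(df["tcdi"], errors="raise")
    if ((tcdi < 0) | (tcdi > 100)).any():
        raise SchemaError("tcdi outside [0, 100]")
    if (tcdi <= 0).any():
        raise SchemaError("log transform requires tcdi > 0")
    df["tcdi"] = tcdi.astype(float)
    df["log_tcdi"] = np.log(df["tcdi"])
    return df


def read_cohort(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a cohort CSV/TSV, apply an optional column mapping, validate.

    ``schema`` maps file column names to canonical names (e.g.
    ``{"zinc_tri2": "Zn_T2"}``).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if schema:
        df = df.rename(columns=dict(schema))
    return validate_cohort(df)


def write_cohort(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a cohort table as TSV with a JSON metadata sidecar."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta or {}, indent=2, default=str))


# ---------------------------------------------------------------------------
# Predictive mean matching / chained equations
# ---------------------------------------------------------------------------

def _pmm_design(df: pd.DataFrame, target: str, predictors: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for c in predictors:
        if c == target:
            continue
        if c in CATEGORICAL_COVARIATES:
            vals = df[c].to_numpy()
            for level in sorted(pd.unique(vals))[1:]:
                cols.append((vals == level).astype(float))
        else:
            cols.append(df[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def pmm_impute(
    df: pd.DataFrame,
    columns: Sequence[str] = IMPUTABLE_COVARIATES,
    n_chains: int = 1,
    n_iterations: int = 5,
    k_donors: int = 5,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Impute missing covariates by chained-equation predictive mean matching.

    Each missing cell is filled with an *observed* donor value: a linear
    predictive model is fit on complete rows, rows are matched on the
    predicted value, and one of the ``k_donors`` nearest donors is drawn
    uniformly.  A single completed dataset is returned (``n_chains`` chains
    are run sequentially and the last is kept; the default single chain
    suffices for downstream single-rectangle analyses).
    """
    df = df.copy()
    other = [c for c in COVARIATES if c not in columns]
    predictors = list(other) + ["log_tcdi"] + list(columns)
    with_missing = [c for c in columns if df[c].isna().any()]
    for c in df.columns:
        if c not in columns and df[c].isna().any():
            raise ValueError(f"missingness outside declared-imputable columns: {c}")
    for c in with_missing:
        frac = df[c].isna().mean()
        if frac >= 0.5:
            raise ValueError(f"column {c} is {frac:.0%} missing (>= 50%)")
        if df[c].notna().sum() == 0:
            raise ValueError(f"column {c} entirely missing; no donors")
    if not with_missing:
        return df

    rng = np.random.default_rng(seed)
    result = df
    for _ in range(max(1, n_chains)):
        work = df.copy()
        # initialize each missing cell with a random observed draw
        for c in with_missing:
            obs = work[c].dropna().to_numpy(dtype=float)
            miss = work[c].isna()
            work.loc[miss, c] = rng.choice(obs, size=int(miss.sum()), replace=True)
        for _ in range(n_iterations):
            for c in with_missing:
                miss_mask = df[c].isna().to_numpy()
                X = _pmm_design(work, c, predictors)
                y = df[c].to_numpy(dtype=float)
                obs_mask = ~miss_mask
                beta, *_ = np.linalg.lstsq(X[obs_mask], y[obs_mask], rcond=None)
                pred = X @ beta
                donors_pred = pred[obs_mask]
                donors_y = y[obs_mask]
                for i in np.flatnonzero(miss_mask):
                    d = np.abs(donors_pred - pred[i])
                    k = min(k_donors, len(donors_y))
                    nearest = np.argsort(d, kind="stable")[:k]
                    work.iloc[i, work.columns.get_loc(c)] = donors_y[
                        nearest[rng.integers(k)]
                    ]
        result = work
    return result


# ---------------------------------------------------------------------------
# Exact tests and descriptives
# ---------------------------------------------------------------------------

def fisher_exact(table: Sequence[Sequence[int]] | np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2xk contingency table.

    For 2x2 tables this is the conditional hypergeometric test (delegated to
    scipy); for 2xk (k > 2) the Fisher-Freeman-Halton generalization is
    computed by exact enumeration of all tables with the observed margins,
    summing the probabilities of tables no more probable than the observed
    one (with a small relative tolerance for floating-point ties).
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("need a 2xk table with k >= 2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("a table margin is zero")
    if t.shape[1] == 2:
        return float(stats.fisher_exact(t, alternative="two-sided")[1])

    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())
    lg = [math.lgamma(i + 1) for i in range(n + 1)]
    const = sum(lg[r] for r in row) + sum(lg[c] for c in col) - lg[n]

    def log_prob(top: tuple[int, ...]) -> float:
        return const - sum(lg[x] for x in top) - sum(
            lg[c - x] for c, x in zip(col, top)
        )

    lp_obs = log_prob(tuple(t[0]))
    k = t.shape[1]
    p_sum = 0.0

    def recurse(j: int, remaining: int, top: list[int]) -> None:
        nonlocal p_sum
        if j == k - 1:
            if remaining > col[j]:
                return
            lp = log_prob(tuple(top + [remaining]))
            if lp <= lp_obs + 1e-7:
                p_sum += math.exp(lp)
            return
        for x in range(0, min(remaining, col[j]) + 1):
            recurse(j + 1, remaining - x, top + [x])

    recurse(0, int(row[0]), [])
    return min(1.0, p_sum)


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration for small groups (both n <= 25, no ties); otherwise the
    normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    exact = (
        len(x) <= 25
        and len(y) <= 25
        and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    )
    method = "exact" if exact else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def descriptives(
    df: pd.DataFrame,
    strata: str = "microbe_present",
    continuous: Sequence[str] = ("maternal_age", "maternal_bmi", "child_age", "tcdi"),
    categorical: Sequence[str] = ("sex", "ses"),
) -> pd.DataFrame:
    """Descriptive statistics overall and per stratum, with test p-values.

    Continuous variables are summarized as mean (SD) and compared between
    strata by the Wilcoxon rank-sum test; categorical variables as n (%)
    with Fisher's exact test (Freeman-Halton for >2 levels).
    """
    groups = sorted(df[strata].unique())
    if len(groups) != 2:
        raise ValueError(f"stratum variable {strata} must have exactly 2 levels")
    g0 = df[df[strata] == groups[0]]
    g1 = df[df[strata] == groups[1]]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("a stratum has zero members")

    rows: list[dict] = []
    for var in categorical:
        levels = sorted(df[var].unique())
        counts = np.array(
            [[int((g[var] == lv).sum()) for lv in levels] for g in (g0, g1)]
        )
        p = fisher_exact(counts)
        rows.append({"variable": var, "level": "", "overall": "", "stratum_0": "",
                     "stratum_1": "", "p_value": p, "test": "fisher_exact"})
        for j, lv in enumerate(levels):
            tot = counts[:, j].sum()
            rows.append({
                "variable": var,
                "level": str(lv),
                "overall": f"{tot} ({100 * tot / len(df):.1f})",
                "stratum_0": f"{counts[0, j]} ({100 * counts[0, j] / len(g0):.1f})",
                "stratum_1": f"{counts[1, j]} ({100 * counts[1, j] / len(g1):.1f})",
                "p_value": np.nan,
                "test": "",
            })
    for var in continuous:
        if np.allclose(g0[var].to_numpy(dtype=float), g0[var].iloc[0]) and np.allclose(
            g1[var].to_numpy(dtype=float), g1[var].iloc[0]
        ) and g0[var].iloc[0] == g1[var].iloc[0]:
            p = 1.0
        else:
            p = wilcoxon_rank_sum(g0[var].dropna(), g1[var].dropna())
        fmt = lambda s: f"{s.mean():.1f} ({s.std(ddof=1):.1f})"
        rows.append({
            "variable": var, "level": "",
            "overall": fmt(df[var].dropna()),
            "stratum_0": fmt(g0[var].dropna()),
            "stratum_1": fmt(g1[var].dropna()),
            "p_value": p, "test": "wilcoxon_rank_sum",
        })
    return pd.DataFrame(rows)


def correlation_matrix(
    df: pd.DataFrame,
    columns: Iterable[str] = EXPOSURE_KEYS,
    method: str = "spearman",
) -> pd.DataFrame:
    """Exposure correlation matrix (Spearman by default, Pearson optional).

    Spearman uses mid-ranks for ties.  Entries with a constant column (or
    fewer than 3 complete pairs) are undefined and reported as NaN.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    cols = list(columns)
    sub = df[cols].astype(float)
    corr = sub.corr(method=method, min_periods=3)
    constant = sub.std(ddof=0) == 0
    for c in sub.columns[constant]:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr
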