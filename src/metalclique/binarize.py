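"""Quantile-based threshold finding: from signature to binary subgroup.

A discovered clique signature says only which exposures matter and in which
direction.  To act as a subgroup indicator each member needs a percentile
threshold: a participant is in the clique iff every ``+`` member's
concentration is strictly above that member's sample percentile and every
``-`` member's is at or below its percentile.  Sample quantiles use linear
interpolation (the "type 7" convention) throughout; this choice is load-
bearing, since the threshold semantics depend on it.

``find_thresholds`` searches the percentile grid exhaustively (one
percentile per member), keeping candidates whose subgroup prevalence lies
within bounds, and returns the candidate maximizing the absolute t-statistic
of the indicator in the covariate-adjusted regression of the log outcome.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd

from .cliques import CliqueSignature, SignedFeature, ThresholdedClique
from .cohort import COVARIATES
from .screen import build_design

DEFAULT_GRID = tuple(range(5, 100, 5))  # 5th..95th percentile in steps of 5


def indicator(
    clique: ThresholdedClique, table: pd.DataFrame
) -> tuple[np.ndarray, float]:
    """Binary membership vector and prevalence of a thresholded clique.

    The empty clique is the vacuous conjunction (everybody in).
    """
    ind = np.ones(len(table), dtype=bool)
    for sf, pct in clique.members:
        if sf.exposure not in table.columns:
            raise KeyError(f"exposure {sf.exposure} missing from table")
        x = table[sf.exposure].to_numpy(dtype=float)
        q = np.percentile(x, pct)
        ind &= (x > q) if sf.sign == "+" else (x <= q)
    vec = ind.astype(int)
    return vec, float(vec.mean())


def find_thresholds(
    signature: CliqueSignature,
    table: pd.DataFrame,
    covariates: Sequence[str] = COVARIATES,
    grid: Sequence[float] = DEFAULT_GRID,
    prevalence_bounds: tuple[float, float] = (0.05, 0.95),
    outcome: str = "log_tcdi",
    seed: int | None = None,
) -> ThresholdedClique:
    """Exhaustive grid search for the percentile thresholds of a signature.

    For every combination of grid percentiles whose induced prevalence lies
    within ``prevalence_bounds`` (and strictly inside (0, 1)), the log
    outcome is regressed on the indicator plus covariates; the combination
    maximizing |t| of the indicator wins.  Ties break toward thresholds
    nearest the 50th percentile, then lexicographically.  The search is
    deterministic; ``seed`` is accepted for interface symmetry and unused.
    """
    if len(grid) == 0:
        raise ValueError("grid must be nonempty")
    lo, hi = prevalence_bounds
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("prevalence bounds must satisfy 0 < lo < hi < 1")
    members = sorted(signature.members)
    k = len(members)
    n = len(table)
    y = table[outcome].to_numpy(dtype=float)

    # per-member binary columns for each grid percentile
    member_cols: list[np.ndarray] = []
    for sf in members:
        x = table[sf.exposure].to_numpy(dtype=float)
        qs = np.percentile(x, list(grid))
        if sf.sign == "+":
            cols = x[:, None] > qs[None, :]
        else:
            cols = x[:, None] <= qs[None, :]
        member_cols.append(cols)

    # residualize against intercept + covariates once (Frisch-Waugh-Lovell)
    C = build_design(table, covariates).to_numpy(dtype=float)
    Q, _ = np.linalg.qr(C)
    dy = y - Q @ (Q.T @ y)
    dof = n - C.shape[1] - 1
    if dof <= 0:
        raise ValueError("not enough rows for the covariate-adjusted model")

    combos = list(itertools.product(range(len(grid)), repeat=k))
    D = np.empty((n, len(combos)))
    for j, combo in enumerate(combos):
        col = member_cols[0][:, combo[0]].copy()
        for m in range(1, k):
            col &= member_cols[m][:, combo[m]]
        D[:, j] = col
    prev = D.mean(axis=0)
    admissible = (prev >= lo) & (prev <= hi) & (prev > 0) & (prev < 1)
    if not admissible.any():
        raise ValueError(
            "no admissible threshold combination: all prevalences outside "
            f"[{lo}, {hi}]"
        )
    Da = D[:, admissible]
    dx = Da - Q @ (Q.T @ Da)
    sxx = (dx * dx).sum(axis=0)
    sxy = dx.T @ dy
    syy = float(dy @ dy)
    beta = sxy / sxx
    rss = syy - beta * sxy
    sigma2 = np.maximum(rss, 0.0) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.abs(beta) / np.sqrt(sigma2 / sxx)
    tstat = np.where(np.isfinite(tstat), tstat, np.inf * np.sign(np.abs(beta)))

    adm_idx = np.flatnonzero(admissible)
    grid_arr = np.asarray(grid, dtype=float)

    def tiebreak(j: int) -> tuple:
        combo = combos[adm_idx[j]]
        pcts = tuple(grid_arr[c] for c in combo)
        return (sum(abs(p - 50.0) for p in pcts), pcts)

    best_t = tstat.max()
    contenders = [j for j in range(len(adm_idx)) if tstat[j] >= best_t - 1e-12]
    best = min(contenders, key=tiebreak)
    combo = combos[adm_idx[best]]
    return ThresholdedClique(
        (sf, float(grid_arr[c])) for sf, c in zip(members, combo)
    )


def perturb_thresholds(
    clique: ThresholdedClique, delta: float
) -> ThresholdedClique:
    """Shift every member's percentile by ``delta`` (sensitivity analysis).

    Raises when any shifted percentile leaves the open interval (0, 100).
    """
    members = []
    for sf, pct in clique.members:
        new = pct + delta
        if not (0.0 < new < 100.0):
            raise ValueError(
                f"perturbed percentile for {sf} leaves (0, 100): {new}"
            )
        members.append((sf, new))
    return ThresholdedClique(members)
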