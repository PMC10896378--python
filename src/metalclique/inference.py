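"""Covariate-balanced inference for a thresholded clique, with effect
modification by microbe presence, randomization p-values and sensitivity
analyses.

The headline estimates are (weighted) least-squares associations of the log
outcome with the clique indicator — overall and stratified by microbe
presence — on the covariate-balanced sample.  Randomization p-values
(``P_rand``) permute the outcome vector only, holding the design and weights
fixed, and use the add-one convention so the smallest attainable value is
1/(B+1).  Sensitivity analyses: threshold perturbation by +/-10 percentiles,
a binarized (>= 75th percentile) outcome on the odds-ratio scale, the
unbalanced microbe association, and a negative-control outcome (pet
ownership) that should show no association with the clique.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .binarize import indicator, perturb_thresholds
from .cliques import ThresholdedClique
from .cohort import COVARIATES
from .screen import AssociationResult, build_design, fit_adjusted


@dataclass
class EffectModificationResult:
    """Clique association overall and within microbe strata."""

    overall: AssociationResult
    stratum_absent: AssociationResult | None
    stratum_present: AssociationResult | None
    #: fractions of the FULL sample that are in-clique within each stratum
    prevalence_absent: float
    prevalence_present: float
    interaction: AssociationResult | None = None
    inestimable: list[str] | None = None

    def __post_init__(self) -> None:
        total = self.prevalence_absent + self.prevalence_present
        if self.overall.subgroup_prevalence is not None and not np.isclose(
            total, self.overall.subgroup_prevalence
        ):
            raise ValueError("stratum prevalences must sum to overall prevalence")


def _perm_seed(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def permutation_pvalue(
    y: np.ndarray,
    X: np.ndarray,
    focal: int,
    weights: np.ndarray | None = None,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator = 0,
    chunk: int = 2_000,
) -> float:
    """Randomization p-value for one regression coefficient.

    The outcome vector is permuted (design and weights fixed); the statistic
    is |t| of column ``focal``; p = (1 + #{|t_perm| >= |t_obs|}) / (1 + B).
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    sw = np.ones(n) if weights is None else np.sqrt(np.asarray(weights, dtype=float))
    Xw = X * sw[:, None]
    pinv = np.linalg.pinv(Xw)
    xtx_inv_jj = float((pinv @ pinv.T)[focal, focal])
    dof = n - p

    def tstats(Y: np.ndarray) -> np.ndarray:
        # Y: (n, B) already row-permuted outcomes (unweighted)
        Yw = Y * sw[:, None]
        B = pinv @ Yw
        resid = Yw - Xw @ B
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(sigma2 * xtx_inv_jj)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = B[focal] / se
        return np.where(np.isfinite(t), t, np.inf)

    t_obs = abs(float(tstats(y[:, None])[0]))
    rng = _perm_seed(seed)
    exceed = 0
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        idx = np.argsort(rng.random((n, b)), axis=0)
        Y = y[idx]
        tp = np.abs(tstats(Y))
        exceed += int((tp >= t_obs - 1e-12).sum())
        done += b
    return (1 + exceed) / (1 + n_permutations)


def _design_with_term(
    df: pd.DataFrame, term: np.ndarray, covariates, name: str = "term"
) -> pd.DataFrame:
    X = build_design(df, covariates)
    X.insert(1, name, np.asarray(term, dtype=float))
    return X


def clique_association(
    table: pd.DataFrame,
    clique: ThresholdedClique,
    weights: np.ndarray | None = None,
    covariates=COVARIATES,
    n_permutations: int | None = None,
    seed: int | np.random.Generator = 0,
    outcome: str = "log_tcdi",
) -> AssociationResult:
    """(Weighted) least squares of the log outcome on the clique indicator."""
    vec, prev = indicator(clique, table)
    if prev in (0.0, 1.0):
        raise ValueError("degenerate clique indicator (all 0 or all 1)")
    res = fit_adjusted(
        table, vec, outcome=outcome, covariates=covariates,
        weights=weights, term_name="clique",
    )
    res.subgroup_prevalence = prev
    if n_permutations:
        X = _design_with_term(table, vec, covariates, "clique")
        res.p_rand = permutation_pvalue(
            table[outcome].to_numpy(dtype=float), X.to_numpy(dtype=float),
            focal=list(X.columns).index("clique"),
            weights=weights, n_permutations=n_permutations, seed=seed,
        )
    return res


def effect_modification(
    table: pd.DataFrame,
    clique: ThresholdedClique,
    weights: np.ndarray | None = None,
    covariates=COVARIATES,
    mode: str = "stratified",
    n_permutations: int | None = None,
    seed: int = 0,
    microbe: str = "microbe_present",
) -> EffectModificationResult:
    """Clique association within microbe strata, plus the interaction test.

    ``stratified`` fits the clique model separately in the microbe-absent
    and microbe-present subsets (each with its slice of the balancing
    weights); ``interaction`` adds a clique-by-microbe product term on the
    full sample.  Stratum prevalences are fractions of the full sample.  A
    stratum whose clique indicator is constant is reported as inestimable
    rather than silently dropped.
    """
    if mode not in ("stratified", "interaction"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = _perm_seed(seed)
    vec, prev = indicator(clique, table)
    m = table[microbe].to_numpy(dtype=int)
    n = len(table)
    overall = clique_association(
        table, clique, weights, covariates, n_permutations, rng
    )
    prev_abs = float((vec[m == 0] == 1).sum()) / n
    prev_pres = float((vec[m == 1] == 1).sum()) / n

    strata: dict[int, AssociationResult | None] = {}
    inestimable: list[str] = []
    for gv, label in ((0, "absent"), (1, "present")):
        mask = m == gv
        sub = table[mask].reset_index(drop=True)
        sub_vec = vec[mask]
        if mask.sum() == 0 or len(np.unique(sub_vec)) < 2:
            strata[gv] = None
            inestimable.append(label)
            continue
        w_sub = None if weights is None else np.asarray(weights)[mask]
        res = fit_adjusted(
            sub, sub_vec, covariates=covariates, weights=w_sub,
            term_name="clique",
        )
        res.subgroup_prevalence = float(sub_vec.mean())
        if n_permutations:
            X = _design_with_term(sub, sub_vec, covariates, "clique")
            res.p_rand = permutation_pvalue(
                sub["log_tcdi"].to_numpy(dtype=float),
                X.to_numpy(dtype=float),
                focal=list(X.columns).index("clique"),
                weights=w_sub, n_permutations=n_permutations, seed=rng,
            )
        strata[gv] = res

    # the formal modification test (interaction model) is always reported;
    # `mode` selects which presentation is the headline in pipeline output
    inter = None
    X = build_design(table, covariates)
    X.insert(1, "clique", vec.astype(float))
    X.insert(2, "microbe", m.astype(float))
    X.insert(3, "clique_x_microbe", (vec * m).astype(float))
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) == Xv.shape[1]:
        y = table["log_tcdi"].to_numpy(dtype=float)
        model = (
            sm.WLS(y, X, weights=np.asarray(weights, dtype=float))
            if weights is not None else sm.OLS(y, X)
        )
        fit = model.fit()
        ci = fit.conf_int().loc["clique_x_microbe"]
        inter = AssociationResult(
            term="clique_x_microbe",
            beta=float(fit.params["clique_x_microbe"]),
            ci_low=float(ci[0]), ci_high=float(ci[1]),
            p_model=float(fit.pvalues["clique_x_microbe"]), n=n,
        )
        if n_permutations:
            inter.p_rand = permutation_pvalue(
                y, Xv, focal=list(X.columns).index("clique_x_microbe"),
                weights=weights, n_permutations=n_permutations, seed=rng,
            )
    else:
        inestimable.append("interaction")
    return EffectModificationResult(
        overall=overall,
        stratum_absent=strata[0],
        stratum_present=strata[1],
        prevalence_absent=prev_abs,
        prevalence_present=prev_pres,
        interaction=inter,
        inestimable=inestimable or None,
    )


def _logistic_or(
    ybin: np.ndarray,
    table: pd.DataFrame,
    vec: np.ndarray,
    weights: np.ndarray | None,
    covariates,
    term_label: str,
) -> AssociationResult:
    """Weighted logistic regression; result on the odds-ratio scale."""
    if len(np.unique(ybin)) < 2:
        raise ValueError("degenerate binary outcome (single class)")
    X = _design_with_term(table, vec, covariates, "clique")
    kw = {} if weights is None else {"var_weights": np.asarray(weights, dtype=float)}
    try:
        fit = sm.GLM(ybin, X, family=sm.families.Binomial(), **kw).fit(maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(
            "logistic fit failed (separation or singular design); a penalized "
            "fallback (e.g. ridge) may be needed"
        ) from exc
    if np.abs(fit.params).max() > 30:
        raise ValueError(
            "logistic fit shows quasi-separation; consider a penalized fallback"
        )
    ci = fit.conf_int().loc["clique"]
    return AssociationResult(
        term=term_label,
        beta=float(np.exp(fit.params["clique"])),
        ci_low=float(np.exp(ci[0])),
        ci_high=float(np.exp(ci[1])),
        p_model=float(fit.pvalues["clique"]),
        n=len(table),
        subgroup_prevalence=float(np.mean(vec)),
    )


def binarized_outcome_analysis(
    table: pd.DataFrame,
    clique: ThresholdedClique,
    threshold_percentile: float = 75.0,
    weights: np.ndarray | None = None,
    covariates=COVARIATES,
) -> AssociationResult:
    """Clique odds ratio for a binarized outcome, I(tcdi >= 75th percentile).

    The cut is the analysis sample's own percentile of the t-scored outcome.
    """
    vec, _ = indicator(clique, table)
    tcdi = table["tcdi"].to_numpy(dtype=float)
    cut = np.percentile(tcdi, threshold_percentile)
    ybin = (tcdi >= cut).astype(float)
    return _logistic_or(
        ybin, table, vec, weights, covariates, term_label="clique_or_binarized"
    )


def negative_control(
    table: pd.DataFrame,
    clique: ThresholdedClique,
    weights: np.ndarray | None = None,
    covariates=COVARIATES,
) -> AssociationResult:
    """Odds ratio of the clique for pet ownership (negative-control outcome).

    A CI covering 1 is consistent with no association, i.e. with minimal
    selection and residual confounding bias.
    """
    if "pet" not in table.columns:
        raise ValueError("pet column (negative-control outcome) missing")
    vec, _ = indicator(clique, table)
    ybin = table["pet"].to_numpy(dtype=float)
    return _logistic_or(
        ybin, table, vec, weights, covariates, term_label="clique_or_pet"
    )


def run_sensitivity_suite(
    table: pd.DataFrame,
    clique: ThresholdedClique,
    weights: np.ndarray | None = None,
    covariates=COVARIATES,
    n_permutations: int | None = 10_000,
    threshold_delta: float = 10.0,
    seed: int = 0,
    enabled: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
) -> dict:
    """Run the six-item sensitivity suite; partial failures are recorded.

    (1) randomization p-values for the main associations; (2) note on the
    minimal covariate set; (3) unbalanced re-fit of the microbe association;
    (4) threshold perturbation by +/- ``threshold_delta`` percentiles with a
    directionality table; (5) binarized-outcome odds ratio; (6) negative-
    control odds ratio.
    """
    rng = np.random.default_rng(seed)
    report: dict = {"clique": str(clique)}

    def run(item: int, key: str, fn):
        if item not in enabled:
            report[key] = {"status": "skipped"}
            return
        try:
            report[key] = {"status": "ok", "result": fn()}
        except Exception as exc:  # suite continues on partial failure
            report[key] = {"status": "failed", "error": str(exc)}

    def item1():
        em = effect_modification(
            table, clique, weights, covariates,
            n_permutations=n_permutations, seed=rng,
        )
        return {
            "overall": em.overall.as_row(),
            "stratum_absent": em.stratum_absent.as_row() if em.stratum_absent else None,
            "stratum_present": (
                em.stratum_present.as_row() if em.stratum_present else None
            ),
            "interaction": em.interaction.as_row() if em.interaction else None,
        }

    run(1, "randomization_pvalues", item1)
    run(2, "minimal_covariates", lambda: {
        "note": "models adjust for the minimal covariate set "
                f"({', '.join(covariates)}); balancing weights address "
                "residual covariate imbalance",
        "covariates": list(covariates),
    })
    run(3, "unbalanced_microbe_association", lambda: fit_adjusted(
        table, "microbe_present", covariates=covariates
    ).as_row())

    def item4():
        base = clique_association(table, clique, weights, covariates)
        rows = []
        for delta in (-threshold_delta, +threshold_delta):
            pert = perturb_thresholds(clique, delta)
            em = effect_modification(table, pert, weights, covariates)
            for label, res in (
                ("overall", em.overall),
                ("absent", em.stratum_absent),
                ("present", em.stratum_present),
            ):
                if res is None:
                    continue
                rows.append({
                    "delta": delta, "stratum": label, "beta": res.beta,
                    "sign_preserved": bool(np.sign(res.beta) == np.sign(base.beta))
                    if label == "overall" else None,
                })
        return {"base_beta": base.beta, "perturbed": rows}

    run(4, "threshold_perturbation", item4)
    run(5, "binarized_outcome", lambda: binarized_outcome_analysis(
        table, clique, 75.0, weights, covariates
    ).as_row())
    run(6, "negative_control", lambda: negative_control(
        table, clique, weights, covariates
    ).as_row())
    return report
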