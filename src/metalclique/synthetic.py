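"""Synthetic cohort generation with a plantable clique-by-microbe interaction.

The generator emulates the structure of a prenatal exposure cohort: 22
weakly correlated log-normal blood-metal concentrations (11 metals at two
trimesters), a binary gut-microbe presence flag linked to covariates, a
t-scored depression outcome generated on the log scale, standard covariates,
and a negative-control outcome (pet ownership) independent of everything.

A ground-truth thresholded clique can be planted: participants inside the
clique subgroup receive an additive log-outcome shift whose size depends on
microbe presence (``effect_in_absent`` / ``effect_in_present``), providing
the recovery target for the discovery and inference stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .binarize import indicator as clique_indicator
from .cliques import EXPOSURE_KEYS, METALS, TRIMESTERS, ThresholdedClique
from .cohort import validate_cohort

#: Plausible geometric means for maternal blood concentrations (ug/L).
DEFAULT_LOG_MEAN = {
    "Pb": np.log(35.0), "As": np.log(1.2), "Cd": np.log(0.45),
    "Cr": np.log(0.9), "Zn": np.log(5000.0), "Se": np.log(100.0),
    "Sb": np.log(0.25), "Cu": np.log(950.0), "Cs": np.log(2.5),
    "Co": np.log(0.3), "Mn": np.log(12.0),
}
DEFAULT_LOG_SD = 0.5
#: Exchangeable latent correlation between exposures ("minimal" correlation).
DEFAULT_EXPOSURE_RHO = 0.2

#: Cohort margins: microbe prevalence, outcome scale, covariate mixes.
DEFAULT_SES_PROBS = (0.545, 0.366, 0.089)  # lower / middle / higher
DEFAULT_SEX_PROB = 0.607                   # P(male)
DEFAULT_BATCH_PROB = 73 / 123              # P(second sequencing batch)


def _default_corr() -> np.ndarray:
    p = len(EXPOSURE_KEYS)
    return np.full((p, p), DEFAULT_EXPOSURE_RHO) + (1 - DEFAULT_EXPOSURE_RHO) * np.eye(p)


def _default_log_means() -> dict[str, float]:
    return {k: DEFAULT_LOG_MEAN[k.split("_")[0]] for k in EXPOSURE_KEYS}


def _default_log_sds() -> dict[str, float]:
    return {k: DEFAULT_LOG_SD for k in EXPOSURE_KEYS}


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort generator.

    Effects (``effect_in_absent``, ``effect_in_present``, covariate effects)
    are additive shifts on the natural-log outcome scale; the outcome is then
    exponentiated back to the t-score scale, calibrated so that with null
    effects its mean and SD match ``outcome_mean`` / ``outcome_sd``.
    """

    n_participants: int = 112
    metal_names: tuple[str, ...] = METALS
    trimesters: tuple[str, ...] = TRIMESTERS
    exposure_log_mean: dict[str, float] = field(default_factory=_default_log_means)
    exposure_log_sd: dict[str, float] = field(default_factory=_default_log_sds)
    exposure_corr: np.ndarray = field(default_factory=_default_corr)
    microbe_prevalence: float = 0.24
    #: log-odds coefficients on centered covariates (confounded assignment)
    microbe_covariate_link: dict[str, float] = field(
        default_factory=lambda: {"maternal_bmi": -0.06, "maternal_age": -0.05}
    )
    outcome_mean: float = 53.0
    outcome_sd: float = 8.1
    planted_clique: ThresholdedClique | None = None
    effect_in_absent: float = 0.0
    effect_in_present: float = 0.0
    #: additive log-outcome effects of centered covariates
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {
            "sex": 0.02, "ses": -0.01, "maternal_age": -0.002,
            "maternal_bmi": 0.002, "child_age": 0.01, "batch": 0.0,
        }
    )
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        corr = np.asarray(self.exposure_corr, dtype=float)
        p = len(self.exposure_keys())
        if corr.shape != (p, p):
            raise ValueError(f"exposure_corr must be {p}x{p}, got {corr.shape}")
        if not np.allclose(corr, corr.T):
            raise ValueError("exposure_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("exposure_corr must have unit diagonal")
        try:
            np.linalg.cholesky(corr + 1e-12 * np.eye(p))
        except np.linalg.LinAlgError as exc:
            raise ValueError("exposure_corr is not positive semi-definite") from exc
        if not (0.0 < self.microbe_prevalence < 1.0):
            raise ValueError("microbe_prevalence must be in (0, 1)")
        if not (0.0 <= self.missing_rate < 0.05):
            raise ValueError("missing_rate must be below 0.05")

    def exposure_keys(self) -> tuple[str, ...]:
        return tuple(
            f"{m}_{t}" for m in self.metal_names for t in self.trimesters
        )

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "SynthConfig":
        """Load a config from YAML/JSON; only scalar fields are expected."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        if "planted_clique" in data and isinstance(data["planted_clique"], str):
            data["planted_clique"] = ThresholdedClique.parse(data["planted_clique"])
        return cls(**data)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a planted clique for recovery tests."""

    clique: ThresholdedClique
    effect_in_absent: float
    effect_in_present: float
    #: subgroup prevalence implied by the thresholds under independent exposures
    implied_prevalence: float


def planted_truth(config: SynthConfig) -> PlantedTruth:
    """Return the planted ground truth, with its implied subgroup prevalence.

    The implied prevalence multiplies per-member marginal probabilities
    (1 - q/100 for ``+`` at percentile q, q/100 for ``-``), which is exact
    when the member exposures are independent.
    """
    if config.planted_clique is None:
        raise ValueError("no planted clique configured")
    prev = 1.0
    for sf, pct in config.planted_clique.members:
        prev *= (1.0 - pct / 100.0) if sf.sign == "+" else pct / 100.0
    return PlantedTruth(
        clique=config.planted_clique,
        effect_in_absent=config.effect_in_absent,
        effect_in_present=config.effect_in_present,
        implied_prevalence=prev,
    )


def generate_cohort(config: SynthConfig) -> pd.DataFrame:
    """Generate one synthetic cohort table.

    Deterministic given ``config.seed``.  Exposures are correlated
    log-normals (Gaussian copula on the log scale); the microbe flag is a
    covariate-linked Bernoulli with its intercept calibrated so the expected
    prevalence matches the config; the outcome is a log-scale linear model
    with Gaussian noise, exponentiated to the t-score scale and capped at
    100; the negative-control outcome is an independent fair coin.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    keys = config.exposure_keys()
    p = len(keys)

    # exposures: latent MVN -> per-exposure log-normal
    corr = np.asarray(config.exposure_corr, dtype=float)
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(p))
    z = rng.standard_normal((n, p)) @ L.T
    log_mu = np.array([config.exposure_log_mean[k] for k in keys])
    log_sd = np.array([config.exposure_log_sd[k] for k in keys])
    exposures = pd.DataFrame(np.exp(log_mu + log_sd * z), columns=list(keys))

    # covariates
    sex = rng.binomial(1, DEFAULT_SEX_PROB, n)
    ses = rng.choice(3, size=n, p=DEFAULT_SES_PROBS)
    maternal_age = np.clip(rng.normal(28.7, 5.8, n), 18.0, 45.0)
    maternal_bmi = np.clip(rng.normal(27.3, 4.5, n), 16.0, 45.0)
    child_age = np.clip(rng.normal(9.7, 0.9, n), 8.0, 12.0)
    batch = rng.binomial(1, DEFAULT_BATCH_PROB, n)
    cov = {
        "sex": sex.astype(float), "ses": ses.astype(float),
        "maternal_age": maternal_age, "maternal_bmi": maternal_bmi,
        "child_age": child_age, "batch": batch.astype(float),
    }
    centered = {k: v - v.mean() for k, v in cov.items()}

    # microbe: covariate-linked Bernoulli, intercept calibrated to prevalence
    eta = np.zeros(n)
    for name, coef in config.microbe_covariate_link.items():
        eta += coef * centered[name]
    lo, hi = -30.0, 30.0
    f = lambda a: expit(a + eta).mean() - config.microbe_prevalence
    alpha = brentq(f, lo, hi)
    microbe = rng.binomial(1, expit(alpha + eta))

    # outcome on log scale, calibrated to t-score mean/SD under null effects
    cv = config.outcome_sd / config.outcome_mean
    sigma_log = np.sqrt(np.log1p(cv**2))
    mu_log = np.log(config.outcome_mean) - sigma_log**2 / 2
    log_y = mu_log + rng.normal(0.0, sigma_log, n)
    for name, coef in config.covariate_effects.items():
        log_y += coef * centered[name]
    if config.planted_clique is not None:
        in_clique, _ = clique_indicator(config.planted_clique, exposures)
        log_y += config.effect_in_absent * in_clique * (1 - microbe)
        log_y += config.effect_in_present * in_clique * microbe
    tcdi = np.minimum(np.exp(log_y), 100.0)

    pet = rng.binomial(1, 0.5, n)  # negative control, independent of all else

    df = pd.DataFrame({"participant_id": [f"P{i:04d}" for i in range(n)]})
    df = pd.concat([df, exposures], axis=1)
    df["microbe_present"] = microbe
    df["tcdi"] = tcdi
    for k in ("sex", "ses", "batch"):
        df[k] = cov[k].astype(int)
    for k in ("maternal_age", "maternal_bmi", "child_age"):
        df[k] = cov[k]
    df["pet"] = pet

    # MCAR missingness on the imputable covariates
    if config.missing_rate > 0:
        for colname in ("maternal_age", "child_age"):
            mask = rng.random(n) < config.missing_rate
            df.loc[mask, colname] = np.nan

    return validate_cohort(df)
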