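"""End-to-end pipeline: simulate/read -> impute -> screen -> discover ->
binarize -> balance -> infer -> sensitivity.

The three analysis stages mirror the study design: individual-exposure
screening, the microbe association, and clique discovery + covariate-
balanced clique inference.  A single global seed fans out to per-stage seeds
through a spawned ``numpy`` SeedSequence (stage order fixed), so each stage
is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import balance as balance_mod
from . import binarize as binarize_mod
from . import inference, screen, synthetic
from .cliques import CliqueSignature, SignedFeature, ThresholdedClique, top_k
from .cohort import COVARIATES, descriptives, pmm_impute, read_cohort, write_cohort
from .discovery import RhSirfConfig, clique_network, rh_sirf

_STAGES = (
    "simulate", "impute", "screen", "discover", "binarize",
    "balance", "infer", "sensitivity",
)


@dataclass
class PipelineConfig:
    """Serializable configuration of a full pipeline run."""

    seed: int = 0
    cohort_path: str | None = None  # when None, a cohort is simulated
    synth: dict = field(default_factory=dict)       # SynthConfig overrides
    rh_sirf: dict = field(default_factory=dict)     # RhSirfConfig overrides
    grid_step: float = 5.0
    prevalence_bounds: tuple[float, float] = (0.05, 0.95)
    n_subclasses: int = 6
    n_permutations: int = 10_000
    top_k: int = 3
    orders: tuple[int, ...] = (2, 3)
    verbosity: int = 1

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "prevalence_bounds" in data:
            data["prevalence_bounds"] = tuple(data["prevalence_bounds"])
        if "orders" in data:
            data["orders"] = tuple(data["orders"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["prevalence_bounds"] = list(self.prevalence_bounds)
        d["orders"] = list(self.orders)
        return d


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed (counter scheme)."""
    counter = _STAGES.index(stage)
    return int(
        np.random.SeedSequence(global_seed).spawn(len(_STAGES))[counter]
        .generate_state(1)[0] % (2**31)
    )


def union_signature(records) -> CliqueSignature:
    """Union the signed features of the chosen top signatures.

    If the same exposure appears with both signs across signatures, the sign
    from the higher-stability signature wins.
    """
    seen: dict[str, SignedFeature] = {}
    for rec in records:
        for sf in sorted(rec.signature.members):
            seen.setdefault(sf.exposure, sf)
    return CliqueSignature(seen.values())


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full pipeline, writing artifacts under ``outdir``.

    Returns the consolidated results dict (also written as results.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config.to_dict()}

    # --- cohort
    if config.cohort_path:
        table = read_cohort(config.cohort_path)
    else:
        synth_cfg = synthetic.SynthConfig(
            seed=stage_seed(config.seed, "simulate"), **config.synth
        )
        table = synthetic.generate_cohort(synth_cfg)
    write_cohort(table, outdir / "cohort.tsv", {"seed": config.seed})

    # --- impute + descriptives
    table = pmm_impute(table, seed=stage_seed(config.seed, "impute"))
    desc = descriptives(table)
    desc.to_csv(outdir / "descriptives.tsv", sep="\t", index=False)

    # --- stage 1 & 2: individual screening and microbe association
    screen_tab = screen.screen_all(table)
    screen_tab.to_csv(outdir / "screen.tsv", sep="\t", index=False)
    results["screen"] = {
        "n_exposures": int(len(screen_tab) - 1),
        "n_fdr_significant": int((screen_tab["p_fdr"].dropna() < 0.05).sum()),
    }

    # --- stage 3a: discovery
    rh_cfg = _build_rh_config(config.rh_sirf)
    records = rh_sirf(table, rh_cfg, seed=stage_seed(config.seed, "discover"))
    pd.DataFrame([r.as_row() for r in records]).to_csv(
        outdir / "stability.tsv", sep="\t", index=False
    )
    eligible = [r for r in records if r.order in config.orders]
    if not eligible:
        raise RuntimeError("discovery produced no signatures of the requested orders")
    top = top_k(eligible, config.top_k)
    edges, closed = clique_network(top, k=config.top_k)
    edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    results["discovery"] = {
        "n_signatures": len(records),
        "n_two_component": sum(1 for r in records if r.order == 2),
        "top": [r.as_row() for r in top],
        "closed_loop": bool(closed),
    }

    # --- stage 3b: binarize the union signature of the top combinations
    signature = union_signature(top)
    grid = tuple(
        float(g) for g in np.arange(config.grid_step, 100, config.grid_step)
    )
    clique = binarize_mod.find_thresholds(
        signature, table, grid=grid, prevalence_bounds=config.prevalence_bounds
    )
    (outdir / "clique.json").write_text(clique.to_json())

    # --- balance
    bal = balance_mod.balance_cohort(table, n_subclasses=config.n_subclasses)
    bal.love_plot_table().to_csv(outdir / "love_plot.tsv", sep="\t", index=False)
    pd.DataFrame({
        "participant_id": table["participant_id"],
        "propensity": bal.propensity,
        "subclass": bal.subclass,
        "weight": bal.weight,
    }).to_csv(outdir / "balance_weights.tsv", sep="\t", index=False)

    # --- inference
    em = inference.effect_modification(
        table, clique, bal.weight,
        n_permutations=config.n_permutations,
        seed=stage_seed(config.seed, "infer"),
    )
    # microbe association on both the balanced and unbalanced data
    microbe_balanced = screen.fit_adjusted(
        table, "microbe_present", weights=bal.weight
    )
    microbe_unbalanced = screen.fit_adjusted(table, "microbe_present")
    results["inference"] = {
        "clique": str(clique),
        "microbe_balanced": microbe_balanced.as_row(),
        "microbe_unbalanced": microbe_unbalanced.as_row(),
        "overall": em.overall.as_row(),
        "stratum_absent": em.stratum_absent.as_row() if em.stratum_absent else None,
        "stratum_present": (
            em.stratum_present.as_row() if em.stratum_present else None
        ),
        "interaction": em.interaction.as_row() if em.interaction else None,
        "prevalence_absent": em.prevalence_absent,
        "prevalence_present": em.prevalence_present,
    }

    # --- sensitivity
    sens = inference.run_sensitivity_suite(
        table, clique, bal.weight,
        n_permutations=config.n_permutations,
        seed=stage_seed(config.seed, "sensitivity"),
    )
    (outdir / "sensitivity.json").write_text(json.dumps(sens, indent=2, default=str))
    results["sensitivity"] = sens

    (outdir / "results.json").write_text(json.dumps(results, indent=2, default=str))
    return results


def _build_rh_config(overrides: dict) -> RhSirfConfig:
    from .discovery import ForestParams, RITParams

    kwargs = dict(overrides)
    if "forest" in kwargs:
        kwargs["forest"] = ForestParams(**kwargs["forest"])
    if "rit" in kwargs:
        kwargs["rit"] = RITParams(**kwargs["rit"])
    return RhSirfConfig(**kwargs)
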