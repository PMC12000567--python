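"""End-to-end orchestration: inputs -> preprocessing -> sources -> model.

Input CSV schemas (header row mandatory, UTF-8, '.' decimal point):

* ``consumers.csv`` — ``lake_id, taxon, group, d2h, d15n, d13c`` (d13c blank
  allowed)
* ``sources.csv`` — ``lake_id, d2h_water, d2h_inlet_dom, d2h_benthic_algae,
  substitute_lake_id`` (last three blank allowed)
* ``environment.csv`` — ``lake_id`` plus numeric variable columns (>= 15
  complete columns required for PCA)

``run_pipeline`` executes the main analysis; ``run_scenarios`` repeats it over
a grid of assumed omega values and source scenarios and checks that the taxon
ranking of allochthony is preserved (Spearman rank correlation).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .environment import EnvironmentPCA
from .isotope_prep import ConsumerPreprocessor, TrophicConfig
from .mixing_model import AllochthonyMixingModel, MixingModelConfig
from .sources import SourceBuilder, SourceConfig, screen_consumers
from .synthetic import GeneratorConfig, generate_dataset

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    ``consumers``/``sources``/``environment`` may be file paths or in-memory
    DataFrames; alternatively set ``simulate`` to generate them.  ``covariate``
    selects the continuous covariate: ``'pc1'`` (environmental PCA),
    ``'forest_pct'``/``'nc_pom'`` (columns of the environment table),
    ``'latent'`` (the simulated gradient itself; simulate runs only, used for
    parameter-recovery studies) or ``'none'``.
    """

    consumers: object = None
    sources: object = None
    environment: object = None
    lakes: object = None  # simulated lake table (carries the latent covariate)
    simulate: GeneratorConfig | None = None
    trophic: TrophicConfig = field(default_factory=TrophicConfig)
    source: SourceConfig = field(default_factory=SourceConfig)
    mixing: MixingModelConfig = field(default_factory=MixingModelConfig)
    covariate: str = "pc1"
    omega_scenarios: tuple = (0.14, 0.23, 0.32)
    source_scenarios: tuple = ("inlet_dom",)
    out_dir: object = None
    seed: int = 0

    def config_hash(self) -> str:
        blob = repr((self.trophic, self.source, self.mixing, self.covariate,
                     self.omega_scenarios, self.source_scenarios, self.seed))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_table(obj, stage: str) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj.copy()
    if obj is None:
        raise PipelineError(f"{stage}: no input table provided")
    path = Path(obj)
    if not path.exists():
        raise PipelineError(f"{stage}: input file not found: {path}")
    return pd.read_csv(path)


def _resolve_covariate(cfg: RunConfig, env: pd.DataFrame | None, lakes, lake_table=None) -> pd.Series:
    """Per-lake covariate values indexed by lake_id."""
    if cfg.covariate == "none":
        return pd.Series(0.0, index=lakes)
    if cfg.covariate == "latent":
        if lake_table is None or "covariate" not in lake_table.columns:
            raise PipelineError("covariate 'latent' is only available for simulated runs")
        return lake_table.set_index("lake_id")["covariate"].reindex(lakes)
    if env is None:
        raise PipelineError(f"covariate {cfg.covariate!r} requested but no environment table given")
    env = env.set_index("lake_id") if "lake_id" in env.columns else env
    if cfg.covariate == "pc1":
        pca = EnvironmentPCA().fit(env)
        return pca.scores_["PC1"].reindex(lakes)
    if cfg.covariate not in env.columns:
        raise PipelineError(f"covariate column {cfg.covariate!r} not in environment table")
    # centre single-column covariates so the intercept keeps its
    # 'environmentally average lake' meaning
    col = env[cfg.covariate].astype(float)
    return (col - col.mean()).reindex(lakes)


def _assemble(cfg: RunConfig):
    """Load/simulate inputs; returns (consumers, sources_table, env_table, truth, lakes)."""
    truth = None
    lakes = cfg.lakes if isinstance(cfg.lakes, pd.DataFrame) else None
    if cfg.simulate is not None:
        ds = generate_dataset(cfg.simulate)
        lakes = ds["lakes"]
        consumers = ds["consumers"]
        src = lakes[["lake_id", "d2h_water", "d2h_inlet_dom", "d2h_benthic_algae"]].copy()
        src["substitute_lake_id"] = ""
        from .synthetic import _ENV_VARIABLES

        env_cols = ["lake_id"] + [c for c, _ in _ENV_VARIABLES[: cfg.simulate.env_n_variables]]
        env = lakes[env_cols]
        truth = ds["truth"]
    else:
        consumers = _load_table(cfg.consumers, "consumers")
        src = _load_table(cfg.sources, "sources")
        env = _load_table(cfg.environment, "environment") if (
            cfg.environment is not None or cfg.covariate in ("pc1", "forest_pct", "nc_pom")
        ) else None
    return consumers, src, env, truth, lakes


def _prepare_model_data(cfg: RunConfig, consumers, src_table, env, lake_table=None):
    """Preprocess consumers, build source pairs, join covariate."""
    lakes = list(pd.unique(src_table["lake_id"]))
    covariate = _resolve_covariate(cfg, env, lakes, lake_table)

    cons = consumers.merge(src_table[["lake_id", "d2h_water"]], on="lake_id", how="left")
    if cons["d2h_water"].isna().any():
        missing = cons.loc[cons["d2h_water"].isna(), "lake_id"].unique()
        raise PipelineError(f"isotope_prep: no water delta-2H for lake(s) {list(missing)}")
    prep = ConsumerPreprocessor(config=cfg.trophic).fit(cons)
    prepared = prep.transform(cons)

    pairs = SourceBuilder(config=cfg.source).fit(src_table).transform(src_table)
    screen = screen_consumers(prepared, pairs, k=2.0)
    screen3 = screen_consumers(prepared, pairs, k=3.0)
    logger.info(
        "pipeline counts: %d samples, %d imputed baselines, %d methane-fixed, "
        "%d outside +-2SD, %d outside +-3SD",
        len(prepared), int(prepared["baseline_imputed"].sum()),
        int(prepared["methane_fixed"].sum()), screen["n_outside"], screen3["n_outside"],
    )

    data = prepared.merge(pairs, on="lake_id", how="left")
    data["covariate"] = data["lake_id"].map(covariate)
    return data, prepared, pairs, {"k2": screen, "k3": screen3}, prep


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute preprocessing -> sources -> mixing model; return a result dict.

    Keys: ``model`` (fitted estimator), ``summary`` (allochthony summaries),
    ``prepared``, ``source_pairs``, ``screening``, ``diagnostics``,
    ``manifest``, and ``truth`` when simulating.  Writes CSV/JSON outputs
    under ``cfg.out_dir`` when set.
    """
    consumers, src_table, env, truth, lake_table = _assemble(cfg)
    data, prepared, pairs, screening, prep = _prepare_model_data(cfg, consumers, src_table, env, lake_table)

    mix_cfg = dataclasses.replace(cfg.mixing, covariate=cfg.covariate, seed=cfg.seed)
    model = AllochthonyMixingModel(config=mix_cfg).fit(data)
    summary = model.summarize_allochthony(seed=cfg.seed)

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "covariate": cfg.covariate,
        "n_samples": int(len(prepared)),
        "n_lakes": int(data["lake_id"].nunique()),
        "n_taxa": int(data["taxon"].nunique()),
        "n_imputed_baselines": int(prepared["baseline_imputed"].sum()),
        "n_methane_fixed": int(prepared["methane_fixed"].sum()),
        "n_outside_2sd": screening["k2"]["n_outside"],
        "n_outside_3sd": screening["k3"]["n_outside"],
        "converged": bool(model.converged_),
        "rhat_max": float(model.rhat_max_),
        "xi_mean": float(model.xi_mean_),
        "dic": float(model.dic_),
        "approx_r2": float(model.r2_),
    }

    result = {
        "model": model,
        "summary": summary,
        "prepared": prepared,
        "source_pairs": pairs,
        "screening": screening,
        "diagnostics": model.diagnose(),
        "manifest": manifest,
        "data": data,
    }
    if truth is not None:
        result["truth"] = truth

    if cfg.out_dir is not None:
        _write_outputs(cfg, result)
    return result


def _write_outputs(cfg: RunConfig, result: dict):
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = result["model"]
    result["prepared"].to_csv(out / "prepared_consumers.csv", index=False)
    result["source_pairs"].to_csv(out / "source_pairs.csv", index=False)
    result["diagnostics"].to_csv(out / "diagnostics.csv", index=False)
    result["summary"]["taxon_intercepts"].to_csv(out / "taxon_intercepts.csv", index=False)
    result["summary"]["curves"].to_csv(out / "allochthony_curves.csv", index=False)
    result["summary"]["global_curve"].to_csv(out / "global_curve.csv", index=False)
    result["summary"]["lake_taxon"].to_csv(out / "lake_taxon_estimates.csv", index=False)
    screen = result["screening"]["k2"]
    pd.DataFrame(
        [(g, n) for g, n in screen["outside_by_group"].items()],
        columns=["group", "n_outside"],
    ).to_csv(out / "screening_report.csv", index=False)

    long_rows = []
    n_per_chain = [len(c) for c in model.chains_]
    for ci, chain in enumerate(model.chains_):
        for pi, name in enumerate(model.param_names_):
            long_rows.append(
                pd.DataFrame({"chain": ci, "draw": np.arange(len(chain)),
                              "parameter": name, "value": chain[:, pi]})
            )
    pd.concat(long_rows, ignore_index=True).to_csv(out / "posterior_draws.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result["manifest"], fh, indent=2, sort_keys=True)


def run_scenarios(cfg: RunConfig) -> dict:
    """One fit per (omega, source scenario) grid cell plus consistency checks.

    Returns ``table`` (per-taxon intercept allochthony and ILR slope per
    scenario), ``rank_consistency`` (Spearman rho of taxon intercept ranking
    vs the base scenario) and the per-cell results.  Non-converged cells are
    flagged and excluded from the consistency statistic.
    """
    consumers, src_table, env, truth, lake_table = _assemble(cfg)
    cells = {}
    tables = []
    base_key = None
    for scen in cfg.source_scenarios:
        for omega in cfg.omega_scenarios:
            key = f"{scen}_omega{omega:g}"
            c = dataclasses.replace(
                cfg,
                trophic=dataclasses.replace(cfg.trophic, omega=omega),
                source=dataclasses.replace(cfg.source, scenario=scen),
                out_dir=None if cfg.out_dir is None else Path(cfg.out_dir) / key,
                simulate=None,
                consumers=consumers, sources=src_table, environment=env, lakes=lake_table,
            )
            res = run_pipeline(c)
            cells[key] = res
            ti = res["summary"]["taxon_intercepts"].copy()
            ti["scenario"] = scen
            ti["omega"] = omega
            ti["converged"] = res["manifest"]["converged"]
            tables.append(ti)
            if scen == cfg.source.scenario and np.isclose(omega, cfg.trophic.omega):
                base_key = key
    table = pd.concat(tables, ignore_index=True)
    if base_key is None:
        base_key = next(iter(cells))

    base = cells[base_key]["summary"]["taxon_intercepts"].set_index("taxon")["allochthony_median"]
    rank = {}
    for key, res in cells.items():
        if key == base_key:
            continue
        if not res["manifest"]["converged"]:
            rank[key] = np.nan
            continue
        other = res["summary"]["taxon_intercepts"].set_index("taxon")["allochthony_median"]
        rho = stats.spearmanr(base, other.reindex(base.index)).statistic
        rank[key] = float(rho)

    out = {"table": table, "rank_consistency": rank, "base": base_key, "cells": cells}
    if cfg.out_dir is not None:
        outdir = Path(cfg.out_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "scenario_table.csv", index=False)
        with open(outdir / "scenario_consistency.json", "w") as fh:
            json.dump({"base": base_key, "spearman_rho": rank}, fh, indent=2, sort_keys=True)
    return out
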