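"""End-to-end pipeline: simulate/load -> grid -> predictors -> spatial
filters -> variation partitioning, with complete on-disk provenance.

Every stage reads and writes plain CSV/JSON so stages are independently
testable; a run directory ends up holding all intermediates, a diagnostics
JSON collecting warnings, and the fraction tables for both the
environment-only (3-set) and environment-plus-spatial (4-set) partitions.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gridding, predictors, spatial, synthetic
from .errors import InputError
from .partition import ModelSuiteResult, run_model_suite

__all__ = ["RunConfig", "RunResult", "run_all", "load_inputs"]

log = logging.getLogger("synervar")

ENV_SET_PREFIXES = {"climatic": "clim_", "topographic": "topo_", "biotic": "bio_"}


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str = "runs/latest"
    seed: int = 0
    sim: synthetic.SimConfig | None = None   # synthetic run when set
    cells_csv: str | None = None             # otherwise, CSV inputs
    ranges_csv: str | None = None
    landcover_csv: str | None = None
    env_csv: str | None = None
    cell_size: float = 110.0
    mask_threshold: float = 0.5
    k_axes: int = 3
    n_classes: int = 21
    filter_threshold: float = 0.1
    max_filters: int | None = 60
    overlap_rule: str = "any-overlap"
    groups: tuple[str, ...] = ("all",)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = synthetic.SimConfig(**sim)
        return cfg


@dataclass
class RunResult:
    out_dir: Path
    cells: pd.DataFrame
    sets: dict[str, predictors.PredictorSet]
    suites: dict[str, ModelSuiteResult]
    diagnostics: dict = field(default_factory=dict)


def load_inputs(config: RunConfig):
    """Load cells/ranges/landcover/env from CSVs named in the config."""
    needed = {
        "cells_csv": config.cells_csv,
        "ranges_csv": config.ranges_csv,
        "landcover_csv": config.landcover_csv,
        "env_csv": config.env_csv,
    }
    missing = [k for k, v in needed.items() if v is None or not Path(v).exists()]
    if missing:
        raise InputError(f"missing input file(s): {missing}")
    cells = pd.read_csv(config.cells_csv)
    ranges = pd.read_csv(config.ranges_csv)
    landcover = pd.read_csv(config.landcover_csv).set_index("cell_id")
    env = pd.read_csv(config.env_csv).set_index("cell_id")
    return cells, ranges, landcover, env


def _split_env_sets(env: pd.DataFrame, shannon: pd.Series) -> dict[str, pd.DataFrame]:
    """Assign env columns to sets by prefix; Shannon joins the biotic set."""
    sets = {}
    for name, prefix in ENV_SET_PREFIXES.items():
        cols = [c for c in env.columns if c.startswith(prefix)]
        df = env[cols].copy()
        if name == "biotic":
            df["bio_landcover_shannon"] = shannon
        if df.shape[1] == 0:
            raise InputError(f"no columns found for predictor set {name!r}")
        sets[name] = df
    return sets


def run_all(config: RunConfig) -> RunResult:
    """Run the whole pipeline and write every intermediate to the run dir."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    diagnostics: dict = {"warnings": [], "seed": config.seed}

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            result = _run_all_inner(config, out, diagnostics)
        diagnostics["warnings"] = [str(w.message) for w in caught]
        diagnostics["elapsed_s"] = round(time.time() - t0, 3)
        (out / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2, default=str))
        result.diagnostics = diagnostics
        return result
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_all_inner(config: RunConfig, out: Path, diagnostics: dict) -> RunResult:
    import sklearn

    log.info(
        "run start seed=%s numpy=%s pandas=%s sklearn=%s",
        config.seed, np.__version__, pd.__version__, sklearn.__version__,
    )

    # -- stage 1: data -----------------------------------------------------
    if config.sim is not None:
        sim_cfg = config.sim
        if sim_cfg.seed != config.seed:
            sim_cfg = synthetic.SimConfig(**{**sim_cfg.__dict__, "seed": config.seed})
        ds = synthetic.simulate_dataset(sim_cfg)
        ds.write(out)
        cells, ranges, landcover, env = ds.cells, ds.ranges, ds.landcover, ds.env
        cell_size = sim_cfg.cell_size
        log.info("simulated dataset: %d cells, %d species", len(cells), len(ranges))
    else:
        cells, ranges, landcover, env = load_inputs(config)
        cell_size = config.cell_size
        log.info("loaded inputs: %d cells, %d species", len(cells), len(ranges))

    # -- stage 2: grid / richness -----------------------------------------
    cells = gridding.mask_cells(cells, threshold=config.mask_threshold)
    richness = gridding.rasterize_richness(cells, ranges, cell_size, rule=config.overlap_rule)
    cells = cells.copy()
    cells["richness"] = richness
    cells["log_richness"] = gridding.transform_richness(richness)
    inc = cells["included"].to_numpy()
    n_inc = int(inc.sum())
    diagnostics["n_cells"], diagnostics["n_included"] = len(cells), n_inc
    log.info("mask: %d of %d cells included", n_inc, len(cells))
    pd.DataFrame(
        {"cell_id": cells["cell_id"], "group": config.groups[0],
         "richness": cells["richness"], "log_richness": cells["log_richness"]}
    ).to_csv(out / "richness.csv", index=False, float_format="%.10g")

    # -- stage 3: predictor sets ------------------------------------------
    env_inc = env.loc[cells.loc[inc, "cell_id"]]
    lc_inc = landcover.loc[cells.loc[inc, "cell_id"]]
    shannon = pd.Series(
        predictors.shannon_diversity(lc_inc.to_numpy()), index=env_inc.index,
        name="bio_landcover_shannon",
    )
    raw_sets = _split_env_sets(env_inc, shannon)
    sets = {name: predictors.build_set(df, name, k=config.k_axes) for name, df in raw_sets.items()}
    pred_rows = []
    for name, ps in sets.items():
        for i, cid in enumerate(env_inc.index):
            pred_rows.append(
                {"cell_id": cid, "set": name,
                 **{f"axis{a + 1}": ps.scores[i, a] for a in range(ps.k)}}
            )
    pd.DataFrame(pred_rows).to_csv(out / "predictors.csv", index=False, float_format="%.10g")
    diagnostics["pca_varexp"] = {n: ps.varexp[: ps.k].tolist() for n, ps in sets.items()}
    diagnostics["vif"] = {n: ps.vif.tolist() for n, ps in sets.items()}
    log.info("predictor sets built: %s", {n: ps.k for n, ps in sets.items()})

    # -- stage 4: spatial basis -------------------------------------------
    coords = cells.loc[inc, ["x_km", "y_km"]].to_numpy(dtype=float)
    spec = spatial.connectivity(coords)
    basis = spatial.build_mem(spec)
    diagnostics["mst_truncation_km"] = spec.truncation_km
    diagnostics["n_mem_vectors"] = basis.m
    log.info("MEM basis: truncation %.1f km, %d vectors", spec.truncation_km, basis.m)

    # -- stage 5: models and partitions -----------------------------------
    y = cells.loc[inc, "log_richness"].to_numpy()
    fcfg = spatial.FilterSelectionConfig(
        threshold=config.filter_threshold, n_classes=config.n_classes,
        max_filters=config.max_filters,
    )
    env_mats = {n: sets[n].scores for n in ("biotic", "climatic", "topographic")}
    suites = {}
    for group in config.groups:
        suite = run_model_suite(y, env_mats, basis, coords, cfg=fcfg)
        suites[group] = suite
        gtag = f"_{group}" if len(config.groups) > 1 else ""
        suite.env_partition.to_frame().to_csv(out / f"fractions_env{gtag}.csv", index=False, float_format="%.10g")
        suite.full_partition.to_frame().to_csv(out / f"fractions{gtag}.csv", index=False, float_format="%.10g")
        suite.correlogram_before.to_frame().to_csv(out / f"correlogram_before{gtag}.csv", index=False, float_format="%.10g")
        suite.correlogram_after.to_frame().to_csv(out / f"correlogram_after{gtag}.csv", index=False, float_format="%.10g")
        if suite.selection.selected:
            fdf = pd.DataFrame(
                basis.vectors[:, suite.selection.selected],
                columns=[f"filter_{j + 1}" for j in range(len(suite.selection.selected))],
            )
            fdf.insert(0, "cell_id", cells.loc[inc, "cell_id"].to_numpy())
            fdf.to_csv(out / f"filters{gtag}.csv", index=False, float_format="%.10g")
        summary = {
            "adj_r2_full": suite.full_partition.adj_r2_full,
            "residual": suite.full_partition.residual,
            "total_importance": {
                n: suite.full_partition.total_importance(n)
                for n in suite.full_partition.set_names
            },
            "n_filters_selected": len(suite.selection.selected),
            "max_abs_moran_i_before": suite.selection.max_abs_i_initial,
            "max_abs_moran_i_after": suite.selection.max_abs_i,
            "filter_selection_converged": bool(suite.selection.converged),
        }
        (out / f"summary{gtag}.json").write_text(json.dumps(summary, indent=2))
        log.info(
            "group %s: adjR2(full)=%.4f, %d filters, max|I| %.3f -> %.3f",
            group, summary["adj_r2_full"], summary["n_filters_selected"],
            suite.selection.max_abs_i_initial, suite.selection.max_abs_i,
        )

    cells.to_csv(out / "cells_analysis.csv", index=False, float_format="%.10g")
    return RunResult(out_dir=out, cells=cells, sets=sets, suites=suites)
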