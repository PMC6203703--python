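"""End-to-end analysis: from climate rasters and occurrences to refugia.

Stage order, per species group:

1. draw a 5000-point background sample from the bias surface and enumerate
   collinearity-free candidate variable subsets (|r| < 0.70, VIF < 5);
2. per species (>= 5 deduplicated occurrences): AICc-select the variable
   subset at β-multiplier 0, then AICc-select the β-multiplier on the
   0–15-by-0.5 grid;
3. fit replicate models (leave-one-out below 30 occurrences, 10-fold
   cross-validation otherwise) against a 10,000-point bias-drawn background,
   project every replicate to all scenarios, threshold each at its own MSS;
4. evaluate (leave-one-out success rate and Poisson-binomial p; continuous
   Boyce index for cross-validated species);
5. refine (drop pixels below 95% replicate agreement), binarize at the mean
   MSS threshold, and stack binary maps into per-scenario richness;
6. observed-pattern statistics on the 1° grid (richness, rarity-weighted
   richness, core areas, autocorrelation-corrected correlation);
7. intersect per-species maps over the five time combinations, stack into
   refugia maps, and measure areas and the fraction outside reserves.

Per-species failures are logged and skipped; they never abort the run.
"""

from __future__ import annotations

import json
import logging
import math
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np

from . import model_eval, niche_model, refugia, richness_maps, spatial_stats
from .model_eval import (
    EvaluationResult,
    ReplicateEnsemble,
    UndefinedResultError,
    choose_replication_mode,
    mss_threshold,
)
from .raster_core import (
    ClimateStack,
    GridSpec,
    OccurrenceSet,
    RasterLayer,
    extract_at_points,
    read_ascii_grid,
    read_occurrences_csv,
    write_ascii_grid,
)

logger = logging.getLogger("climrefugia")

__all__ = [
    "PipelineConfig",
    "SpeciesResult",
    "PipelineResult",
    "run_pipeline",
    "load_fixture",
    "fit_species",
]


@dataclass
class PipelineConfig:
    """All tunable constants of the analysis, defaulted to the standard
    protocol values."""

    seed: int = 0
    min_occurrences: int = 5
    r_threshold: float = 0.70
    vif_threshold: float = 5.0
    selection_background_n: int = 5000
    fitting_background_n: int = 10_000
    beta_grid: np.ndarray | None = None
    agreement: float = 0.95
    top_fraction: float = 0.2
    rwr_cut: float = 0.7
    analysis_cell_size: float = 1.0
    max_candidates: int = 10_000
    combinations: dict | None = None
    present_id: str = "present"


@dataclass
class SpeciesResult:
    species_id: str
    n_occurrences: int
    mode: str
    subset: tuple[str, ...]
    beta_multiplier: float
    evaluation: EvaluationResult
    binary_maps: dict[str, RasterLayer]
    ensemble: ReplicateEnsemble


@dataclass
class PipelineResult:
    config: PipelineConfig
    species: dict[str, SpeciesResult] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    predicted_richness: dict[str, RasterLayer] = field(default_factory=dict)
    observed_richness: RasterLayer | None = None
    observed_rwr: RasterLayer | None = None
    core_areas_richness: list = field(default_factory=list)
    core_areas_rwr: list = field(default_factory=list)
    correlation: spatial_stats.CorrelationResult | None = None
    refugia_maps: dict[str, RasterLayer] = field(default_factory=dict)
    refugia_areas_km2: dict[str, float] = field(default_factory=dict)
    reserve_gap: dict[str, float] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _draw_background_cells(
    rng: np.random.Generator, grid: GridSpec, bias: RasterLayer | None,
    valid: np.ndarray, n: int,
) -> np.ndarray:
    """Flat cell indices drawn from the bias surface over valid cells."""
    w = np.zeros(grid.n_rows * grid.n_cols)
    if bias is None:
        w[valid] = 1.0
    else:
        w[valid] = np.clip(bias.values.ravel()[valid], 0.0, None)
    if w.sum() <= 0:
        raise ValueError("no positive-weight background cells")
    return rng.choice(w.size, size=n, replace=True, p=w / w.sum())


def _dedup_presence_cells(frame) -> np.ndarray:
    """Unique (row, col) cells from an extraction table, first hit kept."""
    seen = {}
    for i, (r, c) in enumerate(zip(frame["row"], frame["col"])):
        if (r, c) not in seen:
            seen[(r, c)] = i
    return np.array(sorted(seen.values()))


def _scenario_features(stack: ClimateStack, spec, subset):
    vals = stack.values_matrix(list(subset))
    return spec.featurize(vals, clamp=True)


def fit_species(
    species_id: str,
    presence_values: np.ndarray,
    presence_cells: np.ndarray,
    candidates,
    background_values: np.ndarray,
    scenarios: dict[str, ClimateStack],
    variable_names: list[str],
    config: PipelineConfig,
    rng: np.random.Generator,
) -> SpeciesResult:
    """Stages 2–5 for one species: selection, β tuning, replication,
    evaluation, refinement, binarization."""
    n = presence_values.shape[0]
    mode, n_rep = choose_replication_mode(n)
    if mode == "excluded":
        raise UndefinedResultError(f"{species_id}: fewer than 5 occurrences")

    best = niche_model.select_variables(
        list(candidates), presence_values, background_values, variable_names
    )
    beta, _ = niche_model.tune_beta_multiplier(
        best.subset,
        presence_values,
        background_values,
        variable_names,
        grid=config.beta_grid,
    )
    subset = best.subset
    var_idx = [variable_names.index(v) for v in subset]
    pres_sub = presence_values[:, var_idx]
    bg_sub = background_values[:, var_idx]

    # replicate partitions: leave-one-out, or 10 shuffled folds
    if mode == "jackknife":
        partitions = [(np.array([i]),) for i in range(n)]
    else:
        perm = rng.permutation(n)
        partitions = [(fold,) for fold in np.array_split(perm, n_rep)]

    present = scenarios[config.present_id]
    grid = present.spec
    nodata = grid.nodata_value
    valid_by_scenario = {sid: s.valid_mask() for sid, s in scenarios.items()}

    ensemble = ReplicateEnsemble(mode=mode, maps={config.present_id: []})
    per_scenario_binaries: dict[str, list[np.ndarray]] = {
        sid: [] for sid in scenarios
    }
    per_scenario_sum: dict[str, np.ndarray] = {}
    heldout_scores: list[float] = []
    heldout_null: list[float] = []
    heldout_success: list[int] = []
    bg_scores_pool: list[np.ndarray] = []

    models = []
    for (heldout,) in partitions:
        train_mask = np.ones(n, dtype=bool)
        train_mask[heldout] = False
        spec_f, bg_feat, pres_feat = niche_model.build_features(
            list(subset), bg_sub, pres_sub[train_mask]
        )
        model = niche_model.fit_maxent(
            pres_feat, bg_feat, beta_multiplier=beta, feature_spec=spec_f
        )
        models.append(model)
        pres_scores = niche_model.predict_logistic(model, pres_feat)
        bg_scores = niche_model.predict_logistic(model, bg_feat)
        thr = mss_threshold(pres_scores, bg_scores)
        ensemble.thresholds.append(thr)
        bg_scores_pool.append(bg_scores)

        # project to every scenario; keep the present map for evaluation
        rep_maps = {}
        for sid, stack in scenarios.items():
            feats = _scenario_features(stack, spec_f, subset)
            suit = niche_model.predict_logistic(model, feats)
            suit[~valid_by_scenario[sid]] = np.nan
            rep_maps[sid] = suit
            binary = suit >= thr
            if sid in per_scenario_sum:
                per_scenario_sum[sid] += np.where(np.isnan(suit), 0.0, suit)
            else:
                per_scenario_sum[sid] = np.where(np.isnan(suit), 0.0, suit)
            per_scenario_binaries[sid].append(binary)

        pm = rep_maps[config.present_id].copy()
        pm[np.isnan(pm)] = nodata
        ensemble.maps[config.present_id].append(
            RasterLayer(grid, pm.reshape(grid.n_rows, grid.n_cols))
        )
        # held-out predictions on the present map
        hv = rep_maps[config.present_id]
        valid_p = valid_by_scenario[config.present_id]
        area_frac = float(np.nanmean(hv[valid_p] >= thr))
        for i in heldout:
            r, c = presence_cells[i]
            score = hv[r * grid.n_cols + c]
            heldout_scores.append(float(score) if not np.isnan(score) else 0.0)
            heldout_success.append(1 if score >= thr else 0)
            heldout_null.append(area_frac)
        ensemble.heldout_rowcol.append(tuple(presence_cells[heldout[0]]))
    ensemble.models = models

    s = int(np.sum(heldout_success))
    q = s / len(heldout_success)
    p = model_eval.poisson_binomial_tail(heldout_null, s)
    cbi = None
    if mode == "crossvalidation":
        try:
            cbi = model_eval.continuous_boyce_index(
                np.asarray(heldout_scores), np.concatenate(bg_scores_pool)
            )
        except UndefinedResultError:
            cbi = None

    # refine and binarize per scenario
    binary_maps: dict[str, RasterLayer] = {}
    n_reps = len(partitions)
    mean_thr = float(np.mean(ensemble.thresholds))
    for sid in scenarios:
        bins = np.stack(per_scenario_binaries[sid])
        agreement = bins.mean(axis=0)
        mean_map = per_scenario_sum[sid] / n_reps
        refined = np.where(agreement >= config.agreement, mean_map, 0.0)
        binary = np.where(refined >= mean_thr, 1.0, 0.0)
        binary[~valid_by_scenario[sid]] = nodata
        binary_maps[sid] = RasterLayer(
            grid,
            binary.reshape(grid.n_rows, grid.n_cols),
            name=f"{species_id}:{sid}",
        )

    evaluation = EvaluationResult(
        species_id=species_id,
        n_occurrences=n,
        mode=mode,
        success_rate=q,
        jackknife_p=p,
        cbi=cbi,
        mss=mean_thr,
    )
    return SpeciesResult(
        species_id=species_id,
        n_occurrences=n,
        mode=mode,
        subset=subset,
        beta_multiplier=beta,
        evaluation=evaluation,
        binary_maps=binary_maps,
        ensemble=ensemble,
    )


def _analysis_grid(spec: GridSpec, cell_size: float) -> GridSpec:
    x0 = math.floor(spec.x_origin / cell_size) * cell_size
    y0 = math.floor(spec.y_origin / cell_size) * cell_size
    x1 = spec.x_origin + spec.n_cols * spec.cell_size
    y1 = spec.y_origin + spec.n_rows * spec.cell_size
    return GridSpec(
        n_rows=int(math.ceil((y1 - y0) / cell_size)),
        n_cols=int(math.ceil((x1 - x0) / cell_size)),
        x_origin=x0,
        y_origin=y0,
        cell_size=cell_size,
        nodata_value=spec.nodata_value,
    )


def run_pipeline(
    scenarios: dict[str, ClimateStack],
    occurrences: OccurrenceSet,
    config: PipelineConfig | None = None,
    bias: RasterLayer | None = None,
    reserves: RasterLayer | None = None,
    output_dir: str | pathlib.Path | None = None,
) -> PipelineResult:
    """Execute every stage and return (and optionally write) all products."""
    t0 = time.time()
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.seed)
    present = scenarios[config.present_id]
    grid = present.spec
    variable_names = present.variable_names
    valid = present.valid_mask()
    result = PipelineResult(config=config)

    # stage 1: background samples and candidate subsets
    sel_cells = _draw_background_cells(
        rng, grid, bias, valid, config.selection_background_n
    )
    all_values = present.values_matrix()
    candidates = niche_model.enumerate_candidate_sets(
        all_values[sel_cells],
        variable_names,
        r_threshold=config.r_threshold,
        vif_threshold=config.vif_threshold,
        max_candidates=config.max_candidates,
    )
    logger.info("candidate subsets: %d", len(candidates))
    fit_cells = _draw_background_cells(
        rng, grid, bias, valid, config.fitting_background_n
    )
    background_values = all_values[fit_cells]

    # stages 2–5 per species
    n_ok = 0
    for sp in occurrences.species_ids:
        t_sp = time.time()
        pts = occurrences.for_species(sp)
        frame = extract_at_points(present, pts)
        frame = frame[frame["valid"]]
        if len(frame) == 0:
            result.skipped[sp] = "no valid extractions"
            logger.warning("%s skipped: no valid extractions", sp)
            continue
        keep = _dedup_presence_cells(frame)
        frame = frame.iloc[keep]
        pres_values = frame[variable_names].to_numpy(dtype=float)
        pres_cells = frame[["row", "col"]].to_numpy(dtype=int)
        if pres_values.shape[0] < config.min_occurrences:
            result.skipped[sp] = (
                f"only {pres_values.shape[0]} occupied cells (< "
                f"{config.min_occurrences})"
            )
            logger.info("%s excluded: %s", sp, result.skipped[sp])
            continue
        try:
            result.species[sp] = fit_species(
                sp,
                pres_values,
                pres_cells,
                candidates,
                background_values,
                scenarios,
                variable_names,
                config,
                rng,
            )
            n_ok += 1
            logger.info(
                "%s: n=%d mode=%s subset=%s beta=%.1f q=%.2f p=%.3g (%.1fs)",
                sp,
                result.species[sp].n_occurrences,
                result.species[sp].mode,
                result.species[sp].subset,
                result.species[sp].beta_multiplier,
                result.species[sp].evaluation.success_rate,
                result.species[sp].evaluation.jackknife_p,
                time.time() - t_sp,
            )
        except Exception as exc:  # per-species robustness contract
            result.skipped[sp] = str(exc)
            logger.warning("%s failed and was skipped: %s", sp, exc)
    if n_ok == 0:
        raise RuntimeError("no species passed the occurrence filter and fitting")

    # stage 5b: predicted richness per scenario
    for sid in scenarios:
        maps = [r.binary_maps[sid] for r in result.species.values()]
        result.predicted_richness[sid] = richness_maps.stack_binary_maps(maps)

    # stage 6: observed-pattern statistics on the analysis grid
    agrid = _analysis_grid(grid, config.analysis_cell_size)
    presence = richness_maps.occurrences_to_cell_presence(occurrences, agrid)
    result.observed_richness = richness_maps.species_richness(presence)
    result.observed_rwr = richness_maps.rarity_weighted_richness(presence)
    result.core_areas_richness = richness_maps.core_areas(
        result.observed_richness, mode="richness", top_fraction=config.top_fraction
    )
    result.core_areas_rwr = richness_maps.core_areas(
        result.observed_rwr, mode="rwr", rwr_cut=config.rwr_cut
    )
    occupied = result.observed_richness.values > 0
    if occupied.sum() >= 10:
        rich_v = np.where(occupied, result.observed_richness.values, agrid.nodata_value)
        rwr_v = np.where(occupied, result.observed_rwr.values, agrid.nodata_value)
        try:
            result.correlation = spatial_stats.dutilleul_test(
                RasterLayer(agrid, rich_v), RasterLayer(agrid, rwr_v)
            )
        except UndefinedResultError as exc:
            logger.warning("correlation undefined: %s", exc)

    # stage 7: refugia
    combos = config.combinations or refugia.standard_combinations(
        present=config.present_id
    )
    for name, combo in combos.items():
        per_species = []
        for r in result.species.values():
            per_species.append(
                refugia.intersect_species_maps(r.binary_maps, combo)
            )
        ref_map = refugia.stack_refugia(per_species)
        result.refugia_maps[name] = ref_map
        result.refugia_areas_km2[name] = refugia.refugia_area(ref_map)
        if reserves is not None:
            try:
                result.reserve_gap[name] = refugia.reserve_gap_fraction(
                    ref_map, reserves
                )
            except UndefinedResultError:
                result.reserve_gap[name] = float("nan")

    result.manifest = {
        "seed": config.seed,
        "n_species_modeled": n_ok,
        "n_species_skipped": len(result.skipped),
        "skipped": result.skipped,
        "n_candidate_subsets": len(candidates),
        "species": [
            {
                "species": r.species_id,
                "n": r.n_occurrences,
                "mode": r.mode,
                "subset": list(r.subset),
                "beta_multiplier": r.beta_multiplier,
                "q": r.evaluation.success_rate,
                "p": r.evaluation.jackknife_p,
                "cbi": r.evaluation.cbi,
                "mss": r.evaluation.mss,
            }
            for r in result.species.values()
        ],
        "refugia_areas_km2": result.refugia_areas_km2,
        "reserve_gap_fraction": result.reserve_gap,
        "correlation": None
        if result.correlation is None
        else {
            "r": result.correlation.r,
            "M_hat": result.correlation.m_hat,
            "t": result.correlation.t,
            "df": result.correlation.df,
            "p": result.correlation.p,
        },
        "runtime_s": round(time.time() - t0, 2),
    }

    if output_dir is not None:
        _write_outputs(result, pathlib.Path(output_dir))
    return result


def _write_outputs(result: PipelineResult, out: pathlib.Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for sid, lyr in result.predicted_richness.items():
        path = out / f"richness_{sid}.asc"
        write_ascii_grid(lyr, path)
        files.append(path.name)
    for name, lyr in result.refugia_maps.items():
        path = out / f"refugia_{name.replace(' ', '_')}.asc"
        write_ascii_grid(lyr, path)
        files.append(path.name)
    if result.observed_richness is not None:
        write_ascii_grid(result.observed_richness, out / "observed_richness.asc")
        write_ascii_grid(result.observed_rwr, out / "observed_rwr.asc")
        files += ["observed_richness.asc", "observed_rwr.asc"]
    import csv

    with open(out / "evaluation.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "n", "mode", "q", "p", "cbi", "mss"])
        for r in result.species.values():
            e = r.evaluation
            writer.writerow(
                [r.species_id, r.n_occurrences, r.mode, e.success_rate,
                 e.jackknife_p, "" if e.cbi is None else e.cbi, e.mss]
            )
    files.append("evaluation.csv")
    with open(out / "core_areas.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mode", "rank", "n_cells", "total_value", "cells"])
        for mode, areas in (
            ("richness", result.core_areas_richness),
            ("rwr", result.core_areas_rwr),
        ):
            for a in areas:
                writer.writerow(
                    [mode, a.rank, a.n_cells, a.total_value,
                     ";".join(f"{r}:{c}" for r, c in sorted(a.cells))]
                )
    files.append("core_areas.csv")
    result.manifest["files"] = sorted(files + ["manifest.json"])
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))


def load_fixture(path: str | pathlib.Path):
    """Load a fixture directory written by ``write_fixture``: scenario
    stacks, occurrences, bias, and reserves."""
    path = pathlib.Path(path)
    scenarios: dict[str, ClimateStack] = {}
    for d in sorted((path / "scenarios").iterdir()):
        if not d.is_dir():
            continue
        layers = {}
        for f in sorted(d.glob("*.asc"), key=lambda p: (len(p.stem), p.stem)):
            layers[f.stem] = read_ascii_grid(f, name=f.stem)
        scenarios[d.name] = ClimateStack(scenario_id=d.name, layers=layers)
    occurrences = read_occurrences_csv(path / "occurrences.csv")
    bias = None
    if (path / "bias.asc").exists():
        bias = read_ascii_grid(path / "bias.asc", name="bias")
    reserves = None
    if (path / "reserves.asc").exists():
        reserves = read_ascii_grid(path / "reserves.asc", name="reserves")
    return scenarios, occurrences, bias, reserves
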