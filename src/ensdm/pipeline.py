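"""End-to-end orchestration: simulate -> fit -> project -> metrics.

A single :class:`RunConfig` (YAML-loadable) and one master seed drive the
whole analysis reproducibly.  The master seed fans out to per-stage seeds
via ``stage_seed``: CRC32 of a stage tag mixed with the master seed, kept
below 2**31, so any stage can be rerun independently yet deterministically.

The stages can run fully in memory (:func:`run_full_analysis`) or
against artifacts on disk through the CLI wrappers in :mod:`ensdm.cli`.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geo_io
from .ensemble import SuitabilityMap, final_fit_and_map, gate_models, project_ensemble
from .evaluation import (
    best_threshold_max_sens_spec,
    confusion_at_threshold,
    cross_validate,
    to_score_scale,
    tss,
    variable_importance,
)
from .grids import EnvStack, ProtectedAreas
from .landscape import (
    DEFAULT_RCMS,
    DEFAULT_WARMING,
    ScenarioSet,
    SpeciesTruth,
    derive_topo_vars,
    make_climate_surfaces,
    make_dem,
    make_protected_areas,
    make_scenarios,
    sample_occurrences,
)
from .occurrences import OccurrenceSet
from .preprocess import (
    MIN_RECORDS,
    extract_env,
    generate_pseudo_absences,
    partition,
    screen_collinearity,
    stepwise_aic,
    thin_by_cell,
)

__all__ = [
    "RunConfig",
    "SpeciesConfig",
    "stage_seed",
    "simulate",
    "fit_species",
    "project_species",
    "metrics_species",
    "run_full_analysis",
    "AnalysisResult",
]

logger = logging.getLogger(__name__)


def stage_seed(master: int, tag: str) -> int:
    """Derive a per-stage seed from the master seed and a stage tag."""
    return (int(master) * 100_003 + zlib.crc32(tag.encode())) % (2**31)


# ----------------------------------------------------------------------
# configuration
@dataclass
class SpeciesConfig:
    """Ground-truth niche and sampling design for one synthetic species."""

    name: str
    responses: dict
    base_rate: float = 0.9
    n_target: int = 60
    bias: dict | None = field(default_factory=lambda: {"n_hotspots": 6, "strength": 0.6})


def _default_species() -> list[SpeciesConfig]:
    # two range-restricted species, as narrow thermal specialists: a
    # cold-adapted upland species (summer-temperature optimum in the cold
    # tail of the landscape) and a warm-adapted coastal/western one
    return [
        SpeciesConfig(
            name="upland_cold",
            responses={"BIO10": ("gaussian", 8.6, 0.45), "twi": ("gaussian", 8.5, 2.5)},
        ),
        SpeciesConfig(
            name="western_warm",
            responses={"BIO11": ("gaussian", 4.8, 0.5), "dist_coast": ("gaussian", 0.0, 8.0)},
        ),
    ]


@dataclass
class RunConfig:
    """All knobs of a pipeline run; every stochastic stage is seeded."""

    outdir: str = "ensdm_run"
    seed: int = 1
    shape: tuple[int, int] = (128, 128)
    cell_size: float = 100.0  # metres per cell: the fine topographic resolution
    relief: dict = field(default_factory=dict)
    climate: dict = field(default_factory=dict)
    warming_by_period: dict = field(default_factory=lambda: dict(DEFAULT_WARMING))
    rcms: tuple = DEFAULT_RCMS
    rcm_jitter_sd: float = 0.15
    species: list = field(default_factory=_default_species)
    pa_coverage: dict = field(default_factory=lambda: {"NNR": 0.05, "IPA": 0.2})
    priority: list = field(
        default_factory=lambda: [
            "BIO10", "BIO11", "BIO4", "BIO17", "dist_coast", "solar_index", "twi",
            "slope", "westerly_aspect", "BIO1", "BIO5", "BIO6", "BIO7", "BIO12",
            "BIO13", "BIO14", "BIO16", "BIO18", "BIO19",
        ]
    )
    r_cut: float = 0.7
    pa_ratio: int = 10
    n_rep: int = 10
    train_frac: float = 0.8
    gate_tss: float = 0.7
    learner_settings: dict = field(default_factory=dict)
    min_records: int = MIN_RECORDS

    def __post_init__(self) -> None:
        self.shape = tuple(self.shape)
        self.species = [
            s if isinstance(s, SpeciesConfig) else SpeciesConfig(**s) for s in self.species
        ]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["rcms"] = list(self.rcms)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @property
    def periods(self) -> list[str]:
        return list(self.warming_by_period)


# ----------------------------------------------------------------------
# stage 1: simulate
@dataclass
class SimulatedData:
    present: EnvStack
    scenarios: ScenarioSet
    occurrences: dict[str, OccurrenceSet]
    protected: ProtectedAreas
    truths: dict[str, SpeciesTruth]


def simulate(config: RunConfig) -> SimulatedData:
    """Generate the full synthetic dataset for one run."""
    dem = make_dem(
        config.shape,
        cell_size=config.cell_size,
        relief_params=config.relief or None,
        seed=stage_seed(config.seed, "dem"),
    )
    topo = derive_topo_vars(dem)
    climate = make_climate_surfaces(dem, seed=stage_seed(config.seed, "climate"), **config.climate)
    layers = dict(climate.layers)
    for name, g in topo.layers.items():
        layers.setdefault(name, g)
    present = EnvStack(layers=layers, period="present", rcm="observed", excluded=climate.excluded)

    scenarios = make_scenarios(
        present,
        warming_by_period=config.warming_by_period,
        rcm_names=config.rcms,
        rcm_jitter_sd=config.rcm_jitter_sd,
        seed=stage_seed(config.seed, "scenarios"),
    )
    occurrences: dict[str, OccurrenceSet] = {}
    truths: dict[str, SpeciesTruth] = {}
    for sp in config.species:
        truth = SpeciesTruth(name=sp.name, responses=sp.responses, base_rate=sp.base_rate)
        truths[sp.name] = truth
        occurrences[sp.name] = sample_occurrences(
            truth,
            present,
            n_target=sp.n_target,
            bias_params=sp.bias,
            seed=stage_seed(config.seed, f"occ:{sp.name}"),
        )
    protected = make_protected_areas(
        present, coverage_fraction=config.pa_coverage, seed=stage_seed(config.seed, "pa")
    )
    return SimulatedData(
        present=present,
        scenarios=scenarios,
        occurrences=occurrences,
        protected=protected,
        truths=truths,
    )


# ----------------------------------------------------------------------
# stage 2: fit
@dataclass
class FitResult:
    species: str
    selected: list[str]
    reports: list
    gated: list[str]
    models: dict
    ensemble_map: SuitabilityMap
    threshold: int
    ensemble_tss: float
    importance: dict
    thinned: OccurrenceSet
    audit: list = field(default_factory=list)


def fit_species(config: RunConfig, data: SimulatedData, species: str) -> FitResult:
    """Thin, augment, select variables, cross-validate, gate and ensemble."""
    audit: list[dict] = []
    occ = data.occurrences[species]
    template = data.present.template
    thinned = thin_by_cell(occ, template, seed=stage_seed(config.seed, f"thin:{species}"))
    audit.append({"stage": "thin", "before": len(occ), "after": len(thinned)})
    if thinned.n_presence < config.min_records:
        raise ValueError(
            f"species {species!r} has {thinned.n_presence} thinned records, "
            f"fewer than the {config.min_records}-record minimum; skipping"
        )
    augmented = generate_pseudo_absences(
        thinned, template, ratio=config.pa_ratio, seed=stage_seed(config.seed, f"pa:{species}")
    )
    table = extract_env(augmented, data.present)
    screened = screen_collinearity(table, priority=config.priority, r_cut=config.r_cut)
    audit.append({"stage": "screen", "candidates": table.columns, "retained": screened})
    selected = stepwise_aic(table.subset_columns(screened), candidates=screened)
    if not selected:  # stepwise found nothing better than the intercept
        selected = screened[:1]
    audit.append({"stage": "stepwise", "selected": selected})
    table_sel = table.subset_columns(selected)

    parts = partition(
        table_sel,
        train_frac=config.train_frac,
        n_rep=config.n_rep,
        seed=stage_seed(config.seed, f"split:{species}"),
    )
    reports = [
        cross_validate(
            alg,
            table_sel,
            parts,
            settings=config.learner_settings.get(alg),
            seed=stage_seed(config.seed, f"cv:{species}:{alg}"),
        )
        for alg in ("GLM", "GAM", "GBM", "RF", "MAXENT")
    ]
    gated = gate_models(reports, tss_min=config.gate_tss)
    audit.append({"stage": "gate", "gated": gated,
                  "mean_tss": {r.algorithm: r.mean_tss for r in reports}})
    ensemble_map, models = final_fit_and_map(
        species,
        table_sel,
        data.present,
        gated,
        reports,
        settings=config.learner_settings,
        seed=stage_seed(config.seed, f"final:{species}"),
    )
    # species-specific operating threshold from the full-data ensemble
    # scores at presence vs pseudo-absence rows (max sens + spec)
    weights = ensemble_map.provenance
    probs = np.zeros(table_sel.n)
    for alg, w in weights.items():
        probs += w * models[alg].predict_table(table_sel)
    scores = to_score_scale(probs)
    pos, neg = scores[table_sel.label == 1], scores[table_sel.label == 0]
    threshold = best_threshold_max_sens_spec(pos, neg)
    ens_tss = tss(confusion_at_threshold(pos, neg, threshold))
    audit.append({"stage": "threshold", "threshold": threshold, "ensemble_tss": ens_tss})

    importance = {
        alg: variable_importance(
            models[alg], table_sel, seed=stage_seed(config.seed, f"imp:{species}:{alg}")
        )
        for alg in gated
    }
    return FitResult(
        species=species,
        selected=selected,
        reports=reports,
        gated=gated,
        models=models,
        ensemble_map=ensemble_map,
        threshold=threshold,
        ensemble_tss=ens_tss,
        importance=importance,
        thinned=thinned,
        audit=audit,
    )


# ----------------------------------------------------------------------
# stage 3: project
def project_species(
    config: RunConfig, data: SimulatedData, fitres: FitResult
) -> dict[tuple[str, str], SuitabilityMap]:
    """Ensemble suitability maps for every (period, rcm), threshold unchanged."""
    maps: dict[tuple[str, str], SuitabilityMap] = {
        ("present", "observed"): fitres.ensemble_map
    }
    for stack in data.scenarios.stacks:
        maps[(stack.period, stack.rcm)] = project_ensemble(
            fitres.models, fitres.ensemble_map.provenance, stack, species=fitres.species
        )
    return maps


# ----------------------------------------------------------------------
# stage 4: metrics
from .vulnerability import (  # noqa: E402  (kept near use for readability)
    binarize,
    pct_change_area,
    pct_mean_suitability,
    pct_overlap,
    persistence_at_points,
    protected_overlap,
    refugia,
    suitable_area,
    summarise_change,
    wilcoxon_exact,
)

METRICS = ("pct_change_area", "pct_overlap", "pct_mean_suitability",
           "pct_suitability_decrease", "persistence")


def metrics_species(
    config: RunConfig,
    data: SimulatedData,
    fitres: FitResult,
    maps: dict[tuple[str, str], SuitabilityMap],
) -> dict:
    """All vulnerability metrics for one species.

    Returns tidy per-RCM rows, per-period summaries (mean +/- SE across
    RCMs), exact rank-sum tests between the first and last future
    periods, protected-area overlaps and the across-RCM refugia grid.
    """
    sp = fitres.species
    t = fitres.threshold
    present_map = maps[("present", "observed")]
    present_range = binarize(present_map, t)
    periods = config.periods
    rcms = list(config.rcms)

    rows: list[dict] = []
    per_period: dict[str, dict[str, dict[str, float]]] = {}
    for period in periods:
        vals: dict[str, dict[str, float]] = {m: {} for m in METRICS}
        for rcm in rcms:
            smap = maps[(period, rcm)]
            rmap = binarize(smap, t)
            ratio = pct_mean_suitability(present_map, smap)
            vals["pct_change_area"][rcm] = pct_change_area(present_range, rmap)
            vals["pct_overlap"][rcm] = pct_overlap(present_range, rmap)
            vals["pct_mean_suitability"][rcm] = ratio
            vals["pct_suitability_decrease"][rcm] = 100.0 - ratio
            vals["persistence"][rcm] = persistence_at_points(fitres.thinned, rmap)
        per_period[period] = vals
        for metric, by_rcm in vals.items():
            for rcm, v in by_rcm.items():
                rows.append(
                    {"species": sp, "period": period, "rcm": rcm, "metric": metric, "value": v}
                )
    summaries = {p: summarise_change(per_period[p], p) for p in periods}

    tests = {}
    if len(periods) >= 2:
        first, last = periods[0], periods[-1]
        for metric in METRICS:
            a = [per_period[first][metric][r] for r in rcms]
            b = [per_period[last][metric][r] for r in rcms]
            tests[metric] = wilcoxon_exact(a, b)

    protected = {}
    for network in data.protected.networks:
        try:
            protected[(network, "present")] = protected_overlap(
                present_range, data.protected, network
            )
        except ValueError:
            protected[(network, "present")] = float("nan")
        for period in periods:
            vals_net = []
            for rcm in rcms:
                rmap = binarize(maps[(period, rcm)], t)
                if rmap.n_suitable:
                    vals_net.append(protected_overlap(rmap, data.protected, network))
            protected[(network, period)] = float(np.mean(vals_net)) if vals_net else float("nan")

    last_period = periods[-1]
    refugia_grid = refugia([binarize(maps[(last_period, r)], t) for r in rcms])

    return {
        "species": sp,
        "threshold": t,
        "present_area": suitable_area(present_range),
        "tidy": pd.DataFrame(rows),
        "summaries": summaries,
        "wilcoxon_first_vs_last": tests,
        "protected_overlap": protected,
        "refugia": refugia_grid,
    }


# ----------------------------------------------------------------------
@dataclass
class AnalysisResult:
    config: RunConfig
    data: SimulatedData
    fits: dict[str, FitResult]
    maps: dict[str, dict]
    metrics: dict[str, dict]
    skipped: dict[str, str] = field(default_factory=dict)

    def tidy_metrics(self) -> pd.DataFrame:
        frames = [m["tidy"] for m in self.metrics.values()]
        return (
            pd.concat(frames, ignore_index=True)
            .sort_values(["species", "period", "rcm", "metric"], kind="mergesort")
            .reset_index(drop=True)
        )

    def write_metrics_csv(self, path) -> Path:
        path = Path(path)
        df = self.tidy_metrics().copy()
        df["value"] = df["value"].map(lambda v: f"{v:.6f}")
        df.to_csv(path, index=False)
        return path


def run_full_analysis(config: RunConfig) -> AnalysisResult:
    """Run simulate -> fit -> project -> metrics for every species in memory."""
    data = simulate(config)
    fits: dict[str, FitResult] = {}
    maps: dict[str, dict] = {}
    metrics: dict[str, dict] = {}
    skipped: dict[str, str] = {}
    for sp in config.species:
        try:
            fitres = fit_species(config, data, sp.name)
        except ValueError as exc:
            logger.warning("species %s skipped: %s", sp.name, exc)
            skipped[sp.name] = str(exc)
            continue
        fits[sp.name] = fitres
        maps[sp.name] = project_species(config, data, fitres)
        metrics[sp.name] = metrics_species(config, data, fitres, maps[sp.name])
    return AnalysisResult(
        config=config, data=data, fits=fits, maps=maps, metrics=metrics, skipped=skipped
    )


# ----------------------------------------------------------------------
# disk helpers used by the CLI
def save_stack(stack: EnvStack, directory: Path) -> list[str]:
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, grid in stack.layers.items():
        geo_io.write_raster(grid, directory / f"{name}.asc")
        written.append(f"{name}.asc")
    return sorted(written)


def save_dataset(data: SimulatedData, outdir) -> Path:
    """Write the complete synthetic dataset plus a manifest."""
    outdir = Path(outdir)
    manifest: dict = {"stacks": {}, "occurrences": {}, "protected": {}}
    manifest["stacks"]["present_observed"] = save_stack(data.present, outdir / "env" / "present_observed")
    for stack in data.scenarios.stacks:
        key = f"{stack.period}_{stack.rcm}"
        manifest["stacks"][key] = save_stack(stack, outdir / "env" / key)
    occ_dir = outdir / "occurrences"
    occ_dir.mkdir(parents=True, exist_ok=True)
    for name, occ in data.occurrences.items():
        geo_io.write_occurrences(occ, occ_dir / f"{name}.csv")
        manifest["occurrences"][name] = f"{name}.csv"
    pa_dir = outdir / "protected"
    pa_dir.mkdir(parents=True, exist_ok=True)
    for network, grid in data.protected.masks.items():
        geo_io.write_raster(grid, pa_dir / f"{network}.asc")
        manifest["protected"][network] = f"{network}.asc"
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir / "manifest.json"


def render_report(result: AnalysisResult) -> str:
    """Plain-text report: gates, thresholds, per-period changes, persistence."""
    lines = ["ensdm analysis report", "=" * 60]
    for sp, fitres in result.fits.items():
        m = result.metrics[sp]
        lines.append(f"\nspecies: {sp}")
        lines.append(f"  selected covariates: {', '.join(fitres.selected)}")
        lines.append(
            "  mean TSS by algorithm: "
            + ", ".join(f"{r.algorithm}={r.mean_tss:.3f}" for r in fitres.reports)
        )
        lines.append(f"  gated (TSS > {result.config.gate_tss}): {', '.join(fitres.gated)}")
        lines.append(
            f"  ensemble threshold={fitres.threshold}  ensemble TSS={fitres.ensemble_tss:.3f}"
        )
        lines.append(f"  present suitable area: {m['present_area']:.1f} sq units")
        for period, summ in m["summaries"].items():
            parts = [
                f"{row['metric']}={row['mean']:.1f}+/-{row['se']:.1f}"
                for _, row in summ.summary.iterrows()
            ]
            lines.append(f"  {period}: " + "; ".join(parts))
        tests = m["wilcoxon_first_vs_last"]
        if tests:
            lines.append(
                "  rank-sum p (first vs last period): "
                + ", ".join(f"{k}={v:.3f}" for k, v in tests.items())
            )
        for (network, period), v in m["protected_overlap"].items():
            lines.append(f"  protected overlap {network} {period}: {v:.1f}%")
    if result.skipped:
        lines.append("\nskipped species:")
        for sp, why in result.skipped.items():
            lines.append(f"  {sp}: {why}")
    return "\n".join(lines) + "\n"
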