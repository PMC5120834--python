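"""TSS-weighted mean ensemble suitability maps.

Only algorithms whose cross-validated mean TSS exceeds 0.7 (strictly)
enter the ensemble; each retained algorithm is refitted on the full data
and its map is combined cellwise with weights proportional to its mean
TSS.  Combination happens on the probability scale and the result is
rescaled once to the integer 0-1000 suitability scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import TSS_GATE, EvalReport, to_score_scale
from .grids import EnvStack, Grid
from .learners import FittedModel, fit, predict_map
from .preprocess import ModelTable

__all__ = [
    "SuitabilityMap",
    "gate_models",
    "weighted_mean_ensemble",
    "final_fit_and_map",
    "project_ensemble",
]


@dataclass
class SuitabilityMap:
    """Ensemble suitability on the integer 0-1000 scale (nodata for sea)."""

    grid: Grid
    species: str = ""
    period: str = "present"
    rcm: str = "observed"
    provenance: dict = field(default_factory=dict)  # algorithm -> normalised weight

    def __post_init__(self) -> None:
        v = self.grid.values[self.grid.mask]
        if v.size and (v.min() < 0 or v.max() > 1000):
            raise ValueError("suitability values must lie in [0, 1000]")
        if self.provenance:
            w = np.array(list(self.provenance.values()), dtype=float)
            if (w < 0).any():
                raise ValueError("ensemble weights must be non-negative")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("ensemble weights must sum to 1")

    def mean_suitability(self) -> float:
        """Mean over land, on the 0-1000 scale."""
        return float(self.grid.land_values().mean())


def gate_models(reports: list[EvalReport], tss_min: float = TSS_GATE) -> list[str]:
    """Algorithms whose mean replicate TSS is strictly above the gate."""
    if not reports:
        raise ValueError("no evaluation reports supplied")
    passed = [r.algorithm for r in reports if r.mean_tss > tss_min]
    if not passed:
        best = max(reports, key=lambda r: r.mean_tss)
        raise ValueError(
            f"no algorithm passed the TSS > {tss_min} gate "
            f"(best: {best.algorithm} at {best.mean_tss:.3f}); "
            "consider more records or different covariates"
        )
    return passed


def weighted_mean_ensemble(maps: list[Grid], weights: list[float]) -> Grid:
    """Cellwise weighted mean of co-registered maps.

    Weights are normalised to sum to 1 (w_i = TSS_i / sum TSS_j when the
    inputs are mean-TSS weights).  A cell that is nodata in any component
    is nodata in the ensemble.  The output shares the input value scale.
    """
    if not maps:
        raise ValueError("no maps to combine")
    if len(maps) != len(weights):
        raise ValueError("need one weight per map")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("weights sum to zero")
    w = w / w.sum()
    template = maps[0]
    for m in maps[1:]:
        if not template.same_geometry(m):
            raise ValueError("ensemble maps must be co-registered")
    stack = np.stack([m.values for m in maps])
    ok = np.isfinite(stack).all(axis=0)
    out = np.full(template.shape, np.nan)
    out[ok] = np.tensordot(w, stack[:, ok], axes=(0, 0))
    return template.copy_with(out)


def final_fit_and_map(
    species: str,
    table: ModelTable,
    env: EnvStack,
    gated: list[str],
    reports: list[EvalReport],
    settings: dict[str, dict] | None = None,
    seed: int = 0,
) -> tuple[SuitabilityMap, dict[str, FittedModel]]:
    """Refit each gated algorithm on all data and build the ensemble map.

    Returns the ensemble suitability map (0-1000) plus the fitted
    component models keyed by algorithm, for reuse when projecting to
    future climate stacks.
    """
    if not gated:
        raise ValueError("no gated algorithms to ensemble")
    tss_by_alg = {r.algorithm: r.mean_tss for r in reports}
    missing = [a for a in gated if a not in tss_by_alg]
    if missing:
        raise ValueError(f"no evaluation report for gated algorithms: {missing}")
    settings = settings or {}
    models: dict[str, FittedModel] = {}
    prob_maps: list[Grid] = []
    weights: list[float] = []
    for i, alg in enumerate(gated):
        model = fit(alg, table, settings=settings.get(alg), seed=seed + i)
        models[alg] = model
        prob_maps.append(predict_map(model, env))
        weights.append(tss_by_alg[alg])
    combined = weighted_mean_ensemble(prob_maps, weights)
    scaled = combined.copy_with(
        np.where(combined.mask, to_score_scale(np.nan_to_num(combined.values)), np.nan)
    )
    w = np.asarray(weights) / np.sum(weights)
    return (
        SuitabilityMap(
            grid=scaled,
            species=species,
            period=env.period,
            rcm=env.rcm,
            provenance={a: float(wi) for a, wi in zip(gated, w)},
        ),
        models,
    )


def project_ensemble(
    models: dict[str, FittedModel],
    provenance: dict[str, float],
    env: EnvStack,
    species: str = "",
) -> SuitabilityMap:
    """Apply already-fitted ensemble components to another climate stack."""
    gated = list(provenance)
    maps = [predict_map(models[a], env) for a in gated]
    combined = weighted_mean_ensemble(maps, [provenance[a] for a in gated])
    scaled = combined.copy_with(
        np.where(combined.mask, to_score_scale(np.nan_to_num(combined.values)), np.nan)
    )
    return SuitabilityMap(
        grid=scaled, species=species, period=env.period, rcm=env.rcm, provenance=provenance
    )
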