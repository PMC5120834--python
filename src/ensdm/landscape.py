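"""Synthetic archipelago generator.

Builds self-contained datasets with the statistical structure a
climate-vulnerability SDM analysis assumes: a digital elevation model
(DEM) with sea surrounding one or more landmasses, topographic covariates
derived from it, bioclim-style temperature/precipitation surfaces with an
elevation lapse and an east-west gradient, species whose occurrence
probability follows a known low-dimensional niche, clustered sampling
bias, future climate stacks per pseudo regional climate model (RCM) with
a stated mean warming and unchanged precipitation, and protected-area
masks.

Spatial autocorrelation comes from Gaussian-smoothed seeded white noise.
Every operation takes an explicit seed and is reproducible.

Layer naming: climate layers follow the bioclim menu BIO1-BIO19
(temperature in degrees C, precipitation in mm); topographic layers are
``elevation``, ``slope`` (degrees), ``westerly_aspect`` (cosine in
[-1, 1]), ``dist_coast`` (cell units), ``twi`` (topographic wetness
index, ln units) and ``solar_index`` (relative clear-sky insolation,
flat ground = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import EXCLUDED_BIOCLIM, TEMPERATURE_LEVEL_LAYERS, EnvStack, Grid, ProtectedAreas
from .occurrences import PRESENCE, OccurrenceSet

__all__ = [
    "SpeciesTruth",
    "ScenarioSet",
    "make_dem",
    "derive_topo_vars",
    "make_climate_surfaces",
    "make_future",
    "make_scenarios",
    "sample_occurrences",
    "make_protected_areas",
    "TOPO_LAYERS",
]

TOPO_LAYERS = ("elevation", "slope", "westerly_aspect", "dist_coast", "twi", "solar_index")

#: default warming (degrees C above present) per period label; the long-term
#: value is the 1.8 degC mean rise the regional climate models project, with
#: the nearer periods on a linear ramp toward it.
DEFAULT_WARMING = {"2020": 0.6, "2050": 1.2, "2080": 1.8}

#: five pseudo-RCM labels mirroring a realistic regional-model ensemble.
DEFAULT_RCMS = ("rcm1", "rcm2", "rcm3", "rcm4", "rcm5")


# ----------------------------------------------------------------------
# noise helper
def _smooth_noise(shape, sigma, rng) -> np.ndarray:
    """Zero-mean, unit-sd spatially autocorrelated field."""
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    return z


# ----------------------------------------------------------------------
# DEM
def make_dem(
    shape: tuple[int, int],
    cell_size: float = 1.0,
    relief_params: dict | None = None,
    seed: int = 0,
) -> Grid:
    """Generate a DEM with smooth relief and sea (nodata) surrounding land.

    relief_params keys (all optional):
      amplitude      relief height above the coastline (map units; default 500);
                     0 gives flat land everywhere at ``base``
      base           coastline elevation (default 0)
      smoothness     Gaussian sigma of the autocorrelated relief, in cells
      land_fraction  target fraction of cells that are land (default 0.45)
      bump_weight    weight of the radial island envelope vs noise
    """
    nrows, ncols = shape
    if nrows < 8 or ncols < 8:
        raise ValueError(f"DEM shape must be at least 8x8, got {shape}")
    p = dict(amplitude=500.0, base=0.0, smoothness=None, land_fraction=0.45, bump_weight=1.2)
    p.update(relief_params or {})
    if not 0 < p["land_fraction"] <= 1:
        raise ValueError("land_fraction must be in (0, 1]")
    sigma = p["smoothness"] if p["smoothness"] is not None else max(2.0, min(shape) / 12)
    rng = np.random.default_rng(seed)

    if p["amplitude"] == 0:
        values = np.full(shape, float(p["base"]))
        return Grid(values, cell_size=cell_size, nodata=-9999.0)

    noise = _smooth_noise(shape, sigma, rng)
    # radial envelope: high mid-grid, negative at the border, so islands
    # sit inside a sea margin
    r = np.hypot(
        (np.arange(nrows)[:, None] - (nrows - 1) / 2) / (nrows / 2),
        (np.arange(ncols)[None, :] - (ncols - 1) / 2) / (ncols / 2),
    )
    envelope = np.cos(np.clip(r, 0, 1.4) * np.pi / 2)
    raw = p["bump_weight"] * envelope + noise
    threshold = np.quantile(raw, 1.0 - p["land_fraction"])
    land = raw >= threshold
    land[0, :] = land[-1, :] = False  # guarantee a sea margin
    land[:, 0] = land[:, -1] = False
    if not land.any():
        raise ValueError("degenerate relief: no land cells produced")
    span = raw.max() - threshold
    elev = p["base"] + p["amplitude"] * (raw - threshold) / (span if span > 0 else 1.0)
    values = np.where(land, elev, np.nan)
    return Grid(values, cell_size=cell_size, nodata=-9999.0)


# ----------------------------------------------------------------------
# topographic covariates
def _filled(dem: Grid) -> np.ndarray:
    """DEM values with sea filled by the nearest land value (for gradients)."""
    land = dem.mask
    if land.all():
        return dem.values
    idx = ndimage.distance_transform_edt(~land, return_indices=True)[1]
    return dem.values[tuple(idx)]


def _gradients(dem: Grid) -> tuple[np.ndarray, np.ndarray]:
    z = _filled(dem)
    gy, gx = np.gradient(z, dem.cell_size)
    return gx, gy


def _d8_accumulation(dem: Grid) -> np.ndarray:
    """D8 upslope contributing area, in cell counts (each cell counts itself)."""
    z = dem.values
    land = dem.mask
    nrows, ncols = z.shape
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    dists = [math.hypot(dr, dc) for dr, dc in offsets]
    acc = np.where(land, 1.0, np.nan)
    rows, cols = np.nonzero(land)
    order = np.argsort(z[rows, cols])[::-1]  # highest first
    for k in order:
        r, c = rows[k], cols[k]
        best, best_drop = None, 0.0
        for (dr, dc), d in zip(offsets, dists):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and land[rr, cc]:
                drop = (z[r, c] - z[rr, cc]) / d
                if drop > best_drop:
                    best, best_drop = (rr, cc), drop
        if best is not None:
            acc[best] += acc[r, c]
    return acc


def derive_topo_vars(dem: Grid, latitude: float = -51.7) -> EnvStack:
    """Derive the topographic covariate stack from a DEM.

    slope: central-difference slope angle in degrees.
    westerly_aspect: cosine of the angle between the downslope direction
    and due west (+1 west-facing, -1 east-facing, 0 on flat ground).
    dist_coast: Euclidean cell distance to the nearest sea cell, minus
    one, so coastal land reads 0; off-grid counts as sea.
    twi: ln(a / tan(beta)) with a the D8 upslope area per unit contour
    width and beta the slope.
    solar_index: relative clear-sky noon insolation on the inclined
    surface at the given latitude (a single scalar for the whole
    archipelago), normalised so flat ground = 1; equator-facing slopes
    score above 1 and poleward slopes below.
    """
    land = dem.mask
    if not land.any():
        raise ValueError("DEM contains no land cells")
    gx, gy = _gradients(dem)
    grad = np.hypot(gx, gy)
    slope_rad = np.arctan(grad)
    slope = np.degrees(slope_rad)

    with np.errstate(invalid="ignore", divide="ignore"):
        westerly = np.where(grad > 0, gx / grad, 0.0)

    padded = np.pad(land, 1, constant_values=False)
    dist = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    dist_coast = np.clip(dist - 1.0, 0.0, None)

    acc = _d8_accumulation(dem)
    # a: upslope area per unit contour width = (cells * cell_area) / cell_size
    a = acc * dem.cell_size
    tan_beta = np.maximum(np.tan(slope_rad), 1e-3)
    twi = np.log(a / tan_beta)

    # noon sun: elevation angle at equinox, horizontal component toward the
    # equator (north for the southern hemisphere; y increases southward)
    sun_h = math.radians(90.0 - abs(latitude))
    equator_y = -1.0 if latitude < 0 else 1.0
    sx, sy, sz = 0.0, equator_y * math.cos(sun_h), math.sin(sun_h)
    norm = np.sqrt(gx**2 + gy**2 + 1.0)
    cos_inc = (-gx * sx + -gy * sy + sz) / norm
    solar = np.clip(cos_inc, 0.0, None) / sz

    def _mask(v):
        return np.where(land, v, np.nan)

    layers = {
        "elevation": dem.values,
        "slope": _mask(slope),
        "westerly_aspect": _mask(westerly),
        "dist_coast": _mask(dist_coast),
        "twi": _mask(twi),
        "solar_index": _mask(solar),
    }
    grids = {n: dem.copy_with(v) for n, v in layers.items()}
    return EnvStack(layers=grids, period="present", rcm="observed")


# ----------------------------------------------------------------------
# climate surfaces
def _quarter_stats(monthly: np.ndarray, reducer) -> np.ndarray:
    """Stat over all 12 wrapping 3-month windows; monthly shape (12, ...)."""
    windows = np.stack(
        [reducer(np.take(monthly, [m, (m + 1) % 12, (m + 2) % 12], axis=0)) for m in range(12)]
    )
    return windows


def make_climate_surfaces(
    dem: Grid,
    lapse_rate: float = 0.0065,
    ew_gradient: float = 2.0,
    noise: float = 0.3,
    seed: int = 0,
    mean_temp: float = 6.6,
    mean_precip: float = 559.0,
    seasonal_amplitude: float = 4.5,
    seasonal_ew: float = 0.15,
    diurnal_range: float = 6.0,
    precip_ew_gradient: float = 0.5,
    precip_noise: float = 0.08,
    precip_seasonality: float = 0.3,
) -> EnvStack:
    """Generate all 19 bioclim layers plus elevation on the DEM grid.

    A 12-month temperature / precipitation cycle is built per cell and the
    bioclim summaries are computed from it, so the usual identities
    (BIO7 = BIO5 - BIO6, BIO10 >= BIO11, BIO16 >= BIO17, precip >= 0)
    hold cellwise by construction.

    Annual mean temperature is ``mean_temp`` minus a lapse of
    ``lapse_rate`` degC per elevation unit, plus an east-west gradient of
    ``ew_gradient`` degC across the full grid width (west warmer) and
    smoothed noise of sd ``noise`` degC.  All anomaly terms are centred
    over land, so the land means of BIO1 and BIO12 equal ``mean_temp``
    and ``mean_precip`` exactly.  The five artefact-flagged layers
    (BIO2/3/8/9/15) are emitted but marked excluded from selection.
    """
    land = dem.mask
    if not land.any():
        raise ValueError("DEM contains no land cells")
    if noise < 0 or precip_noise < 0:
        raise ValueError("noise levels must be non-negative")
    rng = np.random.default_rng(seed)
    nrows, ncols = dem.shape
    xc = (np.arange(ncols) + 0.5)[None, :].repeat(nrows, axis=0) / ncols  # 0..1 west->east

    def centred(anom):
        return anom - anom[land].mean()

    elev = np.where(land, dem.values, 0.0)
    t_anom = centred(-lapse_rate * elev) + centred(-ew_gradient * xc)
    if noise > 0:
        t_anom = t_anom + noise * _smooth_noise(dem.shape, max(2, min(dem.shape) / 16), rng)
        t_anom = centred(t_anom)
    t_ann = mean_temp + t_anom

    amp = seasonal_amplitude * (1.0 + seasonal_ew * centred(xc - 0.5) * 2)
    amp = np.maximum(amp, 0.1)

    p_rel = 1.0 + centred(-precip_ew_gradient * xc)
    if precip_noise > 0:
        p_rel = p_rel + precip_noise * _smooth_noise(dem.shape, max(2, min(dem.shape) / 16), rng)
    p_rel = np.maximum(p_rel, 0.05)
    p_ann = mean_precip * p_rel / p_rel[land].mean()

    months = np.arange(12)
    # southern-hemisphere cycle: warmest around month 0 (January)
    t_cycle = np.cos(2 * np.pi * months / 12)
    p_cycle = 1.0 + precip_seasonality * np.cos(2 * np.pi * (months - 5) / 12)
    p_cycle = p_cycle / p_cycle.sum()

    t_monthly = t_ann[None] + amp[None] * t_cycle[:, None, None]
    tmax_monthly = t_monthly + diurnal_range / 2
    tmin_monthly = t_monthly - diurnal_range / 2
    p_monthly = p_ann[None] * p_cycle[:, None, None]

    q_t = _quarter_stats(t_monthly, lambda w: w.mean(axis=0))
    q_p = _quarter_stats(p_monthly, lambda w: w.sum(axis=0))
    wettest_q = np.argmax(q_p, axis=0)
    driest_q = np.argmin(q_p, axis=0)
    warmest_q = np.argmax(q_t, axis=0)
    coldest_q = np.argmin(q_t, axis=0)

    def q_pick(stat, which):
        return np.take_along_axis(stat, which[None], axis=0)[0]

    bio = {}
    bio["BIO1"] = t_monthly.mean(axis=0)
    bio["BIO2"] = (tmax_monthly - tmin_monthly).mean(axis=0)
    bio["BIO4"] = t_monthly.std(axis=0) * 100
    bio["BIO5"] = tmax_monthly.max(axis=0)
    bio["BIO6"] = tmin_monthly.min(axis=0)
    bio["BIO7"] = bio["BIO5"] - bio["BIO6"]
    bio["BIO3"] = bio["BIO2"] / bio["BIO7"] * 100
    bio["BIO8"] = q_pick(q_t, wettest_q)
    bio["BIO9"] = q_pick(q_t, driest_q)
    bio["BIO10"] = q_t.max(axis=0)
    bio["BIO11"] = q_t.min(axis=0)
    bio["BIO12"] = p_monthly.sum(axis=0)
    bio["BIO13"] = p_monthly.max(axis=0)
    bio["BIO14"] = p_monthly.min(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        bio["BIO15"] = p_monthly.std(axis=0) / p_monthly.mean(axis=0) * 100
    bio["BIO16"] = q_p.max(axis=0)
    bio["BIO17"] = q_p.min(axis=0)
    bio["BIO18"] = q_pick(q_p, warmest_q)
    bio["BIO19"] = q_pick(q_p, coldest_q)

    order = [f"BIO{i}" for i in range(1, 20)]
    layers = {n: dem.copy_with(np.where(land, bio[n], np.nan)) for n in order}
    layers["elevation"] = dem.copy_with(dem.values)
    return EnvStack(layers=layers, period="present", rcm="observed",
                    excluded=frozenset(EXCLUDED_BIOCLIM))


# ----------------------------------------------------------------------
# future climate
def make_future(
    present: EnvStack,
    warming: float,
    rcm_jitter_sd: float = 0.0,
    seed: int = 0,
    period: str = "future",
    rcm: str = "rcm",
) -> EnvStack:
    """Project a stack forward: a pure translation of temperature levels.

    Temperature *level* layers (BIO1, BIO5, BIO6, BIO8-BIO11) are shifted
    by ``warming`` plus one RCM-specific Gaussian jitter of sd
    ``rcm_jitter_sd`` drawn from ``seed``.  Diurnal-range, seasonality
    and all precipitation layers are copied unchanged (so BIO7 = BIO5 -
    BIO6 is automatically preserved), as is every topographic layer.
    """
    if rcm_jitter_sd < 0:
        raise ValueError("rcm_jitter_sd must be non-negative")
    if not any(n in TEMPERATURE_LEVEL_LAYERS for n in present.layers):
        raise ValueError("stack has no temperature layers to project")
    jitter = 0.0
    if rcm_jitter_sd > 0:
        jitter = float(np.random.default_rng(seed).normal(0.0, rcm_jitter_sd))
    delta = warming + jitter
    layers = {}
    for name, g in present.layers.items():
        if name in TEMPERATURE_LEVEL_LAYERS:
            layers[name] = g.copy_with(g.values + delta)
        else:
            layers[name] = g.copy_with(g.values.copy())
    return EnvStack(layers=layers, period=period, rcm=rcm, excluded=present.excluded)


@dataclass
class ScenarioSet:
    """Future stacks over periods x RCMs plus the warming applied to each."""

    stacks: list[EnvStack]
    warming_per_period: dict[tuple[str, str], float]  # (period, rcm) -> degC
    rcm_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(s.period, s.rcm) for s in self.stacks]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (period, rcm) stacks in ScenarioSet")

    def get(self, period: str, rcm: str) -> EnvStack:
        for s in self.stacks:
            if s.period == period and s.rcm == rcm:
                return s
        raise KeyError(f"no stack for period={period!r} rcm={rcm!r}")

    @property
    def periods(self) -> list[str]:
        seen = []
        for s in self.stacks:
            if s.period not in seen:
                seen.append(s.period)
        return seen


def make_scenarios(
    present: EnvStack,
    warming_by_period: dict[str, float] | None = None,
    rcm_names=DEFAULT_RCMS,
    rcm_jitter_sd: float = 0.34,
    seed: int = 0,
) -> ScenarioSet:
    """Build the full period x RCM scenario grid.

    Each RCM gets one stable long-term jitter (sd ``rcm_jitter_sd``,
    matching the projected 1.8 +/- 0.34 degC long-term spread) which is
    scaled down proportionally for nearer periods, so warming increases
    monotonically through time within every RCM.
    """
    warming_by_period = dict(warming_by_period or DEFAULT_WARMING)
    rng = np.random.default_rng(seed)
    jitters = {r: float(rng.normal(0.0, rcm_jitter_sd)) if rcm_jitter_sd > 0 else 0.0
               for r in rcm_names}
    max_w = max(warming_by_period.values()) or 1.0
    stacks, warming = [], {}
    for period, w in warming_by_period.items():
        for r in rcm_names:
            delta = w + jitters[r] * (w / max_w)
            stacks.append(make_future(present, warming=delta, rcm_jitter_sd=0.0,
                                      period=period, rcm=r))
            warming[(period, r)] = delta
    return ScenarioSet(stacks=stacks, warming_per_period=warming, rcm_names=list(rcm_names))


# ----------------------------------------------------------------------
# species truth and sampling
@dataclass
class SpeciesTruth:
    """Known low-dimensional niche: ground truth for recovery tests.

    ``responses`` maps a layer name to a response spec:
      ("gaussian", optimum, breadth)   exp(-((v - optimum)^2) / (2 breadth^2))
      ("logistic", slope, midpoint)    1 / (1 + exp(-slope (v - midpoint)))
    Cell occurrence probability is base_rate times the product of responses.
    """

    name: str
    responses: dict[str, tuple]
    base_rate: float = 0.9

    def __post_init__(self) -> None:
        if not 0 <= self.base_rate <= 1:
            raise ValueError("base_rate must be in [0, 1]")
        for layer, spec in self.responses.items():
            kind = spec[0]
            if kind == "gaussian":
                if spec[2] <= 0:
                    raise ValueError(f"gaussian breadth must be > 0 for {layer}")
            elif kind != "logistic":
                raise ValueError(f"unknown response kind {kind!r} for {layer}")

    def probability(self, env: EnvStack) -> Grid:
        missing = [n for n in self.responses if n not in env]
        if missing:
            raise KeyError(f"niche covariates missing from stack: {missing}")
        template = env.template
        p = np.where(template.mask, float(self.base_rate), np.nan)
        for layer, spec in self.responses.items():
            v = env[layer].values
            if spec[0] == "gaussian":
                _, opt, breadth = spec
                p = p * np.exp(-((v - opt) ** 2) / (2 * breadth**2))
            else:
                _, slope, mid = spec
                p = p / (1.0 + np.exp(-slope * (v - mid)))
        return template.copy_with(p)


def _bias_field(template: Grid, bias_params: dict | None, rng) -> np.ndarray:
    """Clustered sampling-effort field in (0, 1]; None -> uniform effort."""
    if not bias_params:
        return np.ones(template.shape)
    n_hot = int(bias_params.get("n_hotspots", 5))
    sigma = float(bias_params.get("sigma", max(2.0, min(template.shape) / 10)))
    strength = float(bias_params.get("strength", 0.8))
    if not 0 <= strength <= 1:
        raise ValueError("bias strength must be in [0, 1]")
    field_ = np.zeros(template.shape)
    rows, cols = np.nonzero(template.mask)
    if len(rows) == 0:
        return np.ones(template.shape)
    picks = rng.choice(len(rows), size=min(n_hot, len(rows)), replace=False)
    field_[rows[picks], cols[picks]] = 1.0
    field_ = ndimage.gaussian_filter(field_, sigma=sigma, mode="constant")
    if field_.max() > 0:
        field_ = field_ / field_.max()
    return (1.0 - strength) + strength * field_


def sample_occurrences(
    truth: SpeciesTruth,
    env: EnvStack,
    n_target: int,
    bias_params: dict | None = None,
    seed: int = 0,
    enforce_min: int | None = 15,
    max_attempts: int | None = None,
) -> OccurrenceSet:
    """Draw presence records from the niche times a sampling-effort field.

    Rejection sampling: land cells are proposed uniformly and accepted
    with probability niche(cell) * effort(cell), so accepted cells are
    distributed proportionally to that product.  Records get continuous
    coordinates uniform within their cell.  If after the attempt budget
    fewer than ``enforce_min`` records were achieved, an error names the
    achieved count (species with too few records are unusable downstream).
    """
    rng = np.random.default_rng(seed)
    template = env.template
    p = truth.probability(env).values
    effort = _bias_field(template, bias_params, rng)
    w = np.where(template.mask, p * effort, 0.0)
    rows, cols = np.nonzero(template.mask)
    if len(rows) == 0:
        raise ValueError("environment stack has no land cells")
    if max_attempts is None:
        max_attempts = max(200 * n_target, 10_000)

    accepted_r: list[int] = []
    accepted_c: list[int] = []
    if w.max() > 0 and n_target > 0:
        attempts = 0
        batch = max(4 * n_target, 256)
        while len(accepted_r) < n_target and attempts < max_attempts:
            k = rng.integers(0, len(rows), size=batch)
            u = rng.random(batch)
            keep = u < w[rows[k], cols[k]]
            accepted_r.extend(rows[k[keep]])
            accepted_c.extend(cols[k[keep]])
            attempts += batch
        accepted_r = accepted_r[:n_target]
        accepted_c = accepted_c[:n_target]

    n = len(accepted_r)
    if enforce_min is not None and n < min(enforce_min, n_target):
        raise RuntimeError(
            f"could not sample {n_target} occurrences for {truth.name!r}: "
            f"achieved only {n} within the attempt budget"
        )
    rr = np.asarray(accepted_r, dtype=float)
    cc = np.asarray(accepted_c, dtype=float)
    x = template.origin[0] + (cc + rng.random(n)) * template.cell_size
    y = template.origin[1] + (rr + rng.random(n)) * template.cell_size
    df = pd.DataFrame(
        {"species": truth.name, "x": x, "y": y, "label": PRESENCE, "source": "synthetic-survey"}
    )
    return OccurrenceSet(df)


# ----------------------------------------------------------------------
# protected areas
def make_protected_areas(
    env: EnvStack,
    coverage_fraction: float | dict[str, float] = 0.15,
    seed: int = 0,
    networks: tuple[str, ...] = ("NNR", "IPA"),
    disjoint: bool = False,
) -> ProtectedAreas:
    """Generate blob-shaped boolean protection masks over land.

    ``coverage_fraction`` is the approximate fraction of land covered,
    either one value for all networks or a per-network mapping.  With
    ``disjoint=True`` later networks avoid cells already protected.
    """
    template = env.template
    land = template.mask
    if not land.any():
        raise ValueError("environment stack has no land cells")
    rng = np.random.default_rng(seed)
    if not isinstance(coverage_fraction, dict):
        coverage_fraction = {n: float(coverage_fraction) for n in networks}
    masks: dict[str, Grid] = {}
    taken = np.zeros(template.shape, dtype=bool)
    for name in networks:
        cov = coverage_fraction[name]
        if not 0 < cov <= 1:
            raise ValueError(f"coverage for {name!r} must be in (0, 1], got {cov}")
        candidates = land & ~taken if disjoint else land
        if cov >= 1.0:
            sel = candidates.copy()
        else:
            field_ = _smooth_noise(template.shape, max(2.0, min(template.shape) / 12), rng)
            vals = field_[candidates]
            n_want = int(round(cov * land.sum()))
            n_want = min(n_want, candidates.sum())
            if n_want <= 0:
                sel = np.zeros_like(land)
            else:
                cut = np.sort(vals)[::-1][n_want - 1]
                sel = candidates & (field_ >= cut)
        masks[name] = template.copy_with(np.where(land, sel.astype(float), np.nan))
        if disjoint:
            taken |= sel
    return ProtectedAreas(masks=masks)
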