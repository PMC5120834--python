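"""Record cleaning, pseudo-absence design, covariate extraction and
two-stage variable selection.

The pipeline is: spatial thinning to one record per analysis cell,
augmentation with ten background pseudo-absences per presence, extraction
of covariate values at each record, a pairwise Pearson collinearity
screen (|r| > 0.7) resolved by an ecological priority order, and
bidirectional stepwise AIC selection on a binomial GLM capped by the
10-presences-per-variable rule of thumb.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grids import EnvStack, Grid
from .occurrences import PRESENCE, PSEUDO_ABSENCE, OccurrenceSet

__all__ = [
    "ModelTable",
    "thin_by_cell",
    "generate_pseudo_absences",
    "extract_env",
    "screen_collinearity",
    "stepwise_aic",
    "partition",
    "MIN_RECORDS",
]

logger = logging.getLogger(__name__)

#: species with fewer thinned presences than this are not modelled
MIN_RECORDS = 15


@dataclass
class ModelTable:
    """Design matrix for one species: covariates, 0/1 label, row weight.

    Presences carry weight 1 and pseudo-absences weight
    n_presence / n_pseudo, so the two classes contribute equal total
    weight (effective prevalence 0.5) regardless of the background ratio.
    """

    covariates: pd.DataFrame
    label: np.ndarray
    weight: np.ndarray = field(default=None)
    species: str = ""

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=int)
        if len(self.covariates) != len(self.label):
            raise ValueError("covariates and label length mismatch")
        if self.weight is None:
            self.weight = balanced_weights(self.label)
        self.weight = np.asarray(self.weight, dtype=float)
        if (self.weight < 0).any():
            raise ValueError("weights must be non-negative")
        if len(self.label) and not (set(np.unique(self.label)) <= {0, 1}):
            raise ValueError("labels must be 0/1")
        if self.covariates.isna().to_numpy().any():
            raise ValueError("ModelTable must not contain missing covariate values")

    @property
    def n(self) -> int:
        return len(self.label)

    @property
    def n_presence(self) -> int:
        return int(self.label.sum())

    @property
    def columns(self) -> list[str]:
        return list(self.covariates.columns)

    def subset_rows(self, idx) -> "ModelTable":
        return ModelTable(
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
            label=self.label[idx],
            weight=self.weight[idx],
            species=self.species,
        )

    def subset_columns(self, names) -> "ModelTable":
        missing = [n for n in names if n not in self.covariates.columns]
        if missing:
            raise KeyError(f"columns not in table: {missing}")
        return ModelTable(
            covariates=self.covariates[list(names)].copy(),
            label=self.label,
            weight=self.weight,
            species=self.species,
        )


def balanced_weights(label: np.ndarray) -> np.ndarray:
    """Weight 1 per presence; pseudo-absences share the same total weight."""
    label = np.asarray(label, dtype=int)
    n1 = int(label.sum())
    n0 = int((label == 0).sum())
    w = np.ones(len(label), dtype=float)
    if n0 > 0 and n1 > 0:
        w[label == 0] = n1 / n0
    return w


# ----------------------------------------------------------------------
def thin_by_cell(occ: OccurrenceSet, template: Grid, seed: int = 0) -> OccurrenceSet:
    """Reduce sampling bias: keep one uniformly chosen record per cell.

    Applied per species; deterministic for a given seed, and idempotent
    (a thinned set passes through unchanged).
    """
    df = occ.records
    if not len(df):
        return OccurrenceSet(df)
    rng = np.random.default_rng(seed)
    row, col = template.cell_index(df["x"].to_numpy(), df["y"].to_numpy())
    keyed = df.assign(_row=row, _col=col)
    keep_idx = []
    for _, group in keyed.groupby(["species", "label", "_row", "_col"], sort=True):
        keep_idx.append(group.index[rng.integers(0, len(group))])
    out = df.loc[sorted(keep_idx)]
    return OccurrenceSet(out)


def generate_pseudo_absences(
    presences: OccurrenceSet,
    template: Grid,
    ratio: int = 10,
    seed: int = 0,
) -> OccurrenceSet:
    """Augment presences with ratio-times-as-many background points.

    Pseudo-absence cells are drawn uniformly without replacement from
    land cells not holding a presence; each point sits at its cell
    centre.  Presence rows pass through untouched.
    """
    pres = presences.records[presences.records["label"] == PRESENCE]
    if not len(pres):
        raise ValueError("need at least one presence to generate pseudo-absences")
    n_pseudo = int(ratio) * len(pres)
    if n_pseudo == 0:
        return OccurrenceSet(pres)
    rng = np.random.default_rng(seed)
    land_r, land_c = np.nonzero(template.mask)
    prow, pcol = template.cell_index(pres["x"].to_numpy(), pres["y"].to_numpy())
    occupied = set(zip(prow.tolist(), pcol.tolist()))
    free = np.array([i for i in range(len(land_r)) if (land_r[i], land_c[i]) not in occupied])
    if len(free) < n_pseudo:
        raise ValueError(
            f"insufficient unoccupied land cells ({len(free)}) for {n_pseudo} pseudo-absences"
        )
    pick = rng.choice(free, size=n_pseudo, replace=False)
    x, y = template.cell_center(land_r[pick], land_c[pick])
    species = pres["species"].iloc[0]
    pa = pd.DataFrame(
        {"species": species, "x": x, "y": y, "label": PSEUDO_ABSENCE, "source": "background"}
    )
    return OccurrenceSet(pd.concat([pres, pa], ignore_index=True))


def extract_env(occ: OccurrenceSet, env: EnvStack, layers=None) -> ModelTable:
    """Look up covariate values at each record's containing cell.

    Rows whose cell is nodata in any requested layer (or off-grid) are
    dropped with a logged count.
    """
    names = list(layers) if layers is not None else env.selectable_names()
    missing = [n for n in names if n not in env]
    if missing:
        raise KeyError(f"layers missing from environment stack: {missing}")
    df = occ.records
    template = env.template
    row, col = template.cell_index(df["x"].to_numpy(), df["y"].to_numpy())
    inside = (row >= 0) & (row < template.nrows) & (col >= 0) & (col < template.ncols)
    data = np.full((len(df), len(names)), np.nan)
    for j, n in enumerate(names):
        data[inside, j] = env[n].values[row[inside], col[inside]]
    ok = np.isfinite(data).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("extract_env: dropped %d records on nodata/off-grid cells", n_dropped)
    label = (df["label"] == PRESENCE).to_numpy()[ok].astype(int)
    cov = pd.DataFrame(data[ok], columns=names)
    species = df["species"].iloc[0] if len(df) else ""
    return ModelTable(covariates=cov, label=label, species=str(species))


# ----------------------------------------------------------------------
# variable selection
def screen_collinearity(
    table: ModelTable,
    priority: list[str] | None = None,
    r_cut: float = 0.7,
) -> list[str]:
    """Drop the lower-priority member of every highly correlated pair.

    Pairs with |Pearson r| > r_cut over the table rows are processed in
    descending |r|; of each pair still retained, the member ranked lower
    in ``priority`` (ecological importance; unlisted names rank below all
    listed ones, in table order) is removed.  Zero-variance columns are
    excluded up front with a warning since r is undefined for them.
    Returned names are in priority order and are pairwise |r| <= r_cut.
    """
    if table.n < 3:
        raise ValueError("need at least 3 rows to screen collinearity")
    cols = table.columns
    priority = list(priority or [])
    rank = {n: i for i, n in enumerate(priority)}
    for n in cols:
        rank.setdefault(n, len(rank))

    X = table.covariates
    variances = X.var(ddof=0)
    alive = []
    for n in cols:
        if variances[n] <= 0:
            warnings.warn(f"screen_collinearity: dropping zero-variance column {n!r}")
        else:
            alive.append(n)
    corr = X[alive].corr().to_numpy()
    pairs = []
    for i in range(len(alive)):
        for j in range(i + 1, len(alive)):
            r = corr[i, j]
            if np.isfinite(r) and abs(r) > r_cut:
                pairs.append((abs(r), alive[i], alive[j]))
    retained = set(alive)
    for _, a, b in sorted(pairs, key=lambda t: -t[0]):
        if a in retained and b in retained:
            retained.discard(a if rank[a] > rank[b] else b)
    return sorted(retained, key=lambda n: rank[n])


def _glm_aic(table: ModelTable, names: list[str]) -> float:
    """AIC of a weighted binomial GLM; ridge-penalised fallback on failure.

    On perfect separation (or any IRLS failure) the coefficients come
    from an L2-penalised logistic fit and the AIC is the unpenalised
    2k - 2 log L at those coefficients, with a warning.
    """
    y = table.label
    w = table.weight
    X = sm.add_constant(table.covariates[list(names)].to_numpy(), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit()
        if np.isfinite(res.aic):
            return float(res.aic)
        raise ValueError("non-finite AIC")
    except Exception:  # noqa: BLE001 - IRLS failures take many forms
        warnings.warn(
            f"stepwise_aic: binomial GLM failed for {list(names)} (perfect separation?); "
            "using penalised fallback"
        )
        from sklearn.linear_model import LogisticRegression

        k = X.shape[1]
        if X.shape[1] > 1:
            lr = LogisticRegression(C=10.0, max_iter=2000)
            lr.fit(X[:, 1:], y, sample_weight=w)
            eta = lr.decision_function(X[:, 1:])
        else:
            p1 = np.average(y, weights=w).clip(1e-9, 1 - 1e-9)
            eta = np.full(len(y), math.log(p1 / (1 - p1)))
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        llf = float(np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p))))
        return 2 * k - 2 * llf


def stepwise_aic(
    table: ModelTable,
    candidates: list[str] | None = None,
    max_vars: int | None = None,
) -> list[str]:
    """Bidirectional stepwise selection on a binomial GLM, scored by AIC.

    Starts from the intercept-only model; at each step the single add or
    drop that lowers AIC most is taken, with adds barred once
    ``max_vars`` variables are in.  ``max_vars`` defaults to
    floor(n_presences / 10) (at least 1): the 10 presences per variable
    rule of thumb against over-fitting.
    """
    candidates = list(candidates if candidates is not None else table.columns)
    bad = [c for c in candidates if c not in table.covariates.columns]
    if bad:
        raise KeyError(f"candidates not in table: {bad}")
    if max_vars is None:
        max_vars = max(1, table.n_presence // 10)
    if max_vars < 1:
        raise ValueError("max_vars must be >= 1")

    selected: list[str] = []
    best_aic = _glm_aic(table, selected)
    while True:
        moves: list[tuple[float, str, str]] = []
        if len(selected) < max_vars:
            for c in candidates:
                if c not in selected:
                    moves.append((_glm_aic(table, selected + [c]), "add", c))
        for c in selected:
            moves.append((_glm_aic(table, [s for s in selected if s != c]), "drop", c))
        if not moves:
            break
        aic, action, name = min(moves, key=lambda t: t[0])
        if aic >= best_aic - 1e-9:
            break
        best_aic = aic
        if action == "add":
            selected.append(name)
        else:
            selected.remove(name)
    return selected


# ----------------------------------------------------------------------
def partition(
    table: ModelTable,
    train_frac: float = 0.8,
    n_rep: int = 10,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated stratified random train/test splits.

    Each replicate assigns every row to exactly one of train or test,
    with the train fraction applied within each label class so small
    presence sets cannot end up absent from a test fold.
    """
    if table.n < 5:
        raise ValueError("need at least 5 rows to partition")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    for cls in (0, 1):
        if int((table.label == cls).sum()) < 2:
            raise ValueError(f"label class {cls} has fewer than 2 members")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_rep):
        train_idx, test_idx = [], []
        for cls in (0, 1):
            members = np.nonzero(table.label == cls)[0]
            perm = rng.permutation(members)
            n_train = int(round(train_frac * len(members)))
            n_train = min(max(n_train, 1), len(members) - 1)
            train_idx.append(perm[:n_train])
            test_idx.append(perm[n_train:])
        splits.append(
            (np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx)))
        )
    return splits
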