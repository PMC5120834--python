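"""Replicate-based model evaluation.

Continuous model outputs in [0, 1] are reported on an integer 0-1000
suitability scale (round-half-up).  A score >= threshold counts as
predicted present.  The headline accuracy measure is the True Skill
Statistic, TSS = sensitivity + specificity - 1, preferred over kappa for
its independence of prevalence; the operating threshold is the one
maximising sensitivity + specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .learners import FittedModel, fit
from .preprocess import ModelTable

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "to_score_scale",
    "confusion_at_threshold",
    "tss",
    "kappa",
    "sensitivity",
    "specificity",
    "best_threshold_max_sens_spec",
    "cross_validate",
    "variable_importance",
    "TSS_GATE",
]

#: only algorithms with mean replicate TSS strictly above this enter ensembles
TSS_GATE = 0.7
#: conventional quality bands for mean TSS / kappa
EXCELLENT_TSS = 0.8
GOOD_TSS = 0.6

SCORE_MAX = 1000


def to_score_scale(p) -> np.ndarray:
    """Map probabilities in [0, 1] to the integer 0-1000 scale, round half up."""
    p = np.asarray(p, dtype=float)
    return np.floor(p * SCORE_MAX + 0.5).astype(int)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of predicted vs observed presence / pseudo-absence."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_presence(self) -> int:
        return self.tp + self.fn

    @property
    def n_absence(self) -> int:
        return self.fp + self.tn


def confusion_at_threshold(scores_pos, scores_neg, t) -> ConfusionMatrix:
    """Confusion matrix when scores >= t are called present."""
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if scores_pos.size == 0 or scores_neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    return ConfusionMatrix(
        tp=int((scores_pos >= t).sum()),
        fn=int((scores_pos < t).sum()),
        fp=int((scores_neg >= t).sum()),
        tn=int((scores_neg < t).sum()),
    )


def sensitivity(cm: ConfusionMatrix) -> float:
    if cm.n_presence == 0:
        raise ValueError("no observed presences; sensitivity undefined")
    return cm.tp / cm.n_presence


def specificity(cm: ConfusionMatrix) -> float:
    if cm.n_absence == 0:
        raise ValueError("no observed pseudo-absences; specificity undefined")
    return cm.tn / cm.n_absence


def tss(cm: ConfusionMatrix) -> float:
    """True Skill Statistic = sensitivity + specificity - 1, in [-1, 1]."""
    return sensitivity(cm) + specificity(cm) - 1.0


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: chance-corrected agreement from the marginals."""
    n = cm.n
    if n == 0 or cm.n_presence == 0 or cm.n_absence == 0:
        raise ValueError("kappa needs both observed classes")
    po = (cm.tp + cm.tn) / n
    pred_pos = (cm.tp + cm.fp) / n
    pred_neg = (cm.fn + cm.tn) / n
    pe = pred_pos * cm.n_presence / n + pred_neg * cm.n_absence / n
    if pe >= 1.0:
        warnings.warn("kappa: chance agreement is 1; returning 0")
        return 0.0
    return (po - pe) / (1.0 - pe)


def best_threshold_max_sens_spec(scores_pos, scores_neg, grid_max: int = SCORE_MAX) -> int:
    """Integer threshold on 0-1000 maximising sensitivity + specificity.

    Exhaustive over 0..grid_max; ties resolved to the smallest threshold.
    """
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if scores_pos.size == 0 or scores_neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ts = np.arange(grid_max + 1)
    sp = np.sort(scores_pos)
    sn = np.sort(scores_neg)
    tp = sp.size - np.searchsorted(sp, ts, side="left")  # #(pos >= t)
    tn = np.searchsorted(sn, ts, side="left")  # #(neg < t)
    # sens + spec = (tp * n_neg + tn * n_pos) / (n_pos * n_neg): compare the
    # integer numerator so exact ties resolve to the smallest threshold
    total = tp * sn.size + tn * sp.size
    return int(np.argmax(total))


@dataclass
class EvalReport:
    """Per-replicate evaluation results for one algorithm."""

    algorithm: str
    replicates: pd.DataFrame  # columns: replicate, tss, kappa, sensitivity, specificity, threshold
    n_skipped: int = 0

    @property
    def mean_tss(self) -> float:
        return float(self.replicates["tss"].mean())

    @property
    def sd_tss(self) -> float:
        return float(self.replicates["tss"].std(ddof=1)) if len(self.replicates) > 1 else 0.0

    @property
    def passes_gate(self) -> bool:
        return self.mean_tss > TSS_GATE

    @property
    def quality_band(self) -> str:
        m = self.mean_tss
        if m > EXCELLENT_TSS:
            return "excellent"
        if m >= GOOD_TSS:
            return "good"
        return "poor"

    def summary(self) -> dict:
        reps = self.replicates
        return {
            "algorithm": self.algorithm,
            "n_replicates": len(reps),
            "n_skipped": self.n_skipped,
            "mean_tss": self.mean_tss,
            "sd_tss": self.sd_tss,
            "mean_kappa": float(reps["kappa"].mean()),
            "mean_sensitivity": float(reps["sensitivity"].mean()),
            "mean_specificity": float(reps["specificity"].mean()),
            "mean_threshold": float(reps["threshold"].mean()),
            "passes_gate": self.passes_gate,
            "quality_band": self.quality_band,
        }


def cross_validate(
    algorithm: str,
    table: ModelTable,
    partitions,
    settings: dict | None = None,
    seed: int = 0,
) -> EvalReport:
    """Fit on each training split, evaluate on its test split.

    Per replicate: scores are put on the 0-1000 scale, the threshold
    maximising sensitivity + specificity is found on the test scores, and
    TSS / kappa / sensitivity / specificity are recorded at it.
    Replicates whose test fold lacks a class are skipped with a warning.
    """
    rows = []
    n_skipped = 0
    for k, (train_idx, test_idx) in enumerate(partitions):
        test = table.subset_rows(test_idx)
        if len(np.unique(test.label)) < 2:
            warnings.warn(f"cross_validate: replicate {k} has a single-class test fold; skipped")
            n_skipped += 1
            continue
        train = table.subset_rows(train_idx)
        model = fit(algorithm, train, settings=settings, seed=seed + k)
        scores = to_score_scale(model.predict_table(test))
        pos = scores[test.label == 1]
        neg = scores[test.label == 0]
        t = best_threshold_max_sens_spec(pos, neg)
        cm = confusion_at_threshold(pos, neg, t)
        rows.append(
            {
                "replicate": k,
                "tss": tss(cm),
                "kappa": kappa(cm),
                "sensitivity": sensitivity(cm),
                "specificity": specificity(cm),
                "threshold": t,
            }
        )
    if not rows:
        raise ValueError("all replicates were skipped; cannot evaluate")
    return EvalReport(algorithm=algorithm.upper(), replicates=pd.DataFrame(rows), n_skipped=n_skipped)


def variable_importance(
    model: FittedModel,
    table: ModelTable,
    n_shuffles: int = 5,
    seed: int = 0,
) -> dict[str, float]:
    """Shuffle-based importance on the 0-100 scale.

    For each covariate, its column is randomly permuted (others fixed),
    predictions are recomputed, and the importance is 100 x (1 - r) with
    r the Pearson correlation between original and shuffled predictions,
    averaged over ``n_shuffles`` and clamped to [0, 100].  Importances
    are per-variable and do not sum to anything in particular.
    """
    rng = np.random.default_rng(seed)
    X = table.covariates[model.covariates].to_numpy(dtype=float)
    base = model.predict(X)
    out: dict[str, float] = {}
    if np.std(base) <= 1e-12:
        warnings.warn("variable_importance: constant predictions; importances set to 0")
        return {name: 0.0 for name in model.covariates}
    for j, name in enumerate(model.covariates):
        vals = []
        for _ in range(n_shuffles):
            Xs = X.copy()
            Xs[:, j] = rng.permutation(Xs[:, j])
            pred = model.predict(Xs)
            if np.std(pred) <= 1e-12:
                r = 0.0
            else:
                r = stats.pearsonr(base, pred).statistic
            vals.append(100.0 * (1.0 - r))
        out[name] = float(np.clip(np.mean(vals), 0.0, 100.0))
    return out
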