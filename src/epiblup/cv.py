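"""k-fold cross-validation of genomic prediction models.

Individuals are randomly partitioned into k validation groups: the first
k-1 groups hold exactly floor(n/k) individuals and the last group the
remainder. For each fold, variance components are (by default) re-estimated
on the training individuals, GBLUP total genetic values are computed for
the held-out and training individuals, and prediction accuracy is the
Pearson correlation between total genetic values and phenotypes. GRMs are
built once on the full sample; the fold structure applies to phenotypes
only.

Summaries report mean +/- sample SD (k-1 denominator) across folds, and
model comparisons report the percent accuracy increase over a baseline
model, 100 * (acc - baseline) / baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    TooFewIndividualsError,
    UndefinedAccuracyError,
    UndefinedIncreaseError,
)
from .gblup import accuracy, predict_gblup
from .greml import ModelSpec, VarianceFit, fit_greml
from .grm import GRM

__all__ = ["FoldPlan", "CVResult", "make_folds", "run_cv",
           "accuracy_increase", "model_report"]


@dataclass
class FoldPlan:
    """Per-individual fold labels in 0..k-1."""

    k: int
    seed: int
    individual_ids: np.ndarray
    labels: np.ndarray

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class CVResult:
    """Per-fold accuracies and fits plus mean +/- SD summaries."""

    plan: FoldPlan
    val_accuracy: np.ndarray      # NaN marks a missing fold
    train_accuracy: np.ndarray
    fits: list[VarianceFit]
    model: str = ""
    warnings_: list[str] = field(default_factory=list)

    def _summary(self, a: np.ndarray) -> tuple[float, float]:
        ok = a[~np.isnan(a)]
        return float(np.mean(ok)), float(np.std(ok, ddof=1))

    @property
    def val_mean_sd(self) -> tuple[float, float]:
        return self._summary(self.val_accuracy)

    @property
    def train_mean_sd(self) -> tuple[float, float]:
        return self._summary(self.train_accuracy)

    def mean_h2(self, effect: str) -> float:
        return float(np.mean([f.h2(effect) for f in self.fits]))


def make_folds(ids, k: int = 10, seed: int = 0) -> FoldPlan:
    """Random fold plan: k-1 folds of floor(n/k), remainder in the last."""
    ids = np.asarray(ids, dtype=object)
    n = len(ids)
    if n < 2 * k:
        raise TooFewIndividualsError(f"need at least {2 * k} individuals for k={k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base = n // k
    labels = np.empty(n, dtype=np.int64)
    for f in range(k - 1):
        labels[perm[f * base:(f + 1) * base]] = f
    labels[perm[(k - 1) * base:]] = k - 1
    return FoldPlan(k=k, seed=seed, individual_ids=ids, labels=labels)


def run_cv(grms: list[GRM], y: np.ndarray, folds: FoldPlan,
           refit_per_fold: bool = True,
           whole_sample_fit: VarianceFit | None = None,
           model: str = "", **fit_options) -> CVResult:
    """k-fold cross-validated GBLUP accuracy for one model.

    ``refit_per_fold=False`` reuses ``whole_sample_fit`` (or one fit on the
    full data) for every fold — a documented speed option; the default
    re-estimates variance components on each training set. Folds whose
    accuracy is undefined (constant vectors) are recorded as missing and
    excluded from summaries with a warning.
    """
    ids = folds.individual_ids
    y = np.asarray(y, dtype=np.float64)
    if len(y) != len(ids):
        raise ConsistencyError("phenotype length does not match fold plan")
    if not np.array_equal(grms[0].individual_ids, ids):
        raise ConsistencyError("GRM ordering does not match fold plan")

    shared_fit = whole_sample_fit
    if not refit_per_fold and shared_fit is None:
        shared_fit = fit_greml(ModelSpec(grms=grms, y=y), **fit_options)

    k = folds.k
    val_acc = np.full(k, np.nan)
    train_acc = np.full(k, np.nan)
    fits: list[VarianceFit] = []
    notes: list[str] = []
    for v in range(k):
        val_mask = folds.labels == v
        t_idx = np.flatnonzero(~val_mask)
        v_idx = np.flatnonzero(val_mask)
        y_t = y[t_idx]
        if refit_per_fold:
            sub = [g.reorder(t_idx) for g in grms]
            fit = fit_greml(ModelSpec(grms=sub, y=y_t), **fit_options)
        else:
            fit = shared_fit
        fits.append(fit)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pred_v = predict_gblup(fit, grms, y_t, ids[t_idx], ids[v_idx])
            pred_t = predict_gblup(fit, grms, y_t, ids[t_idx], ids[t_idx])
        try:
            val_acc[v] = accuracy(pred_v.g_hat, y[v_idx])
        except UndefinedAccuracyError:
            notes.append(f"fold {v}: validation accuracy undefined; marked missing")
        try:
            train_acc[v] = accuracy(pred_t.g_hat, y_t)
        except UndefinedAccuracyError:
            notes.append(f"fold {v}: training accuracy undefined; marked missing")
    for msg in notes:
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return CVResult(plan=folds, val_accuracy=val_acc, train_accuracy=train_acc,
                    fits=fits, model=model, warnings_=notes)


def accuracy_increase(model_acc: float, baseline_acc: float) -> float:
    """Percent accuracy increase over a baseline model."""
    if baseline_acc == 0.0:
        raise UndefinedIncreaseError("baseline accuracy is zero")
    return 100.0 * (model_acc - baseline_acc) / baseline_acc


def model_report(results: dict[str, CVResult], baseline: str = "A",
                 ) -> pd.DataFrame:
    """Comparison table across models sharing one fold plan.

    Columns: training/validation accuracy mean and SD, percent increase of
    the validation (and training) accuracy over the baseline model, and the
    per-model total heritability (mean over folds). Rounding is left to the
    caller; values are unrounded.
    """
    if baseline not in results:
        raise ConsistencyError(f"baseline model {baseline!r} not in results")
    ref_plan = results[baseline].plan
    for name, res in results.items():
        if not (np.array_equal(res.plan.labels, ref_plan.labels)
                and np.array_equal(res.plan.individual_ids,
                                   ref_plan.individual_ids)):
            raise ConsistencyError(f"model {name!r} used a different fold plan")
    base_t, _ = results[baseline].train_mean_sd
    base_v, _ = results[baseline].val_mean_sd
    rows = []
    for name, res in results.items():
        tm, ts = res.train_mean_sd
        vm, vs = res.val_mean_sd
        rows.append({
            "model": name,
            "train_acc_mean": tm, "train_acc_sd": ts,
            "val_acc_mean": vm, "val_acc_sd": vs,
            "train_increase_pct": accuracy_increase(tm, base_t),
            "val_increase_pct": accuracy_increase(vm, base_v),
            "total_h2_mean": float(np.mean([f.total_h2 for f in res.fits])),
        })
    return pd.DataFrame(rows).set_index("model")
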