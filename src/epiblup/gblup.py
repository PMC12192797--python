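"""GBLUP of per-effect and total genetic values.

With variance components (sigma2_i, sigma2_e) estimated on the training
individuals t, the training-phenotype covariance is

    V_t = sum_i sigma2_i S_i[t, t] + sigma2_e I.

The GLS mean is mu = (1' V_t^-1 1)^-1 1' V_t^-1 y_t, and the BLUP of the
i-th genetic effect for any individuals p covered by the GRMs (including
the training individuals themselves) is the covariance projection

    u_i[p] = sigma2_i S_i[p, t] V_t^-1 (y_t - 1 mu),

so the total genetic value is g = sum_i u_i. Validation phenotypes never
enter: only rows/columns of the full-sample GRMs and training phenotypes do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import pearsonr

from .errors import ConsistencyError, UndefinedAccuracyError
from .greml import VarianceFit
from .grm import GRM

__all__ = ["PredictionSet", "predict_gblup", "accuracy"]


@dataclass
class PredictionSet:
    """Per-effect and total genetic values for the requested individuals."""

    individual_ids: np.ndarray
    effects: list[str]
    u: dict                      # effect -> (n_predict,) array
    g_hat: np.ndarray            # total genetic value
    mu_hat: float
    partition: np.ndarray        # 'train' / 'validation' per predicted individual


def _positions(all_ids: np.ndarray, wanted) -> np.ndarray:
    lookup = {i: k for k, i in enumerate(all_ids)}
    try:
        return np.array([lookup[i] for i in wanted], dtype=np.int64)
    except KeyError as e:
        raise ConsistencyError(f"individual {e.args[0]!r} absent from GRMs") from e


def predict_gblup(fit: VarianceFit, grms: list[GRM], y_train: np.ndarray,
                  train_ids, predict_ids) -> PredictionSet:
    """GBLUP for ``predict_ids`` from training phenotypes ``y_train``.

    ``grms`` are full-population GRMs sharing one individual ordering;
    ``y_train`` is aligned to ``train_ids``. ``predict_ids`` may overlap the
    training set (training-accuracy use).
    """
    if [g.effect for g in grms] != fit.effects:
        raise ConsistencyError("GRM effects do not match the variance fit")
    all_ids = grms[0].individual_ids
    for g in grms[1:]:
        if not np.array_equal(g.individual_ids, all_ids):
            raise ConsistencyError("GRMs have mismatched individual orderings")
    t = _positions(all_ids, train_ids)
    p = _positions(all_ids, predict_ids)
    y_train = np.asarray(y_train, dtype=np.float64)
    if len(y_train) != len(t):
        raise ConsistencyError("y_train length does not match train_ids")

    n_t = len(t)
    train_set = set(t.tolist())
    partition = np.array(["train" if k in train_set else "validation" for k in p],
                         dtype=object)

    if np.all(fit.sigma2 == 0.0):
        warnings.warn("all genetic variances are zero; predictions are 0",
                      RuntimeWarning, stacklevel=2)
        mu = float(np.mean(y_train))
        zeros = np.zeros(len(p))
        return PredictionSet(np.asarray(predict_ids, dtype=object), fit.effects,
                             {e: zeros.copy() for e in fit.effects},
                             zeros.copy(), mu, partition)

    V_t = fit.sigma2_e * np.eye(n_t)
    for s2, g in zip(fit.sigma2, grms):
        if s2 > 0.0:
            V_t += s2 * g.values[np.ix_(t, t)]
    cf = cho_factor(V_t, lower=True, check_finite=False)
    ones = np.ones(n_t)
    Vinv1 = cho_solve(cf, ones, check_finite=False)
    mu = float(Vinv1 @ y_train) / float(Vinv1.sum())
    alpha = cho_solve(cf, y_train - mu, check_finite=False)

    u: dict = {}
    g_hat = np.zeros(len(p))
    for s2, g in zip(fit.sigma2, grms):
        if s2 > 0.0:
            u_e = s2 * (g.values[np.ix_(p, t)] @ alpha)
        else:
            u_e = np.zeros(len(p))
        u[g.effect] = u_e
        g_hat += u_e
    return PredictionSet(np.asarray(predict_ids, dtype=object), fit.effects,
                         u, g_hat, mu, partition)


def accuracy(g_hat: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between predicted genetic values and phenotypes."""
    g_hat = np.asarray(g_hat, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(g_hat) != len(y):
        raise ConsistencyError("prediction and phenotype lengths differ")
    if len(y) < 3:
        raise UndefinedAccuracyError("need at least 3 individuals")
    if np.std(g_hat) == 0.0 or np.std(y) == 0.0:
        raise UndefinedAccuracyError("constant vector; correlation undefined")
    return float(pearsonr(g_hat, y).statistic)
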