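"""Multi-component genomic REML (GREML).

Model
-----
    y = 1 mu + sum_i u_i + e,   u_i ~ N(0, sigma2_i S_i),  e ~ N(0, sigma2_e I)

with one record per individual, an intercept-only fixed part (phenotypes are
pre-adjusted residuals), and f relationship matrices S_i. The phenotypic
covariance is V = sum_i sigma2_i S_i + sigma2_e I and the restricted
log-likelihood (up to a constant) is

    logL = -1/2 [ log|V| + log(1' V^-1 1) + y' P y ],
    P = V^-1 - V^-1 1 (1' V^-1 1)^-1 1' V^-1.

Estimation maximizes logL over the non-negative variance components with an
EM-REML warm-up (guaranteed ascent, no GRM inversion):

    sigma2_i <- sigma2_i + sigma2_i^2 (y'P S_i P y - tr(P S_i)) / n

followed by average-information (AI) updates with step halving; an AI step
is accepted only if it does not decrease logL, otherwise the iteration falls
back to EM, so the recorded likelihood trace is monotone. Singular S_i are
unproblematic: every solve is against V, which the residual term keeps
positive definite.

Components driven to the zero boundary are pinned (with a few re-entry
chances) and flagged. Heritability of effect i is
h2_i = sigma2_i / (sum_j sigma2_j + sigma2_e).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .errors import ConsistencyError, EmptyModelError
from .grm import GRM

__all__ = ["ModelSpec", "VarianceFit", "fit_greml", "heritability_table",
           "screen_effects"]


@dataclass
class ModelSpec:
    """Ordered random-effect structure plus the phenotype vector."""

    grms: list[GRM]
    y: np.ndarray
    individual_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.grms:
            raise EmptyModelError("at least one random effect is required")
        self.y = np.asarray(self.y, dtype=np.float64)
        n = len(self.y)
        ref = self.grms[0].individual_ids
        if self.individual_ids is None:
            self.individual_ids = ref
        for g in self.grms:
            if g.n != n:
                raise ConsistencyError(
                    f"GRM {g.effect} dimension {g.n} != phenotype length {n}"
                )
            if not np.array_equal(g.individual_ids, self.individual_ids):
                raise ConsistencyError(
                    f"GRM {g.effect} individual ordering mismatch"
                )

    @property
    def effects(self) -> list[str]:
        return [g.effect for g in self.grms]


@dataclass
class VarianceFit:
    """GREML estimates and diagnostics."""

    effects: list[str]
    sigma2: np.ndarray            # per-effect genetic variances
    sigma2_e: float
    loglik: float
    converged: bool
    n_iter: int
    boundary: np.ndarray          # per-effect pinned-at-zero flags
    trace: list[dict] = field(default_factory=list)
    warnings_: list[str] = field(default_factory=list)

    @property
    def sigma2_total(self) -> float:
        return float(np.sum(self.sigma2) + self.sigma2_e)

    @property
    def heritabilities(self) -> np.ndarray:
        return self.sigma2 / self.sigma2_total

    @property
    def total_h2(self) -> float:
        return float(np.sum(self.heritabilities))

    def h2(self, effect: str) -> float:
        return float(self.heritabilities[self.effects.index(effect)])


def _grm_collinearity(grms: Sequence[GRM]) -> list[str]:
    """Warn when two relationship matrices are (near-)proportional."""
    notes = []
    for a in range(len(grms)):
        for b in range(a + 1, len(grms)):
            va = grms[a].values.ravel()
            vb = grms[b].values.ravel()
            denom = np.linalg.norm(va) * np.linalg.norm(vb)
            if denom > 0 and abs(float(va @ vb)) / denom > 0.9999:
                notes.append(
                    f"GRMs {grms[a].effect} and {grms[b].effect} are collinear; "
                    "their variance split is not identifiable (only the sum is)"
                )
    return notes


def _restricted_loglik(theta: np.ndarray, S_list: list[np.ndarray],
                       y: np.ndarray) -> float:
    n = len(y)
    V = theta[-1] * np.eye(n)
    for t, S in zip(theta[:-1], S_list):
        V += t * S
    cf = cho_factor(V, lower=True, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    Vinv1 = cho_solve(cf, np.ones(n), check_finite=False)
    s = float(Vinv1.sum())
    Vinvy = cho_solve(cf, y, check_finite=False)
    yPy = float(y @ Vinvy) - float(y @ Vinv1) ** 2 / s
    return -0.5 * (logdet + np.log(s) + yPy)


def fit_greml(spec: ModelSpec, tol: float = 1e-6, tol_logl: float = 1e-8,
              max_iter: int = 200, n_em_warmup: int = 3,
              pin_frac: float = 1e-10, residual_floor_frac: float = 1e-8,
              ) -> VarianceFit:
    """Restricted maximum likelihood over non-negative variance components.

    Convergence requires the relative change of every free component to fall
    below ``tol`` and the logL change below ``tol_logl``. ``pin_frac`` times
    the phenotypic variance is the pin-at-zero threshold; a pinned component
    may re-enter up to three times before being frozen.
    """
    y = spec.y
    n = len(y)
    f = len(spec.grms)
    if n < f + 2:
        raise ConsistencyError("too few individuals for the number of components")
    S_list = [g.values for g in spec.grms]
    vy = float(np.var(y))
    if vy <= 0:
        raise ValueError("phenotype vector is constant")

    warn_notes = _grm_collinearity(spec.grms)

    # symmetric start: half the variance to the residual, half shared equally
    theta = np.full(f + 1, 0.5 * vy / f)
    theta[-1] = 0.5 * vy
    floor = residual_floor_frac * vy
    pin = pin_frac * vy
    pin_counts = np.zeros(f, dtype=int)
    frozen = np.zeros(f, dtype=bool)

    trace: list[dict] = []
    logL = -np.inf
    converged = False
    it = 0
    eye = np.eye(n)
    ones = np.ones(n)

    for it in range(1, max_iter + 1):
        V = theta[-1] * eye
        for t, S in zip(theta[:-1], S_list):
            V += t * S
        cf = cho_factor(V, lower=True, check_finite=False)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        Vinv = cho_solve(cf, eye, check_finite=False)
        Vinv1 = Vinv @ ones
        s = float(Vinv1.sum())
        P = Vinv - np.outer(Vinv1, Vinv1) / s
        Py = P @ y
        yPy = float(y @ Py)
        logL_new = -0.5 * (logdet + np.log(s) + yPy)

        # per-component quadratic forms and traces (S_e = I for the residual)
        SPy = [S @ Py for S in S_list] + [Py]
        q = np.array([float(Py @ v) for v in SPy])
        tr = np.array([float((P * S).sum()) for S in S_list] + [float(np.trace(P))])
        grad = 0.5 * (q - tr)

        step_kind = "em"
        theta_new = theta.copy()
        if it > n_em_warmup:
            # average-information update with step halving
            PSPy = [P @ v for v in SPy]
            k = f + 1
            AI = np.empty((k, k))
            for a in range(k):
                for b in range(a, k):
                    AI[a, b] = AI[b, a] = 0.5 * float(SPy[a] @ PSPy[b])
            free = np.array([not frozen[i] for i in range(f)] + [True])
            AI_f = AI[np.ix_(free, free)]
            AI_f = AI_f + 1e-8 * np.eye(AI_f.shape[0]) * max(np.trace(AI_f), 1.0)
            try:
                delta = np.linalg.solve(AI_f, grad[free])
                step = 1.0
                for _ in range(8):
                    cand = theta.copy()
                    cand[free] = theta[free] + step * delta
                    cand[:f] = np.maximum(cand[:f], 0.0)
                    cand[:f][frozen] = 0.0
                    cand[-1] = max(cand[-1], floor)
                    cand_logL = _restricted_loglik(cand, S_list, y)
                    if cand_logL >= logL_new - 1e-10 * max(1.0, abs(logL_new)):
                        theta_new = cand
                        step_kind = "ai"
                        break
                    step *= 0.5
            except np.linalg.LinAlgError:
                pass
        if step_kind == "em":
            # EM-REML ascent step (inversion-free form)
            for i in range(f):
                if frozen[i]:
                    theta_new[i] = 0.0
                else:
                    theta_new[i] = theta[i] + theta[i] ** 2 * (q[i] - tr[i]) / n
            theta_new[-1] = max(theta[-1] + theta[-1] ** 2 * (q[-1] - tr[-1]) / n,
                                floor)
            theta_new[:f] = np.maximum(theta_new[:f], 0.0)

        # pin-at-zero handling with limited re-entry
        for i in range(f):
            if frozen[i]:
                continue
            if theta_new[i] < pin:
                pin_counts[i] += 1
                if pin_counts[i] > 3:
                    frozen[i] = True
                    theta_new[i] = 0.0
                else:
                    theta_new[i] = pin  # keep a toehold for re-entry

        rel = np.abs(theta_new - theta) / np.maximum(np.abs(theta), 1e-12 * vy)
        active = np.concatenate([~frozen, [True]])
        rel_change = float(rel[active].max()) if active.any() else 0.0
        dlog = logL_new - logL if np.isfinite(logL) else np.inf

        trace.append({"iter": it, "logL": logL_new, "step": step_kind,
                      "theta": theta.copy()})
        theta = theta_new
        if rel_change < tol and abs(dlog) < tol_logl:
            converged = True
            logL = logL_new
            break
        logL = logL_new

    if not converged:
        warn_notes = warn_notes + [f"REML did not converge in {max_iter} iterations"]
        warnings.warn(warn_notes[-1], RuntimeWarning, stacklevel=2)

    sigma2 = theta[:f].copy()
    boundary = frozen | (sigma2 <= pin)
    sigma2[frozen] = 0.0
    return VarianceFit(
        effects=spec.effects,
        sigma2=sigma2,
        sigma2_e=float(theta[-1]),
        loglik=float(logL),
        converged=converged,
        n_iter=it,
        boundary=boundary,
        trace=trace,
        warnings_=warn_notes,
    )


def heritability_table(fit: VarianceFit) -> pd.DataFrame:
    """Per-effect variance and heritability, with a Total row.

    Values are unrounded; round only for presentation.
    """
    rows = [{"effect": e, "sigma2": float(s), "h2": float(h)}
            for e, s, h in zip(fit.effects, fit.sigma2, fit.heritabilities)]
    rows.append({"effect": "residual", "sigma2": fit.sigma2_e, "h2": np.nan})
    rows.append({"effect": "total", "sigma2": fit.sigma2_total,
                 "h2": fit.total_h2})
    return pd.DataFrame(rows)


def screen_effects(h2_by_effect, threshold: float = 0.005) -> list[str]:
    """Retain effect types whose heritability strictly exceeds ``threshold``.

    Accepts a :class:`VarianceFit` or a mapping effect -> h2 (e.g. a printed
    full-model heritability column); order is preserved.
    """
    if isinstance(h2_by_effect, VarianceFit):
        items = list(zip(h2_by_effect.effects, h2_by_effect.heritabilities))
    else:
        items = list(h2_by_effect.items())
    kept = [e for e, h in items if h > threshold]
    if not kept:
        raise EmptyModelError(
            f"no effect type has heritability above {threshold}"
        )
    return kept
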