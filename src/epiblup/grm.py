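"""Genomic relationship matrices (GRMs) for SNP, epistasis and partition effects.

The mixed model treats each effect type i as a random vector u_i with
Var(u_i) = sigma2_i * S_i, where S_i is an n x n relationship matrix:

* Additive (A): VanRaden method 1 — centered allele dosages W = X - 2p,
  S_A = W W' / sum_j 2 p_j (1 - p_j).
* Dominance (D): orthogonal dominance covariates (h = -2p^2, 2pq, -2q^2 for
  x = 0, 1, 2), S_D = H H' / sum_j (2 p_j q_j)^2. Under HWE this coding is
  uncorrelated with the additive one, which keeps the variance partition
  interpretable.
* Epistasis (AA, AD, DD, AAA, AAD, ADD, DDD): Hadamard (elementwise)
  products of the *unnormalized* additive and dominance cross-products
  K_A = W W', K_D = H H' — the genomic form of Henderson's device — each
  rescaled once so its mean diagonal is exactly 1. These are approximate
  epistasis GRMs; the Schur product theorem guarantees they stay PSD.
* AA partitioned by chromosome: with per-chromosome cross-products K_c
  (K_A = sum_c K_c), the intra-chromosome part is sum_c K_c o K_c and the
  inter-chromosome part is K_A o K_A - sum_c K_c o K_c, an exact identity
  before normalization.

Numerical rank is the count of eigenvalues above n * eps * lambda_max, the
standard surrogate for matrix rank of a PSD matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConsistencyError, DegenerateGRMError, DegenerateSNPError
from .genotype_io import GenotypeData

__all__ = [
    "GRM",
    "RankReport",
    "EPISTASIS_TAGS",
    "additive_design",
    "dominance_design",
    "crossproducts",
    "additive_grm",
    "dominance_grm",
    "epistasis_grm",
    "epistasis_grms",
    "partition_aa",
    "numerical_rank",
]

#: Hadamard recipes: which unnormalized cross-products to multiply elementwise.
EPISTASIS_TAGS: dict[str, str] = {
    "AA": "AA",
    "AD": "AD",
    "DD": "DD",
    "AAA": "AAA",
    "AAD": "AAD",
    "ADD": "ADD",
    "DDD": "DDD",
}


@dataclass
class GRM:
    """Named n x n symmetric relationship matrix.

    ``normalization`` is the scalar the raw cross-product was divided by,
    so ``values * normalization`` recovers the unnormalized matrix.
    """

    effect: str
    values: np.ndarray
    normalization: float
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ConsistencyError("GRM shape does not match id count")
        if not np.allclose(self.values, self.values.T, rtol=1e-10, atol=1e-10):
            raise ConsistencyError("GRM is not symmetric")

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def reorder(self, idx: np.ndarray) -> "GRM":
        """GRM restricted/permuted to individual positions ``idx``."""
        idx = np.asarray(idx)
        return GRM(self.effect, self.values[np.ix_(idx, idx)],
                   self.normalization, self.individual_ids[idx])


@dataclass
class RankReport:
    effect: str
    n: int
    rank: int
    tolerance: float


# ---------------------------------------------------------------------------
# SNP designs and first-order GRMs
# ---------------------------------------------------------------------------

def _check_polymorphic(g: GenotypeData) -> np.ndarray:
    p = g.allele_freq
    if np.any((p <= 0.0) | (p >= 1.0)):
        bad = np.asarray(g.snp_ids)[(p <= 0.0) | (p >= 1.0)]
        raise DegenerateSNPError(
            f"monomorphic SNP(s) {list(bad[:5])}; apply maf_filter first"
        )
    return p


def additive_design(g: GenotypeData) -> np.ndarray:
    """Centered dosage matrix W = X - 2p (n x m)."""
    p = _check_polymorphic(g)
    return g.x - 2.0 * p


def dominance_design(g: GenotypeData) -> np.ndarray:
    """Orthogonal dominance covariates (n x m)."""
    p = _check_polymorphic(g)
    q = 1.0 - p
    x = g.x
    h = np.empty_like(x)
    h[x == 0] = (-2.0 * p * p * np.ones_like(x))[x == 0]
    h[x == 1] = (2.0 * p * q * np.ones_like(x))[x == 1]
    h[x == 2] = (-2.0 * q * q * np.ones_like(x))[x == 2]
    return h


def crossproducts(g: GenotypeData) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized additive and dominance cross-products (K_A, K_D)."""
    w = additive_design(g)
    h = dominance_design(g)
    return w @ w.T, h @ h.T


def additive_grm(g: GenotypeData) -> GRM:
    """VanRaden method-1 additive GRM."""
    p = _check_polymorphic(g)
    w = additive_design(g)
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    return GRM("A", (w @ w.T) / denom, denom, g.individual_ids)


def dominance_grm(g: GenotypeData) -> GRM:
    """Orthogonal-coding dominance GRM."""
    p = _check_polymorphic(g)
    h = dominance_design(g)
    denom = float(np.sum((2.0 * p * (1.0 - p)) ** 2))
    return GRM("D", (h @ h.T) / denom, denom, g.individual_ids)


# ---------------------------------------------------------------------------
# Epistasis GRMs (Hadamard products)
# ---------------------------------------------------------------------------

def _mean_diag_normalize(effect: str, raw: np.ndarray,
                         ids: np.ndarray) -> GRM:
    md = float(np.mean(np.diag(raw)))
    if md <= 1e-300:
        raise DegenerateGRMError(f"{effect} GRM has zero mean diagonal")
    return GRM(effect, raw / md, md, ids)


def epistasis_grm(kind: str, K_A: np.ndarray, K_D: np.ndarray,
                  individual_ids: np.ndarray) -> GRM:
    """Hadamard-product epistasis GRM from unnormalized cross-products.

    ``kind`` spells the factors: each 'A' contributes one Hadamard factor of
    K_A and each 'D' one of K_D (e.g. 'AAD' -> K_A o K_A o K_D). The product
    is rescaled to mean diagonal 1.
    """
    if kind not in EPISTASIS_TAGS:
        raise ValueError(f"unknown epistasis tag {kind!r}")
    if K_A.shape != K_D.shape:
        raise ConsistencyError("K_A and K_D shapes differ")
    raw = np.ones_like(K_A)
    for ch in kind:
        raw = raw * (K_A if ch == "A" else K_D)
    return _mean_diag_normalize(kind, raw, individual_ids)


def epistasis_grms(g: GenotypeData, kinds: tuple[str, ...] = tuple(EPISTASIS_TAGS),
                   ) -> dict[str, GRM]:
    """All requested epistasis GRMs, computing K_A and K_D once."""
    K_A, K_D = crossproducts(g)
    return {k: epistasis_grm(k, K_A, K_D, g.individual_ids) for k in kinds}


def partition_aa(g: GenotypeData) -> tuple[GRM, GRM]:
    """Intra- and inter-chromosome additive-by-additive GRMs.

    Before normalization the two parts sum exactly to the global Hadamard
    product K_A o K_A.
    """
    w = additive_design(g)
    K_A = w @ w.T
    intra_raw = np.zeros_like(K_A)
    for c in dict.fromkeys(g.chrom):
        wc = w[:, g.chrom == c]
        K_c = wc @ wc.T
        intra_raw += K_c * K_c
    inter_raw = K_A * K_A - intra_raw
    intra = _mean_diag_normalize("AA_intra", intra_raw, g.individual_ids)
    if float(np.mean(np.diag(inter_raw))) <= 1e-12 * float(np.mean(np.diag(intra_raw))):
        raise DegenerateGRMError(
            "inter-chromosome AA component is zero (single chromosome?)"
        )
    inter = _mean_diag_normalize("AA_inter", inter_raw, g.individual_ids)
    return intra, inter


# ---------------------------------------------------------------------------
# Rank diagnostics
# ---------------------------------------------------------------------------

def numerical_rank(grm: GRM) -> RankReport:
    """Numerical rank: eigenvalues above tau = n * eps * lambda_max."""
    eigvals = np.linalg.eigvalsh(grm.values)
    lam_max = float(eigvals[-1]) if eigvals.size else 0.0
    if lam_max <= 0.0:
        return RankReport(grm.effect, grm.n, 0, 0.0)
    tol = grm.n * np.finfo(np.float64).eps * lam_max
    return RankReport(grm.effect, grm.n, int(np.sum(eigvals > tol)), tol)
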