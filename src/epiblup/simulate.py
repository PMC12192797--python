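"""Synthetic phased genotypes with LD and phenotypes with known variance fractions.

Genotypes
---------
Each chromosome carries a founder pool of F haplotypes. Per-SNP allele
frequencies are drawn uniformly between the MAF floor and its complement,
and founder alleles follow a first-order Markov chain along the chromosome
(copy the previous allele with probability ``ld_rho``, else a fresh
Bernoulli draw), which induces LD that decays with marker distance. Each
individual's two haplotypes are founder mosaics: a Poisson number of
crossovers per chromosome switches between founders, and the founder
identity carries over across chromosome boundaries, so two individuals that
draw the same founders are related genome-wide. Founder usage is *skewed*
(geometric weights, ``founder_concentration``): a few dominant ancestors
contribute most of the genome — the signature of an intensively selected
closed breeding population with huge paternal half-sib families — while the
minor founders keep the allele-frequency spectrum broad down to the MAF
floor. The skew is what gives the genomic relationship matrices enough
off-diagonal dispersion for multi-component variance estimation at
desk-scale n. Columns whose sample MAF falls below the floor (or are
monomorphic) have their founder alleles redrawn and the affected genotypes
recomposed from the stored mosaic, with bounded retries. The one-generation
mosaic compresses an entire ancestral pedigree, so the compact founder pool
stands in for many generations of accumulated kinship; LD decay is
qualitative, not a calibrated cattle demography.

Phenotypes
----------
Drawn from exactly the covariance model the estimator fits: for each effect
type i with variance fraction c_i, u_i ~ N(0, c_i S_i) with S_i the same
relationship matrix the GREML/GBLUP modules build (mean diagonal ~ 1, so
c_i is the target heritability on the phenotypic scale), plus i.i.d.
residuals with variance 1 - sum c_i. Additive, dominance and haplotype
components are drawn exactly through their design matrices (u = sqrt(c/d) W z);
epistasis components use a symmetric eigenfactorization of S_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, GeneratorError
from .genotype_io import GenotypeData, PhenotypeTable
from .grm import (
    additive_design,
    dominance_design,
    epistasis_grm,
    partition_aa,
)
from .haplotype import BlockScheme, define_blocks, haplotype_dosages

__all__ = ["SimConfig", "SimTruth", "simulate_genotypes", "simulate_phenotypes"]

_COMPONENTS = ("A", "D", "AA", "AA_intra", "AA_inter", "H")


@dataclass
class SimConfig:
    """Study conditions for the synthetic data.

    Defaults give the desk-scale profile: n = 2000 individuals and 20
    chromosomes of 200 SNPs (m = 4000) on 100 Mb chromosomes, a pool of 10
    founder haplotypes used with geometric concentration 0.45 (dominant-
    ancestor kinship, see module docstring), one expected crossover per
    gamete per chromosome, Markov LD parameter 0.5, 5% MAF floor, and the
    low-heritability fertility regime h2_A = 0.05, h2_AA = 0.06 with
    everything else residual. ``founder_concentration`` = 1 gives uniform
    founder usage (weak, unstructured kinship).
    """

    n: int = 2000
    n_chrom: int = 20
    snps_per_chrom: int = 200
    chrom_length_bp: int = 100_000_000
    founders: int = 10
    founder_concentration: float = 0.45
    crossover_rate: float = 1.0
    ld_rho: float = 0.5
    maf_floor: float = 0.05
    fractions: dict = field(default_factory=lambda: {"A": 0.05, "AA": 0.06})
    block_scheme: BlockScheme | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.founders < 2:
            raise ConfigError("founder pool must hold at least 2 haplotypes")
        if not 0.0 < self.founder_concentration <= 1.0:
            raise ConfigError("founder concentration must lie in (0, 1]")
        if not 0.0 <= self.maf_floor < 0.5:
            raise ConfigError("MAF floor must lie in [0, 0.5)")
        bad = set(self.fractions) - set(_COMPONENTS)
        if bad:
            raise ConfigError(f"unknown variance components {sorted(bad)}")
        if any(c < 0 for c in self.fractions.values()):
            raise ConfigError("variance fractions must be non-negative")
        if sum(self.fractions.values()) > 1.0 + 1e-12:
            raise ConfigError("variance fractions must sum to at most 1")

    @property
    def m(self) -> int:
        return self.n_chrom * self.snps_per_chrom


@dataclass
class SimTruth:
    """Realized genetic values and variance fractions of one simulation."""

    seed: int
    fractions: dict
    components: dict             # effect -> (n,) realized genetic values
    residual: np.ndarray
    realized_var: dict           # effect -> realized variance of u_i


def _founder_haplotypes(rng: np.random.Generator, F: int, q: np.ndarray,
                        rho: float) -> np.ndarray:
    """F founder haplotypes with Markov-dependent adjacent alleles."""
    m = len(q)
    H = np.empty((F, m), dtype=np.int8)
    H[:, 0] = rng.random(F) < q[0]
    for j in range(1, m):
        copy = rng.random(F) < rho
        fresh = (rng.random(F) < q[j]).astype(np.int8)
        H[:, j] = np.where(copy, H[:, j - 1], fresh)
    return H


def _mosaic(rng: np.random.Generator, weights: np.ndarray, start: np.ndarray,
            pos: np.ndarray, length: int, rate: float) -> np.ndarray:
    """Founder index per gamete per SNP under Poisson crossovers.

    ``start`` holds each gamete's founder at the chromosome start and is
    updated in place to the founder at the chromosome end, carrying founder
    identity across chromosomes. Crossovers switch to a founder drawn with
    the (possibly skewed) usage ``weights``.
    """
    m = len(pos)
    F = len(weights)
    n_gametes = len(start)
    idx = np.empty((n_gametes, m), dtype=np.int16)
    n_cross = rng.poisson(rate, size=n_gametes)
    for g in range(n_gametes):
        k = n_cross[g]
        if k == 0:
            idx[g] = start[g]
            continue
        breaks = np.sort(rng.integers(0, length, size=k))
        founders = np.concatenate([[start[g]],
                                   rng.choice(F, size=k, p=weights)])
        seg = np.searchsorted(breaks, pos, side="right")
        idx[g] = founders[seg]
        start[g] = founders[-1]
    return idx


def simulate_genotypes(cfg: SimConfig) -> GenotypeData:
    """Phased multi-chromosome genotypes honouring the MAF floor."""
    rng = np.random.default_rng(cfg.seed)
    n, F = cfg.n, cfg.founders
    weights = cfg.founder_concentration ** np.arange(F)
    weights /= weights.sum()
    chroms, positions, snp_ids = [], [], []
    hap1_cols, hap2_cols = [], []
    # genome-wide founder state per gamete
    state1 = rng.choice(F, size=n, p=weights)
    state2 = rng.choice(F, size=n, p=weights)
    for c in range(cfg.n_chrom):
        name = f"chr{c + 1}"
        pos = np.unique(rng.integers(1, cfg.chrom_length_bp,
                                     size=cfg.snps_per_chrom))
        while pos.size < cfg.snps_per_chrom:  # top up collisions
            extra = rng.integers(1, cfg.chrom_length_bp,
                                 size=cfg.snps_per_chrom - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        q = rng.uniform(cfg.maf_floor, 1.0 - cfg.maf_floor, size=cfg.snps_per_chrom)
        founders = _founder_haplotypes(rng, F, q, cfg.ld_rho)
        trace1 = _mosaic(rng, weights, state1, pos, cfg.chrom_length_bp,
                         cfg.crossover_rate)
        trace2 = _mosaic(rng, weights, state2, pos, cfg.chrom_length_bp,
                         cfg.crossover_rate)
        cols = np.arange(cfg.snps_per_chrom)
        h1 = founders[trace1, cols]
        h2 = founders[trace2, cols]
        # enforce the MAF floor by redrawing founder alleles at bad columns
        for attempt in range(200):
            p = (h1 + h2).mean(axis=0) / 2.0
            maf = np.minimum(p, 1.0 - p)
            bad = np.flatnonzero((maf < cfg.maf_floor) | (maf == 0.0))
            if bad.size == 0:
                break
            founders[:, bad] = rng.random((F, bad.size)) < q[bad]
            h1[:, bad] = founders[trace1[:, bad], bad]
            h2[:, bad] = founders[trace2[:, bad], bad]
        else:
            raise GeneratorError(
                "could not satisfy the MAF floor; founder pool too small?"
            )
        chroms.append(np.full(cfg.snps_per_chrom, name, dtype=object))
        positions.append(pos)
        snp_ids.append(np.array([f"{name}_snp{j + 1}" for j in cols], dtype=object))
        hap1_cols.append(h1)
        hap2_cols.append(h2)
    return GenotypeData(
        individual_ids=np.array([f"ind{i + 1:05d}" for i in range(n)], dtype=object),
        snp_ids=np.concatenate(snp_ids),
        chrom=np.concatenate(chroms),
        pos_bp=np.concatenate(positions),
        hap1=np.hstack(hap1_cols),
        hap2=np.hstack(hap2_cols),
    )


def _mvn_from_grm(rng: np.random.Generator, S: np.ndarray, c: float) -> np.ndarray:
    lam, U = np.linalg.eigh(S)
    lam = np.clip(lam, 0.0, None)
    z = rng.standard_normal(len(lam))
    return U @ (np.sqrt(c * lam) * z)


def simulate_phenotypes(g: GenotypeData, cfg: SimConfig,
                        ) -> tuple[PhenotypeTable, SimTruth]:
    """Phenotypes under the multi-component covariance model, mean 0."""
    fr = {k: v for k, v in cfg.fractions.items() if v > 0.0}
    if sum(fr.values()) > 1.0 + 1e-12:
        raise ConfigError("variance fractions sum above 1")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919]))
    n = g.n
    components: dict = {}
    p = g.allele_freq

    need_KA = any(k in fr for k in ("AA",))
    if "A" in fr:
        w = additive_design(g)
        d = float(np.sum(2.0 * p * (1.0 - p)))
        components["A"] = np.sqrt(fr["A"] / d) * (w @ rng.standard_normal(g.m))
    if "D" in fr:
        h = dominance_design(g)
        d = float(np.sum((2.0 * p * (1.0 - p)) ** 2))
        components["D"] = np.sqrt(fr["D"] / d) * (h @ rng.standard_normal(g.m))
    if need_KA:
        w = additive_design(g)
        K_A = w @ w.T
        S_AA = epistasis_grm("AA", K_A, K_A, g.individual_ids).values
        components["AA"] = _mvn_from_grm(rng, S_AA, fr["AA"])
    if "AA_intra" in fr or "AA_inter" in fr:
        intra, inter = partition_aa(g)
        if "AA_intra" in fr:
            components["AA_intra"] = _mvn_from_grm(rng, intra.values, fr["AA_intra"])
        if "AA_inter" in fr:
            components["AA_inter"] = _mvn_from_grm(rng, inter.values, fr["AA_inter"])
    if "H" in fr:
        scheme = cfg.block_scheme or BlockScheme("distance", 7_500_000)
        hb = haplotype_dosages(g, define_blocks(g, scheme))
        designs = [d.dosage.astype(np.float64) - 2.0 * d.freq
                   for d in hb.dosages if not d.monomorphic]
        if not designs:
            raise ConfigError("haplotype fraction requested but no polymorphic block")
        Wh = np.hstack(designs)
        md = float(np.mean(np.sum(Wh * Wh, axis=1)))
        components["H"] = np.sqrt(fr["H"] / md) * (Wh @ rng.standard_normal(Wh.shape[1]))

    resid_var = 1.0 - sum(fr.values())
    e = (np.sqrt(resid_var) * rng.standard_normal(n) if resid_var > 0
         else np.zeros(n))
    y = e + sum(components.values(), np.zeros(n))
    pheno = PhenotypeTable(g.individual_ids.copy(), y)
    truth = SimTruth(
        seed=cfg.seed,
        fractions=dict(fr),
        components=components,
        residual=e,
        realized_var={k: float(np.var(v)) for k, v in components.items()},
    )
    return pheno, truth
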