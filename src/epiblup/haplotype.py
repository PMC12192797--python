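"""Haplotype blocks and the multi-allelic haplotype GRM.

A chromosome segment (block) is treated as one locus whose distinct observed
haplotypes act as alleles; each individual carries two allele copies per
block, so allele dosages per block sum to 2. The haplotype additive GRM is
the cross-product of the centered allele-dosage matrices, summed over blocks
and rescaled to mean diagonal 1:

    K_H = sum_b W_b W_b',   W_b[:, k] = dosage_k - 2 f_bk,
    S_H = K_H / mean(diag(K_H)).

Blocking schemes: a fixed number of SNPs or a fixed physical distance, each
either as consecutive non-overlapping blocks or as sliding windows with a
step of one SNP. Distance bins are half-open intervals anchored at
coordinate 0 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGRMError, InvalidSchemeError, PhaseRequiredError
from .genotype_io import GenotypeData
from .grm import GRM

__all__ = [
    "BlockScheme",
    "Block",
    "BlockDosages",
    "HaplotypeBlocks",
    "define_blocks",
    "haplotype_dosages",
    "haplotype_grm",
]


@dataclass
class BlockScheme:
    """Haplotype blocking scheme.

    method : 'snp_count' or 'distance'
    size : block size — SNP count (>= 2) or bp length (> 0)
    sliding : sliding windows (step = 1 SNP) instead of consecutive blocks
    """

    method: str
    size: int
    sliding: bool = False
    step: int = 1

    def __post_init__(self) -> None:
        if self.method not in ("snp_count", "distance"):
            raise InvalidSchemeError(f"unknown blocking method {self.method!r}")
        if self.method == "snp_count" and self.size < 2:
            raise InvalidSchemeError("snp_count block size must be >= 2")
        if self.method == "distance" and self.size <= 0:
            raise InvalidSchemeError("distance block size must be positive")
        if self.step != 1:
            raise InvalidSchemeError("only a step of one SNP is supported")


@dataclass(frozen=True)
class Block:
    """Half-open SNP index range [start, stop) on one chromosome.

    Indices refer to columns of the genome-wide SNP arrays.
    """

    chrom: str
    start: int
    stop: int

    @property
    def n_snps(self) -> int:
        return self.stop - self.start


@dataclass
class BlockDosages:
    """Observed haplotype alleles of one block and per-individual dosages."""

    block: Block
    alleles: list[str]           # bit strings over the block's SNPs
    dosage: np.ndarray           # (n, K) allele copy counts in {0,1,2}
    freq: np.ndarray             # (K,) allele frequencies, sum to 1

    @property
    def monomorphic(self) -> bool:
        return len(self.alleles) < 2


@dataclass
class HaplotypeBlocks:
    blocks: list[Block]
    dosages: list[BlockDosages] = field(default_factory=list)
    individual_ids: np.ndarray | None = None

    @property
    def n_monomorphic(self) -> int:
        return sum(d.monomorphic for d in self.dosages)


# ---------------------------------------------------------------------------
# Block definitions
# ---------------------------------------------------------------------------

def define_blocks(g: GenotypeData, scheme: BlockScheme) -> list[Block]:
    """Block definitions under ``scheme``, per chromosome.

    snp_count/fixed: consecutive windows of ``size`` SNPs; a trailing window
    of one SNP is merged into the previous block. snp_count/sliding: every
    full window at each SNP start. distance/fixed: half-open bins
    [k*L, (k+1)*L) anchored at 0 bp, keeping bins with >= 2 SNPs.
    distance/sliding: one window of L bp starting at each SNP position,
    deduplicated by SNP content and kept when >= 2 SNPs.
    """
    blocks: list[Block] = []
    for c in dict.fromkeys(g.chrom):
        idx = np.flatnonzero(g.chrom == c)
        lo, hi = int(idx[0]), int(idx[-1]) + 1  # contiguous after sorting
        n_c = hi - lo
        pos = g.pos_bp[lo:hi]
        if scheme.method == "snp_count":
            size = scheme.size
            if scheme.sliding:
                if n_c < size:
                    if n_c >= 2:
                        blocks.append(Block(c, lo, hi))
                    continue
                blocks.extend(Block(c, lo + s, lo + s + size)
                              for s in range(n_c - size + 1))
            else:
                if n_c < 2:
                    continue
                starts = list(range(0, n_c, size))
                bounds = [(s, min(s + size, n_c)) for s in starts]
                if len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] < 2:
                    bounds[-2] = (bounds[-2][0], bounds[-1][1])
                    bounds.pop()
                blocks.extend(Block(c, lo + a, lo + b) for a, b in bounds)
        else:  # distance
            L = scheme.size
            if scheme.sliding:
                seen: set[tuple[int, int]] = set()
                for j in range(n_c):
                    stop = int(np.searchsorted(pos, pos[j] + L, side="left"))
                    if stop - j >= 2 and (j, stop) not in seen:
                        seen.add((j, stop))
                        blocks.append(Block(c, lo + j, lo + stop))
            else:
                k_bins = np.asarray(pos // L)
                for k in dict.fromkeys(k_bins.tolist()):
                    members = np.flatnonzero(k_bins == k)
                    if members.size >= 2:
                        blocks.append(Block(c, lo + int(members[0]),
                                            lo + int(members[-1]) + 1))
    return blocks


# ---------------------------------------------------------------------------
# Haplotype alleles and dosages
# ---------------------------------------------------------------------------

def haplotype_dosages(g: GenotypeData, blocks: list[Block]) -> HaplotypeBlocks:
    """Enumerate observed haplotype alleles per block and count copies."""
    if g.hap1 is None or g.hap2 is None:  # pragma: no cover - container always phased
        raise PhaseRequiredError("phased haplotypes required")
    n = g.n
    out = HaplotypeBlocks(blocks=list(blocks),
                          individual_ids=g.individual_ids.copy())
    for b in blocks:
        sub = np.vstack([g.hap1[:, b.start:b.stop], g.hap2[:, b.start:b.stop]])
        # encode each haplotype row as a bit string
        strings = np.array(["".join(map(str, row)) for row in sub], dtype=object)
        alleles, inverse = np.unique(strings, return_inverse=True)
        K = len(alleles)
        dosage = np.zeros((n, K), dtype=np.int64)
        np.add.at(dosage, (np.tile(np.arange(n), 2), inverse), 1)
        freq = dosage.mean(axis=0) / 2.0
        out.dosages.append(BlockDosages(b, list(alleles), dosage, freq))
    return out


def haplotype_grm(hb: HaplotypeBlocks) -> GRM:
    """Multi-allelic haplotype additive GRM (tag H), mean diagonal 1.

    Monomorphic blocks carry no variance and are skipped.
    """
    if not hb.dosages:
        raise DegenerateGRMError("no haplotype dosages; run haplotype_dosages")
    K_H = None
    used = 0
    for d in hb.dosages:
        if d.monomorphic:
            continue
        w = d.dosage.astype(np.float64) - 2.0 * d.freq
        contrib = w @ w.T
        K_H = contrib if K_H is None else K_H + contrib
        used += 1
    if K_H is None or used == 0:
        raise DegenerateGRMError("all haplotype blocks are monomorphic")
    md = float(np.mean(np.diag(K_H)))
    if md <= 1e-300:
        raise DegenerateGRMError("haplotype GRM has zero mean diagonal")
    ids = hb.individual_ids
    if ids is None:
        ids = np.array([f"ind{i}" for i in range(K_H.shape[0])], dtype=object)
    return GRM("H", K_H / md, md, ids)
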