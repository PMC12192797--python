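"""Genotype, phenotype, SNP-map and GRM file I/O.

The in-memory genotype container is :class:`GenotypeData`: a phase-resolved
biallelic SNP panel. The counted allele is the VCF ALT allele (code ``1`` in
the tabular dialect), so the genotype code is ``x = hap1 + hap2`` with
``x in {0, 1, 2}`` copies of ALT, and the per-SNP allele frequency is the
column mean of ``x`` divided by two.

File dialects
-------------
* Phased VCF 4.x with GT fields (read via cyvcf2).
* Tabular haplotypes: TSV whose header line is ``#id  hap  <snp ids...>``,
  followed by two rows per individual (hap labels 1 and 2) of {0,1} alleles.
* SNP map: TSV ``#snp_id  chrom  pos_bp``.
* Phenotypes: TSV ``#id  y`` (one record per individual).
* GRM text: header lines (effect, normalization, ids) then lower-triangle
  ``id_i  id_j  value`` triplets at full precision.
* GRM binary: GCTA-style layout — ``prefix.grm.bin`` holds the lower
  triangle (diagonal included) row-major, ``prefix.grm.id`` the ids; element
  width defaults to float64 for exact round trips and is auto-detected on
  read (4-byte files, i.e. true GCTA output, are accepted too). Effect tag
  and normalization go in a ``prefix.grm.json`` sidecar.

Missing genotypes are rejected rather than imputed: the pipeline assumes a
fully imputed panel upstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    ConsistencyError,
    DuplicateSiteError,
    EmptyPanelError,
    MalformedFileError,
    MissingGenotypeError,
    PhaseRequiredError,
    UnsupportedRecordError,
)

__all__ = [
    "GenotypeData",
    "PhenotypeTable",
    "read_phased_vcf",
    "read_tabular_genotypes",
    "write_tabular_genotypes",
    "read_snp_map",
    "write_snp_map",
    "read_phenotypes",
    "write_phenotypes",
    "maf_filter",
    "write_grm",
    "read_grm",
]


@dataclass
class GenotypeData:
    """Phase-resolved biallelic SNP panel.

    Attributes
    ----------
    individual_ids : (n,) array of str
    snp_ids : (m,) array of str
    chrom : (m,) array of str
        Chromosome label per SNP.
    pos_bp : (m,) array of int
        Physical position (bp); strictly increasing within a chromosome.
    hap1, hap2 : (n, m) int8 arrays
        Allele indicators in {0, 1}, phase-resolved.
    """

    individual_ids: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    hap1: np.ndarray
    hap2: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.hap1 = np.asarray(self.hap1, dtype=np.int8)
        self.hap2 = np.asarray(self.hap2, dtype=np.int8)
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    @property
    def x(self) -> np.ndarray:
        """Genotype codes (n, m) in {0,1,2}: copies of the counted allele."""
        return (self.hap1 + self.hap2).astype(np.float64)

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele (column mean of x over 2)."""
        return self.x.mean(axis=0) / 2.0

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        n, m = self.hap1.shape
        if self.hap2.shape != (n, m):
            raise ConsistencyError("hap1 and hap2 shapes differ")
        if len(self.individual_ids) != n or len(self.snp_ids) != m:
            raise ConsistencyError("id lengths do not match haplotype matrices")
        if len(self.chrom) != m or len(self.pos_bp) != m:
            raise ConsistencyError("SNP map lengths do not match SNP count")
        if len(set(self.individual_ids)) != n:
            raise ConsistencyError("duplicate individual ids")
        if len(set(self.snp_ids)) != m:
            raise ConsistencyError("duplicate SNP ids")
        for h in (self.hap1, self.hap2):
            if h.size and (h.min() < 0 or h.max() > 1):
                raise ValueError("haplotype entries must be in {0,1}")
        # strictly increasing positions within each chromosome
        for c in dict.fromkeys(self.chrom):
            pos = self.pos_bp[self.chrom == c]
            if pos.size > 1 and not np.all(np.diff(pos) > 0):
                raise DuplicateSiteError(
                    f"positions not strictly increasing on chromosome {c}"
                )

    # -- subsetting ---------------------------------------------------------

    def subset_snps(self, mask: np.ndarray) -> "GenotypeData":
        mask = np.asarray(mask)
        return GenotypeData(
            individual_ids=self.individual_ids.copy(),
            snp_ids=self.snp_ids[mask],
            chrom=self.chrom[mask],
            pos_bp=self.pos_bp[mask],
            hap1=self.hap1[:, mask],
            hap2=self.hap2[:, mask],
        )

    def subset_individuals(self, idx: np.ndarray) -> "GenotypeData":
        idx = np.asarray(idx)
        return GenotypeData(
            individual_ids=self.individual_ids[idx],
            snp_ids=self.snp_ids.copy(),
            chrom=self.chrom.copy(),
            pos_bp=self.pos_bp.copy(),
            hap1=self.hap1[idx],
            hap2=self.hap2[idx],
        )


@dataclass
class PhenotypeTable:
    """One residual phenotypic record per individual (N = n)."""

    individual_ids: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.y = np.asarray(self.y, dtype=np.float64)
        if len(self.individual_ids) != len(self.y):
            raise ConsistencyError("phenotype ids and values differ in length")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ConsistencyError("repeated phenotype records; expected N = n")
        if np.any(~np.isfinite(self.y)):
            raise ValueError("missing or non-finite phenotype values")

    def aligned_to(self, ids: Sequence[str]) -> np.ndarray:
        """Return y reordered to ``ids``; every id must have a record."""
        lookup = {i: k for k, i in enumerate(self.individual_ids)}
        try:
            order = [lookup[i] for i in ids]
        except KeyError as e:  # pragma: no cover - message clarity
            raise ConsistencyError(f"no phenotype for individual {e.args[0]}") from e
        return self.y[order]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(path: str | Path, require_phase: bool = True) -> GenotypeData:
    """Read a phased, biallelic-SNP VCF into a :class:`GenotypeData`.

    The counted allele is ALT. Records are sorted by (chromosome in order of
    first appearance, position). Multi-allelic records, missing GTs and —
    when ``require_phase`` — unphased GTs raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    snp_ids, chroms, positions = [], [], []
    h1_cols, h2_cols = [], []
    seen: set[tuple[str, int]] = set()
    for v in vcf:
        if len(v.ALT) != 1:
            raise UnsupportedRecordError(
                f"multi-allelic record at {v.CHROM}:{v.POS}"
            )
        key = (v.CHROM, v.POS)
        if key in seen:
            raise DuplicateSiteError(f"duplicate site {v.CHROM}:{v.POS}")
        seen.add(key)
        a1, a2 = [], []
        for g in v.genotypes:  # [allele1, allele2, phased]
            if g[0] < 0 or g[1] < 0:
                raise MissingGenotypeError(f"missing GT at {v.CHROM}:{v.POS}")
            if require_phase and not g[2]:
                raise PhaseRequiredError(f"unphased GT at {v.CHROM}:{v.POS}")
            a1.append(g[0])
            a2.append(g[1])
        snp_ids.append(v.ID if v.ID else f"{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        positions.append(v.POS)
        h1_cols.append(a1)
        h2_cols.append(a2)
    if not snp_ids:
        raise MalformedFileError(f"no usable records in {path}")

    chrom_order = {c: k for k, c in enumerate(dict.fromkeys(chroms))}
    order = sorted(range(len(snp_ids)), key=lambda j: (chrom_order[chroms[j]], positions[j]))
    return GenotypeData(
        individual_ids=np.array(individual_ids, dtype=object),
        snp_ids=np.array([snp_ids[j] for j in order], dtype=object),
        chrom=np.array([chroms[j] for j in order], dtype=object),
        pos_bp=np.array([positions[j] for j in order], dtype=np.int64),
        hap1=np.array(h1_cols, dtype=np.int8).T[:, order],
        hap2=np.array(h2_cols, dtype=np.int8).T[:, order],
    )


# ---------------------------------------------------------------------------
# Tabular haplotypes + SNP map
# ---------------------------------------------------------------------------

def write_tabular_genotypes(g: GenotypeData, geno_path: str | Path,
                            map_path: str | Path | None = None) -> None:
    """Write the tabular haplotype dialect (and optionally the SNP map)."""
    with open(geno_path, "w") as fh:
        fh.write("#id\thap\t" + "\t".join(map(str, g.snp_ids)) + "\n")
        for i, ind in enumerate(g.individual_ids):
            fh.write(f"{ind}\t1\t" + "\t".join(map(str, g.hap1[i])) + "\n")
            fh.write(f"{ind}\t2\t" + "\t".join(map(str, g.hap2[i])) + "\n")
    if map_path is not None:
        write_snp_map(g, map_path)


def write_snp_map(g: GenotypeData, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#snp_id\tchrom\tpos_bp\n")
        for s, c, p in zip(g.snp_ids, g.chrom, g.pos_bp):
            fh.write(f"{s}\t{c}\t{p}\n")


def read_snp_map(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    snp_ids, chroms, pos = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise MalformedFileError(f"bad SNP-map line: {line!r}")
            snp_ids.append(parts[0])
            chroms.append(parts[1])
            pos.append(int(parts[2]))
    return (np.array(snp_ids, dtype=object), np.array(chroms, dtype=object),
            np.array(pos, dtype=np.int64))


def read_tabular_genotypes(geno_path: str | Path,
                           map_path: str | Path) -> GenotypeData:
    """Read the tabular haplotype dialect; semantics identical to the VCF reader."""
    with open(geno_path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise MalformedFileError(f"empty genotype file {geno_path}")
    header = lines[0]
    if not header.startswith("#"):
        raise MalformedFileError("missing header line (expected '#id\\thap\\t...')")
    snp_ids = header.lstrip("#").split("\t")[2:]
    body = lines[1:]
    if not body or len(body) % 2 != 0:
        raise MalformedFileError("expected two haplotype rows per individual")

    ids, h1, h2 = [], [], []
    for k in range(0, len(body), 2):
        r1 = body[k].split("\t")
        r2 = body[k + 1].split("\t")
        if r1[0] != r2[0]:
            raise MalformedFileError(
                f"haplotype rows not paired by individual near {r1[0]!r}"
            )
        if (r1[1], r2[1]) != ("1", "2"):
            raise MalformedFileError(f"bad hap labels for individual {r1[0]!r}")
        if len(r1) - 2 != len(snp_ids) or len(r2) - 2 != len(snp_ids):
            raise MalformedFileError(f"wrong column count for individual {r1[0]!r}")
        for tok in r1[2:] + r2[2:]:
            if tok not in ("0", "1"):
                raise ValueError(f"haplotype entry {tok!r} not in {{0,1}}")
        ids.append(r1[0])
        h1.append([int(t) for t in r1[2:]])
        h2.append([int(t) for t in r2[2:]])

    map_ids, chroms, pos = read_snp_map(map_path)
    lookup = {s: j for j, s in enumerate(map_ids)}
    try:
        order = [lookup[s] for s in snp_ids]
    except KeyError as e:
        raise ConsistencyError(f"SNP {e.args[0]!r} absent from map") from e
    # reorder columns so that the map's (chromosome, position) sort applies
    chrom_order = {c: k for k, c in enumerate(dict.fromkeys(chroms))}
    col_sort = sorted(range(len(snp_ids)),
                      key=lambda j: (chrom_order[chroms[order[j]]], pos[order[j]]))
    o = [order[j] for j in col_sort]
    return GenotypeData(
        individual_ids=np.array(ids, dtype=object),
        snp_ids=np.array([snp_ids[j] for j in col_sort], dtype=object),
        chrom=chroms[o],
        pos_bp=pos[o],
        hap1=np.array(h1, dtype=np.int8)[:, col_sort],
        hap2=np.array(h2, dtype=np.int8)[:, col_sort],
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def write_phenotypes(p: PhenotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#id\ty\n")
        for i, v in zip(p.individual_ids, p.y):
            fh.write(f"{i}\t{float(v)!r}\n")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    ids, ys = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise MalformedFileError(f"bad phenotype line: {line!r}")
            ids.append(parts[0])
            ys.append(float(parts[1]))
    if not ids:
        raise MalformedFileError(f"empty phenotype file {path}")
    return PhenotypeTable(np.array(ids, dtype=object), np.array(ys))


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------

def maf_filter(g: GenotypeData, threshold: float) -> tuple[GenotypeData, int]:
    """Retain SNP j iff min(p_j, 1-p_j) >= threshold (boundary inclusive).

    Returns the filtered panel and the number of SNPs removed.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    p = g.allele_freq
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= threshold
    removed = int((~keep).sum())
    if removed == g.m:
        raise EmptyPanelError("MAF filter removed every SNP")
    if removed == 0:
        return g, 0
    return g.subset_snps(keep), removed


# ---------------------------------------------------------------------------
# GRM files
# ---------------------------------------------------------------------------

def write_grm(grm, path: str | Path, format: str = "text") -> None:
    """Write a GRM as text triplets or a GCTA-layout binary pair.

    ``path`` is the file path for text, or the prefix for binary
    (``prefix.grm.bin`` / ``prefix.grm.id`` / ``prefix.grm.json``).
    """
    ids = list(grm.individual_ids)
    vals = np.asarray(grm.values, dtype=np.float64)
    n = len(ids)
    if format == "text":
        with open(path, "w") as fh:
            fh.write(f"#effect\t{grm.effect}\n")
            fh.write(f"#normalization\t{grm.normalization!r}\n")
            fh.write("#ids\t" + "\t".join(map(str, ids)) + "\n")
            for i in range(n):
                for j in range(i + 1):
                    fh.write(f"{ids[i]}\t{ids[j]}\t{float(vals[i, j])!r}\n")
    elif format == "binary":
        prefix = str(path)
        tri = vals[np.tril_indices(n)]
        tri.astype(np.float64).tofile(prefix + ".grm.bin")
        with open(prefix + ".grm.id", "w") as fh:
            for i in ids:
                fh.write(f"{i}\t{i}\n")
        with open(prefix + ".grm.json", "w") as fh:
            json.dump({"effect": grm.effect,
                       "normalization": grm.normalization}, fh)
    else:
        raise ValueError(f"unknown GRM format {format!r}")


def read_grm(path: str | Path, format: str = "text"):
    """Read a GRM written by :func:`write_grm` (or a GCTA float32 binary)."""
    from .grm import GRM  # local import to avoid a cycle

    if format == "text":
        effect, norm, ids = None, 1.0, None
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#effect"):
                    effect = line.split("\t")[1]
                elif line.startswith("#normalization"):
                    norm = float(line.split("\t")[1])
                elif line.startswith("#ids"):
                    ids = line.split("\t")[1:]
                else:
                    i, j, v = line.split("\t")
                    entries.append((i, j, float(v)))
        if ids is None:
            raise MalformedFileError("GRM text file lacks an #ids header")
        index = {i: k for k, i in enumerate(ids)}
        n = len(ids)
        vals = np.zeros((n, n))
        for i, j, v in entries:
            if i not in index or j not in index:
                raise ConsistencyError(f"triplet id {i!r}/{j!r} not in header ids")
            vals[index[i], index[j]] = v
            vals[index[j], index[i]] = v
        return GRM(effect=effect or "A", values=vals, normalization=norm,
                   individual_ids=np.array(ids, dtype=object))

    if format == "binary":
        prefix = str(path)
        with open(prefix + ".grm.id") as fh:
            ids = [ln.split("\t")[0] for ln in fh.read().splitlines() if ln]
        n = len(ids)
        n_elem = n * (n + 1) // 2
        size = Path(prefix + ".grm.bin").stat().st_size
        if size == 8 * n_elem:
            tri = np.fromfile(prefix + ".grm.bin", dtype=np.float64)
        elif size == 4 * n_elem:
            tri = np.fromfile(prefix + ".grm.bin", dtype=np.float32).astype(np.float64)
        else:
            raise ConsistencyError("grm.bin size inconsistent with grm.id")
        vals = np.zeros((n, n))
        vals[np.tril_indices(n)] = tri
        vals = vals + np.tril(vals, -1).T
        meta = {"effect": "A", "normalization": 1.0}
        meta_path = Path(prefix + ".grm.json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
        return GRM(effect=meta["effect"], values=vals,
                   normalization=meta["normalization"],
                   individual_ids=np.array(ids, dtype=object))

    raise ValueError(f"unknown GRM format {format!r}")
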