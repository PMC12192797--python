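"""Genotype/phenotype/GRM file I/O and the MAF filter."""

import numpy as np
import pytest

import epiblup as eb
from epiblup.errors import (DuplicateSiteError, EmptyPanelError,
                            MalformedFileError, MissingGenotypeError,
                            PhaseRequiredError, UnsupportedRecordError)

from conftest import panel_from_x, random_panel

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##contig=<ID=chr2>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf(path, records, samples=("s1", "s2")):
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(samples="\t".join(samples)))
        for rec in records:
            fh.write(rec + "\n")


class TestVCFReader:
    def test_alt_dosage_and_frequency(self, tmp_path):
        """GTs 0|1 and 1|1 give x = [1, 2] and ALT frequency 0.75."""
        vcf = tmp_path / "a.vcf"
        write_vcf(vcf, ["chr1\t100\tsnp1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1"])
        g = eb.read_phased_vcf(vcf)
        assert g.x.tolist() == [[1.0], [2.0]]
        assert g.allele_freq[0] == pytest.approx(0.75)
        assert g.hap1.ravel().tolist() == [0, 1]
        assert g.hap2.ravel().tolist() == [1, 1]

    def test_unphased_rejected(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        write_vcf(vcf, ["chr1\t100\tsnp1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1|1"])
        with pytest.raises(PhaseRequiredError):
            eb.read_phased_vcf(vcf, require_phase=True)

    def test_unphased_allowed_when_not_required(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        write_vcf(vcf, ["chr1\t100\tsnp1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1|1"])
        g = eb.read_phased_vcf(vcf, require_phase=False)
        assert g.x.tolist() == [[1.0], [2.0]]

    def test_multiallelic_rejected(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        write_vcf(vcf, ["chr1\t100\tsnp1\tA\tG,T\t.\tPASS\t.\tGT\t0|1\t1|1"])
        with pytest.raises(UnsupportedRecordError):
            eb.read_phased_vcf(vcf)

    def test_duplicate_site_rejected(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        write_vcf(vcf, ["chr1\t100\tsnp1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1",
                        "chr1\t100\tsnp2\tA\tC\t.\tPASS\t.\tGT\t0|0\t0|1"])
        with pytest.raises(DuplicateSiteError):
            eb.read_phased_vcf(vcf)

    def test_missing_gt_rejected(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        write_vcf(vcf, ["chr1\t100\tsnp1\tA\tG\t.\tPASS\t.\tGT\t.|.\t1|1"])
        with pytest.raises(MissingGenotypeError):
            eb.read_phased_vcf(vcf)

    def test_records_sorted_by_chrom_and_position(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        write_vcf(vcf, ["chr1\t500\tsnpB\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1",
                        "chr1\t100\tsnpA\tA\tG\t.\tPASS\t.\tGT\t0|0\t0|1",
                        "chr2\t50\tsnpC\tA\tG\t.\tPASS\t.\tGT\t1|1\t0|0"])
        g = eb.read_phased_vcf(vcf)
        assert list(g.snp_ids) == ["snpA", "snpB", "snpC"]
        assert list(g.pos_bp) == [100, 500, 50]

    def test_vcf_and_tabular_agree(self, tmp_path, rng):
        """Equivalent content through both readers yields identical panels."""
        g = random_panel(rng, n=4, m=6, n_chrom=2)
        records = []
        for j in range(g.m):
            gts = "\t".join(f"{g.hap1[i, j]}|{g.hap2[i, j]}" for i in range(g.n))
            records.append(f"{g.chrom[j]}\t{g.pos_bp[j]}\t{g.snp_ids[j]}"
                           f"\tA\tG\t.\tPASS\t.\tGT\t{gts}")
        vcf = tmp_path / "a.vcf"
        write_vcf(vcf, records, samples=tuple(g.individual_ids))
        gv = eb.read_phased_vcf(vcf)
        eb.write_tabular_genotypes(g, tmp_path / "g.tsv", tmp_path / "map.tsv")
        gt = eb.read_tabular_genotypes(tmp_path / "g.tsv", tmp_path / "map.tsv")
        for a, b in ((gv, gt),):
            assert np.array_equal(a.hap1, b.hap1)
            assert np.array_equal(a.hap2, b.hap2)
            assert list(a.snp_ids) == list(b.snp_ids)


class TestTabular:
    def test_single_individual(self, tmp_path):
        (tmp_path / "g.tsv").write_text(
            "#id\thap\ts0\ts1\n" "a\t1\t0\t1\n" "a\t2\t1\t1\n")
        (tmp_path / "map.tsv").write_text(
            "#snp_id\tchrom\tpos_bp\ns0\tchr1\t100\ns1\tchr1\t200\n")
        g = eb.read_tabular_genotypes(tmp_path / "g.tsv", tmp_path / "map.tsv")
        assert g.x.tolist() == [[1.0, 2.0]]

    def test_empty_file(self, tmp_path):
        (tmp_path / "g.tsv").write_text("")
        (tmp_path / "map.tsv").write_text("#snp_id\tchrom\tpos_bp\n")
        with pytest.raises(MalformedFileError):
            eb.read_tabular_genotypes(tmp_path / "g.tsv", tmp_path / "map.tsv")

    def test_odd_haplotype_rows(self, tmp_path):
        (tmp_path / "g.tsv").write_text(
            "#id\thap\ts0\n" "a\t1\t0\n" "a\t2\t1\n" "b\t1\t0\n")
        (tmp_path / "map.tsv").write_text("#snp_id\tchrom\tpos_bp\ns0\tchr1\t1\n")
        with pytest.raises(MalformedFileError):
            eb.read_tabular_genotypes(tmp_path / "g.tsv", tmp_path / "map.tsv")

    def test_bad_allele_value(self, tmp_path):
        (tmp_path / "g.tsv").write_text(
            "#id\thap\ts0\n" "a\t1\t2\n" "a\t2\t1\n")
        (tmp_path / "map.tsv").write_text("#snp_id\tchrom\tpos_bp\ns0\tchr1\t1\n")
        with pytest.raises(ValueError):
            eb.read_tabular_genotypes(tmp_path / "g.tsv", tmp_path / "map.tsv")

    def test_round_trip(self, tmp_path, rng):
        g = random_panel(rng, n=10, m=20, n_chrom=2)
        eb.write_tabular_genotypes(g, tmp_path / "g.tsv", tmp_path / "map.tsv")
        g2 = eb.read_tabular_genotypes(tmp_path / "g.tsv", tmp_path / "map.tsv")
        assert np.array_equal(g.hap1, g2.hap1)
        assert np.array_equal(g.hap2, g2.hap2)
        assert np.array_equal(g.x, g2.x)
        assert list(g.individual_ids) == list(g2.individual_ids)

    def test_phenotype_round_trip(self, tmp_path, rng):
        p = eb.PhenotypeTable(np.array(["a", "b"], dtype=object),
                              np.array([0.123456789012345, -2.5]))
        eb.write_phenotypes(p, tmp_path / "y.tsv")
        p2 = eb.read_phenotypes(tmp_path / "y.tsv")
        assert np.array_equal(p.y, p2.y)
        assert p2.aligned_to(["b", "a"]).tolist() == [-2.5, 0.123456789012345]


class TestMAFFilter:
    def make_panel_with_freqs(self, freqs, n=100):
        """Panel whose column frequencies are exactly ``freqs`` (over 2n alleles)."""
        n_alt = [int(round(2 * n * f)) for f in freqs]
        hap = np.zeros((2 * n, len(freqs)), dtype=np.int8)
        for j, k in enumerate(n_alt):
            hap[:k, j] = 1
        return panel_from_x(hap[:n] + hap[n:])

    def test_boundary_inclusive(self):
        g = self.make_panel_with_freqs([0.01, 0.05, 0.30, 0.99])
        kept, removed = eb.maf_filter(g, 0.05)
        assert list(kept.snp_ids) == ["s1", "s2"]
        assert removed == 2

    def test_threshold_zero_identity(self, rng):
        g = random_panel(rng, n=20, m=10)
        kept, removed = eb.maf_filter(g, 0.0)
        assert removed == 0 and kept.m == 10

    def test_threshold_half(self):
        g = self.make_panel_with_freqs([0.5, 0.49])
        kept, removed = eb.maf_filter(g, 0.5)
        assert list(kept.snp_ids) == ["s0"] and removed == 1

    def test_all_removed(self):
        g = self.make_panel_with_freqs([0.01, 0.02])
        with pytest.raises(EmptyPanelError):
            eb.maf_filter(g, 0.05)

    def test_idempotent(self, rng):
        g = random_panel(rng, n=50, m=30)
        once, r1 = eb.maf_filter(g, 0.1)
        twice, r2 = eb.maf_filter(once, 0.1)
        assert r2 == 0
        assert np.array_equal(once.x, twice.x)

    def test_frequency_invariant(self, rng):
        g = random_panel(rng, n=30, m=15)
        assert np.allclose(g.x.mean(axis=0), 2 * g.allele_freq)
        assert np.all((g.allele_freq >= 0) & (g.allele_freq <= 1))


class TestGRMFiles:
    def test_text_triplets_identity(self, tmp_path):
        grm = eb.GRM("A", np.eye(2), 1.0, np.array(["1", "2"], dtype=object))
        eb.write_grm(grm, tmp_path / "g.grm.txt", format="text")
        lines = [ln for ln in (tmp_path / "g.grm.txt").read_text().splitlines()
                 if not ln.startswith("#")]
        assert lines == ["1\t1\t1.0", "2\t1\t0.0", "2\t2\t1.0"]

    @pytest.mark.parametrize("fmt", ["text", "binary"])
    def test_round_trip_exact(self, tmp_path, rng, fmt):
        a = rng.standard_normal((5, 8))
        vals = a @ a.T
        grm = eb.GRM("AA", vals, 3.7, np.array([f"c{i}" for i in range(5)],
                                               dtype=object))
        path = tmp_path / ("g.grm.txt" if fmt == "text" else "g")
        eb.write_grm(grm, path, format=fmt)
        back = eb.read_grm(path, format=fmt)
        assert np.allclose(back.values, vals, atol=1e-12, rtol=0)
        assert back.effect == "AA"
        assert back.normalization == pytest.approx(3.7)
        assert list(back.individual_ids) == list(grm.individual_ids)

    def test_binary_equals_text(self, tmp_path, rng):
        a = rng.standard_normal((4, 4))
        grm = eb.GRM("D", a @ a.T, 1.0,
                     np.array(["w", "x", "y", "z"], dtype=object))
        eb.write_grm(grm, tmp_path / "t.txt", format="text")
        eb.write_grm(grm, tmp_path / "b", format="binary")
        t = eb.read_grm(tmp_path / "t.txt", format="text")
        b = eb.read_grm(tmp_path / "b", format="binary")
        assert np.array_equal(t.values, b.values)

    def test_gcta_float32_accepted(self, tmp_path, rng):
        """A true single-precision GCTA grm.bin still reads (to float32 accuracy)."""
        a = rng.standard_normal((3, 3))
        vals = (a @ a.T).astype(np.float64)
        tri = vals[np.tril_indices(3)].astype(np.float32)
        tri.tofile(tmp_path / "g.grm.bin")
        (tmp_path / "g.grm.id").write_text("a\ta\nb\tb\nc\tc\n")
        back = eb.read_grm(tmp_path / "g", format="binary")
        assert np.allclose(back.values, vals, atol=1e-6)
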