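"""VCF reading, filtering, dosage recoding, sharing and annotation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonalpop import synthdata as sd
from clonalpop import variants as va
from conftest import truth_site_index

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=contig_1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


def write_vcf(tmp_path, body, name="t.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


class TestReadVcf:
    def test_empty_body(self, tmp_path):
        assert va.read_vcf(write_vcf(tmp_path, "")) == []

    def test_round_trip_site_count(self, small_world, clean_vcf):
        ref, truth, _ = small_world
        sites = va.read_vcf(clean_vcf)
        expected = int(((truth.dosage > 0).any(axis=0) | ref.het_mask).sum())
        assert len(sites) == expected

    def test_indel_flagged_not_snv(self, tmp_path):
        body = "contig_1\t100\t.\tA\tAT\t50\tPASS\t.\tGT:DP:AD\t0/0/1:30:20,10\n"
        (site,) = va.read_vcf(write_vcf(tmp_path, body))
        assert not site.is_snv

    def test_multiallelic_split(self, tmp_path):
        body = "contig_1\t100\t.\tA\tC,G\t50\tPASS\t.\tGT:DP:AD\t0/1/2:30:10,12,8\n"
        sites = va.read_vcf(write_vcf(tmp_path, body))
        assert len(sites) == 2
        by_alt = {s.alt_allele: s for s in sites}
        assert by_alt["C"].calls["S1"].dosage == 1
        assert by_alt["G"].calls["S1"].dosage == 1
        assert by_alt["C"].calls["S1"].alt_reads == 12
        assert by_alt["G"].calls["S1"].alt_reads == 8

    def test_missing_genotype_coded(self, tmp_path):
        body = "contig_1\t100\t.\tA\tC\t50\tPASS\t.\tGT:DP:AD\t././.:30:20,10\n"
        (site,) = va.read_vcf(write_vcf(tmp_path, body))
        assert site.calls["S1"].dosage == va.MISSING

    def test_wrong_ploidy_rejected(self, tmp_path):
        body = "contig_1\t100\t.\tA\tC\t50\tPASS\t.\tGT:DP:AD\t0/1:30:20,10\n"
        with pytest.raises(va.PloidyError):
            va.read_vcf(write_vcf(tmp_path, body))


def make_site(quality=50.0, depth=30, dosage=1, contig="contig_1", pos=100):
    return va.VariantSite(
        contig=contig, position=pos, ref_allele="A", alt_allele="C",
        quality=quality,
        calls={"S1": va.GenotypeCall(dosage=dosage, depth=depth, alt_reads=depth // 3)},
    )


class TestFilters:
    CFG = va.FilterConfig()

    def test_low_quality_removed(self):
        assert va.apply_filters([make_site(quality=25.0)], self.CFG) == []

    def test_extreme_depths_removed(self):
        assert va.apply_filters([make_site(depth=250)], self.CFG) == []
        assert va.apply_filters([make_site(depth=15)], self.CFG) == []
        kept = va.apply_filters([make_site(depth=20), make_site(depth=200, pos=200)], self.CFG)
        assert len(kept) == 2

    def test_reference_het_site_removed(self):
        ref = sd.generate_reference_profile(10, 0.0, seed=0)
        ref.dosage[0] = 1  # position 1 heterozygous in the reference
        site_het = make_site(pos=1)
        site_hom = make_site(pos=101)
        kept = va.apply_filters([site_het, site_hom], self.CFG, ref=ref)
        assert [s.position for s in kept] == [101]

    def test_uncovered_reference_site_removed(self):
        ref = sd.generate_reference_profile(10, 0.0, seed=0)
        kept = va.apply_filters([make_site(pos=99_999)], self.CFG, ref=ref)
        assert kept == []

    def test_idempotent(self, small_world, clean_vcf):
        ref, _, _ = small_world
        sites = va.read_vcf(clean_vcf)
        once = va.apply_filters(sites, self.CFG, ref=ref)
        twice = va.apply_filters(once, self.CFG, ref=ref)
        assert once == twice


class TestRecode:
    def test_bijection_over_triploid_genotypes(self, tmp_path):
        rows = []
        for pos, gt in ((10, "0/0/0"), (20, "0/0/1"), (30, "0/1/1"), (40, "1/1/1")):
            rows.append(
                f"contig_1\t{pos}\t.\tA\tC\t50\tPASS\t.\tGT:DP:AD\t{gt}:30:20,10\n"
            )
        path = tmp_path / "gt.vcf"
        path.write_text(VCF_HEADER + "".join(rows))
        matrix = va.recode_dosage(va.read_vcf(path))
        assert matrix.dosage.tolist() == [[0, 1, 2, 3]]

    def test_truth_round_trip_exact(self, small_world, clean_vcf):
        """Error-free saturating-depth VCF reproduces the truth matrix."""
        ref, truth, _ = small_world
        sites = va.read_vcf(clean_vcf)
        filtered = va.apply_filters(sites, va.FilterConfig(), ref=ref)
        matrix = va.recode_dosage(filtered, groups=truth.groups)
        index = truth_site_index(truth)
        cols = [index[(str(c), int(p))] for c, p in zip(matrix.contigs, matrix.positions)]
        rows = [truth.sample_ids.index(s) for s in matrix.sample_ids]
        assert np.array_equal(truth.dosage[np.ix_(rows, cols)], matrix.dosage)
        # every ref-homozygous variant site survives the filters
        hom_variant = int(((truth.dosage > 0).any(axis=0) & ~ref.het_mask).sum())
        assert matrix.n_sites == hom_variant


class TestSharing:
    def matrix(self, dosage, groups=None):
        dosage = np.asarray(dosage)
        return va.GenotypeMatrix(
            sample_ids=[f"S{i}" for i in range(dosage.shape[0])],
            contigs=np.array(["c1"] * dosage.shape[1]),
            positions=np.arange(1, dosage.shape[1] + 1),
            dosage=dosage,
            groups=groups or {},
        )

    def test_fixed_site_is_not_unique(self):
        m = self.matrix([[1, 0], [1, 0], [1, 1]])
        s = va.polymorphic_partition(m)
        assert s.fixed_sites == 1
        assert s.per_sample_unique == {"S0": 0, "S1": 0, "S2": 1}

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_partition_identity(self, seed):
        rng = np.random.default_rng(seed)
        dosage = rng.integers(0, 4, size=(4, 30))
        s = va.polymorphic_partition(self.matrix(dosage))
        assert sum(s.shared_by_k.values()) == s.total_polymorphic

    def test_venn_counts_match_truth(self, small_world, small_spec):
        # restrict to reference-homozygous sites, as the filter stage does
        ref, truth, _ = small_world
        hom = ~ref.het_mask
        sub = va.GenotypeMatrix(
            sample_ids=truth.sample_ids,
            contigs=truth.contigs[hom],
            positions=truth.positions[hom],
            dosage=truth.dosage[:, hom],
            groups=truth.groups,
        )
        s = va.polymorphic_partition(sub, groups=truth.groups)
        v = s.venn
        # sites shared within one population only = its private SNVs
        assert v["A_only"] == small_spec.private_snvs_per_population
        assert v["B_only"] == small_spec.private_snvs_per_population
        assert v["both"] == small_spec.shared_snvs_all
        # inclusion-exclusion: |A| + |B| - |both| = |A union B|
        assert v["shared_within_A"] + v["shared_within_B"] - v["both"] == (
            v["A_only"] + v["B_only"] + v["both"]
        )

    def test_unknown_group_sample_rejected(self):
        m = self.matrix([[1, 0], [0, 1]])
        with pytest.raises(KeyError):
            va.polymorphic_partition(m, groups={"ghost": "A", "S0": "B"})


class TestAnnotation:
    def sites(self, positions, ref="G", alt="A"):
        return [
            va.VariantSite(
                contig="contig_1", position=p, ref_allele=ref, alt_allele=alt,
                quality=50.0,
                calls={"S1": va.GenotypeCall(dosage=1, depth=30, alt_reads=10)},
            )
            for p in positions
        ]

    def test_cds_is_coding_and_intron_detected(self, tmp_path):
        gff = tmp_path / "toy.gff3"
        sd.write_toy_gff(
            gff,
            [{"contig": "contig_1", "start": 100, "end": 500,
              "exons": [(100, 200), (400, 500)], "cds": [(150, 200)]}],
        )
        summary = va.annotate_snvs(
            self.sites([160, 110, 300, 900]), gff
        )
        assert summary.class_counts == {
            "coding": 1, "exon_noncoding": 1, "intronic": 1, "intergenic": 1
        }

    def test_spectrum_transitions_vs_transversions(self, tmp_path):
        gff = tmp_path / "empty.gff3"
        sd.write_toy_gff(gff, [])
        sites = (
            self.sites([10, 20], ref="G", alt="A")
            + self.sites([30], ref="C", alt="T")
            + self.sites([40], ref="A", alt="C")
        )
        with pytest.warns(UserWarning):
            summary = va.annotate_snvs(sites, gff)
        assert summary.transitions == 3
        assert summary.transversions == 1
        assert summary.spectrum["G>A"] == 2

    def test_uniform_snvs_intergenic_fraction(self, tmp_path):
        # one gene covering 10% of the coordinate span -> ~90% intergenic
        gff = tmp_path / "g.gff3"
        sd.write_toy_gff(
            gff, [{"contig": "contig_1", "start": 1, "end": 1000,
                   "exons": [(1, 1000)], "cds": [(1, 1000)]}]
        )
        positions = list(range(1, 10_001, 10))  # uniform over 1..10000
        summary = va.annotate_snvs(self.sites(positions), gff)
        frac = summary.class_fractions()["intergenic"]
        assert frac == pytest.approx(0.9, abs=0.02)
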