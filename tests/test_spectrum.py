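"""Mutation classes, CpG islands, annotation, sharing, phasing, statistics."""

from __future__ import annotations

import itertools
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from dnmkit.io import GeneModel, Genome
from dnmkit.pedigree import Member, Pedigree, Trio
from dnmkit.sites import GT, Genotype, SiteRecord, SiteTable
from dnmkit.spectrum import (
    COLLAPSED_CLASSES,
    AnnotationError,
    CpgIsland,
    annotate_region,
    classify_cgi,
    classify_mutation,
    cpg_island_test,
    cpg_site_mask,
    detect_shared,
    islands_to_intervals,
    phase_parent_of_origin,
    alpha,
    predict_cgi,
    pooled_region_rate,
    region_rate,
    sw_rate_tests,
    ts_tv_test,
)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class TestClassify:
    def test_cpg_c_to_t(self):
        mc = classify_mutation("C", "T", prev_base="A", next_base="G")
        assert mc.collapsed_class == "C:G>T:A"
        assert mc.is_transition and mc.sw_category == "S>W"
        assert mc.cpg_context == "CpG" and mc.is_cpg_to_tpg

    def test_reverse_strand_equivalent(self):
        plus = classify_mutation("C", "T", prev_base="A", next_base="G")
        minus = classify_mutation("G", "A", prev_base="C", next_base="T")
        assert minus.collapsed_class == plus.collapsed_class
        assert minus.is_cpg_to_tpg and minus.cpg_context == "CpG"

    def test_enumeration_of_all_twelve_substitutions(self):
        classes = {}
        for ref, alt in itertools.permutations("ACGT", 2):
            classes.setdefault(classify_mutation(ref, alt).collapsed_class, []).append((ref, alt))
        assert set(classes) == set(COLLAPSED_CLASSES)
        assert all(len(v) == 2 for v in classes.values())
        ts = [c for c in classes if classify_mutation(*classes[c][0]).is_transition]
        assert sorted(ts) == ["A:T>G:C", "C:G>T:A"]

    def test_sw_mapping(self):
        assert classify_mutation("C", "G").sw_category == "S>S"
        assert classify_mutation("C", "A").sw_category == "S>W"
        assert classify_mutation("A", "G").sw_category == "W>S"
        assert classify_mutation("A", "T").sw_category == "W>W"

    def test_contig_edge_counts_as_non_cpg(self):
        mc = classify_mutation("G", "A", prev_base=None, next_base="T")
        assert mc.cpg_context == "nonCpG" and not mc.is_cpg_to_tpg

    @given(
        ref=st.sampled_from("ACGT"),
        alt=st.sampled_from("ACGT"),
        prev=st.sampled_from("ACGT"),
        nxt=st.sampled_from("ACGT"),
    )
    @settings(derandomize=True, max_examples=100)
    def test_reverse_complement_invariance(self, ref, alt, prev, nxt):
        if ref == alt:
            return
        a = classify_mutation(ref, alt, prev, nxt)
        b = classify_mutation(COMP[ref], COMP[alt], COMP[nxt], COMP[prev])
        assert a.collapsed_class == b.collapsed_class
        assert a.sw_category == b.sw_category
        assert a.cpg_context == b.cpg_context and a.is_cpg_to_tpg == b.is_cpg_to_tpg


class TestCgi:
    def test_cg_repeat_is_one_island(self):
        seq = "CG" * 150
        islands = predict_cgi(seq, chrom="chr1")
        assert len(islands) == 1
        isl = islands[0]
        assert (isl.start, isl.end) == (0, 300)
        assert isl.gc_fraction == 1.0
        assert isl.obs_exp_cpg == pytest.approx(2.0, rel=1e-2)

    def test_at_only_sequence_empty(self):
        assert predict_cgi("AT" * 200) == []

    def test_criteria_on_output(self):
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=3000))
        island = "".join(rng.choice(list("ACGT"), p=[0.17, 0.33, 0.33, 0.17], size=600))
        islands = predict_cgi(base + island + base)
        for isl in islands:
            assert isl.length >= 200
            assert isl.gc_fraction >= 0.5
            assert isl.obs_exp_cpg >= 0.6

    def test_simulated_truth_recovered(self, small_dataset):
        """Predicted islands overlap the planted ones (Jaccard >= 0.9)."""
        ds = small_dataset
        pred = islands_to_intervals(predict_cgi(ds.genome))
        truth = ds.cgi
        inter = pred.intersect(truth).total_length()
        union = pred.total_length() + truth.total_length() - inter
        assert union > 0
        assert inter / union >= 0.9

    def test_idempotent_on_island_sequence(self):
        rng = np.random.default_rng(17)
        seq = "".join(rng.choice(list("ACGT"), p=[0.17, 0.33, 0.33, 0.17], size=800))
        first = predict_cgi(seq, chrom="x")
        assert len(first) == 1
        sub = seq[first[0].start : first[0].end]
        again = predict_cgi(sub, chrom="x")
        assert len(again) == 1
        assert (again[0].start, again[0].end) == (0, first[0].length)


class TestClassifyCgi:
    GENES = [
        GeneModel("g1", "chr1", 1000, 2000, "+", exons=[(1000, 2000)]),
        GeneModel("g2", "chr1", 5000, 6000, "-", exons=[(5000, 6000)]),
    ]

    def _cls(self, start, end):
        isl = CpgIsland("chr1", start, end, 0.6, 0.8)
        classify_cgi([isl], self.GENES)
        return isl.cgi_class

    def test_priority_tss_over_gene_body(self):
        assert self._cls(900, 1200) == "TSS"

    def test_minus_strand_tss_at_feature_end(self):
        assert self._cls(5900, 6100) == "TSS"
        assert self._cls(4900, 5100) == "TTS"

    def test_tts(self):
        assert self._cls(1900, 2100) == "TTS"

    def test_intragenic_and_intergenic(self):
        assert self._cls(1200, 1500) == "intragenic"
        assert self._cls(3000, 3400) == "intergenic"

    def test_brute_force_interval_oracle(self, rng):
        for _ in range(100):
            s = int(rng.integers(0, 7000))
            e = s + int(rng.integers(200, 1500))
            got = self._cls(s, e)
            tss = any(s <= g.tss < e for g in self.GENES)
            tts = any(s <= g.tts < e for g in self.GENES)
            body = any(g.start < e and s < g.end for g in self.GENES)
            expected = "TSS" if tss else "TTS" if tts else "intragenic" if body else "intergenic"
            assert got == expected


class TestRegionRate:
    def test_zero_mutations(self):
        assert region_rate(0, 1e7, 106) == 0.0

    def test_pooled_equals_mean_parameterization(self):
        assert pooled_region_rate(16, 11_890_473 * 106) == pytest.approx(
            region_rate(16, 11_890_473, 106)
        )

    def test_domain(self):
        with pytest.raises(ValueError):
            region_rate(1, 0, 106)


def _gene_with_cds(genome_seq, strand="+"):
    """Single-exon gene covering the whole sequence, CDS = positions 0..len."""
    n = len(genome_seq)
    return GeneModel("g", "chr1", 0, n, strand, exons=[(0, n)], cds=[(0, n, 0)])


class TestAnnotateRegion:
    def test_synonymous_third_position(self):
        # CTG -> CTA is Leu -> Leu
        genome = Genome({"chr1": "ATGCTGTAA"})
        gene = _gene_with_cds("ATGCTGTAA")
        ann = annotate_region(SimpleNamespace(chrom="chr1", pos=5, ref="G", alt="A"), [gene], genome)
        assert ann.region == "exon_CDS" and ann.effect == "synonymous"

    def test_nonsynonymous_first_position(self):
        # internal ATG -> TTG is Met -> Leu
        genome = Genome({"chr1": "ATGATGTAA"})
        gene = _gene_with_cds("ATGATGTAA")
        ann = annotate_region(SimpleNamespace(chrom="chr1", pos=3, ref="A", alt="T"), [gene], genome)
        assert ann.region == "exon_CDS" and ann.effect == "nonsynonymous"

    def test_intron_and_splice_window(self):
        seq = "ATGAAA" + "G" * 50 + "TTTTAA"
        genome = Genome({"chr1": seq})
        gene = GeneModel(
            "g", "chr1", 0, len(seq), "+",
            exons=[(0, 6), (56, 62)],
            cds=[(0, 6, 0), (56, 62, 0)],
        )
        splice = annotate_region(SimpleNamespace(chrom="chr1", pos=7, ref="G", alt="A"), [gene], genome)
        assert splice.region == "intron" and splice.effect == "splice"
        deep = annotate_region(SimpleNamespace(chrom="chr1", pos=30, ref="G", alt="A"), [gene], genome)
        assert deep.region == "intron" and deep.effect is None

    def test_utr_and_intergenic(self):
        seq = "A" * 100
        genome = Genome({"chr1": seq})
        gene = GeneModel("g", "chr1", 10, 40, "+", exons=[(10, 40)], cds=[(20, 35, 0)])
        utr = annotate_region(SimpleNamespace(chrom="chr1", pos=12, ref="A", alt="G"), [gene], genome)
        assert utr.region == "UTR"
        inter = annotate_region(SimpleNamespace(chrom="chr1", pos=80, ref="A", alt="G"), [gene], genome)
        assert inter.region == "intergenic"

    def test_reference_mismatch_raises(self):
        genome = Genome({"chr1": "ATGCTGTAA"})
        gene = _gene_with_cds("ATGCTGTAA")
        with pytest.raises(AnnotationError, match="mismatch"):
            annotate_region(SimpleNamespace(chrom="chr1", pos=5, ref="T", alt="A"), [gene], genome)

    def test_random_cds_mutations_vs_translation_oracle(self, rng):
        """Strand-aware effect labels equal brute-force translate-and-compare."""
        codons = [
            a + b + c
            for a in "ACGT" for b in "ACGT" for c in "ACGT"
            if a + b + c not in ("TAA", "TAG", "TGA")
        ]
        cds = "ATG" + "".join(rng.choice(codons, size=40)) + "TAA"
        for strand in "+-":
            seq = cds if strand == "+" else str(Seq(cds).reverse_complement())
            genome = Genome({"chr1": seq})
            gene = _gene_with_cds(seq, strand)
            for _ in range(60):
                pos = int(rng.integers(0, len(seq)))
                ref = seq[pos]
                alt = rng.choice([b for b in "ACGT" if b != ref])
                ann = annotate_region(
                    SimpleNamespace(chrom="chr1", pos=pos, ref=ref, alt=alt), [gene], genome
                )
                mutated = seq[:pos] + alt + seq[pos + 1 :]
                tx = mutated if strand == "+" else str(Seq(mutated).reverse_complement())
                expected = (
                    "synonymous"
                    if Seq(tx).translate() == Seq(cds).translate()
                    else "nonsynonymous"
                )
                assert ann.effect == expected


def _sib_pedigree():
    return Pedigree(
        [
            Member("d", "f", 1, None, None, "F0"),
            Member("m", "f", 2, None, None, "F0"),
            *[Member(f"k{i}", "f", 1, "d", "m", "F1") for i in range(1, 5)],
        ]
    )


def _cand(offspring, pos, alt="G"):
    return SimpleNamespace(offspring=offspring, chrom="chr1", pos=pos, ref="A", alt=alt)


class TestDetectShared:
    def test_planted_groups_recovered(self, small_dataset):
        ds = small_dataset
        truth_groups = (
            ds.truth.dnms.dropna(subset=["mosaic_group"])
            .groupby("mosaic_group")
            .apply(lambda g: (g.iloc[0]["chrom"], int(g.iloc[0]["pos"]), tuple(sorted(g["offspring"]))),
                   include_groups=False)
        )
        cands = [
            SimpleNamespace(offspring=r.offspring, chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt)
            for r in ds.truth.dnms.itertuples()
        ]
        res = detect_shared(cands, ds.pedigree)
        got = {(k[0], k[1], tuple(sorted(c))) for k, c in res.groups}
        expected = {(c, p, carriers) for c, p, carriers in truth_groups}
        assert got == expected

    def test_no_sharing(self):
        res = detect_shared([_cand("k1", 10), _cand("k2", 20)], _sib_pedigree())
        assert res.n_shared == 0 and res.shared_fraction == 0.0

    def test_fraction_counts_groups_once(self):
        cands = [_cand("k1", 10), _cand("k2", 10), _cand("k3", 10), _cand("k1", 50)]
        res = detect_shared(cands, _sib_pedigree())
        assert res.n_unique == 2 and res.n_shared == 1
        assert res.shared_fraction == pytest.approx(0.5)


class TestPhasing:
    TRIO = Trio("d", "m", "k", "f")

    def _table(self):
        # flank site where dad is 1/1, mum 0/0: kid's alt allele is paternal
        calls = {
            "d": Genotype(GT.HOM_ALT, (0, 50), 50, 99),
            "m": Genotype(GT.HOM_REF, (50, 0), 50, 99),
            "k": Genotype(GT.HET, (25, 25), 50, 99),
        }
        rec = SiteRecord("chr1", 120, "T", ["C"], {}, calls)
        return SiteTable.from_records([rec])

    def _reads(self, rows):
        return pd.DataFrame(rows, columns=["read_id", "sample", "chrom", "pos", "allele"])

    def test_paternal_assignment(self):
        dnm = SimpleNamespace(chrom="chr1", pos=100, ref="A", alt="G", de_novo_allele="G")
        reads = self._reads(
            [("r1", "k", "chr1", 100, "G"), ("r1", "k", "chr1", 120, "C"),
             ("r2", "k", "chr1", 100, "G"), ("r2", "k", "chr1", 120, "C")]
        )
        res = phase_parent_of_origin(dnm, reads, self._table(), self.TRIO)
        assert res.origin == "paternal" and res.supporting_reads == 2

    def test_maternal_assignment_via_ref_allele(self):
        dnm = SimpleNamespace(chrom="chr1", pos=100, ref="A", alt="G", de_novo_allele="G")
        reads = self._reads(
            [("r1", "k", "chr1", 100, "G"), ("r1", "k", "chr1", 120, "T")]
        )
        res = phase_parent_of_origin(dnm, reads, self._table(), self.TRIO)
        assert res.origin == "maternal"

    def test_conflicting_reads_unknown(self):
        dnm = SimpleNamespace(chrom="chr1", pos=100, ref="A", alt="G", de_novo_allele="G")
        reads = self._reads(
            [("r1", "k", "chr1", 100, "G"), ("r1", "k", "chr1", 120, "C"),
             ("r2", "k", "chr1", 100, "G"), ("r2", "k", "chr1", 120, "T")]
        )
        res = phase_parent_of_origin(dnm, reads, self._table(), self.TRIO)
        assert res.origin == "unknown"

    def test_no_informative_reads_unknown(self):
        dnm = SimpleNamespace(chrom="chr1", pos=100, ref="A", alt="G", de_novo_allele="G")
        res = phase_parent_of_origin(dnm, self._reads([]), self._table(), self.TRIO)
        assert res.origin == "unknown" and res.supporting_reads == 0

    def test_alpha(self):
        results = [
            SimpleNamespace(origin="paternal")] * 3 + [SimpleNamespace(origin="maternal")] * 2
        assert alpha(results) == pytest.approx(1.5)


class TestSpectrumStats:
    def test_ts_tv_chi_square_against_one_to_two_null(self):
        ratio, chi2, p = ts_tv_test(170, 138)
        assert ratio == pytest.approx(1.23, abs=0.005)
        # hand-computed: (170-102.667)^2/102.667 + (138-205.333)^2/205.333
        assert chi2 == pytest.approx(66.24, abs=0.01)
        assert p < 1e-10

    def test_equal_to_expectation_zero(self):
        _, chi2, p = ts_tv_test(100, 200)
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_wilcoxon_identical_vectors_p_one(self):
        res = sw_rate_tests({"S>W": [1.0, 1.0, 1.0], "W>S": [1.0, 1.0, 1.0]})
        assert res["pairwise"][("S>W", "W>S")][1] == pytest.approx(1.0)

    def test_kruskal_detects_elevated_category(self, rng):
        rates = {
            "S>W": rng.normal(3.0, 0.3, 50),
            "S>S": rng.normal(1.0, 0.3, 50),
            "W>S": rng.normal(1.0, 0.3, 50),
            "W>W": rng.normal(1.0, 0.3, 50),
        }
        res = sw_rate_tests(rates)
        assert res["kruskal"][1] < 1e-6
        assert res["pairwise"][("S>S", "S>W")][1] < 1e-6

    def test_cpg_island_test_proportional_expectation(self):
        chi2, p = cpg_island_test(16, 50, 11_890_473, 12_766_207)
        from scipy import stats as ss

        frac = 11_890_473 / (11_890_473 + 12_766_207)
        ref = ss.chisquare([16, 50], [66 * frac, 66 * (1 - frac)])
        assert chi2 == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))


class TestCpgMask:
    def test_mask_marks_both_bases(self):
        mask = cpg_site_mask("ACGT")
        assert list(mask) == [False, True, True, False]
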