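"""DNM screening cascade: scan, filters, cohort rules, curation."""

from __future__ import annotations

import itertools

import pytest

from dnmkit.intervals import IntervalSet
from dnmkit.pedigree import Member, Pedigree, Trio
from dnmkit.screen import (
    FilterThresholds,
    DnmCandidate,
    HOMALT_PARENTS,
    HOMREF_PARENTS,
    apply_individual_filters,
    apply_site_filters,
    automated_curation,
    filter_recurrent_and_clustered,
    scan_mendelian_violations,
)
from dnmkit.sites import GT, Genotype, SiteRecord, SiteTable

T = FilterThresholds()
TRIO = Trio("dad", "mum", "kid", "fam1")


def _site(pos, gts, info=None, ref="A", alt="G"):
    calls = {
        s: Genotype(g, (40, 0) if g == GT.HOM_REF else ((0, 40) if g == GT.HOM_ALT else (20, 20)), 40, 99)
        for s, g in zip(("dad", "mum", "kid"), gts)
    }
    return SiteRecord("chr1", pos, ref, [alt] if alt else [], info or {}, calls)


def _good_genotype(gt=GT.HET, ad=(25, 25), dp=50, gq=99):
    return Genotype(gt, ad, dp, gq)


def _candidate(
    pos=100,
    offspring_ad=(25, 25),
    offspring_dp=50,
    parent_ad=(50, 0),
    parent_dp=50,
    gq=99,
    info=None,
    orientation=HOMREF_PARENTS,
    offspring="kid",
    family="fam1",
    chrom="chr1",
    alt="G",
):
    pg = GT.HOM_REF if orientation == HOMREF_PARENTS else GT.HOM_ALT
    return DnmCandidate(
        trio_id=offspring,
        offspring=offspring,
        family=family,
        chrom=chrom,
        pos=pos,
        ref="A",
        alt=alt,
        orientation=orientation,
        offspring_gt=Genotype(GT.HET, offspring_ad, offspring_dp, gq),
        father_gt=Genotype(pg, parent_ad, parent_dp, gq),
        mother_gt=Genotype(pg, parent_ad, parent_dp, gq),
        info=info or {},
    )


class TestScan:
    def test_all_trio_genotype_configurations(self):
        """Brute-force enumeration: only 0/0+0/0->0/1 and 1/1+1/1->0/1 qualify."""
        gts = (GT.HOM_REF, GT.HET, GT.HOM_ALT)
        combos = list(itertools.product(gts, gts, gts))
        records = [_site(10 * (i + 1), combo) for i, combo in enumerate(combos)]
        table = SiteTable.from_records(records)
        cands, skipped = scan_mendelian_violations(table, TRIO)
        expected = {
            10 * (i + 1)
            for i, (f, m, c) in enumerate(combos)
            if c == GT.HET and ((f == m == GT.HOM_REF) or (f == m == GT.HOM_ALT))
        }
        assert {c.pos for c in cands} == expected
        assert len(cands) == 2 and skipped == 0

    def test_orientation_labels(self):
        records = [
            _site(10, (GT.HOM_REF, GT.HOM_REF, GT.HET)),
            _site(20, (GT.HOM_ALT, GT.HOM_ALT, GT.HET)),
        ]
        cands, _ = scan_mendelian_violations(SiteTable.from_records(records), TRIO)
        assert [c.orientation for c in cands] == [HOMREF_PARENTS, HOMALT_PARENTS]

    def test_expected_het_not_a_candidate(self):
        records = [_site(10, (GT.HOM_REF, GT.HOM_ALT, GT.HET))]
        cands, _ = scan_mendelian_violations(SiteTable.from_records(records), TRIO)
        assert cands == []

    def test_missing_genotype_skipped_and_counted(self):
        records = [_site(10, (GT.HOM_REF, GT.MISSING, GT.HET))]
        cands, skipped = scan_mendelian_violations(SiteTable.from_records(records), TRIO)
        assert cands == [] and skipped == 1

    def test_indels_excluded(self):
        rec = SiteRecord(
            "chr1", 10, "AT", ["A"], {},
            {s: Genotype(g, (20, 20), 40, 99) for s, g in
             zip(("dad", "mum", "kid"), (GT.HOM_REF, GT.HOM_REF, GT.HET))},
        )
        cands, _ = scan_mendelian_violations(SiteTable.from_records([rec]), TRIO)
        assert cands == []


class TestSiteFilters:
    @pytest.mark.parametrize(
        "info,kept",
        [
            ({"QD": 1.9}, False),
            ({"QD": 2.0}, True),  # strict inequality at the boundary
            ({"MQ": 39.9}, False),
            ({"MQ": 40.0}, True),
            ({"FS": 60.0}, True),
            ({"FS": 60.1}, False),
            ({"SOR": 3.0}, True),
            ({"SOR": 3.01}, False),
            ({"MQRankSum": -12.5}, True),
            ({"MQRankSum": -12.6}, False),
            ({"ReadPosRankSum": -8.0}, True),
            ({"ReadPosRankSum": -8.5}, False),
            ({}, True),  # all annotations missing: kept
        ],
    )
    def test_boundary_semantics(self, info, kept):
        c = _candidate(info=info)
        out = apply_site_filters([c], T)
        assert (len(out) == 1) is kept

    def test_flags_named_per_filter(self):
        c = _candidate(info={"QD": 1.0, "FS": 80.0})
        apply_site_filters([c], T)
        assert c.filter_flags == {"site_QD", "site_FS"}


class TestIndividualFilters:
    @pytest.mark.parametrize(
        "kw,kept,flag",
        [
            (dict(offspring_ad=(10, 10), offspring_dp=20), False, "dp_bounds"),
            (dict(offspring_dp=21, offspring_ad=(10, 11)), True, None),
            (dict(offspring_dp=100, offspring_ad=(50, 50), parent_dp=100), False, "dp_bounds"),
            (dict(gq=80), False, "gq"),
            (dict(gq=81), True, None),
            (dict(parent_ad=(49, 1)), False, "parent_ad"),
            (dict(offspring_ad=(14, 6), offspring_dp=50), True, None),  # AB exactly 0.30
            (dict(offspring_ad=(15, 5), offspring_dp=50), False, "ab"),
            (dict(offspring_ad=(5, 15), offspring_dp=50), False, "ab"),
            (dict(offspring_ad=(0, 0)), False, "ab_degenerate"),
            # trio mean (80+80+24)/3 = 61.3; child 24 < 0.5 * 61.3 -> removed
            (dict(offspring_dp=24, offspring_ad=(12, 12), parent_dp=80), False, "dp_ratio"),
        ],
    )
    def test_criteria_and_boundaries(self, kw, kept, flag):
        c = _candidate(**kw)
        out = apply_individual_filters([c], T)
        assert (len(out) == 1) is kept
        if flag:
            assert flag in c.filter_flags

    def test_homalt_orientation_parent_ad_symmetry(self):
        c = _candidate(orientation=HOMALT_PARENTS, parent_ad=(1, 49))
        apply_individual_filters([c], T)
        assert "parent_ad" in c.filter_flags

    def test_near_indel_window(self):
        indels = IntervalSet.from_tuples([("chr1", 200, 202)])
        kept = apply_individual_filters([_candidate(pos=195)], T, indels)
        assert kept == []
        kept = apply_individual_filters([_candidate(pos=194)], T, indels)
        assert len(kept) == 1

    def test_dp_trio_uses_mean_of_members(self):
        # trio mean = (30+30+90)/3 = 50; child 90 < 2*50 -> kept
        c = _candidate(offspring_dp=90, offspring_ad=(45, 45), parent_dp=30)
        assert len(apply_individual_filters([c], T)) == 1
        # trio mean = (20.5+20.5+90)/3 = 43.67; child 90 > 2*43.67 -> removed
        c = _candidate(offspring_dp=90, offspring_ad=(45, 45), parent_dp=21)
        apply_individual_filters([c], T)
        assert "dp_ratio" in c.filter_flags


class TestOracleEquivalence:
    def test_survivors_match_bruteforce_on_random_panel(self, rng):
        """Cascade survivors equal an independent predicate evaluation."""
        cands = []
        for i in range(500):
            info = {}
            for key, lo, hi in (
                ("QD", 0.5, 10.0), ("MQ", 30.0, 62.0), ("FS", 0.0, 90.0),
                ("SOR", 0.5, 5.0), ("MQRankSum", -16.0, 4.0), ("ReadPosRankSum", -10.0, 4.0),
            ):
                if rng.random() < 0.9:
                    info[key] = float(rng.uniform(lo, hi))
            dp_o = int(rng.integers(10, 120))
            ad1 = int(rng.integers(0, dp_o + 1))
            cands.append(
                _candidate(
                    pos=10 * i,
                    info=info,
                    offspring_dp=dp_o,
                    offspring_ad=(dp_o - ad1, ad1),
                    parent_dp=int(rng.integers(10, 120)),
                    parent_ad=(50, int(rng.integers(0, 3))),
                    gq=int(rng.integers(60, 100)),
                )
            )
        survivors = apply_site_filters(cands, T)
        survivors = apply_individual_filters(survivors, T)
        got = {c.pos for c in survivors}

        def brute(c):
            i = c.info
            if i.get("QD", 99) < 2 or i.get("MQ", 99) < 40:
                return False
            if i.get("FS", 0) > 60 or i.get("SOR", 0) > 3:
                return False
            if i.get("MQRankSum", 0) < -12.5 or i.get("ReadPosRankSum", 0) < -8:
                return False
            gts = [c.father_gt, c.mother_gt, c.offspring_gt]
            if any(g.dp <= 20 or g.dp >= 100 or g.gq <= 80 for g in gts):
                return False
            if c.father_gt.ad[1] > 0 or c.mother_gt.ad[1] > 0:
                return False
            tot = sum(c.offspring_gt.ad)
            if tot == 0:
                return False
            ab = c.offspring_gt.ad[1] / tot
            if ab < 0.3 or ab > 0.7:
                return False
            mean_dp = (c.father_gt.dp + c.mother_gt.dp + c.offspring_gt.dp) / 3
            if c.offspring_gt.dp < 0.5 * mean_dp or c.offspring_gt.dp > 2 * mean_dp:
                return False
            return True

        expected = {c.pos for c in cands if brute(c)}
        assert got == expected

    def test_filter_order_independence(self, rng):
        """Site and individual filters are pure predicates: any order, same set."""
        cands = [
            _candidate(
                pos=i,
                info={"QD": float(rng.uniform(0, 5)), "SOR": float(rng.uniform(1, 4))},
                offspring_dp=int(rng.integers(15, 110)),
                offspring_ad=(20, int(rng.integers(0, 40))),
                gq=int(rng.integers(70, 100)),
            )
            for i in range(200)
        ]

        def clone(c):
            return _candidate(
                pos=c.pos, info=dict(c.info),
                offspring_dp=c.offspring_gt.dp, offspring_ad=c.offspring_gt.ad,
                gq=c.offspring_gt.gq,
            )

        a = apply_individual_filters(apply_site_filters([clone(c) for c in cands], T), T)
        b = apply_site_filters(apply_individual_filters([clone(c) for c in cands], T), T)
        assert {c.pos for c in a} == {c.pos for c in b}


def _mini_pedigree():
    return Pedigree(
        [
            Member("d1", "fam1", 1, None, None, "F0"),
            Member("m1", "fam1", 2, None, None, "F0"),
            Member("k1", "fam1", 1, "d1", "m1", "F1"),
            Member("k2", "fam1", 2, "d1", "m1", "F1"),
            Member("k3", "fam1", 1, "d1", "m1", "F1"),
            Member("k4", "fam1", 2, "d1", "m1", "F1"),
            Member("d2", "fam2", 1, None, None, "F0"),
            Member("m2", "fam2", 2, None, None, "F0"),
            Member("x1", "fam2", 1, "d2", "m2", "F1"),
        ]
    )


class TestCohortFilters:
    def test_cross_family_recurrence_removed(self):
        ped = _mini_pedigree()
        c1 = _candidate(pos=100, offspring="k1", family="fam1")
        c2 = _candidate(pos=100, offspring="x1", family="fam2")
        out = filter_recurrent_and_clustered([c1, c2], ped)
        assert out == [] and c1.recurrent and c2.recurrent

    def test_four_full_sibs_share_one_group(self):
        ped = _mini_pedigree()
        cands = [_candidate(pos=100, offspring=k) for k in ("k1", "k2", "k3", "k4")]
        out = filter_recurrent_and_clustered(cands, ped)
        assert len(out) == 4
        groups = {c.shared_group for c in out}
        assert groups == {0}

    def test_cluster_window_boundary(self):
        ped = _mini_pedigree()
        a, b = _candidate(pos=1000), _candidate(pos=1100)
        filter_recurrent_and_clustered([a, b], ped)
        assert a.clustered and b.clustered  # 100 bp apart: flagged
        a, b = _candidate(pos=1000), _candidate(pos=1101)
        filter_recurrent_and_clustered([a, b], ped)
        assert not a.clustered and not b.clustered  # 101 bp: not flagged


class TestCuration:
    def test_parental_support_arithmetic(self):
        # 7/105 = 6.7% < 10% -> kept
        c = _candidate(parent_ad=(48, 3))
        c.mother_gt = Genotype(GT.HOM_REF, (50, 4), 54, 99)
        curated, fdr = automated_curation([c], T)
        assert curated == [c] and fdr == 0.0
        # 10/101 = 9.9% -> kept
        c = _candidate(parent_ad=(45, 5))
        c.mother_gt = Genotype(GT.HOM_REF, (46, 5), 51, 99)
        curated, _ = automated_curation([c], T)
        assert len(curated) == 1
        # 11/101 = 10.9% -> removed
        c = _candidate(parent_ad=(44, 6))
        c.mother_gt = Genotype(GT.HOM_REF, (46, 5), 51, 99)
        curated, fdr = automated_curation([c], T)
        assert curated == [] and c.curation_verdict == "parental_support"
        assert fdr == 1.0

    def test_homalt_orientation_counts_ref_support(self):
        c = _candidate(orientation=HOMALT_PARENTS, parent_ad=(6, 44))
        c.mother_gt = Genotype(GT.HOM_ALT, (5, 46), 51, 99)
        curated, _ = automated_curation([c], T)
        assert curated == [] and c.curation_verdict == "parental_support"

    def test_zero_parental_depth_uncurateable(self):
        c = _candidate(parent_ad=(0, 0))
        c.mother_gt = Genotype(GT.HOM_REF, (0, 0), 0, 99)
        curated, _ = automated_curation([c], T)
        assert curated == [] and c.curation_verdict == "no_parental_depth"

    def test_mask_removal_and_fdr(self):
        mask = IntervalSet.from_tuples([("chr1", 90, 110)])
        inside = _candidate(pos=100)
        outside = _candidate(pos=200)
        curated, fdr = automated_curation([inside, outside], T, low_mq_mask=mask)
        assert curated == [outside]
        assert inside.curation_verdict == "bad_region"
        assert fdr == pytest.approx(0.5)

    def test_no_removals_fdr_zero(self):
        cands = [_candidate(pos=p) for p in (10, 20, 30)]
        _, fdr = automated_curation(cands, T)
        assert fdr == 0.0

    def test_raw_support_channel_overrides_ad(self):
        """Support dropped from AD by the caller is still found in raw reads."""
        c = _candidate(parent_ad=(50, 0))
        c.father_id, c.mother_id = "dad", "mum"
        raw = {("dad", "chr1", 100): (40, 10)}  # 10/(50+50) = 10% -> removed
        curated, _ = automated_curation([c], T, raw_support=raw)
        assert curated == [] and c.curation_verdict == "parental_support"


class TestNoiseFreePipeline:
    def test_noise_free_survivors_equal_planted_set(self, noise_free_dataset):
        """Without artifacts the screen recovers exactly the planted DNMs."""
        from dnmkit.pipeline import run_pipeline

        ds = noise_free_dataset
        res = run_pipeline(
            ds.table, ds.pedigree, ds.tracks,
            mask=None, raw_support=ds.raw_support,
        )
        truth = set(
            zip(ds.truth.dnms.offspring, ds.truth.dnms.chrom, ds.truth.dnms.pos)
        )
        got = {(c.offspring, c.chrom, c.pos) for c in res.curated}
        assert got == truth
        assert res.fdr == 0.0

    def test_every_removed_candidate_carries_a_flag(self, small_dataset):
        from dnmkit.pipeline import run_pipeline

        ds = small_dataset
        res = run_pipeline(
            ds.table, ds.pedigree, ds.tracks,
            mask=ds.truth.mask, raw_support=ds.raw_support,
        )
        curated_ids = {id(c) for c in res.curated}
        for c in res.candidates:
            if id(c) not in curated_ids:
                assert c.filter_flags or c.recurrent or (
                    c.curation_verdict not in (None, "pass")
                )
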