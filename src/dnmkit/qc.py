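"""Pedigree sanity checks from genotype data.

Before any DNM calling, declared relationships are verified with two
allele-sharing summaries that need no allele-frequency estimates (the
founder panel here is too small for stable frequencies):

* the opposite-homozygote fraction — parent-offspring pairs cannot be
  opposite homozygotes except through genotyping error or a de novo
  mutation, so the fraction is ~0 for true parent-offspring pairs,
  intermediate for full sibs, and largest for unrelated pairs;
* the identity-by-state (IBS 0/1/2) distribution — parent-offspring
  pairs share at least one allele almost everywhere.

Trio assignments are additionally checked by the Mendelian-error rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import Trio
from .sites import GT, SiteTable

PARENT_OFFSPRING = "parent_offspring"
FULL_SIB = "full_sib"
UNRELATED = "unrelated"
AMBIGUOUS = "ambiguous"


class InsufficientSitesError(ValueError):
    pass


@dataclass(frozen=True)
class RelationshipThresholds:
    """Decision bounds on the pair summaries.

    Defaults assume deep-coverage calls with low genotyping error: true
    parent-offspring pairs show essentially no opposite homozygotes and
    IBS >= 1 nearly everywhere; sib and unrelated bounds are generous
    because the statistics separate by an order of magnitude.
    """

    min_sites: int = 1000
    po_opp_hom_max: float = 0.001
    po_ibs_ge1_min: float = 0.99
    sib_opp_hom_max: float = 0.05
    unrelated_opp_hom_min: float = 0.05


@dataclass(frozen=True)
class PairRelationStats:
    n_sites: int
    opposite_homozygote_fraction: float
    ibs_distribution: tuple[float, float, float]
    verdict: str

    def __post_init__(self) -> None:
        if abs(sum(self.ibs_distribution) - 1.0) > 1e-9:
            raise ValueError("IBS fractions must sum to 1")


def classify_relationship(
    table: SiteTable,
    sample_a: str,
    sample_b: str,
    thresholds: RelationshipThresholds = RelationshipThresholds(),
) -> PairRelationStats:
    """Classify a sample pair from biallelic sites called in both."""
    ja = table.sample_index(sample_a)
    jb = table.sample_index(sample_b)
    ga, gb = table.gt[:, ja], table.gt[:, jb]
    usable = table.is_snv & (ga != GT.MISSING) & (gb != GT.MISSING)
    n = int(usable.sum())
    if n < thresholds.min_sites:
        raise InsufficientSitesError(
            f"{n} usable sites for ({sample_a}, {sample_b}); "
            f"need >= {thresholds.min_sites}"
        )
    a, b = ga[usable].astype(np.int16), gb[usable].astype(np.int16)
    opp = ((a == GT.HOM_REF) & (b == GT.HOM_ALT)) | (
        (a == GT.HOM_ALT) & (b == GT.HOM_REF)
    )
    opp_frac = float(opp.mean())
    # IBS = 2 - |dosage difference|: identical genotypes share 2 alleles,
    # hom-vs-het shares 1, opposite homozygotes share 0
    ibs = 2 - np.abs(a - b)
    dist = tuple(float((ibs == k).mean()) for k in (0, 1, 2))
    ibs_ge1 = dist[1] + dist[2]
    t = thresholds
    if opp_frac <= t.po_opp_hom_max and ibs_ge1 >= t.po_ibs_ge1_min:
        verdict = PARENT_OFFSPRING
    elif opp_frac <= t.sib_opp_hom_max:
        verdict = FULL_SIB
    elif opp_frac >= t.unrelated_opp_hom_min:
        verdict = UNRELATED
    else:
        verdict = AMBIGUOUS
    return PairRelationStats(n, opp_frac, dist, verdict)


def mendelian_error_rate(table: SiteTable, trio: Trio) -> float:
    """Fraction of jointly called sites violating Mendelian transmission.

    A site counts as an error when the offspring genotype is impossible
    given the parents (de novo mutation not excepted — true DNMs are so
    rare they do not move this statistic).
    """
    jf = table.sample_index(trio.father)
    jm = table.sample_index(trio.mother)
    jc = table.sample_index(trio.child)
    f, m, c = table.gt[:, jf], table.gt[:, jm], table.gt[:, jc]
    usable = table.is_snv & (f != GT.MISSING) & (m != GT.MISSING) & (c != GT.MISSING)
    if not usable.any():
        return 0.0
    f, m, c = f[usable], m[usable], c[usable]
    # possible offspring genotypes by parental pair
    both_ref = (f == GT.HOM_REF) & (m == GT.HOM_REF)
    both_alt = (f == GT.HOM_ALT) & (m == GT.HOM_ALT)
    opp = ((f == GT.HOM_REF) & (m == GT.HOM_ALT)) | (
        (f == GT.HOM_ALT) & (m == GT.HOM_REF)
    )
    ref_het = ((f == GT.HOM_REF) & (m == GT.HET)) | ((f == GT.HET) & (m == GT.HOM_REF))
    alt_het = ((f == GT.HOM_ALT) & (m == GT.HET)) | ((f == GT.HET) & (m == GT.HOM_ALT))
    violation = (
        (both_ref & (c != GT.HOM_REF))
        | (both_alt & (c != GT.HOM_ALT))
        | (opp & (c != GT.HET))
        | (ref_het & (c == GT.HOM_ALT))
        | (alt_het & (c == GT.HOM_REF))
    )
    return float(violation.mean())


def verify_pedigree(table: SiteTable, pedigree, thresholds=RelationshipThresholds()):
    """Check all declared trios; returns a list of per-trio QC rows.

    Each row holds the trio id, both parent-pair verdicts and the
    Mendelian-error rate; ``ok`` requires both parents classified as
    parent_offspring to the child.
    """
    rows = []
    for trio in pedigree.trios():
        rf = classify_relationship(table, trio.father, trio.child, thresholds)
        rm = classify_relationship(table, trio.mother, trio.child, thresholds)
        mer = mendelian_error_rate(table, trio)
        rows.append(
            {
                "trio": trio.id,
                "father_verdict": rf.verdict,
                "mother_verdict": rm.verdict,
                "mendelian_error_rate": mer,
                "ok": rf.verdict == PARENT_OFFSPRING and rm.verdict == PARENT_OFFSPRING,
            }
        )
    return rows
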