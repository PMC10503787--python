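"""Trio-based de novo mutation screening.

The screen proceeds in four stages, each a pure predicate over the
evidence so the final survivor set is order-independent:

1. Mendelian-violation scan: offspring-het sites where both parents are
   identical homozygotes (0/0 + 0/0 -> 0/1, or 1/1 + 1/1 -> 0/1).
2. Hard site filters on the caller's INFO annotations (QD, MQ, FS, SOR,
   MQRankSum, ReadPosRankSum); a missing annotation never removes a
   candidate (rank-sum tests are undefined without het carriers).
3. Individual filters on depth, genotype quality, parental allelic depth,
   offspring allelic balance, trio-relative depth and indel proximity.
4. Cohort filters: cross-family recurrences are removed as artifacts,
   full-sib sharing is recorded as parental mosaicism, nearby candidates
   are flagged as clustered.

Automated curation then replaces visual read inspection with the two
automatable criteria: summed parental read support of the de novo allele
at or above 10%, and location inside a poor-mapping mask. The removed
fraction is the screen's false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .pedigree import Pedigree, Trio
from .sites import GT, Genotype, SiteTable

HOMREF_PARENTS = "homref_parents"
HOMALT_PARENTS = "homalt_parents"

VERDICT_PASS = "pass"
VERDICT_PARENTAL_SUPPORT = "parental_support"
VERDICT_BAD_REGION = "bad_region"
VERDICT_NO_DEPTH = "no_parental_depth"


@dataclass(frozen=True)
class FilterThresholds:
    """Cut-offs of the screening cascade.

    Boundary semantics follow the removal conditions verbatim: DP and GQ
    removals are inclusive (DP <= 20, DP >= 100, GQ <= 80), the hard site
    filters and the allelic-balance window are strict.
    """

    qd_min: float = 2.0
    mq_min: float = 40.0
    fs_max: float = 60.0
    sor_max: float = 3.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0
    dp_low: int = 20
    dp_high: int = 100
    gq_min: int = 80
    ab_low: float = 0.3
    ab_high: float = 0.7
    trio_dp_low_factor: float = 0.5
    trio_dp_high_factor: float = 2.0
    indel_window: int = 5
    cluster_window: int = 100
    parental_support_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.ab_low < self.ab_high < 1:
            raise ValueError("need 0 < ab_low < ab_high < 1")
        if self.indel_window < 0 or self.cluster_window < 0:
            raise ValueError("windows must be >= 0")
        if not 0 < self.trio_dp_low_factor < self.trio_dp_high_factor:
            raise ValueError("need 0 < trio_dp_low_factor < trio_dp_high_factor")


@dataclass
class DnmCandidate:
    """One offspring-specific Mendelian-violation site with its verdicts."""

    trio_id: str
    offspring: str
    family: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    orientation: str
    offspring_gt: Genotype
    father_gt: Genotype
    mother_gt: Genotype
    info: dict[str, float] = field(default_factory=dict)
    filter_flags: set[str] = field(default_factory=set)
    curation_verdict: str | None = None
    shared_group: int | None = None
    clustered: bool = False
    recurrent: bool = False
    row: int | None = None  # source row in the SiteTable, if any

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)

    @property
    def removed(self) -> bool:
        return bool(self.filter_flags) or self.recurrent

    @property
    def de_novo_allele(self) -> str:
        """The allele absent from both parents."""
        return self.alt if self.orientation == HOMREF_PARENTS else self.ref


# ---------------------------------------------------------------------------
# stage 1: Mendelian-violation scan


def scan_mendelian_violations(
    table: SiteTable, trio: Trio
) -> tuple[list[DnmCandidate], int]:
    """Find offspring-het sites with identical homozygous parents.

    Returns (candidates, n_skipped) where n_skipped counts biallelic SNV
    rows skipped because a trio member's genotype was missing.
    """
    jf = table.sample_index(trio.father)
    jm = table.sample_index(trio.mother)
    jc = table.sample_index(trio.child)
    snv = table.is_snv
    gtf, gtm, gtc = table.gt[:, jf], table.gt[:, jm], table.gt[:, jc]
    missing = snv & ((gtf == -1) | (gtm == -1) | (gtc == -1))
    homref = snv & (gtc == GT.HET) & (gtf == GT.HOM_REF) & (gtm == GT.HOM_REF)
    homalt = snv & (gtc == GT.HET) & (gtf == GT.HOM_ALT) & (gtm == GT.HOM_ALT)
    candidates = []
    for row in np.flatnonzero(homref | homalt):
        row = int(row)
        info = {
            k: float(v[row]) for k, v in table.info.items() if not np.isnan(v[row])
        }
        candidates.append(
            DnmCandidate(
                trio_id=trio.id,
                offspring=trio.child,
                family=trio.family,
                chrom=table.chrom_of(row),
                pos=int(table.pos[row]),
                ref=table.ref[row],
                alt=table.alt[row],
                orientation=HOMREF_PARENTS if homref[row] else HOMALT_PARENTS,
                offspring_gt=table.genotype_at(row, trio.child),
                father_gt=table.genotype_at(row, trio.father),
                mother_gt=table.genotype_at(row, trio.mother),
                info=info,
                row=row,
            )
        )
    return candidates, int(missing.sum())


# ---------------------------------------------------------------------------
# stage 2: hard site filters


def apply_site_filters(
    candidates: Iterable[DnmCandidate], thresholds: FilterThresholds = FilterThresholds()
) -> list[DnmCandidate]:
    """Flag candidates failing the caller's hard INFO filters; return survivors."""
    t = thresholds
    checks = (
        ("QD", lambda v: v < t.qd_min, "site_QD"),
        ("MQ", lambda v: v < t.mq_min, "site_MQ"),
        ("FS", lambda v: v > t.fs_max, "site_FS"),
        ("SOR", lambda v: v > t.sor_max, "site_SOR"),
        ("MQRankSum", lambda v: v < t.mqranksum_min, "site_MQRankSum"),
        ("ReadPosRankSum", lambda v: v < t.readposranksum_min, "site_ReadPosRankSum"),
    )
    survivors = []
    for c in candidates:
        for key, bad, flag in checks:
            v = c.info.get(key)
            if v is not None and not np.isnan(v) and bad(v):
                c.filter_flags.add(flag)
        if not c.filter_flags:
            survivors.append(c)
    return survivors


# ---------------------------------------------------------------------------
# stage 3: individual filters


def indel_intervals(table: SiteTable, trio: Trio) -> IntervalSet:
    """Reference spans of indel records carried by any trio member."""
    cols = [table.sample_index(s) for s in trio.members]
    carried = np.isin(table.gt[:, cols], (GT.HET, GT.HOM_ALT)).any(axis=1)
    rows = np.flatnonzero(table.is_indel & carried)
    return IntervalSet.from_tuples(
        (table.chrom_of(int(r)), int(table.pos[r]), int(table.pos[r]) + len(table.ref[r]))
        for r in rows
    )


def apply_individual_filters(
    candidates: Iterable[DnmCandidate],
    thresholds: FilterThresholds = FilterThresholds(),
    indels: IntervalSet | None = None,
) -> list[DnmCandidate]:
    """Apply depth/quality/balance filters per trio member; return survivors.

    Removal reasons (any one removes):

    ``dp_bounds``      any member DP <= dp_low or DP >= dp_high
    ``gq``             any member GQ <= gq_min
    ``parent_ad``      identical-homozygote parent shows the de novo allele
    ``ab`` / ``ab_degenerate``  offspring allelic balance outside
                       (ab_low, ab_high), or AD0+AD1 = 0
    ``dp_ratio``       offspring DP outside (0.5, 2) x mean trio DP
    ``near_indel``     within ``indel_window`` bp of an indel in the trio
    ``missing_evidence``  a required FORMAT field is absent
    """
    t = thresholds
    padded = None
    if indels is not None and indels.data:
        w = t.indel_window
        padded = IntervalSet(
            {
                chrom: np.column_stack(
                    (np.maximum(arr[:, 0] - w, 0), arr[:, 1] + w)
                )
                for chrom, arr in indels.data.items()
            }
        )
    survivors = []
    for c in candidates:
        trio_gts = (c.father_gt, c.mother_gt, c.offspring_gt)
        if any(g.dp is None or g.gq is None for g in trio_gts) or any(
            g.ad is None for g in (c.father_gt, c.mother_gt)
        ):
            c.filter_flags.add("missing_evidence")
        else:
            if any(g.dp <= t.dp_low or g.dp >= t.dp_high for g in trio_gts):
                c.filter_flags.add("dp_bounds")
            if any(g.gq <= t.gq_min for g in trio_gts):
                c.filter_flags.add("gq")
            parent_alt_slot = 1 if c.orientation == HOMREF_PARENTS else 0
            if any(g.ad[parent_alt_slot] > 0 for g in (c.father_gt, c.mother_gt)):
                c.filter_flags.add("parent_ad")
            ab = c.offspring_gt.ab
            if c.offspring_gt.ad is None or ab is None:
                c.filter_flags.add("ab_degenerate")
            elif ab < t.ab_low or ab > t.ab_high:
                c.filter_flags.add("ab")
            dp_trio = sum(g.dp for g in trio_gts) / 3.0
            if (
                c.offspring_gt.dp < t.trio_dp_low_factor * dp_trio
                or c.offspring_gt.dp > t.trio_dp_high_factor * dp_trio
            ):
                c.filter_flags.add("dp_ratio")
        if padded is not None and padded.contains(c.chrom, c.pos):
            c.filter_flags.add("near_indel")
        if not c.filter_flags:
            survivors.append(c)
    return survivors


# ---------------------------------------------------------------------------
# stage 4: cohort filters


def filter_recurrent_and_clustered(
    candidates: Sequence[DnmCandidate],
    pedigree: Pedigree,
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[DnmCandidate]:
    """Cross-family recurrence removal, sib sharing, cluster flagging.

    Identical (chrom, pos, alt) candidates in samples from different
    families are removed as recurrent artifacts; identical candidates
    among full sibs are retained and given one shared_group id; two or
    more candidates of one offspring within ``cluster_window`` bp get the
    clustered flag (retained pending curation).
    """
    by_key: dict[tuple, list[DnmCandidate]] = {}
    for c in candidates:
        by_key.setdefault(c.key, []).append(c)
    group_counter = 0
    survivors: list[DnmCandidate] = []
    for key in sorted(by_key):
        group = by_key[key]
        families = {c.family for c in group}
        if len(families) > 1:
            for c in group:
                c.recurrent = True
            continue
        carriers = sorted({c.offspring for c in group})
        if len(carriers) > 1 and all(
            pedigree.are_full_sibs(a, b)
            for i, a in enumerate(carriers)
            for b in carriers[i + 1 :]
        ):
            for c in group:
                c.shared_group = group_counter
            group_counter += 1
        survivors.extend(group)
    by_offspring: dict[str, list[DnmCandidate]] = {}
    for c in survivors:
        by_offspring.setdefault(c.offspring, []).append(c)
    for group in by_offspring.values():
        group.sort(key=lambda c: (c.chrom, c.pos))
        for a, b in zip(group, group[1:]):
            if a.chrom == b.chrom and b.pos - a.pos <= thresholds.cluster_window:
                a.clustered = b.clustered = True
    survivors.sort(key=lambda c: (c.chrom, c.pos, c.offspring))
    return survivors


# ---------------------------------------------------------------------------
# automated curation


def _parental_support(
    c: DnmCandidate, raw_support: Mapping[tuple[str, str, int], tuple[int, int]] | None
) -> tuple[int, int]:
    """(de novo allele reads, total reads) summed over the two parents.

    Counts come from the raw-read support table when available — the
    caller may have dropped the supporting reads from the parents' AD —
    and fall back to the VCF AD otherwise.
    """
    alt_sum = tot_sum = 0
    for parent, g in (("father", c.father_gt), ("mother", c.mother_gt)):
        sample = getattr(c, f"{parent}_id", None) or parent
        counts = None
        if raw_support is not None:
            counts = raw_support.get((sample, c.chrom, c.pos))
        if counts is None and g.ad is not None:
            counts = g.ad
        if counts is None:
            continue
        ref_n, alt_n = counts
        de_novo = alt_n if c.orientation == HOMREF_PARENTS else ref_n
        alt_sum += de_novo
        tot_sum += ref_n + alt_n
    return alt_sum, tot_sum


def build_raw_support_lookup(
    df: pd.DataFrame,
) -> dict[tuple[str, str, int], tuple[int, int]]:
    """Index a raw-support table by (sample, chrom, pos)."""
    return {
        (r.sample, r.chrom, int(r.pos)): (int(r.ref_count), int(r.alt_count))
        for r in df.itertuples()
    }


def automated_curation(
    candidates: Sequence[DnmCandidate],
    thresholds: FilterThresholds = FilterThresholds(),
    low_mq_mask: IntervalSet | None = None,
    raw_support: pd.DataFrame | Mapping | None = None,
    parent_ids: Mapping[str, tuple[str, str]] | None = None,
) -> tuple[list[DnmCandidate], float]:
    """Automated replacement of visual curation; returns (curated, FDR).

    A candidate is removed when the summed parental read support of the
    de novo allele reaches ``parental_support_fraction`` of the summed
    parental depth, when it falls in the poor-mapping mask, or when no
    parental depth is available to check. FDR is the removed fraction of
    the candidates entering curation.

    ``parent_ids`` maps offspring id -> (father id, mother id) so raw
    support can be looked up per parent sample.
    """
    if isinstance(raw_support, pd.DataFrame):
        raw_support = build_raw_support_lookup(raw_support)
    curated: list[DnmCandidate] = []
    n_removed = 0
    for c in candidates:
        if parent_ids is not None and c.offspring in parent_ids:
            c.father_id, c.mother_id = parent_ids[c.offspring]
        verdict = VERDICT_PASS
        if low_mq_mask is not None and low_mq_mask.contains(c.chrom, c.pos):
            verdict = VERDICT_BAD_REGION
        else:
            alt_sum, tot_sum = _parental_support(c, raw_support)
            if tot_sum == 0:
                verdict = VERDICT_NO_DEPTH
            elif alt_sum / tot_sum >= thresholds.parental_support_fraction:
                verdict = VERDICT_PARENTAL_SUPPORT
        c.curation_verdict = verdict
        if verdict == VERDICT_PASS:
            curated.append(c)
        else:
            n_removed += 1
    total = len(candidates)
    fdr = n_removed / total if total else 0.0
    return curated, fdr
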