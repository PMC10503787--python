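"""Callable-genome size (CS) and false-negative rate (FNR) per offspring.

CS is the denominator of the per-generation rate: the number of assayed
positions where the offspring's depth lies strictly between half and
double the mean trio depth — the same relative-depth rule the candidate
screen applies, keeping numerator and denominator commensurate. It is
computed by interval arithmetic over piecewise-constant depth tracks.

FNR calibrates the allelic-balance filter: at sites where one parent is
homozygous reference and the other homozygous alternate, the offspring is
an obligate heterozygote; the fraction of such het calls with allelic
balance outside the acceptance window estimates the probability that the
same filter discards a true de novo heterozygote.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .intervals import DepthTrack, IntervalSet, combined_breakpoints
from .pedigree import Trio
from .screen import FilterThresholds
from .sites import GT, SiteTable


class InsufficientDataError(ValueError):
    """Not enough evaluable sites to calibrate."""


@dataclass(frozen=True)
class CallabilityResult:
    offspring: str
    cs: int
    genome_assayed: int

    def __post_init__(self) -> None:
        if not 0 <= self.cs <= self.genome_assayed:
            raise ValueError("need 0 <= cs <= genome_assayed")

    @property
    def fraction(self) -> float:
        return self.cs / self.genome_assayed if self.genome_assayed else 0.0


@dataclass(frozen=True)
class FnrEstimate:
    offspring: str
    n_true_het: int
    n_failed_ab: int

    @property
    def fnr(self) -> float:
        return self.n_failed_ab / self.n_true_het


def count_callable_sites(
    tracks: dict[str, DepthTrack],
    trio: Trio,
    thresholds: FilterThresholds = FilterThresholds(),
    assayed: IntervalSet | None = None,
    mask: IntervalSet | None = None,
) -> CallabilityResult:
    """Count positions with trio-consistent offspring depth.

    A position is callable iff ``low_factor * DP_trio < DP_child <
    high_factor * DP_trio`` with DP_trio the mean of the three members'
    depths there. ``assayed`` restricts the evaluated genome (defaults to
    the union of the child's track); ``mask`` removes excluded intervals
    (e.g. sex chromosome, unassigned contigs). Track gaps are
    non-callable and produce a warning.
    """
    member_tracks = [tracks[s] for s in trio.members]
    child = tracks[trio.child]
    chroms = set()
    for t in member_tracks:
        chroms.update(t.chroms)
    cs = 0
    assayed_bp = 0
    gap_bp = 0
    for chrom in sorted(chroms):
        breaks = combined_breakpoints(member_tracks, chrom)
        if assayed is not None and chrom in assayed.data:
            breaks = np.unique(np.concatenate([breaks, assayed.data[chrom].ravel()]))
        if mask is not None and chrom in mask.data:
            breaks = np.unique(np.concatenate([breaks, mask.data[chrom].ravel()]))
        if len(breaks) < 2:
            continue
        lengths = np.diff(breaks)
        starts = breaks[:-1]
        keep = np.ones(len(starts), dtype=bool)
        if assayed is not None:
            keep &= assayed.contains(chrom, starts)
        if mask is not None:
            keep &= ~mask.contains(chrom, starts)
        depths = np.vstack([t.segment_values(chrom, breaks) for t in member_tracks])
        child_d = child.segment_values(chrom, breaks)
        has_gap = np.isnan(depths).any(axis=0)
        gap_bp += int(lengths[keep & has_gap].sum())
        assayed_bp += int(lengths[keep].sum())
        with np.errstate(invalid="ignore"):
            dp_trio = depths.mean(axis=0)
            ok = (
                keep
                & ~has_gap
                & (child_d > thresholds.trio_dp_low_factor * dp_trio)
                & (child_d < thresholds.trio_dp_high_factor * dp_trio)
            )
        cs += int(lengths[ok].sum())
    if gap_bp:
        warnings.warn(
            f"{gap_bp} assayed bp lack depth information for trio {trio.id}; "
            "treated as non-callable",
            stacklevel=2,
        )
    return CallabilityResult(offspring=trio.child, cs=cs, genome_assayed=assayed_bp)


def count_callable_sites_bruteforce(
    tracks: dict[str, DepthTrack],
    trio: Trio,
    thresholds: FilterThresholds = FilterThresholds(),
    assayed: IntervalSet | None = None,
    mask: IntervalSet | None = None,
) -> int:
    """Per-base reference implementation of the callable-site rule.

    Quadratically slower than :func:`count_callable_sites`; used as an
    independent oracle in tests only.
    """
    member_tracks = [tracks[s] for s in trio.members]
    chroms = set()
    for t in member_tracks:
        chroms.update(t.chroms)
    cs = 0
    for chrom in sorted(chroms):
        hi = 0
        for t in member_tracks:
            if chrom in t.data:
                hi = max(hi, int(t.data[chrom][1].max()))
        pos = np.arange(hi, dtype=np.int64)
        if assayed is not None:
            pos = pos[assayed.contains(chrom, pos)]
        if mask is not None:
            pos = pos[~mask.contains(chrom, pos)]
        if not len(pos):
            continue
        depths = np.vstack([t.value_at(chrom, pos) for t in member_tracks])
        child_d = tracks[trio.child].value_at(chrom, pos)
        with np.errstate(invalid="ignore"):
            dp_trio = depths.mean(axis=0)
            ok = (
                ~np.isnan(depths).any(axis=0)
                & (child_d > thresholds.trio_dp_low_factor * dp_trio)
                & (child_d < thresholds.trio_dp_high_factor * dp_trio)
            )
        cs += int(ok.sum())
    return cs


def estimate_fnr(
    table: SiteTable,
    trio: Trio,
    thresholds: FilterThresholds = FilterThresholds(),
) -> FnrEstimate:
    """Allelic-balance miss rate at obligate-heterozygote sites.

    Denominator: offspring het calls at biallelic SNVs where one parent is
    0/0 and the other 1/1 and both parents pass the same DP/GQ/AD checks
    the screen applies. Numerator: those failing the AB window. Offspring
    calls that are not het at such sites are excluded from both (they are
    genotyping misses, not AB-filter losses).
    """
    t = thresholds
    jf = table.sample_index(trio.father)
    jm = table.sample_index(trio.mother)
    jc = table.sample_index(trio.child)
    gtf, gtm, gtc = table.gt[:, jf], table.gt[:, jm], table.gt[:, jc]
    opp = table.is_snv & (
        ((gtf == GT.HOM_REF) & (gtm == GT.HOM_ALT))
        | ((gtf == GT.HOM_ALT) & (gtm == GT.HOM_REF))
    )
    for j, gtp in ((jf, gtf), (jm, gtm)):
        dp, gq = table.dp[:, j], table.gq[:, j]
        ad0, ad1 = table.ad0[:, j], table.ad1[:, j]
        opp &= (dp > t.dp_low) & (dp < t.dp_high) & (gq > t.gq_min)
        # homozygous parents must be clean for their genotype class
        opp &= np.where(gtp == GT.HOM_REF, ad1 == 0, ad0 == 0)
    evaluable = opp & (gtc == GT.HET)
    ad0c = table.ad0[:, jc][evaluable]
    ad1c = table.ad1[:, jc][evaluable]
    tot = ad0c + ad1c
    with np.errstate(divide="ignore", invalid="ignore"):
        ab = np.where(tot > 0, ad1c / np.maximum(tot, 1), np.nan)
    failed = np.isnan(ab) | (ab < t.ab_low) | (ab > t.ab_high)
    n = int(evaluable.sum())
    if n == 0:
        raise InsufficientDataError(
            f"no evaluable opposite-homozygote sites for trio {trio.id}"
        )
    return FnrEstimate(
        offspring=trio.child, n_true_het=n, n_failed_ab=int(failed.sum())
    )
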