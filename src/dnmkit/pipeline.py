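"""End-to-end orchestration: screen, calibrate, estimate.

Ties the per-trio screening cascade, cohort filters, automated curation,
callable-genome and FNR calibration and rate estimation together over one
dataset held in memory. The command-line interface and the test suite
both drive this module; every reported number is reproducible by calling
the owning module's function on the stored intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .callability import CallabilityResult, FnrEstimate, count_callable_sites, estimate_fnr
from .intervals import DepthTrack, IntervalSet
from .pedigree import Pedigree
from .rates import (
    GroupComparison,
    RateEstimate,
    TransmissionResult,
    aggregate_rates,
    count_f1_transmissions,
    per_offspring_rate,
    transmission_test,
)
from .screen import (
    DnmCandidate,
    FilterThresholds,
    apply_individual_filters,
    apply_site_filters,
    automated_curation,
    filter_recurrent_and_clustered,
    indel_intervals,
    scan_mendelian_violations,
)
from .sites import SiteTable


@dataclass
class PipelineResult:
    """Everything the pipeline computed for one dataset."""

    candidates: list[DnmCandidate]  # all Mendelian violations, flags set
    curated: list[DnmCandidate]
    fdr: float
    callability: dict[str, CallabilityResult]
    fnr: dict[str, FnrEstimate]
    per_offspring: list[RateEstimate]
    aggregate: RateEstimate
    comparison: GroupComparison | None
    transmission: TransmissionResult
    n_sites_skipped: int = 0

    def candidate_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            rows.append(
                {
                    "offspring": c.offspring,
                    "family": c.family,
                    "chrom": c.chrom,
                    "pos": c.pos,
                    "ref": c.ref,
                    "alt": c.alt,
                    "orientation": c.orientation,
                    "flags": ",".join(sorted(c.filter_flags)) or ".",
                    "recurrent": c.recurrent,
                    "clustered": c.clustered,
                    "shared_group": -1 if c.shared_group is None else c.shared_group,
                    "curation": c.curation_verdict or ".",
                }
            )
        return pd.DataFrame(rows)


def screen_all_trios(
    table: SiteTable,
    pedigree: Pedigree,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[DnmCandidate], list[DnmCandidate], int]:
    """Scan and per-trio filter every trio; returns (all, survivors, skipped)."""
    all_candidates: list[DnmCandidate] = []
    survivors: list[DnmCandidate] = []
    skipped = 0
    for trio in pedigree.trios():
        cands, n_miss = scan_mendelian_violations(table, trio)
        skipped += n_miss
        all_candidates.extend(cands)
        kept = apply_site_filters(cands, thresholds)
        indels = indel_intervals(table, trio)
        kept = apply_individual_filters(kept, thresholds, indels)
        survivors.extend(kept)
    return all_candidates, survivors, skipped


def run_pipeline(
    table: SiteTable,
    pedigree: Pedigree,
    tracks: dict[str, DepthTrack] | None = None,
    thresholds: FilterThresholds = FilterThresholds(),
    mask: IntervalSet | None = None,
    raw_support: pd.DataFrame | None = None,
    generation_time: float = 2.0,
    assayed: IntervalSet | None = None,
) -> PipelineResult:
    """Run screening, curation, calibration and rate estimation.

    ``mask`` marks excluded/poor-mapping intervals: candidates inside it
    are removed at curation and the same intervals are excluded from the
    callable-genome denominator, keeping the estimate unbiased.
    Per-offspring counts use curated candidates, so the Eq.-level FDR
    term is zero; the curation FDR is reported alongside.
    """
    candidates, survivors, skipped = screen_all_trios(table, pedigree, thresholds)
    survivors = filter_recurrent_and_clustered(survivors, pedigree, thresholds)
    parent_ids = {
        m.id: (m.father, m.mother)
        for m in pedigree.members.values()
        if m.father is not None
    }
    curated, fdr = automated_curation(
        survivors, thresholds, low_mq_mask=mask, raw_support=raw_support,
        parent_ids=parent_ids,
    )

    trios = pedigree.trios()
    callability: dict[str, CallabilityResult] = {}
    fnr: dict[str, FnrEstimate] = {}
    per_offspring: list[RateEstimate] = []
    for trio in trios:
        fnr[trio.child] = estimate_fnr(table, trio, thresholds)
        if tracks is not None:
            callability[trio.child] = count_callable_sites(
                tracks, trio, thresholds, assayed=assayed, mask=mask
            )
    n_by_child: dict[str, int] = {}
    for c in curated:
        n_by_child[c.offspring] = n_by_child.get(c.offspring, 0) + 1
    for trio in trios:
        if trio.child not in callability:
            continue
        cs = callability[trio.child].cs
        f = fnr[trio.child].fnr
        n = n_by_child.get(trio.child, 0)
        per_offspring.append(
            RateEstimate(
                offspring=trio.child,
                n_dnm=n,
                fdr=0.0,
                cs=cs,
                fnr=f,
                mu=per_offspring_rate(n, 0.0, cs, f),
                generation_time_years=generation_time,
            )
        )
    groups = {m.id: m.population for m in pedigree.members.values() if m.population}
    families = {m.id: m.family for m in pedigree.members.values()}
    if per_offspring:
        aggregate, comparison = aggregate_rates(
            per_offspring, groups=groups, generation_time=generation_time,
            clusters=families,
        )
    else:
        aggregate, comparison = (
            RateEstimate("aggregate", 0, 0.0, 1, 0.0, 0.0, None, generation_time),
            None,
        )
    f1_dnms = [c for c in curated if pedigree.offspring_of(c.offspring)]
    transmission = transmission_test(count_f1_transmissions(f1_dnms, table, pedigree))
    return PipelineResult(
        candidates=candidates,
        curated=curated,
        fdr=fdr,
        callability=callability,
        fnr=fnr,
        per_offspring=per_offspring,
        aggregate=aggregate,
        comparison=comparison,
        transmission=transmission,
        n_sites_skipped=skipped,
    )
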