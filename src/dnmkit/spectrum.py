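"""Mutation-spectrum and genomic-context characterization of curated DNMs.

Covers strand-collapsed mutation classes (six classes; transitions are
A:T>G:C and C:G>T:A), strong/weak pairing categories, CpG context and
CpG>TpG calls, CpG-island prediction under the Gardiner-Garden & Frommer
criteria (length >= 200 bp, GC >= 50%, observed/expected CpG >= 0.6),
island classification against gene models, pooled ("zero-inflated")
regional rates, coding-effect annotation, full-sib sharing, read-backed
parent-of-origin phasing and the spectrum statistics battery.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .intervals import IntervalSet
from .io import GeneModel, Genome
from .pedigree import Pedigree, Trio
from .sites import GT, SiteTable

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PAIR = {"A": "A:T", "C": "C:G", "G": "C:G", "T": "A:T"}
#: the six strand-collapsed classes, transitions first
COLLAPSED_CLASSES = (
    "A:T>G:C", "C:G>T:A", "A:T>C:G", "A:T>T:A", "C:G>A:T", "C:G>G:C",
)
TRANSITIONS = frozenset({"A:T>G:C", "C:G>T:A"})


# ---------------------------------------------------------------------------
# mutation classes


@dataclass(frozen=True)
class MutationClass:
    collapsed_class: str
    is_transition: bool
    sw_category: str
    cpg_context: str  # "CpG" | "nonCpG"
    is_cpg_to_tpg: bool


def classify_mutation(
    ref: str,
    alt: str,
    prev_base: str | None = None,
    next_base: str | None = None,
) -> MutationClass:
    """Strand-collapsed class of a single-base substitution.

    CpG context means the reference C is followed by G (or, equivalently
    on the other strand, the reference G is preceded by C); a missing
    neighbour at a contig edge counts as non-CpG.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt or ref not in COMPLEMENT or alt not in COMPLEMENT:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    if ref in "AC":
        r, a = ref, alt
    else:
        r, a = COMPLEMENT[ref], COMPLEMENT[alt]
    # alt side written as the base pair led by the collapsed alt base,
    # e.g. C>T -> C:G>T:A, A>G -> A:T>G:C
    collapsed = f"{_PAIR[r]}>{a}:{COMPLEMENT[a]}"
    sw = f"{'S' if r in 'CG' else 'W'}>{'S' if a in 'CG' else 'W'}"
    prev_base = (prev_base or "").upper()
    next_base = (next_base or "").upper()
    in_cpg = (ref == "C" and next_base == "G") or (ref == "G" and prev_base == "C")
    cpg_to_tpg = (ref == "C" and alt == "T" and next_base == "G") or (
        ref == "G" and alt == "A" and prev_base == "C"
    )
    return MutationClass(
        collapsed_class=collapsed,
        is_transition=collapsed in TRANSITIONS,
        sw_category=sw,
        cpg_context="CpG" if in_cpg else "nonCpG",
        is_cpg_to_tpg=cpg_to_tpg,
    )


def classify_candidate(c, genome: Genome) -> MutationClass:
    """Classify a candidate using its reference context."""
    seq = genome.sequences[c.chrom]
    prev_base = seq[c.pos - 1] if c.pos > 0 else None
    next_base = seq[c.pos + 1] if c.pos + 1 < len(seq) else None
    return classify_mutation(c.ref, c.alt, prev_base, next_base)


def cpg_site_mask(seq: str) -> np.ndarray:
    """Boolean mask of positions that are part of a CpG dinucleotide."""
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    c, g = arr == b"C", arr == b"G"
    cpg_start = np.zeros(len(arr), dtype=bool)
    cpg_start[:-1] = c[:-1] & g[1:]
    mask = cpg_start.copy()
    mask[1:] |= cpg_start[:-1]  # the G of each CpG
    return mask


# ---------------------------------------------------------------------------
# CpG islands


@dataclass
class CpgIsland:
    chrom: str
    start: int  # 0-based half-open
    end: int
    gc_fraction: float
    obs_exp_cpg: float
    cgi_class: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def _interval_stats(cum_gc, cum_c, cum_g, cum_cpg, s, e):
    L = e - s
    n_gc = cum_gc[e] - cum_gc[s]
    n_c = cum_c[e] - cum_c[s]
    n_g = cum_g[e] - cum_g[s]
    n_cpg = cum_cpg[max(e - 1, s)] - cum_cpg[s]
    gc = n_gc / L
    obs_exp = (n_cpg * L / (n_c * n_g)) if n_c and n_g else 0.0
    return gc, obs_exp


def predict_cgi(
    genome: Genome | str,
    min_length: int = 200,
    min_gc: float = 0.5,
    min_obs_exp: float = 0.6,
    step: int = 1,
    chrom: str | None = None,
    edge_window: int = 50,
) -> list[CpgIsland]:
    """Predict CpG islands by the sliding-seed criteria.

    Seed windows of ``min_length`` bp (advanced by ``step``) that satisfy
    all three criteria are merged when overlapping; merged intervals are
    re-tested and their ends trimmed base-by-base until the interval
    passes (intervals shrinking below ``min_length`` are dropped).
    Because window averaging blurs boundaries by up to a window length,
    ends are then refined: bases are trimmed while the terminal
    ``edge_window`` bp fail the GC criterion locally.
    """
    if isinstance(genome, str):
        genome = Genome({chrom or "seq": genome})
    islands: list[CpgIsland] = []
    for name, seq in genome.sequences.items():
        n = len(seq)
        if n < min_length:
            continue
        arr = np.frombuffer(seq.upper().encode(), dtype="S1")
        c, g = arr == b"C", arr == b"G"
        gc = c | g
        cpg = np.zeros(n, dtype=bool)
        cpg[:-1] = c[:-1] & g[1:]
        cum_gc = np.concatenate([[0], np.cumsum(gc)])
        cum_c = np.concatenate([[0], np.cumsum(c)])
        cum_g = np.concatenate([[0], np.cumsum(g)])
        cum_cpg = np.concatenate([[0], np.cumsum(cpg)])
        w = min_length
        starts = np.arange(0, n - w + 1, step)
        n_gc = cum_gc[starts + w] - cum_gc[starts]
        n_c = cum_c[starts + w] - cum_c[starts]
        n_g = cum_g[starts + w] - cum_g[starts]
        n_cpg = cum_cpg[starts + w - 1] - cum_cpg[starts]
        with np.errstate(divide="ignore", invalid="ignore"):
            obs_exp = np.where(n_c * n_g > 0, n_cpg * w / np.maximum(n_c * n_g, 1), 0.0)
        passing = (n_gc / w >= min_gc) & (obs_exp >= min_obs_exp)
        idx = np.flatnonzero(passing)
        if not len(idx):
            continue
        # merge overlapping passing windows
        merged: list[list[int]] = []
        for i in idx:
            s, e = int(starts[i]), int(starts[i]) + w
            if merged and s <= merged[-1][1]:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            gc_f, oe = _interval_stats(cum_gc, cum_c, cum_g, cum_cpg, s, e)
            # trim failing merged intervals back to a passing core
            while (gc_f < min_gc or oe < min_obs_exp) and e - s > min_length:
                gc_l, oe_l = _interval_stats(cum_gc, cum_c, cum_g, cum_cpg, s + 1, e)
                gc_r, oe_r = _interval_stats(cum_gc, cum_c, cum_g, cum_cpg, s, e - 1)
                if (gc_l >= min_gc and oe_l >= min_obs_exp) or (
                    min(gc_l / min_gc, oe_l / min_obs_exp)
                    >= min(gc_r / min_gc, oe_r / min_obs_exp)
                ):
                    s += 1
                    gc_f, oe = gc_l, oe_l
                else:
                    e -= 1
                    gc_f, oe = gc_r, oe_r
            # Boundary refinement: window averaging blurs edges by up to a
            # window length, so snap to the maximal-scoring subsegment of
            # per-base CpG score (+1 per CpG start, constant penalty per
            # base). The penalty sits halfway to the minimum CpG-start
            # density an island can have under the criteria, so the
            # segment tracks the CpG-dense core.
            penalty = 0.5 * min_obs_exp * (min_gc / 2) ** 2
            s2, e2 = _max_scoring_segment(cum_cpg, s, e, penalty)
            # the score marks CpG starts; include the G of a terminal CpG
            if e2 < n and cum_cpg[e2] - cum_cpg[e2 - 1] > 0:
                e2 += 1
            if e2 - s2 >= min_length:
                s, e = s2, e2
            gc_f, oe = _interval_stats(cum_gc, cum_c, cum_g, cum_cpg, s, e)
            if gc_f >= min_gc and oe >= min_obs_exp and e - s >= min_length:
                islands.append(CpgIsland(name, s, e, float(gc_f), float(oe)))
    return islands


def _max_scoring_segment(
    cum_cpg: np.ndarray, s: int, e: int, penalty: float
) -> tuple[int, int]:
    """Kadane scan for the best-scoring subsegment of [s, e)."""
    score = np.diff(cum_cpg[s : e + 1]).astype(float) - penalty
    best_sum = cur_sum = 0.0
    best = (s, s)
    cur_start = 0
    for i, v in enumerate(score):
        cur_sum += v
        if cur_sum <= 0:
            cur_sum = 0.0
            cur_start = i + 1
        elif cur_sum > best_sum:
            best_sum = cur_sum
            best = (s + cur_start, s + i + 1)
    return best


def islands_to_intervals(islands: Iterable[CpgIsland]) -> IntervalSet:
    return IntervalSet.from_tuples((i.chrom, i.start, i.end) for i in islands)


def classify_cgi(
    islands: Sequence[CpgIsland], genes: Sequence[GeneModel]
) -> list[CpgIsland]:
    """Assign each island one of TSS > TTS > intragenic > intergenic.

    TSS/TTS when the island contains the annotated transcription start or
    termination base of any gene; intragenic when it overlaps a gene body
    otherwise; intergenic else.
    """
    for isl in islands:
        cls = "intergenic"
        for g in genes:
            if g.chrom != isl.chrom:
                continue
            if isl.start <= g.tss < isl.end:
                cls = "TSS"
                break
            if isl.start <= g.tts < isl.end:
                cls = "TTS"  # keep scanning: TSS of another gene outranks
                continue
            if cls == "intergenic" and g.start < isl.end and isl.start < g.end:
                cls = "intragenic"
        isl.cgi_class = cls
    return list(islands)


# ---------------------------------------------------------------------------
# regional rates (pooled / "zero-inflated")


def region_rate(n_dnms: float, mean_region_length: float, n_offspring: int) -> float:
    """Pooled regional rate n / (2 * mean length * N offspring).

    Robust to most offspring carrying zero mutations in a small region:
    counts and callable lengths are summed over offspring before dividing.
    """
    if mean_region_length <= 0 or n_offspring <= 0:
        raise ValueError("region length and offspring count must be positive")
    if n_dnms < 0:
        raise ValueError("negative mutation count")
    return n_dnms / (2.0 * mean_region_length * n_offspring)


def pooled_region_rate(n_dnms: float, summed_region_length: float) -> float:
    """Same estimator parameterized by the summed per-offspring length."""
    if summed_region_length <= 0:
        raise ValueError("summed region length must be positive")
    return n_dnms / (2.0 * summed_region_length)


# ---------------------------------------------------------------------------
# genomic-region / coding-effect annotation


class AnnotationError(ValueError):
    """Gene model and reference disagree; the mutation is unresolvable."""


@dataclass(frozen=True)
class RegionAnnotation:
    region: str  # intergenic | intron | exon_CDS | UTR
    effect: str | None = None  # synonymous | nonsynonymous | splice
    gene: str | None = None


def annotate_region(
    dnm, genes: Sequence[GeneModel], genome: Genome, splice_window: int = 2
) -> RegionAnnotation:
    """Locate a mutation and, for CDS hits, its in-frame coding effect.

    Intronic positions within ``splice_window`` bp of an exon boundary are
    flagged as splice. Codon lookup is strand-aware; a CDS whose stored
    reference disagrees with the genome raises :class:`AnnotationError`.
    """
    chrom, pos = dnm.chrom, dnm.pos
    for g in genes:
        if g.chrom != chrom or not g.start <= pos < g.end:
            continue
        for s, e, _ in g.cds:
            if s <= pos < e:
                effect = _coding_effect(dnm, g, genome)
                return RegionAnnotation("exon_CDS", effect, g.id)
        for s, e in g.exons:
            if s <= pos < e:
                return RegionAnnotation("UTR", None, g.id)
        for s, e in g.introns():
            if s <= pos < e:
                effect = "splice" if (pos - s < splice_window or e - pos <= splice_window) else None
                return RegionAnnotation("intron", effect, g.id)
        return RegionAnnotation("intron", None, g.id)
    return RegionAnnotation("intergenic")


def _coding_effect(dnm, gene: GeneModel, genome: Genome) -> str:
    segments = sorted(gene.cds)
    cds_seq = "".join(genome.fetch(gene.chrom, s, e) for s, e, _ in segments)
    if len(cds_seq) % 3 != 0:
        raise AnnotationError(f"CDS length of {gene.id} not divisible by 3")
    offset = 0
    cds_pos = None
    for s, e, _ in segments:
        if s <= dnm.pos < e:
            cds_pos = offset + (dnm.pos - s)
            break
        offset += e - s
    assert cds_pos is not None
    if cds_seq[cds_pos].upper() != dnm.ref.upper():
        raise AnnotationError(
            f"reference mismatch in {gene.id} at {dnm.chrom}:{dnm.pos}"
        )
    mutated = cds_seq[:cds_pos] + dnm.alt + cds_seq[cds_pos + 1 :]
    if gene.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
        mutated = str(Seq(mutated).reverse_complement())
    aa_ref = str(Seq(cds_seq).translate())
    aa_alt = str(Seq(mutated).translate())
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


# ---------------------------------------------------------------------------
# full-sib sharing


@dataclass(frozen=True)
class SharedResult:
    n_unique: int
    n_shared: int
    groups: tuple[tuple[tuple[str, int, str], tuple[str, ...]], ...]
    spectrum_chi2: float | None = None
    spectrum_p: float | None = None

    @property
    def shared_fraction(self) -> float:
        return self.n_shared / self.n_unique if self.n_unique else 0.0


def detect_shared(
    candidates: Sequence, pedigree: Pedigree, genome: Genome | None = None
) -> SharedResult:
    """Group identical candidates among full sibs; compare spectra.

    The shared fraction counts each sib-shared mutation once:
    shared unique mutations / total unique mutations. With a reference
    genome the shared and non-shared class spectra are compared by
    chi-square over the six collapsed classes (skipped when expected
    counts are degenerate).
    """
    by_key: dict[tuple, list] = {}
    for c in candidates:
        by_key.setdefault((c.chrom, c.pos, c.alt), []).append(c)
    groups = []
    shared_keys = set()
    for key, group in by_key.items():
        carriers = sorted({c.offspring for c in group})
        if len(carriers) >= 2 and all(
            pedigree.are_full_sibs(a, b)
            for i, a in enumerate(carriers)
            for b in carriers[i + 1 :]
        ):
            groups.append((key, tuple(carriers)))
            shared_keys.add(key)
    n_unique = len(by_key)
    chi2 = p = None
    if genome is not None and shared_keys and len(by_key) > len(shared_keys):
        shared_counts = Counter()
        other_counts = Counter()
        for key, group in by_key.items():
            cls = classify_candidate(group[0], genome).collapsed_class
            (shared_counts if key in shared_keys else other_counts)[cls] += 1
        obs = np.array(
            [
                [shared_counts.get(k, 0) for k in COLLAPSED_CLASSES],
                [other_counts.get(k, 0) for k in COLLAPSED_CLASSES],
            ]
        )
        obs = obs[:, obs.sum(axis=0) > 0]
        if obs.shape[1] >= 2:
            res = stats.chi2_contingency(obs)
            chi2, p = float(res.statistic), float(res.pvalue)
    return SharedResult(
        n_unique=n_unique,
        n_shared=len(shared_keys),
        groups=tuple(sorted(groups)),
        spectrum_chi2=chi2,
        spectrum_p=p,
    )


# ---------------------------------------------------------------------------
# parent-of-origin phasing


@dataclass(frozen=True)
class PhasingResult:
    dnm_key: tuple[str, int, str]
    offspring: str
    origin: str  # paternal | maternal | unknown
    supporting_reads: int
    informative_site: int | None = None


def _allele_set(gt_code: int, ref: str, alt: str) -> set[str] | None:
    if gt_code == GT.HOM_REF:
        return {ref}
    if gt_code == GT.HET:
        return {ref, alt}
    if gt_code == GT.HOM_ALT:
        return {alt}
    return None


def phase_parent_of_origin(
    dnm,
    reads: pd.DataFrame,
    table: SiteTable,
    trio: Trio,
) -> PhasingResult:
    """Read-backed parent-of-origin of one de novo mutation.

    Reads carrying the de novo allele are followed to flanking sites
    where the offspring is heterozygous and the observed allele occurs in
    exactly one parent's genotype. Any conflict between informative reads
    yields ``unknown`` (strict policy); so does absence of informative
    reads.
    """
    key = (dnm.chrom, dnm.pos, dnm.alt)
    sub = reads[(reads["sample"] == trio.child) & (reads["chrom"] == dnm.chrom)]
    carrier_reads = set(
        sub[(sub["pos"] == dnm.pos) & (sub["allele"] == dnm.de_novo_allele)]["read_id"]
    )
    if not carrier_reads:
        return PhasingResult(key, trio.child, "unknown", 0)
    flank = sub[sub["read_id"].isin(carrier_reads) & (sub["pos"] != dnm.pos)]
    jf = table.sample_index(trio.father)
    jm = table.sample_index(trio.mother)
    jc = table.sample_index(trio.child)
    cid = table.chrom_names.index(dnm.chrom)
    votes: dict[str, int] = {"paternal": 0, "maternal": 0}
    used_site = None
    for r in flank.itertuples():
        hits = np.flatnonzero((table.chrom_id == cid) & (table.pos == int(r.pos)))
        if not len(hits):
            continue
        row = int(hits[0])
        if table.gt[row, jc] != GT.HET:
            continue
        ref, alt = table.ref[row], table.alt[row]
        f_set = _allele_set(int(table.gt[row, jf]), ref, alt)
        m_set = _allele_set(int(table.gt[row, jm]), ref, alt)
        if f_set is None or m_set is None:
            continue
        allele = r.allele
        in_f, in_m = allele in f_set, allele in m_set
        if in_f == in_m:
            continue  # not attributable to one parent
        votes["paternal" if in_f else "maternal"] += 1
        used_site = int(r.pos)
    if votes["paternal"] and votes["maternal"]:
        return PhasingResult(key, trio.child, "unknown", 0)
    for origin in ("paternal", "maternal"):
        if votes[origin]:
            return PhasingResult(key, trio.child, origin, votes[origin], used_site)
    return PhasingResult(key, trio.child, "unknown", 0)


def alpha(results: Iterable[PhasingResult]) -> float:
    """Male-to-female mutation ratio over resolved DNMs."""
    n_pat = sum(1 for r in results if r.origin == "paternal")
    n_mat = sum(1 for r in results if r.origin == "maternal")
    if n_mat == 0:
        raise ValueError("no maternally phased mutations; alpha undefined")
    return n_pat / n_mat


# ---------------------------------------------------------------------------
# spectrum statistics


def ts_tv_test(n_ts: int, n_tv: int) -> tuple[float, float, float]:
    """(ratio, chi2, p) of transition:transversion counts vs the 1:2 null.

    The null is a uniform distribution over the six collapsed classes,
    two of which are transitions.
    """
    total = n_ts + n_tv
    if total == 0:
        raise ValueError("no mutations")
    res = stats.chisquare([n_ts, n_tv], f_exp=[total / 3.0, 2.0 * total / 3.0])
    ratio = n_ts / n_tv if n_tv else float("inf")
    return ratio, float(res.statistic), float(res.pvalue)


def sw_rate_tests(
    rates_by_category: Mapping[str, Sequence[float]]
) -> dict:
    """Kruskal-Wallis across S/W categories with pairwise rank-sum tests."""
    cats = sorted(c for c, v in rates_by_category.items() if len(v) > 0)
    if len(cats) < 2:
        return {"skipped": "fewer than two non-empty categories"}
    groups = [np.asarray(rates_by_category[c], dtype=float) for c in cats]
    if np.ptp(np.concatenate(groups)) == 0:  # all values tied
        kw_stat, kw_p = 0.0, 1.0
    else:
        kw = stats.kruskal(*groups)
        kw_stat, kw_p = float(kw.statistic), float(kw.pvalue)
    pairwise = {}
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            x, y = rates_by_category[a], rates_by_category[b]
            if np.ptp(np.concatenate([x, y])) == 0:
                pairwise[(a, b)] = (0.0, 1.0)
            else:
                res = stats.ranksums(x, y)
                pairwise[(a, b)] = (float(res.statistic), float(res.pvalue))
    return {"kruskal": (kw_stat, kw_p), "pairwise": pairwise}


def cpg_island_test(
    count_inside: int, count_outside: int, sites_inside: float, sites_outside: float
) -> tuple[float, float]:
    """Chi-square of CpG>TpG counts inside vs outside islands.

    The expectation is proportional to the callable CpG site counts in
    each compartment.
    """
    total = count_inside + count_outside
    if total == 0 or sites_inside <= 0 or sites_outside <= 0:
        raise ValueError("degenerate inputs")
    frac = sites_inside / (sites_inside + sites_outside)
    res = stats.chisquare(
        [count_inside, count_outside], f_exp=[total * frac, total * (1 - frac)]
    )
    return float(res.statistic), float(res.pvalue)
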