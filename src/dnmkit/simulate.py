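"""Synthetic pedigree datasets with known truth.

Generates a toy reference genome (CpG-depleted background, planted
CpG islands, valid gene models), 2- or 3-generation pedigrees, founder
diversity, planted germline mutations (with parental mosaicism, a CpG
rate elevation and parent-of-origin), and per-sample genotype evidence
(depth, allelic depths, genotype qualities, caller INFO annotations,
somatic/artifact false positives, under-genotyped parental carriers and
phase-informative read observations). Every downstream stage of the
pipeline is testable against the returned truth without any download.

Defaults state the study conditions this generator emulates: 50x target
coverage, clutches of 10 full sibs, a per-generation single-nucleotide
mutation rate of 4.56e-9/bp, ~60% paternal mutations, and founder
nucleotide diversity of 4e-3.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .intervals import DepthTrack, IntervalSet
from .io import GeneModel, Genome
from .pedigree import Member, Pedigree
from .sites import GT, SiteTable

BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")

TWO_GEN = "two_gen"
THREE_GEN_INBRED = "three_gen_inbred"
THREE_GEN_OUTBRED = "three_gen_outbred"
PEDIGREE_TYPES = (TWO_GEN, THREE_GEN_INBRED, THREE_GEN_OUTBRED)


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the simulated world; defaults are the emulated study design."""

    # genome
    genome_length: int = 5_000_000  # total over chromosomes
    n_chroms: int = 2
    gc_content: float = 0.42
    cgi_density_per_mb: float = 8.0
    cgi_length_mean: float = 700.0
    genes_per_mb: float = 8.0
    # pedigree
    n_families: int = 2
    pedigree_type: str = TWO_GEN
    sibs_per_clutch: int = 10
    # mutation process
    true_mu: float = 4.56e-9
    mosaic_fraction: float = 0.2
    mosaic_transmission_prob: float = 0.5
    paternal_fraction: float = 0.6
    cpg_rate_multiplier: float = 3.4
    # founder diversity
    pi: float = 0.004
    allele_freq_low: float = 0.05
    allele_freq_high: float = 0.95
    # evidence / error model
    depth_mean: float = 50.0
    depth_shape: float = 25.0  # gamma shape of 1 kb window means (NB mixing)
    depth_window: int = 1000
    gq_low_prob: float = 0.005
    gq_low_range: tuple[int, int] = (30, 95)
    hom_ref_error: float = 2e-4  # specific-allele error reads in clean homozygotes
    fp_rate: float = 1e-7  # somatic/artifact het per bp per offspring
    fp_hard_filter_fraction: float = 0.5
    fp_gq_low_prob: float = 0.6
    fp_masked_fraction: float = 0.3
    fp_near_indel_fraction: float = 0.1
    fp_somatic_beta: tuple[float, float] = (1.5, 8.0)
    parental_contamination_rate: float = 1e-7  # per bp per trio
    contamination_raw_fraction: float = 0.35
    contamination_detected_prob: float = 0.2
    decoy_indels_per_mb: float = 2.0
    mask_fraction: float = 0.01
    invariant_fraction: float = 0.001
    # phasing evidence
    informative_read_rate: float = 0.7
    reads_per_dnm: int = 8
    read_span: int = 300
    #: draw allelic depths at the exact expected balance instead of
    #: binomially (noise-free oracle runs only)
    exact_allele_balance: bool = False

    def __post_init__(self) -> None:
        for name in (
            "mosaic_fraction", "mosaic_transmission_prob", "paternal_fraction",
            "fp_hard_filter_fraction", "fp_masked_fraction", "mask_fraction",
            "invariant_fraction", "informative_read_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.true_mu < 0:
            raise ValueError("true_mu must be >= 0")
        if self.sibs_per_clutch < 1:
            raise ValueError("sibs_per_clutch must be >= 1")
        if self.pedigree_type not in PEDIGREE_TYPES:
            raise ValueError(f"pedigree_type must be one of {PEDIGREE_TYPES}")

    def noise_free(self) -> "SimConfig":
        """Variant without artifacts or quality noise (for oracle tests)."""
        return replace(
            self,
            gq_low_prob=0.0,
            hom_ref_error=0.0,
            fp_rate=0.0,
            parental_contamination_rate=0.0,
            mask_fraction=0.0,
            decoy_indels_per_mb=0.0,
            depth_shape=1e9,  # effectively uniform coverage
            exact_allele_balance=True,
        )


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    dnms: pd.DataFrame  # offspring, chrom, pos, ref, alt, parent_of_origin, mosaic_group
    fp_sites: pd.DataFrame  # offspring, chrom, pos, ref, alt, kind
    mask: IntervalSet
    transmissions: pd.DataFrame  # f1, chrom, pos, f2, transmitted
    true_mu: float


# ---------------------------------------------------------------------------
# genome


_CPG_DEPLETION = 0.9  # fraction of background CpG dinucleotides rewritten


def _markov_background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """Random sequence with target GC and strong CpG depletion (obs/exp ~ 0.1).

    Methylated vertebrate genomes are CpG-poor outside islands; without
    this depletion chance windows would satisfy the island criteria.
    """
    # compensate for the G->A/T rewrites below so the final GC hits target
    q = gc + _CPG_DEPLETION * (gc / 2) ** 2 * 2
    p = np.array([(1 - q) / 2, q / 2, q / 2, (1 - q) / 2])
    arr = rng.choice(BASES, size=n, p=p)
    c_then_g = np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G")) + 1
    rewrite = c_then_g[rng.random(len(c_then_g)) < _CPG_DEPLETION]
    arr[rewrite] = rng.choice(np.array([b"A", b"T"], dtype="S1"), size=len(rewrite))
    return arr


def _cgi_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    p = np.array([0.175, 0.325, 0.325, 0.175])
    return rng.choice(BASES, size=n, p=p)


_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = np.array(
    [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS]
)


def _codon_weights(gc: float) -> np.ndarray:
    """Background-composition codon weights with CpG-containing codons rare."""
    p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "C": gc / 2, "G": gc / 2}
    w = np.array(
        [
            p[c[0]] * p[c[1]] * p[c[2]] * ((1 - _CPG_DEPLETION) if "CG" in c else 1.0)
            for c in _CODONS
        ]
    )
    return w / w.sum()


def _design_gene(
    rng: np.random.Generator, gc: float = 0.42
) -> tuple[str, list[tuple[int, int]], list[int]]:
    """Design a transcript: (sequence, exon spans, CDS lengths per exon).

    Layout in transcript orientation: 60 bp 5'UTR + CDS split across
    exons with introns between + 60 bp 3'UTR. The CDS translates without
    internal stops by construction; all parts keep the CpG-depleted
    background composition so genes do not mimic CpG islands.
    """
    n_exons = int(rng.integers(2, 5))
    n_codons = int(rng.integers(80, 200))
    # sample codons sequentially, suppressing CpGs across codon junctions
    # as well as inside codons so CDS keeps the background's CpG depletion
    w_base = _codon_weights(gc)
    starts_g = np.array([c[0] == "G" for c in _CODONS])
    w_after_c = w_base * np.where(starts_g, 1 - _CPG_DEPLETION, 1.0)
    w_after_c /= w_after_c.sum()
    parts = ["ATG"]
    for _ in range(n_codons - 2):
        w = w_after_c if parts[-1][-1] == "C" else w_base
        parts.append(str(rng.choice(_CODONS, p=w)))
    parts.append("TAA")
    cds = "".join(parts)
    cuts = np.sort(rng.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False))
    chunks = np.split(np.arange(len(cds)), cuts)
    cds_lens = [len(ch) for ch in chunks]
    utr = lambda: _markov_background(rng, 60, gc).tobytes().decode()
    introns = [
        _markov_background(rng, int(rng.integers(200, 600)), gc).tobytes().decode()
        for _ in range(n_exons - 1)
    ]
    seq_parts = []
    exon_spans = []
    pos = 0
    cds_done = 0
    for i, clen in enumerate(cds_lens):
        exon_seq = ""
        if i == 0:
            exon_seq += utr()
        exon_seq += cds[cds_done : cds_done + clen]
        cds_done += clen
        if i == n_exons - 1:
            exon_seq += utr()
        exon_spans.append((pos, pos + len(exon_seq)))
        seq_parts.append(exon_seq)
        pos += len(exon_seq)
        if i < n_exons - 1:
            seq_parts.append(introns[i])
            pos += len(introns[i])
    return "".join(seq_parts), exon_spans, cds_lens


_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp(s: str) -> str:
    return s.upper().translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_genome(
    config: SimConfig, seed: int | np.random.SeedSequence
) -> tuple[Genome, list[GeneModel], IntervalSet]:
    """Generate (reference, gene models, true CpG-island intervals).

    Island segments satisfy the prediction criteria by construction
    (high-GC, CpG-rich composition); the background is CpG-depleted like
    a methylated vertebrate genome, so islands are the only segments
    expected to pass. Gene CDS are valid (start/stop codon, length
    divisible by 3, no internal stop); islands never overwrite CDS.
    """
    if config.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb")
    rng = np.random.default_rng(seed)
    chrom_len = config.genome_length // config.n_chroms
    sequences: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    cgi_tuples: list[tuple[str, int, int]] = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        arr = _markov_background(rng, chrom_len, config.gc_content)
        # --- genes ---
        n_genes = rng.poisson(config.genes_per_mb * chrom_len / 1e6)
        cursor = int(rng.integers(500, 3000))
        gi = 0
        while gi < n_genes and cursor < chrom_len - 6000:
            seq, exon_spans, cds_lens = _design_gene(rng, config.gc_content)
            strand = "+" if rng.random() < 0.5 else "-"
            start = cursor
            end = start + len(seq)
            if end > chrom_len - 500:
                break
            gseq = seq if strand == "+" else _revcomp(seq)
            arr[start:end] = np.frombuffer(gseq.upper().encode(), dtype="S1")
            exons = []
            cds = []
            offset = 0
            utr5 = 60
            cds_done = 0
            for i, (es, ee) in enumerate(exon_spans):
                clen = cds_lens[i]
                cs = es + (utr5 if i == 0 else 0)
                ce = cs + clen
                phase = (3 - cds_done % 3) % 3
                cds_done += clen
                exons.append((es, ee))
                cds.append((cs, ce, phase))
            if strand == "-":
                L = len(seq)
                exons = [(L - ee, L - es) for es, ee in exons][::-1]
                cds = [(L - ce, L - cs, ph) for cs, ce, ph in cds][::-1]
            exons = [(start + s, start + e) for s, e in exons]
            cds = [(start + s, start + e, ph) for s, e, ph in cds]
            genes.append(
                GeneModel(
                    id=f"{chrom}_g{gi + 1}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    exons=exons,
                    cds=cds,
                )
            )
            gi += 1
            cursor = end + int(rng.integers(2000, 12000))
        # --- CpG islands ---
        forbidden = IntervalSet.from_tuples(
            (chrom, max(0, s - 10), e + 10) for g in genes if g.chrom == chrom for s, e, _ in g.cds
        )
        placed = IntervalSet({})
        n_cgi = rng.poisson(config.cgi_density_per_mb * chrom_len / 1e6)
        chrom_genes = [g for g in genes if g.chrom == chrom]
        for k in range(n_cgi):
            L = int(np.clip(rng.gamma(4.0, config.cgi_length_mean / 4.0), 250, 4000))
            target = rng.random()
            if target < 0.5 and chrom_genes:  # aim at TSS/TTS for class variety
                g = chrom_genes[int(rng.integers(len(chrom_genes)))]
                anchor = g.tss if target < 0.25 else g.tts
                inward = 45 if (g.strand == "+") == (target < 0.25) else -44
                if inward > 0:
                    s = anchor + inward - L
                else:
                    s = anchor + inward
                s = max(0, min(s, chrom_len - L))
            else:
                s = int(rng.integers(0, chrom_len - L))
            e = s + L
            span = IntervalSet({chrom: np.array([[s, e]])})
            if span.intersect(forbidden).total_length() or span.intersect(placed).total_length():
                continue
            arr[s:e] = _cgi_sequence(rng, L)
            cgi_tuples.append((chrom, s, e))
            placed = IntervalSet.from_tuples(placed.to_tuples() + [(chrom, s, e)])
        sequences[chrom] = arr
    genome = Genome({c: a.tobytes().decode() for c, a in sequences.items()})
    return genome, genes, IntervalSet.from_tuples(cgi_tuples)


# ---------------------------------------------------------------------------
# pedigree construction


def build_pedigree(config: SimConfig) -> Pedigree:
    """Families of the configured design, populations alternating by family."""
    members: list[Member] = []
    for fi in range(config.n_families):
        fam = f"fam{fi + 1}"
        pop = "pop1" if fi % 2 == 0 else "pop2"
        S = config.sibs_per_clutch

        def add(mid, sex, father, mother, gen):
            members.append(Member(f"{fam}_{mid}", fam, sex, father and f"{fam}_{father}",
                                  mother and f"{fam}_{mother}", gen, pop))

        if config.pedigree_type == TWO_GEN:
            add("F0f", 1, None, None, "F0")
            add("F0m", 2, None, None, "F0")
            for i in range(S):
                add(f"F1s{i + 1:02d}", 1 if i % 2 == 0 else 2, "F0f", "F0m", "F1")
        elif config.pedigree_type == THREE_GEN_INBRED:
            add("F0f", 1, None, None, "F0")
            add("F0m", 2, None, None, "F0")
            add("F1f", 1, "F0f", "F0m", "F1")
            add("F1m", 2, "F0f", "F0m", "F1")
            for i in range(S):
                add(f"F2s{i + 1:02d}", 1 if i % 2 == 0 else 2, "F1f", "F1m", "F2")
        else:  # three_gen_outbred: two founder pairs, one F1 from each
            add("F0f1", 1, None, None, "F0")
            add("F0m1", 2, None, None, "F0")
            add("F0f2", 1, None, None, "F0")
            add("F0m2", 2, None, None, "F0")
            add("F1f", 1, "F0f1", "F0m1", "F1")
            add("F1m", 2, "F0f2", "F0m2", "F1")
            for i in range(S):
                add(f"F2s{i + 1:02d}", 1 if i % 2 == 0 else 2, "F1f", "F1m", "F2")
    return Pedigree(members)


# ---------------------------------------------------------------------------
# pedigree genotypes + planted mutations


class _PanelSim:
    """Founder diversity panel and Mendelian transmission bookkeeping."""

    def __init__(self, config, genome, pedigree, rng):
        self.config = config
        self.genome = genome
        self.pedigree = pedigree
        lengths = genome.lengths()
        self.chrom_names = list(lengths)
        self.chrom_len = np.array([lengths[c] for c in self.chrom_names])
        total = int(self.chrom_len.sum())
        # mean heterozygosity per segregating site under uniform frequencies
        lo, hi = config.allele_freq_low, config.allele_freq_high
        f_mean_het = 2 * (0.5 - ((hi - lo) ** 2 / 12 + 0.25))
        n_sites = rng.poisson(config.pi / f_mean_het * total)
        flat = np.sort(rng.choice(total, size=min(n_sites, total // 3), replace=False))
        self.chrom_id = np.searchsorted(np.cumsum(self.chrom_len), flat, side="right")
        offs = np.concatenate([[0], np.cumsum(self.chrom_len)[:-1]])
        self.pos = flat - offs[self.chrom_id]
        self.freq = rng.uniform(lo, hi, size=len(flat))
        self.ref = np.array(
            [genome.base_at(self.chrom_names[c], p) for c, p in zip(self.chrom_id, self.pos)],
            dtype=object,
        )
        alt_choice = rng.integers(0, 3, size=len(flat))
        self.alt = np.empty(len(flat), dtype=object)
        for i, (r, k) in enumerate(zip(self.ref, alt_choice)):
            others = [b for b in "ACGT" if b != r]
            self.alt[i] = others[k]
        self.samples = pedigree.sample_ids
        self.gt = np.zeros((len(flat), len(self.samples)), dtype=np.int8)
        self.from_father = np.zeros_like(self.gt)
        self.from_mother = np.zeros_like(self.gt)
        self._fill(rng)

    def _fill(self, rng):
        idx = {s: j for j, s in enumerate(self.samples)}
        done: set[str] = set()
        pending = list(self.pedigree.members.values())
        n = len(self.pos)
        while pending:
            rest = []
            for m in pending:
                if m.is_founder:
                    self.gt[:, idx[m.id]] = rng.binomial(2, self.freq).astype(np.int8)
                    done.add(m.id)
                elif m.father in done and m.mother in done:
                    for parent, out in ((m.father, self.from_father), (m.mother, self.from_mother)):
                        pg = self.gt[:, idx[parent]]
                        allele = np.where(
                            pg == 2, 1, np.where(pg == 1, rng.random(n) < 0.5, 0)
                        ).astype(np.int8)
                        out[:, idx[m.id]] = allele
                    self.gt[:, idx[m.id]] = (
                        self.from_father[:, idx[m.id]] + self.from_mother[:, idx[m.id]]
                    )
                    done.add(m.id)
                else:
                    rest.append(m)
            pending = rest


def simulate_pedigree(
    config: SimConfig,
    genome: Genome,
    seed: int | np.random.SeedSequence,
    pedigree: Pedigree | None = None,
) -> tuple[Pedigree, "_PanelSim", SimTruth]:
    """Simulate founder diversity, transmission and planted mutations.

    Mutations are planted per offspring per parental side at the
    configured rate, positions weighted so CpG sites mutate at
    ``cpg_rate_multiplier`` times the non-CpG rate while the genome-wide
    average stays ``true_mu``. A fraction ``mosaic_fraction`` of planted
    events is early-embryonic: shared across the clutch with independent
    per-sib transmission (event counts are scaled so the marginal
    per-offspring rate is preserved). F1 mutations transmit to each F2
    offspring with probability 0.5.
    """
    rng = np.random.default_rng(seed)
    if pedigree is None:
        pedigree = build_pedigree(config)
    panel = _PanelSim(config, genome, pedigree, rng)

    from .spectrum import cpg_site_mask

    cpg_positions = {}
    noncpg_positions = {}
    for chrom, seq in genome.sequences.items():
        mask = cpg_site_mask(seq)
        cpg_positions[chrom] = np.flatnonzero(mask)
        noncpg_positions[chrom] = np.flatnonzero(~mask)
    n_cpg = sum(len(v) for v in cpg_positions.values())
    n_non = sum(len(v) for v in noncpg_positions.values())
    w_cpg = config.cpg_rate_multiplier * n_cpg / (config.cpg_rate_multiplier * n_cpg + n_non)
    chrom_weights_cpg = np.array([len(cpg_positions[c]) for c in genome.chroms], dtype=float)
    chrom_weights_non = np.array([len(noncpg_positions[c]) for c in genome.chroms], dtype=float)
    panel_keys = {
        (panel.chrom_names[c], int(p)) for c, p in zip(panel.chrom_id, panel.pos)
    }

    L = genome.total_length()
    mu = config.true_mu
    m = config.mosaic_fraction
    p_tr = config.mosaic_transmission_prob

    def draw_position() -> tuple[str, int]:
        while True:
            use_cpg = rng.random() < w_cpg
            weights = chrom_weights_cpg if use_cpg else chrom_weights_non
            ci = rng.choice(len(weights), p=weights / weights.sum())
            chrom = genome.chroms[ci]
            pool = cpg_positions[chrom] if use_cpg else noncpg_positions[chrom]
            pos = int(pool[rng.integers(len(pool))])
            if (chrom, pos) not in panel_keys:
                return chrom, pos

    def draw_alt(chrom: str, pos: int) -> str:
        seq = genome.sequences[chrom]
        ref = seq[pos]
        nxt = seq[pos + 1] if pos + 1 < len(seq) else ""
        prv = seq[pos - 1] if pos > 0 else ""
        if ref == "C" and nxt == "G":
            probs = {"T": 0.75, "A": 0.125, "G": 0.125}
        elif ref == "G" and prv == "C":
            probs = {"A": 0.75, "T": 0.125, "C": 0.125}
        else:
            ts = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
            probs = {b: (0.5 if b == ts else 0.25) for b in "ACGT" if b != ref}
        bases, p = zip(*probs.items())
        return str(rng.choice(np.array(bases), p=np.array(p)))

    dnm_rows = []
    group_counter = 0
    idx = {s: j for j, s in enumerate(panel.samples)}
    extra_het: dict[tuple[str, int, str, str], None] = {}

    for fam, fam_members in pedigree.families().items():
        clutches: dict[tuple[str, str], list[str]] = {}
        for mid in fam_members:
            mm = pedigree[mid]
            if mm.father is not None:
                clutches.setdefault((mm.father, mm.mother), []).append(mid)
        for (father, mother), sibs in clutches.items():
            for parent, side, frac in (
                (father, "paternal", config.paternal_fraction),
                (mother, "maternal", 1 - config.paternal_fraction),
            ):
                # non-mosaic: private to one offspring
                for child in sibs:
                    k = rng.poisson(2 * L * mu * frac * (1 - m))
                    for _ in range(k):
                        chrom, pos = draw_position()
                        alt = draw_alt(chrom, pos)
                        dnm_rows.append((child, chrom, pos, genome.base_at(chrom, pos), alt, side, None))
                        extra_het[(chrom, pos, alt, child)] = None
                # mosaic events shared across the clutch; the event count is
                # scaled by 1/p_tr so each sib's marginal rate stays mu*frac*m
                k_events = rng.poisson(2 * L * mu * frac * m / p_tr)
                for _ in range(k_events):
                    carriers = [s for s in sibs if rng.random() < p_tr]
                    if not carriers:
                        continue
                    chrom, pos = draw_position()
                    alt = draw_alt(chrom, pos)
                    ref = genome.base_at(chrom, pos)
                    gid = group_counter if len(carriers) >= 2 else None
                    if gid is not None:
                        group_counter += 1
                    for child in carriers:
                        dnm_rows.append((child, chrom, pos, ref, alt, side, gid))
                        extra_het[(chrom, pos, alt, child)] = None

    dnms = pd.DataFrame(
        dnm_rows,
        columns=["offspring", "chrom", "pos", "ref", "alt", "parent_of_origin", "mosaic_group"],
    )

    # F1 -> F2 transmission of F1 mutations
    trans_rows = []
    for row in dnms.itertuples():
        kids = pedigree.offspring_of(row.offspring)
        for kid in kids:
            transmitted = bool(rng.random() < 0.5)
            trans_rows.append((row.offspring, row.chrom, row.pos, kid, transmitted))
            if transmitted:
                extra_het[(row.chrom, row.pos, row.alt, kid)] = None
    transmissions = pd.DataFrame(
        trans_rows, columns=["f1", "chrom", "pos", "f2", "transmitted"]
    )

    # low-mappability mask
    mask_tuples = []
    for chrom, clen in genome.lengths().items():
        target = config.mask_fraction * clen
        covered = 0
        while covered < target:
            Lm = int(rng.integers(1000, 4000))
            s = int(rng.integers(0, clen - Lm))
            mask_tuples.append((chrom, s, s + Lm))
            covered += Lm
    mask = IntervalSet.from_tuples(mask_tuples) if mask_tuples else IntervalSet({})

    truth = SimTruth(
        dnms=dnms,
        fp_sites=pd.DataFrame(
            columns=["offspring", "chrom", "pos", "ref", "alt", "kind"]
        ),
        mask=mask,
        transmissions=transmissions,
        true_mu=mu,
    )
    panel.extra_het = extra_het  # (chrom, pos, alt, sample) -> None
    return pedigree, panel, truth


# ---------------------------------------------------------------------------
# evidence generation


_INFO_VIOLATIONS = (
    ("QD", 0.5, 1.9),
    ("MQ", 20.0, 39.0),
    ("FS", 61.0, 120.0),
    ("SOR", 3.1, 6.0),
    ("MQRankSum", -20.0, -12.6),
    ("ReadPosRankSum", -15.0, -8.1),
)


def _clean_info(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    """Caller annotations for well-behaved sites (never violate the hard filters)."""
    return {
        "QD": np.clip(rng.normal(17, 4, n), 2.5, 40.0),
        "MQ": np.clip(rng.normal(60, 0.8, n), 55.0, 62.0),
        "FS": np.clip(np.abs(rng.normal(2, 2, n)), 0.0, 30.0),
        "SOR": rng.uniform(0.7, 2.5, n),
        "MQRankSum": np.clip(rng.normal(0, 1, n), -5.0, 5.0),
        "ReadPosRankSum": np.clip(rng.normal(0, 1, n), -5.0, 5.0),
    }


def simulate_evidence(
    panel: _PanelSim,
    truth: SimTruth,
    config: SimConfig,
    seed: int | np.random.SeedSequence,
    pedigree: Pedigree,
    genome: Genome,
) -> tuple[SiteTable, dict[str, DepthTrack], pd.DataFrame, pd.DataFrame]:
    """Draw genotype evidence around the truth.

    Returns (site table, per-sample depth tracks, read observations,
    raw parental support). Depth is negative-binomial via gamma window
    means mixed with per-site Poisson draws; allelic depths are binomial
    around the true allele fraction; planted artifacts get skewed
    balance, lowered qualities and hard-filter violations at the
    configured rates; under-genotyped parental carriers put their alt
    reads in the raw-support channel (and, when "detected", into AD).
    """
    rng = np.random.default_rng(seed)
    samples = panel.samples
    idx = {s: j for j, s in enumerate(samples)}
    chrom_names = panel.chrom_names
    lengths = genome.lengths()
    chrom_len = np.array([lengths[c] for c in chrom_names])
    L = int(chrom_len.sum())
    win = config.depth_window
    n_win = int(np.ceil(chrom_len.max() / win))

    # --- window depth means (NB mixing), also the bedGraph tracks ---
    W = rng.gamma(
        config.depth_shape,
        config.depth_mean / config.depth_shape,
        size=(len(chrom_names), n_win, len(samples)),
    )
    tracks: dict[str, DepthTrack] = {}
    for s in samples:
        data = {}
        for ci, chrom in enumerate(chrom_names):
            nw = int(np.ceil(chrom_len[ci] / win))
            starts = np.arange(nw, dtype=np.int64) * win
            ends = np.minimum(starts + win, chrom_len[ci])
            data[chrom] = (starts, ends, W[ci, :nw, idx[s]])
        tracks[s] = DepthTrack(data)

    # --- assemble site list -------------------------------------------------
    used = {(int(c), int(p)) for c, p in zip(panel.chrom_id, panel.pos)}
    cindex = {c: i for i, c in enumerate(chrom_names)}

    extra_rows: list[dict] = []  # chrom_id, pos, ref, alt, het_samples, kind info

    def add_row(ci, pos, ref, alt, kind, **kw):
        if (ci, pos) in used:
            return None
        used.add((ci, pos))
        row = dict(ci=ci, pos=pos, ref=ref, alt=alt, kind=kind, **kw)
        extra_rows.append(row)
        return row

    # planted germline mutations (and transmitted F1 mutations)
    by_site: dict[tuple[str, int, str], list[str]] = {}
    site_ref: dict[tuple[str, int, str], str] = {}
    for (chrom, pos, alt, sample) in panel.extra_het:
        by_site.setdefault((chrom, pos, alt), []).append(sample)
    for r in truth.dnms.itertuples():
        site_ref[(r.chrom, int(r.pos), r.alt)] = r.ref
    for (chrom, pos, alt), carriers in by_site.items():
        ref = site_ref.get((chrom, pos, alt)) or genome.base_at(chrom, pos)
        add_row(cindex[chrom], pos, ref, alt, "dnm", het=carriers)

    # decoy indels (filter bait near which artifact SNVs cluster)
    non_founders = [m.id for m in pedigree.members.values() if not m.is_founder]
    indel_positions: list[tuple[int, int]] = []
    n_indels = rng.poisson(config.decoy_indels_per_mb * L / 1e6)
    for _ in range(n_indels):
        ci = int(rng.choice(len(chrom_names), p=chrom_len / chrom_len.sum()))
        pos = int(rng.integers(1, chrom_len[ci] - 2))
        seq = genome.sequences[chrom_names[ci]]
        carrier = non_founders[int(rng.integers(len(non_founders)))]
        if add_row(ci, pos, seq[pos : pos + 2], seq[pos], "indel", het=[carrier]):
            indel_positions.append((ci, pos))

    # somatic/artifact false positives per offspring
    fp_rows = []
    for child in non_founders:
        for _ in range(rng.poisson(config.fp_rate * L)):
            u = rng.random()
            if u < config.fp_masked_fraction and truth.mask.data:
                chrom, s, e = truth.mask.to_tuples()[
                    int(rng.integers(len(truth.mask.to_tuples())))
                ]
                ci, pos = cindex[chrom], int(rng.integers(s, e))
            elif (
                u < config.fp_masked_fraction + config.fp_near_indel_fraction
                and indel_positions
            ):
                ci, ipos = indel_positions[int(rng.integers(len(indel_positions)))]
                pos = int(np.clip(ipos + rng.integers(-5, 6), 0, chrom_len[ci] - 1))
            else:
                ci = int(rng.choice(len(chrom_names), p=chrom_len / chrom_len.sum()))
                pos = int(rng.integers(0, chrom_len[ci]))
            ref = genome.base_at(chrom_names[ci], pos)
            alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
            row = add_row(ci, pos, ref, alt, "somatic", het=[child], offspring=child)
            if row is not None:
                fp_rows.append((child, chrom_names[ci], pos, ref, alt, "somatic"))

    # under-genotyped parental carriers (inherited, not de novo)
    for trio_child in non_founders:
        mm = pedigree[trio_child]
        for _ in range(rng.poisson(config.parental_contamination_rate * L)):
            ci = int(rng.choice(len(chrom_names), p=chrom_len / chrom_len.sum()))
            pos = int(rng.integers(0, chrom_len[ci]))
            ref = genome.base_at(chrom_names[ci], pos)
            alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
            carrier = mm.father if rng.random() < 0.5 else mm.mother
            row = add_row(
                ci, pos, ref, alt, "contamination",
                het=[trio_child], carrier=carrier,
                detected=bool(rng.random() < config.contamination_detected_prob),
            )
            if row is not None:
                fp_rows.append(
                    (trio_child, chrom_names[ci], pos, ref, alt, "parental_carrier")
                )

    # invariant sites (monomorphic, for context/round-trip realism)
    n_inv = rng.poisson(config.invariant_fraction * L)
    for _ in range(n_inv):
        ci = int(rng.choice(len(chrom_names), p=chrom_len / chrom_len.sum()))
        pos = int(rng.integers(0, chrom_len[ci]))
        add_row(ci, pos, genome.base_at(chrom_names[ci], pos), "", "invariant")

    truth.fp_sites = pd.DataFrame(
        fp_rows, columns=["offspring", "chrom", "pos", "ref", "alt", "kind"]
    )

    # --- merge panel + extra rows into one table ---------------------------
    n_panel = len(panel.pos)
    n_extra = len(extra_rows)
    n = n_panel + n_extra
    chrom_id = np.concatenate(
        [panel.chrom_id, np.array([r["ci"] for r in extra_rows], dtype=np.int64)]
    ).astype(np.int32)
    pos = np.concatenate(
        [panel.pos, np.array([r["pos"] for r in extra_rows], dtype=np.int64)]
    )
    ref = np.concatenate([panel.ref, np.array([r["ref"] for r in extra_rows], dtype=object)])
    alt = np.concatenate([panel.alt, np.array([r["alt"] for r in extra_rows], dtype=object)])
    gt = np.zeros((n, len(samples)), dtype=np.int8)
    gt[:n_panel] = panel.gt
    for k, r in enumerate(extra_rows):
        for s in r.get("het", []):
            gt[n_panel + k, idx[s]] = int(GT.HET)

    # --- evidence draws -----------------------------------------------------
    win_idx = (pos // win).astype(np.int64)
    lam = W[chrom_id, win_idx, :]  # (n, n_samples)
    dp = rng.poisson(lam).astype(np.int32)
    np.maximum(dp, 1, out=dp)
    p_alt = np.select(
        [gt == 0, gt == 1, gt == 2],
        [config.hom_ref_error, 0.5, 1.0 - config.hom_ref_error],
    )
    if config.exact_allele_balance:
        ad1 = np.rint(dp * p_alt).astype(np.int32)
    else:
        ad1 = rng.binomial(dp, p_alt).astype(np.int32)
    gq = np.full((n, len(samples)), 99, dtype=np.int16)
    low = rng.random((n, len(samples))) < config.gq_low_prob
    lo, hi = config.gq_low_range
    gq[low] = rng.integers(lo, hi + 1, size=int(low.sum()))

    info = _clean_info(rng, n)
    # invariant sites carry no caller annotations
    inv_rows = n_panel + np.array(
        [k for k, r in enumerate(extra_rows) if r["kind"] == "invariant"], dtype=int
    )
    for key in info:
        info[key][inv_rows] = np.nan

    # --- artifact overrides -------------------------------------------------
    raw_rows = []
    a_b = config.fp_somatic_beta
    for k, r in enumerate(extra_rows):
        i = n_panel + k
        if r["kind"] == "somatic":
            j = idx[r["offspring"]]
            frac = rng.beta(*a_b)
            ad1[i, j] = rng.binomial(dp[i, j], frac)
            if rng.random() < config.fp_gq_low_prob:
                gq[i, j] = int(rng.integers(lo, hi + 1))
            if rng.random() < config.fp_hard_filter_fraction:
                key, vlo, vhi = _INFO_VIOLATIONS[int(rng.integers(len(_INFO_VIOLATIONS)))]
                info[key][i] = rng.uniform(vlo, vhi)
        elif r["kind"] == "contamination":
            j = idx[r["carrier"]]
            k_alt = int(rng.binomial(dp[i, j], config.contamination_raw_fraction))
            raw_rows.append(
                (r["carrier"], chrom_names[r["ci"]], r["pos"], int(dp[i, j]) - k_alt, k_alt)
            )
            if r["detected"]:
                ad1[i, j] = k_alt  # caller kept the alt reads in AD
            else:
                ad1[i, j] = 0  # dropped: only the raw-read channel sees them

    ad0 = dp - ad1
    # contamination carriers with dropped reads: AD undercounts DP
    order = np.lexsort((pos, chrom_id))
    table = SiteTable(
        chrom_names,
        chrom_id[order],
        pos[order],
        ref[order],
        alt[order],
        samples,
        gt[order],
        ad0[order],
        ad1[order],
        dp[order],
        gq[order],
        {k: v[order] for k, v in info.items()},
    )

    reads = _phasing_reads(panel, truth, config, rng, pedigree, genome)
    raw_support = pd.DataFrame(
        raw_rows, columns=["sample", "chrom", "pos", "ref_count", "alt_count"]
    )
    return table, tracks, reads, raw_support


def _phasing_reads(
    panel: _PanelSim,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
    pedigree: Pedigree,
    genome: Genome,
) -> pd.DataFrame:
    """Read observations linking each mutation to informative flank sites.

    For a mutation of known parental origin, an informative flank is a
    panel site where the offspring is heterozygous and the allele it
    inherited from the originating parent is absent from the other
    parent — a read pair spanning both sites then phases the mutation.
    """
    rows = []
    counter = 0
    idx = {s: j for j, s in enumerate(panel.samples)}
    for r in truth.dnms.itertuples():
        child_j = idx[r.offspring]
        mm = pedigree[r.offspring]
        origin_parent = mm.father if r.parent_of_origin == "paternal" else mm.mother
        other_parent = mm.mother if r.parent_of_origin == "paternal" else mm.father
        attempt = rng.random() < config.informative_read_rate
        flank = None
        if attempt:
            ci = panel.chrom_names.index(r.chrom)
            near = np.flatnonzero(
                (panel.chrom_id == ci)
                & (np.abs(panel.pos - r.pos) <= config.read_span)
                & (panel.pos != r.pos)
            )
            for s_row in near:
                if panel.gt[s_row, child_j] != 1:
                    continue
                from_origin = (
                    panel.from_father[s_row, child_j]
                    if r.parent_of_origin == "paternal"
                    else panel.from_mother[s_row, child_j]
                )
                other_gt = panel.gt[s_row, idx[other_parent]]
                # allele x from the originating parent must be absent in
                # the other parent's genotype for attribution
                if (from_origin == 1 and other_gt == 0) or (
                    from_origin == 0 and other_gt == 2
                ):
                    allele = panel.alt[s_row] if from_origin == 1 else panel.ref[s_row]
                    flank = (int(panel.pos[s_row]), str(allele))
                    break
        for _ in range(config.reads_per_dnm):
            counter += 1
            rid = f"r{counter:07d}"
            rows.append((rid, r.offspring, r.chrom, int(r.pos), r.alt))
            if flank is not None:
                rows.append((rid, r.offspring, r.chrom, flank[0], flank[1]))
    return pd.DataFrame(rows, columns=["read_id", "sample", "chrom", "pos", "allele"])


# ---------------------------------------------------------------------------
# convenience wrapper


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: Genome
    genes: list[GeneModel]
    cgi: IntervalSet
    pedigree: Pedigree
    truth: SimTruth
    table: SiteTable
    tracks: dict[str, DepthTrack]
    reads: pd.DataFrame
    raw_support: pd.DataFrame


def simulate_dataset(config: SimConfig, seed: int) -> SimulatedDataset:
    """Run the three stages with per-stage child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    s_genome, s_ped, s_ev = ss.spawn(3)
    genome, genes, cgi = simulate_genome(config, s_genome)
    pedigree, panel, truth = simulate_pedigree(config, genome, s_ped)
    table, tracks, reads, raw_support = simulate_evidence(
        panel, truth, config, s_ev, pedigree, genome
    )
    return SimulatedDataset(
        config=config,
        genome=genome,
        genes=genes,
        cgi=cgi,
        pedigree=pedigree,
        truth=truth,
        table=table,
        tracks=tracks,
        reads=reads,
        raw_support=raw_support,
    )

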