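"""Readers and writers for the standard formats the pipeline touches.

VCF v4.2 (pysam), FASTA (pyfaidx), GFF3 (gffutils), BED/bedGraph and
6-column PED are converted at this boundary to the internal 0-based
half-open data model; nothing outside this module parses or formats text.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import pyfaidx
import pysam

from .intervals import DepthTrack, IntervalSet
from .pedigree import GENERATIONS, Member, Pedigree
from .sites import GT, Genotype, INFO_KEYS, SiteRecord


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# VCF


def read_vcf(
    path: str | os.PathLike, sample_subset: Sequence[str] | None = None
) -> tuple[list[str], Iterator[SiteRecord]]:
    """Open a VCF and return (samples, record iterator).

    Records come back in file order with VCF's 1-based POS converted to
    0-based. Missing FORMAT keys yield missing-valued :class:`Genotype`
    fields; multiallelic records are preserved.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF header of {path}: {exc}") from exc
    header_samples = list(vf.header.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in header_samples]
        if missing:
            raise KeyError(f"samples absent from VCF header: {missing}")
        samples = list(sample_subset)
    else:
        samples = header_samples
    return samples, _iter_vcf(vf, samples)


def _iter_vcf(vf: pysam.VariantFile, samples: list[str]) -> Iterator[SiteRecord]:
    for rec in vf:
        alts = [a for a in (rec.alts or []) if a not in (".", "<NON_REF>")]
        info = {}
        for key in INFO_KEYS:
            if key in rec.info:
                val = rec.info[key]
                if isinstance(val, tuple):
                    val = val[0]
                info[key] = float(val)
        calls = {}
        for s in samples:
            calls[s] = _parse_call(rec.samples[s])
        yield SiteRecord(rec.chrom, rec.pos - 1, rec.ref, alts, info, calls)
    vf.close()


def _parse_call(sample) -> Genotype:
    gt_tuple = sample.get("GT")
    if gt_tuple is None or any(a is None for a in gt_tuple) or len(gt_tuple) != 2:
        gt = GT.MISSING
        indices = None
    else:
        indices = (int(gt_tuple[0]), int(gt_tuple[1]))
        n_alt = sum(1 for a in indices if a > 0)
        if indices[0] != indices[1]:
            gt = GT.HET
        elif n_alt:
            gt = GT.HOM_ALT
        else:
            gt = GT.HOM_REF
    ad = sample.get("AD")
    if ad is not None and len(ad) >= 2 and ad[0] is not None and ad[1] is not None:
        ad = (int(ad[0]), int(ad[1]))
    else:
        ad = None
    dp = sample.get("DP")
    gq = sample.get("GQ")
    return Genotype(
        gt=gt,
        ad=ad,
        dp=None if dp is None else int(dp),
        gq=None if gq is None else int(gq),
        allele_indices=indices,
    )


def write_vcf(
    samples: Sequence[str],
    records: Iterable[SiteRecord],
    path: str | os.PathLike,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write records as VCF v4.2; inverse of :func:`read_vcf`.

    ``records`` must be sorted by (chrom, pos); contig lengths may be given
    (otherwise contig lines are emitted as contigs are first seen, with a
    generous placeholder length).
    """
    records = list(records)
    header = pysam.VariantHeader()
    seen: dict[str, int] = dict(contigs or {})
    for rec in records:
        if rec.chrom not in seen:
            seen[rec.chrom] = 2**29
    order = {}
    for chrom, length in seen.items():
        header.contigs.add(chrom, length=length)
        order[chrom] = len(order)
    key = [(order[r.chrom], r.pos) for r in records]
    if any(k2 < k1 for k1, k2 in zip(key, key[1:])):
        raise ValueError("records must be sorted by (chrom, pos)")
    # END is emitted by htslib for symbolic-allele (invariant) records
    header.info.add("END", 1, "Integer", "End position")
    for k in INFO_KEYS:
        header.info.add(k, 1, "Float", f"{k} annotation")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            # invariant sites: pysam requires ≥2 alleles, so emit the
            # symbolic non-ref placeholder and strip it when reading back
            alleles = tuple([rec.ref] + rec.alts) if rec.alts else (rec.ref, "<NON_REF>")
            vrec = out.new_record(
                contig=rec.chrom,
                start=rec.pos,
                stop=rec.pos + len(rec.ref),
                alleles=alleles,
            )
            for k, v in rec.info.items():
                vrec.info[k] = v
            for s in samples:
                g = rec.calls.get(s)
                if g is None:
                    g = Genotype(GT.MISSING)
                call = vrec.samples[s]
                call["GT"] = _gt_tuple(g)
                if g.ad is not None:
                    # internal AD is always (ref, alt1); pad Number=R slots
                    pad = len(vrec.alleles) - 2
                    call["AD"] = tuple(g.ad) + (None,) * pad
                if g.dp is not None:
                    call["DP"] = g.dp
                if g.gq is not None:
                    call["GQ"] = g.gq
            out.write(vrec)


def _gt_tuple(g: Genotype) -> tuple:
    if g.gt == GT.MISSING:
        return (None, None)
    if g.allele_indices is not None:
        return g.allele_indices
    return {GT.HOM_REF: (0, 0), GT.HET: (0, 1), GT.HOM_ALT: (1, 1)}[g.gt]


# ---------------------------------------------------------------------------
# PED


def read_pedigree(path: str | os.PathLike) -> Pedigree:
    """Read 6-column PED; phenotype column holds ``population:generation``."""
    members = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            fam, mid, father, mother, sex, pheno = fields
            pop, _, gen = pheno.partition(":")
            if gen not in GENERATIONS:
                raise FormatError(
                    f"{path}:{lineno}: phenotype must be 'population:generation' "
                    f"with generation in {GENERATIONS}, got {pheno!r}"
                )
            members.append(
                Member(
                    id=mid,
                    family=fam,
                    sex=int(sex),
                    father=None if father == "0" else father,
                    mother=None if mother == "0" else mother,
                    generation=gen,
                    population=pop,
                )
            )
    return Pedigree(members)


def write_pedigree(ped: Pedigree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for m in ped.members.values():
            fh.write(
                f"{m.family}\t{m.id}\t{m.father or 0}\t{m.mother or 0}\t"
                f"{m.sex}\t{m.population}:{m.generation}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


class Genome:
    """In-memory reference with 0-based half-open random access."""

    def __init__(self, sequences: Mapping[str, str]) -> None:
        self.sequences = {c: s.upper() for c, s in sequences.items()}

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]

    def base_at(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos]

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


def read_reference(path: str | os.PathLike) -> Genome:
    """Load a FASTA (indexed via pyfaidx) into a :class:`Genome`."""
    fa = pyfaidx.Fasta(str(path))
    names = list(fa.keys())
    if len(set(names)) != len(names):
        raise FormatError("duplicate sequence names in FASTA")
    genome = Genome({name: str(fa[name][:]) for name in names})
    fa.close()
    return genome


def write_fasta(genome: Genome, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models


@dataclass
class GeneModel:
    """One gene with a single transcript's exon/CDS structure.

    Coordinates 0-based half-open; ``cds`` tuples are (start, end, phase)
    in genomic order.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        """Transcription start site (position of the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Transcription termination site."""
        return self.end - 1 if self.strand == "+" else self.start

    def introns(self) -> list[tuple[int, int]]:
        exons = sorted(self.exons)
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:]) if s2 > e1
        ]


def read_gff(path: str | os.PathLike) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon/CDS features into gene models."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    for cds in db.features_of_type("CDS"):
        parents = [p for p in db.parents(cds, featuretype="mRNA")]
        if not parents:
            raise FormatError(f"CDS {cds.id} has no parent mRNA")
    genes = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            continue
        mrna = mrnas[0]
        exons = [
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        ]
        cds = [
            (f.start - 1, f.end, int(f.frame) if f.frame != "." else 0)
            for f in db.children(mrna, featuretype="CDS")
        ]
        genes.append(
            GeneModel(
                id=gene.id,
                chrom=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand,
                exons=sorted(exons),
                cds=sorted(cds),
            )
        )
    return genes


def write_gff(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.id}"
            fh.write(
                f"{g.chrom}\tdnmkit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mid = f"{g.id}.t1"
            fh.write(
                f"{g.chrom}\tdnmkit\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={g.id}\n"
            )
            for i, (s, e) in enumerate(sorted(g.exons), 1):
                fh.write(
                    f"{g.chrom}\tdnmkit\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mid}.exon{i};Parent={mid}\n"
                )
            for i, (s, e, phase) in enumerate(sorted(g.cds), 1):
                fh.write(
                    f"{g.chrom}\tdnmkit\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"ID={mid}.cds{i};Parent={mid}\n"
                )


# ---------------------------------------------------------------------------
# BED / bedGraph


def read_bed(path: str | os.PathLike) -> IntervalSet:
    tuples = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            tuples.append((fields[0], int(fields[1]), int(fields[2])))
    return IntervalSet.from_tuples(tuples)


def write_bed(intervals: IntervalSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals.to_tuples():
            fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bedgraph(path: str | os.PathLike) -> DepthTrack:
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")[:4]
            by_chrom.setdefault(chrom, []).append((int(s), int(e), float(v)))
    data = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        arr = np.array(rows, dtype=np.float64)
        data[chrom] = (
            arr[:, 0].astype(np.int64),
            arr[:, 1].astype(np.int64),
            arr[:, 2],
        )
    return DepthTrack(data)


def write_bedgraph(track: DepthTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, (starts, ends, values) in track.data.items():
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Auxiliary TSVs (read observations, raw parental support)

READ_OBS_COLUMNS = ["read_id", "sample", "chrom", "pos", "allele"]
RAW_SUPPORT_COLUMNS = ["sample", "chrom", "pos", "ref_count", "alt_count"]


def read_observations(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "sample": str, "chrom": str})
    missing = set(READ_OBS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"read observation table lacks columns {sorted(missing)}")
    return df


def write_observations(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, columns=READ_OBS_COLUMNS)


def read_raw_support(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = set(RAW_SUPPORT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"raw support table lacks columns {sorted(missing)}")
    return df


def write_raw_support(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, columns=RAW_SUPPORT_COLUMNS)
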