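"""Core in-memory containers for variant and invariant sites.

Genotype evidence for a whole pedigree is held column-wise in a
:class:`SiteTable` (one row per site, one column per sample) so that the
screening and calibration stages can run as vectorized numpy operations.
Record-at-a-time views (:class:`SiteRecord`) are materialized only at format
boundaries and in small examples.

Coordinates are 0-based half-open internally; conversion to the 1-based
conventions of VCF/GFF happens in :mod:`dnmkit.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

#: INFO annotations consumed by the hard site filters.
INFO_KEYS = ("QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum")

MISSING = -1


class GT(IntEnum):
    """Diploid genotype classes for biallelic sites."""

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


@dataclass(frozen=True)
class Genotype:
    """One sample's call at one site.

    ``dp`` is the caller's DP and need not equal ``ad[0] + ad[1]``.
    Missing integer fields are ``None`` at this level (encoded as -1 inside
    a :class:`SiteTable`).
    """

    gt: GT
    ad: tuple[int, int] | None = None
    dp: int | None = None
    gq: int | None = None
    #: raw allele indices from the source record; only meaningful for
    #: multiallelic records, where the GT class alone is ambiguous.
    #: Excluded from equality: (0, 1) and None both mean a plain het.
    allele_indices: tuple[int, int] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.ad is not None and (self.ad[0] < 0 or self.ad[1] < 0):
            raise ValueError(f"negative allelic depth: {self.ad}")
        if self.gq is not None and not 0 <= self.gq <= 99:
            raise ValueError(f"GQ out of range [0, 99]: {self.gq}")

    @property
    def ab(self) -> float | None:
        """Allelic balance AD1/(AD0+AD1); None if AD missing or zero."""
        if self.ad is None or self.ad[0] + self.ad[1] == 0:
            return None
        return self.ad[1] / (self.ad[0] + self.ad[1])


@dataclass
class SiteRecord:
    """One variant or invariant site with per-sample calls.

    ``pos`` is 0-based. ``alts`` may be empty (monomorphic site) or hold
    several alleles (multiallelic record, preserved on reading; the DNM
    screen decomposes to biallelic SNVs).
    """

    chrom: str
    pos: int
    ref: str
    alts: list[str] = field(default_factory=list)
    info: dict[str, float] = field(default_factory=dict)
    calls: dict[str, Genotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if not self.ref or any(b not in "ACGTN" for b in self.ref.upper()):
            raise ValueError(f"bad reference allele {self.ref!r}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != 1 or any(len(a) != 1 for a in self.alts)

    @property
    def is_biallelic_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alts) == 1 and len(self.alts[0]) == 1


class SiteTable:
    """Column-wise table of biallelic (or invariant) sites.

    Per-sample matrices are shaped ``(n_sites, n_samples)``:

    ``gt``
        int8 genotype codes (:class:`GT`; -1 missing).
    ``ad0, ad1, dp``
        int32 read counts (-1 missing).
    ``gq``
        int16 genotype quality (-1 missing).

    INFO annotations are float arrays with NaN for missing. ``alt`` is the
    empty string for invariant sites. Rows are expected sorted by
    (chrom, pos); constructors enforce this.
    """

    def __init__(
        self,
        chrom_names: Sequence[str],
        chrom_id: np.ndarray,
        pos: np.ndarray,
        ref: np.ndarray,
        alt: np.ndarray,
        samples: Sequence[str],
        gt: np.ndarray,
        ad0: np.ndarray,
        ad1: np.ndarray,
        dp: np.ndarray,
        gq: np.ndarray,
        info: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        n = len(pos)
        self.chrom_names = list(chrom_names)
        self.chrom_id = np.asarray(chrom_id, dtype=np.int32)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = np.asarray(alt, dtype=object)
        self.samples = list(samples)
        self.gt = np.asarray(gt, dtype=np.int8)
        self.ad0 = np.asarray(ad0, dtype=np.int32)
        self.ad1 = np.asarray(ad1, dtype=np.int32)
        self.dp = np.asarray(dp, dtype=np.int32)
        self.gq = np.asarray(gq, dtype=np.int16)
        self.info = {
            k: np.asarray(v, dtype=np.float64) for k, v in (info or {}).items()
        }
        for arr in (self.chrom_id, self.ref, self.alt):
            if len(arr) != n:
                raise ValueError("site-level arrays must share one length")
        for arr in (self.gt, self.ad0, self.ad1, self.dp, self.gq):
            if arr.shape != (n, len(self.samples)):
                raise ValueError(
                    f"per-sample matrix shape {arr.shape} != ({n}, {len(self.samples)})"
                )
        order = np.lexsort((self.pos, self.chrom_id))
        if not np.array_equal(order, np.arange(n)):
            raise ValueError("sites must be sorted by (chrom, pos)")

    # -- basic introspection ------------------------------------------------

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in table") from None

    def chrom_of(self, row: int) -> str:
        return self.chrom_names[self.chrom_id[row]]

    @property
    def is_indel(self) -> np.ndarray:
        ref_len = np.fromiter((len(r) for r in self.ref), int, count=len(self))
        alt_len = np.fromiter((len(a) for a in self.alt), int, count=len(self))
        return (ref_len != 1) | ((alt_len != 1) & (alt_len != 0))

    @property
    def is_snv(self) -> np.ndarray:
        ref_len = np.fromiter((len(r) for r in self.ref), int, count=len(self))
        alt_len = np.fromiter((len(a) for a in self.alt), int, count=len(self))
        return (ref_len == 1) & (alt_len == 1)

    def info_col(self, key: str) -> np.ndarray:
        """INFO column as float array (NaN where absent)."""
        if key in self.info:
            return self.info[key]
        return np.full(len(self), np.nan)

    # -- subsetting ---------------------------------------------------------

    def subset_rows(self, index: np.ndarray) -> "SiteTable":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SiteTable(
            self.chrom_names,
            self.chrom_id[index],
            self.pos[index],
            self.ref[index],
            self.alt[index],
            self.samples,
            self.gt[index],
            self.ad0[index],
            self.ad1[index],
            self.dp[index],
            self.gq[index],
            {k: v[index] for k, v in self.info.items()},
        )

    def select_samples(self, samples: Sequence[str]) -> "SiteTable":
        cols = [self.sample_index(s) for s in samples]
        return SiteTable(
            self.chrom_names,
            self.chrom_id,
            self.pos,
            self.ref,
            self.alt,
            list(samples),
            self.gt[:, cols],
            self.ad0[:, cols],
            self.ad1[:, cols],
            self.dp[:, cols],
            self.gq[:, cols],
            self.info,
        )

    # -- record views -------------------------------------------------------

    def genotype_at(self, row: int, sample: str) -> Genotype:
        j = self.sample_index(sample)
        ad = None
        if self.ad0[row, j] >= 0:
            ad = (int(self.ad0[row, j]), int(self.ad1[row, j]))
        return Genotype(
            gt=GT(int(self.gt[row, j])),
            ad=ad,
            dp=None if self.dp[row, j] < 0 else int(self.dp[row, j]),
            gq=None if self.gq[row, j] < 0 else int(self.gq[row, j]),
        )

    def iter_records(self) -> Iterator[SiteRecord]:
        for i in range(len(self)):
            info = {
                k: float(v[i]) for k, v in self.info.items() if not np.isnan(v[i])
            }
            calls = {s: self.genotype_at(i, s) for s in self.samples}
            alts = [self.alt[i]] if self.alt[i] else []
            yield SiteRecord(self.chrom_of(i), int(self.pos[i]), self.ref[i], alts, info, calls)

    @classmethod
    def from_records(
        cls, records: Iterable[SiteRecord], samples: Sequence[str] | None = None
    ) -> "SiteTable":
        """Build a table from biallelic/invariant records.

        Multiallelic records are decomposed into one biallelic row per
        alternate allele (genotype codes re-expressed against that allele;
        other-alt carriers become missing).
        """
        rows: list[tuple] = []
        chrom_names: list[str] = []
        chrom_lookup: dict[str, int] = {}
        sample_list = list(samples) if samples is not None else None
        for rec in records:
            if sample_list is None:
                sample_list = list(rec.calls)
            if rec.chrom not in chrom_lookup:
                chrom_lookup[rec.chrom] = len(chrom_names)
                chrom_names.append(rec.chrom)
            for split in decompose(rec):
                rows.append((chrom_lookup[split.chrom], split))
        if sample_list is None:
            sample_list = []
        n = len(rows)
        chrom_id = np.array([c for c, _ in rows], dtype=np.int32)
        pos = np.array([r.pos for _, r in rows], dtype=np.int64)
        ref = np.array([r.ref for _, r in rows], dtype=object)
        alt = np.array([(r.alts[0] if r.alts else "") for _, r in rows], dtype=object)
        s = len(sample_list)
        gt = np.full((n, s), MISSING, dtype=np.int8)
        ad0 = np.full((n, s), MISSING, dtype=np.int32)
        ad1 = np.full((n, s), MISSING, dtype=np.int32)
        dp = np.full((n, s), MISSING, dtype=np.int32)
        gq = np.full((n, s), MISSING, dtype=np.int16)
        info = {k: np.full(n, np.nan) for k in INFO_KEYS}
        for i, (_, r) in enumerate(rows):
            for k in INFO_KEYS:
                if k in r.info:
                    info[k][i] = r.info[k]
            for j, samp in enumerate(sample_list):
                g = r.calls.get(samp)
                if g is None:
                    continue
                gt[i, j] = int(g.gt)
                if g.ad is not None:
                    ad0[i, j], ad1[i, j] = g.ad
                if g.dp is not None:
                    dp[i, j] = g.dp
                if g.gq is not None:
                    gq[i, j] = g.gq
        order = np.lexsort((pos, chrom_id))
        tbl = cls(
            chrom_names, chrom_id[order], pos[order], ref[order], alt[order],
            sample_list, gt[order], ad0[order], ad1[order], dp[order], gq[order],
            {k: v[order] for k, v in info.items()},
        )
        return tbl


def decompose(rec: SiteRecord) -> list[SiteRecord]:
    """Split a multiallelic record into biallelic records.

    For each alternate allele *k*, genotypes are recoded against a ref/alt-k
    pair; calls carrying another alternate become missing. Biallelic and
    invariant records pass through unchanged.
    """
    if len(rec.alts) <= 1:
        return [rec]
    out = []
    for k, alt in enumerate(rec.alts, start=1):
        calls = {}
        for samp, g in rec.calls.items():
            calls[samp] = _recode(g, k)
        out.append(SiteRecord(rec.chrom, rec.pos, rec.ref, [alt], dict(rec.info), calls))
    return out


def _recode(g: Genotype, k: int) -> Genotype:
    """Re-express a call against alternate allele *k* (1-based).

    Calls touching any other alternate allele become missing; per-allele AD
    is not recoverable after decomposition so AD is dropped for them.
    """
    if g.gt == GT.MISSING or g.allele_indices is None:
        if g.gt in (GT.MISSING, GT.HOM_REF):
            return g
        return Genotype(GT.MISSING, dp=g.dp, gq=g.gq)
    a, b = g.allele_indices
    if any(x not in (0, k) for x in (a, b)):
        return Genotype(GT.MISSING, dp=g.dp, gq=g.gq)
    n_alt = (a == k) + (b == k)
    return Genotype(GT(n_alt), ad=g.ad, dp=g.dp, gq=g.gq, allele_indices=(min(a, b) and 1 or 0, max(a, b) and 1 or 0))
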