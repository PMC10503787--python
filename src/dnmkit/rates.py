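"""Germline mutation-rate estimation from curated counts and calibrations.

The per-offspring per-site per-generation rate is

    mu = n_dnm * (1 - FDR) / (2 * CS * (1 - FNR))

with n_dnm the candidate count, FDR the curation false-discovery rate,
CS the callable genome size and FNR the allelic-balance false-negative
rate. The factor 2 counts the two assayed haploid genomes per offspring.
Aggregation uses t-based confidence intervals over per-offspring rates
and Welch's t-test for group comparisons (the unequal-variance variant,
with Welch-Satterthwaite degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class RateEstimate:
    """Per-offspring or aggregate rate with its calibration components."""

    offspring: str  # sample id or "aggregate"
    n_dnm: float
    fdr: float
    cs: float
    fnr: float
    mu: float
    ci95: tuple[float, float] | None = None
    generation_time_years: float | None = None

    @property
    def mu_per_year(self) -> float | None:
        if self.generation_time_years is None:
            return None
        return per_year_rate(self.mu, self.generation_time_years)


@dataclass(frozen=True)
class GroupComparison:
    """Welch's t-test between two groups of per-offspring rates."""

    groups: tuple[str, str]
    means: tuple[float, float]
    t_statistic: float
    df: float
    p_value: float


@dataclass(frozen=True)
class TransmissionResult:
    """F1-to-F2 transmission of curated F1 mutations vs the fair 50%."""

    n_dnms: int
    n_transmitted: int
    n_trials: int
    fractions: tuple[float, ...]
    chi2: float
    chi2_p: float
    binom_p: float

    @property
    def mean_fraction(self) -> float:
        return float(np.mean(self.fractions)) if self.fractions else float("nan")


def per_offspring_rate(n_dnm: float, fdr: float, cs: float, fnr: float) -> float:
    """Point estimate mu = n(1-FDR) / (2 CS (1-FNR))."""
    if cs <= 0:
        raise ValueError("callable size must be positive")
    if not 0 <= fdr < 1 or not 0 <= fnr < 1:
        raise ValueError("FDR and FNR must lie in [0, 1)")
    if n_dnm < 0:
        raise ValueError("negative candidate count")
    return n_dnm * (1.0 - fdr) / (2.0 * cs * (1.0 - fnr))


def per_year_rate(mu: float, generation_time: float) -> float:
    """Convert a per-generation rate to per-year."""
    if generation_time <= 0:
        raise ValueError("generation time must be positive")
    return mu / generation_time


def aggregate_rates(
    estimates: Sequence[RateEstimate],
    groups: Mapping[str, str] | None = None,
    generation_time: float | None = None,
    clusters: Mapping[str, str] | None = None,
) -> tuple[RateEstimate, GroupComparison | None]:
    """Mean rate across offspring with a t-based 95% CI.

    ``clusters`` maps offspring id to its family: full sibs share
    early-embryonic (mosaic) mutations, so offspring of one clutch are
    positively correlated and the family, not the offspring, is the
    independent sampling unit. When given, the CI is a t interval over
    family mean rates; otherwise over per-offspring rates.

    ``groups`` maps offspring id to a group label (e.g. population); when
    exactly two groups are present a Welch's t-test compares them. A
    single estimate yields a point estimate without a CI.
    """
    if not estimates:
        raise ValueError("no estimates to aggregate")
    mus = np.array([e.mu for e in estimates], dtype=float)
    n = len(mus)
    mean = float(mus.mean())
    if clusters:
        by_fam: dict[str, list[float]] = {}
        for e in estimates:
            by_fam.setdefault(clusters.get(e.offspring, e.offspring), []).append(e.mu)
        units = np.array([np.mean(v) for v in by_fam.values()])
    else:
        units = mus
    ci = None
    if len(units) >= 2:
        se = float(units.std(ddof=1)) / np.sqrt(len(units))
        half = stats.t.ppf(0.975, len(units) - 1) * se
        ci = (mean - half, mean + half)
    agg = RateEstimate(
        offspring="aggregate",
        n_dnm=float(sum(e.n_dnm for e in estimates)),
        fdr=float(np.mean([e.fdr for e in estimates])),
        cs=float(np.mean([e.cs for e in estimates])),
        fnr=float(np.mean([e.fnr for e in estimates])),
        mu=mean,
        ci95=ci,
        generation_time_years=generation_time,
    )
    comparison = None
    if groups:
        labels = sorted({groups[e.offspring] for e in estimates if e.offspring in groups})
        if len(labels) == 2:
            a = mus[[groups.get(e.offspring) == labels[0] for e in estimates]]
            b = mus[[groups.get(e.offspring) == labels[1] for e in estimates]]
            if len(a) >= 2 and len(b) >= 2:
                res = stats.ttest_ind(a, b, equal_var=False)
                comparison = GroupComparison(
                    groups=(labels[0], labels[1]),
                    means=(float(a.mean()), float(b.mean())),
                    t_statistic=float(res.statistic),
                    df=float(res.df),
                    p_value=float(res.pvalue),
                )
    return agg, comparison


def transmission_test(
    carrier_counts: Sequence[tuple[int, int]]
) -> TransmissionResult:
    """Test F1->F2 transmission against Binomial(n, 0.5).

    ``carrier_counts`` holds one (carriers, sibs assayed) pair per F1
    mutation. The pooled carrier total is tested against half the pooled
    trials with a df=1 chi-square and an exact two-sided binomial test.
    """
    counts = [(k, n) for k, n in carrier_counts if n > 0]
    if not counts:
        return TransmissionResult(0, 0, 0, (), float("nan"), float("nan"), float("nan"))
    k_tot = sum(k for k, _ in counts)
    n_tot = sum(n for _, n in counts)
    fractions = tuple(k / n for k, n in counts)
    chi2_res = stats.chisquare([k_tot, n_tot - k_tot], [n_tot / 2, n_tot / 2])
    binom_p = stats.binomtest(k_tot, n_tot, 0.5).pvalue
    return TransmissionResult(
        n_dnms=len(counts),
        n_transmitted=k_tot,
        n_trials=n_tot,
        fractions=fractions,
        chi2=float(chi2_res.statistic),
        chi2_p=float(chi2_res.pvalue),
        binom_p=float(binom_p),
    )


def count_f1_transmissions(dnms, table, pedigree) -> list[tuple[int, int]]:
    """Carrier counts of F1 mutations among each F1 parent's offspring.

    ``dnms`` are candidates (with offspring/chrom/pos/alt and optionally a
    source row); mutations of individuals without offspring are skipped.
    Offspring with missing genotypes at the site are excluded from the
    trial count.
    """
    from .sites import GT  # local import to keep module dependencies light

    counts = []
    for c in dnms:
        kids = pedigree.offspring_of(c.offspring)
        if not kids:
            continue
        row = getattr(c, "row", None)
        if row is None:
            cid = table.chrom_names.index(c.chrom)
            hits = np.flatnonzero(
                (table.chrom_id == cid) & (table.pos == c.pos) & (table.alt == c.alt)
            )
            if not len(hits):
                continue
            row = int(hits[0])
        gts = [int(table.gt[row, table.sample_index(k)]) for k in kids]
        trials = sum(g != int(GT.MISSING) for g in gts)
        carriers = sum(g in (int(GT.HET), int(GT.HOM_ALT)) for g in gts)
        if trials:
            counts.append((carriers, trials))
    return counts


def effective_population_size(pi: float, mu: float) -> float:
    """Long-term Ne = pi / (4 mu) under mutation-drift equilibrium."""
    if pi <= 0 or mu <= 0:
        raise ValueError("pi and mu must be positive")
    return pi / (4.0 * mu)
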