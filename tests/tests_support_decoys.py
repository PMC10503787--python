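"""Shared decoy-candidate factory and independent filter predicate.

The predicate re-states every cut-off of the screening cascade in plain
arithmetic, independent of the implementation, so tests can compare the
cascade's survivor set against it.
"""

from __future__ import annotations

from dnmkit.screen import DnmCandidate, HOMREF_PARENTS
from dnmkit.sites import GT, Genotype


def make_decoys(rng, n=500):
    cands = []
    for i in range(n):
        info = {}
        for key, lo, hi in (
            ("QD", 0.5, 10.0),
            ("MQ", 30.0, 62.0),
            ("FS", 0.0, 90.0),
            ("SOR", 0.5, 5.0),
            ("MQRankSum", -16.0, 4.0),
            ("ReadPosRankSum", -10.0, 4.0),
        ):
            if rng.random() < 0.9:
                info[key] = float(rng.uniform(lo, hi))
        dp_o = int(rng.integers(10, 120))
        ad1 = int(rng.integers(0, dp_o + 1))
        dp_p = int(rng.integers(10, 120))
        p_ad1 = int(rng.integers(0, 3))
        gq = int(rng.integers(60, 100))
        cands.append(
            DnmCandidate(
                trio_id="kid",
                offspring="kid",
                family="fam1",
                chrom="chr1",
                pos=10 * i,
                ref="A",
                alt="G",
                orientation=HOMREF_PARENTS,
                offspring_gt=Genotype(GT.HET, (dp_o - ad1, ad1), dp_o, gq),
                father_gt=Genotype(GT.HOM_REF, (dp_p - p_ad1, p_ad1), dp_p, gq),
                mother_gt=Genotype(GT.HOM_REF, (dp_p, 0), dp_p, gq),
                info=info,
            )
        )
    return cands


def brute_force_pass(c) -> bool:
    i = c.info
    if i.get("QD", 99) < 2.0 or i.get("MQ", 99) < 40.0:
        return False
    if i.get("FS", 0) > 60.0 or i.get("SOR", 0) > 3.0:
        return False
    if i.get("MQRankSum", 0) < -12.5 or i.get("ReadPosRankSum", 0) < -8.0:
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
    mean_dp = (c.father_gt.dp + c.mother_gt.dp + c.offspring_gt.dp) / 3.0
    if c.offspring_gt.dp < 0.5 * mean_dp or c.offspring_gt.dp > 2.0 * mean_dp:
        return False
    return True
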