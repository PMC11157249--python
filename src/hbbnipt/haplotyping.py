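"""Parental HBB haplotypes and transmission inference from plasma ratios.

Long-read sequencing of a 2.2 kb HBB amplicon (chr11:5246155-5248406)
gives, per parent, reads spanning several heterozygous positions at once.
Heterozygous sites are called from minor-allele read frequencies, reads
are partitioned into two clusters by greedy agreement, and the per-cluster
majority alleles form the two parental haplotypes.  The common 619 bp
deletion participates as an allele in phase with the SNPs: reads spanning
the deletion junction carry ``DEL619`` at a pseudo-site.

Each of the four (maternal haplotype, paternal haplotype) transmission
combinations implies one fetal genotype at every phased site, hence one
expected plasma allele proportion given the fetal fraction; summing
per-site binomial log-likelihoods scores the combinations jointly, so the
read ratios at SNPs linked to a mutation inform the mutation-site call
even when the ratio at the mutation site itself is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_caller import (
    DEFAULT_TAU,
    Genotype,
    GenotypeCall,
    GenotypeHypothesis,
    P_FLOOR,
    expected_fraction,
    _norm_gt,
)
from scipy.stats import binom

__all__ = [
    "AMPLICON_REGION",
    "DEL619_ALLELE",
    "HaplotypePair",
    "TransmissionResult",
    "PhasingError",
    "call_amplicon_variants",
    "phase_haplotypes",
    "infer_transmission",
    "transmission_to_call",
    "combined_call",
]

AMPLICON_REGION = ("chr11", 5246155, 5248406)
DEL619_ALLELE = "DEL619"

#: minor-allele read-frequency threshold for calling a heterozygous site
#: on long-read amplicon data (tolerant of the platform's error rate)
MIN_MINOR_FREQ = 0.16
#: indel candidates need stronger support than substitutions
MIN_INDEL_FREQ = 0.30
MIN_COVERAGE = 100


class PhasingError(RuntimeError):
    pass


@dataclass
class HaplotypePair:
    """Two phased allele vectors for one parent over amplicon sites."""

    parent: str  # mother | father
    sites: list[tuple[str, int]]
    hap1: tuple[str, ...]
    hap2: tuple[str, ...]
    support1: float = 0.5
    support2: float = 0.5

    def __post_init__(self) -> None:
        if len(self.hap1) != len(self.sites) or len(self.hap2) != len(self.sites):
            raise ValueError("haplotype vectors must match the site list")
        if self.support1 + self.support2 > 1.0 + 1e-9:
            raise ValueError("haplotype supports cannot exceed 1 in total")

    def genotype_at(self, site: tuple[str, int]) -> Genotype:
        i = self.sites.index(site)
        return _norm_gt((self.hap1[i], self.hap2[i]))

    def haplotype(self, index: int) -> tuple[str, ...]:
        return self.hap1 if index == 1 else self.hap2


@dataclass
class TransmissionResult:
    maternal_hap: Optional[int]  # 1 or 2
    paternal_hap: Optional[int]
    combo_logliks: np.ndarray  # 2x2, [maternal-1][paternal-1]
    mutation_site_gt: Optional[Genotype]
    ambiguous: bool
    uninformative: bool = False
    log_likelihood_ratio: float = float("inf")
    site_genotypes: dict[tuple[str, int], Genotype] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Amplicon variant calling and phasing


def call_amplicon_variants(
    matrix: pd.DataFrame,
    min_minor_freq: float = MIN_MINOR_FREQ,
    min_indel_freq: float = MIN_INDEL_FREQ,
    min_coverage: int = MIN_COVERAGE,
) -> list:
    """Identify heterozygous candidate sites in a read x site allele matrix.

    Columns are sites, rows reads; missing observations are NaN.  A site is
    called when its minor-allele frequency exceeds ``min_minor_freq``
    (``min_indel_freq`` for indel/deletion tokens).  Raises when overall
    coverage is below ``min_coverage`` reads.
    """
    if len(matrix) < min_coverage:
        raise PhasingError(
            f"coverage {len(matrix)} below minimum {min_coverage} reads"
        )
    called = []
    for col in matrix.columns:
        vals = matrix[col].dropna()
        if vals.empty:
            continue
        freqs = vals.value_counts(normalize=True)
        if len(freqs) < 2:
            continue
        minor_allele = freqs.index[1]
        minor = float(freqs.iloc[1])
        is_indel = str(minor_allele).startswith(("INS", "DEL")) or str(
            freqs.index[0]
        ).startswith(("INS", "DEL"))
        threshold = min_indel_freq if is_indel else min_minor_freq
        if minor > threshold:
            called.append(col)
    return called


def phase_haplotypes(
    matrix: pd.DataFrame,
    called_sites: Optional[Sequence] = None,
    parent: str = "unknown",
    max_iter: int = 20,
    **variant_kwargs,
) -> HaplotypePair:
    """Partition amplicon reads into two haplotype clusters.

    Greedy agreement clustering: seed haplotypes from the two most frequent
    complementary allele patterns at the highest-coverage pair of called
    sites, assign every read to the consensus it agrees with best (ties
    stay unassigned), then alternate consensus/assignment until stable.
    """
    if called_sites is None:
        called_sites = call_amplicon_variants(matrix, **variant_kwargs)
    called_sites = list(called_sites)
    if not called_sites:
        raise PhasingError("no heterozygous site to phase")
    sub = matrix[called_sites]

    if len(called_sites) == 1:
        col = sub[called_sites[0]].dropna()
        freqs = col.value_counts()
        a, b = freqs.index[0], freqs.index[1]
        n = len(col)
        return HaplotypePair(
            parent, _site_keys(called_sites), (a,), (b,),
            float(freqs.iloc[0]) / n, float(freqs.iloc[1]) / n,
        )

    # seed from the pair of called sites with highest joint coverage
    cov = sub.notna().astype(int)
    best_pair, best_n = None, -1
    for i in range(len(called_sites)):
        for j in range(i + 1, len(called_sites)):
            n = int((cov.iloc[:, i] & cov.iloc[:, j]).sum())
            if n > best_n:
                best_n, best_pair = n, (called_sites[i], called_sites[j])
    if best_n < 1:
        raise PhasingError("no read links two heterozygous sites")
    pair_obs = sub[list(best_pair)].dropna()
    patterns = pair_obs.value_counts()
    seed1 = patterns.index[0]
    seed2 = None
    for pat in patterns.index[1:]:
        if pat[0] != seed1[0] and pat[1] != seed1[1]:
            seed2 = pat
            break
    if seed2 is None:
        seed2 = patterns.index[1] if len(patterns) > 1 else None
    if seed2 is None:
        raise PhasingError("cannot seed two haplotypes: only one pattern observed")

    # consensus vectors over all called sites, seeded at the pair
    cons = [dict(zip(best_pair, seed1)), dict(zip(best_pair, seed2))]
    vals = sub.to_numpy(dtype=object)
    assign = np.full(len(sub), -1)
    for _ in range(max_iter):
        score = np.zeros((len(sub), 2))
        for ci, c in enumerate(cons):
            for j, site in enumerate(called_sites):
                if site not in c:
                    continue
                colv = vals[:, j]
                covered = pd.notna(colv)
                score[covered, ci] += np.where(colv[covered] == c[site], 1, -1)
        new_assign = np.where(score[:, 0] > score[:, 1], 0,
                              np.where(score[:, 1] > score[:, 0], 1, -1))
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for ci in range(2):
            members = vals[assign == ci]
            if not len(members):
                continue
            for j, site in enumerate(called_sites):
                colv = pd.Series(members[:, j]).dropna()
                if len(colv):
                    cons[ci][site] = colv.value_counts().index[0]

    hap1 = tuple(cons[0].get(s, "N") for s in called_sites)
    hap2 = tuple(cons[1].get(s, "N") for s in called_sites)
    n = len(sub)
    return HaplotypePair(
        parent,
        _site_keys(called_sites),
        hap1,
        hap2,
        float((assign == 0).sum()) / n,
        float((assign == 1).sum()) / n,
    )


def _site_keys(cols: Sequence) -> list[tuple[str, int]]:
    keys = []
    for c in cols:
        if isinstance(c, tuple) and len(c) == 2:
            keys.append((str(c[0]), int(c[1])))
        elif isinstance(c, str) and ":" in c:
            chrom, _, pos = c.rpartition(":")
            keys.append((chrom, int(pos)))
        else:
            keys.append(c)
    return keys


# ---------------------------------------------------------------------------
# Transmission inference


def infer_transmission(
    plasma_counts: Mapping[tuple[str, int], Mapping[str, int]],
    maternal: HaplotypePair,
    paternal: HaplotypePair,
    ff: float,
    mutation_site: Optional[tuple[str, int]] = None,
    counted_alleles: Optional[Mapping[tuple[str, int], str]] = None,
    tau: float = DEFAULT_TAU,
) -> TransmissionResult:
    """Joint likelihood over the four parental-haplotype transmissions.

    For each (maternal hap, paternal hap) combination the implied fetal
    genotype at every phased site with plasma counts yields an expected
    allele proportion; the combination log-likelihood sums per-site
    binomial terms.  If all four combinations imply identical genotypes at
    every covered site the result is uninformative — the linked-SNP ratios
    cannot reveal which haplotype was transmitted.
    """
    if ff <= 0.0:
        raise ValueError("fetal fraction must be positive")
    shared = [s for s in maternal.sites if s in paternal.sites and s in plasma_counts]
    if not shared:
        raise ValueError("no phased site with plasma counts")

    logliks = np.zeros((2, 2))
    combo_site_gts: dict[tuple[int, int], dict[tuple[str, int], Genotype]] = {}
    for mi in (1, 2):
        for pi in (1, 2):
            total = 0.0
            gts: dict[tuple[str, int], Genotype] = {}
            for site in shared:
                m_allele = maternal.haplotype(mi)[maternal.sites.index(site)]
                p_allele = paternal.haplotype(pi)[paternal.sites.index(site)]
                fetal = _norm_gt((m_allele, p_allele))
                gts[site] = fetal
                counts = plasma_counts[site]
                counted = (
                    counted_alleles[site]
                    if counted_alleles and site in counted_alleles
                    else _default_counted(maternal, site)
                )
                m_gt = maternal.genotype_at(site)
                universe = set(m_gt) | set(paternal.genotype_at(site)) | {counted}
                k = int(counts.get(counted, 0))
                n = int(sum(counts.get(a, 0) for a in universe))
                if n == 0:
                    continue
                p = expected_fraction(m_gt, fetal, counted, ff)
                p = min(max(p, P_FLOOR), 1.0 - P_FLOOR)
                total += float(binom.logpmf(k, n, p))
            logliks[mi - 1, pi - 1] = total
            combo_site_gts[(mi, pi)] = gts

    gt_patterns = {tuple(sorted(g.items())) for g in combo_site_gts.values()}
    if len(gt_patterns) == 1:
        return TransmissionResult(
            None, None, logliks, None, ambiguous=True, uninformative=True,
            log_likelihood_ratio=0.0,
        )

    order = sorted(
        ((mi, pi) for mi in (1, 2) for pi in (1, 2)),
        key=lambda c: -logliks[c[0] - 1, c[1] - 1],
    )
    top, runner = order[0], order[1]
    llr = float(
        logliks[top[0] - 1, top[1] - 1] - logliks[runner[0] - 1, runner[1] - 1]
    )
    ambiguous = llr < tau
    site_gts = combo_site_gts[top]
    mut_gt = site_gts.get(mutation_site) if mutation_site else None
    return TransmissionResult(
        top[0], top[1], logliks, mut_gt, ambiguous,
        log_likelihood_ratio=llr, site_genotypes=site_gts,
    )


def _default_counted(hap: HaplotypePair, site: tuple[str, int]) -> str:
    """Counted allele at a phased site: lexicographically last parental
    allele (stable and symmetric; the binomial is invariant to the choice)."""
    return max(hap.genotype_at(site))


def transmission_to_call(
    result: TransmissionResult,
    site: tuple[str, int],
    maternal: HaplotypePair,
    paternal: HaplotypePair,
) -> GenotypeCall:
    """Render the transmission result as a genotype call at one site."""
    chrom, pos = site
    if result.uninformative:
        return GenotypeCall(chrom, pos, "haplotype", (), [], no_call=True,
                            reason="transmission uninformative")
    gt = result.site_genotypes.get(site)
    if gt is None:
        mi = result.maternal_hap or 1
        pi = result.paternal_hap or 1
        gt = _norm_gt((
            maternal.haplotype(mi)[maternal.sites.index(site)],
            paternal.haplotype(pi)[paternal.sites.index(site)],
        ))
    if result.ambiguous:
        # top two combinations may imply distinct genotypes at this site
        order = np.argsort(result.combo_logliks, axis=None)[::-1]
        gts: list[Genotype] = []
        for flat in order[:2]:
            mi, pi = divmod(int(flat), 2)
            g = _norm_gt((
                maternal.haplotype(mi + 1)[maternal.sites.index(site)],
                paternal.haplotype(pi + 1)[paternal.sites.index(site)],
            ))
            if g not in gts:
                gts.append(g)
        return GenotypeCall(chrom, pos, "haplotype", tuple(gts),
                            log_likelihood_ratio=result.log_likelihood_ratio,
                            ambiguous=True)
    return GenotypeCall(chrom, pos, "haplotype", (gt,),
                        log_likelihood_ratio=result.log_likelihood_ratio,
                        ambiguous=False)


def combined_call(
    ratio_call: GenotypeCall, haplotype_call: Optional[GenotypeCall]
) -> GenotypeCall:
    """Merge a ratio-based call with a haplotype-transmission call.

    An informative, unambiguous haplotype call overrides the ratio-only
    call; otherwise the ratio call stands, annotated with the haplotype
    status.  (Linked-SNP evidence aggregates many positions and resolves
    cases the single-site ratio cannot.)
    """
    if (
        haplotype_call is not None
        and not haplotype_call.no_call
        and not haplotype_call.ambiguous
        and haplotype_call.called_gt
    ):
        return GenotypeCall(
            ratio_call.chrom or haplotype_call.chrom,
            ratio_call.pos or haplotype_call.pos,
            "combined",
            haplotype_call.called_gt,
            ratio_call.hypotheses,
            haplotype_call.log_likelihood_ratio,
            ambiguous=False,
        )
    reason = None
    if haplotype_call is None:
        reason = "no haplotype information"
    elif haplotype_call.no_call:
        reason = haplotype_call.reason or "haplotype no-call"
    elif haplotype_call.ambiguous:
        reason = "haplotype transmission ambiguous"
    out = GenotypeCall(
        ratio_call.chrom,
        ratio_call.pos,
        "combined",
        ratio_call.called_gt,
        ratio_call.hypotheses,
        ratio_call.log_likelihood_ratio,
        ambiguous=ratio_call.ambiguous,
        no_call=ratio_call.no_call,
        reason=reason if not ratio_call.no_call else ratio_call.reason,
    )
    return out
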