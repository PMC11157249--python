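"""Fetal fraction (FF) estimation and in-silico size-selection (ISS) scan.

The FF is the proportion of plasma cfDNA molecules of fetal origin.  It is
estimated from *informative SNPs*: panel positions where the mother is
homozygous but the plasma contains a second allele, which must have been
transmitted to the fetus by the father.  Because the fetus carries one
maternal-type and one paternal-type allele, the obligate-fetal allele marks
only half of the fetal molecules, so

    FF = 2 x mean over informative SNPs of (fetal-allele reads / depth).

Fetal fragments tend to be shorter than maternal ones, so excluding
fragments above a length cutoff (ISS) enriches the FF at the cost of read
depth; :func:`iss_scan` traces that trade-off over a grid of cutoffs and
:func:`select_cutoff` picks an operating point under a read-retention
constraint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .fragments_io import AlleleCountTable, FragmentTable, count_alleles, size_select

__all__ = [
    "GenotypeMap",
    "InformativeSnp",
    "FFEstimate",
    "IssPoint",
    "IssCurve",
    "CutoffChoice",
    "NoInformativeSnpsError",
    "find_informative_snps",
    "estimate_ff",
    "iss_scan",
    "select_cutoff",
    "read_genotype_map",
]

#: genotype map: (chrom, pos) -> unordered allele pair
GenotypeMap = Mapping[tuple[str, int], tuple[str, str]]

#: Proportion thresholds for accepting a non-maternal allele as fetal.
#: Below the noise floor it is indistinguishable from sequencing error;
#: above the upper bound it more likely reflects a maternal genotyping
#: error than a fetal allele (a fetal allele cannot exceed ~FF/2).
DEFAULT_NOISE_FLOOR = 0.005
DEFAULT_UPPER_BOUND = 0.25


class NoInformativeSnpsError(RuntimeError):
    """No informative SNP available; FF estimation must be refused."""


@dataclass(frozen=True)
class InformativeSnp:
    chrom: str
    pos: int
    maternal_allele: str
    fetal_allele: str
    fetal_reads: int
    total_reads: int
    paternal_consistent: Optional[bool] = None

    @property
    def fetal_proportion(self) -> float:
        return self.fetal_reads / self.total_reads


@dataclass
class FFEstimate:
    """Fetal fraction with its per-SNP provenance."""

    ff: float
    n_snps: int
    per_snp: list[InformativeSnp]
    informative_read_count: int
    length_cutoff: Optional[int] = None

    @property
    def ff_percent(self) -> float:
        return 100.0 * self.ff


@dataclass
class IssPoint:
    cutoff: int
    estimate: Optional[FFEstimate]
    informative_reads: int
    valid: bool


@dataclass
class IssCurve:
    baseline: FFEstimate
    points: list[IssPoint]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                cutoff_bp=p.cutoff,
                ff_percent=p.estimate.ff_percent if p.valid else np.nan,
                n_informative_snps=p.estimate.n_snps if p.valid else 0,
                informative_reads=p.informative_reads,
            )
            for p in self.points
        ]
        return pd.DataFrame(rows)


@dataclass
class CutoffChoice:
    cutoff: Optional[int]
    estimate: FFEstimate
    constrained: bool  # False when no scan point met the retention constraint


def find_informative_snps(
    counts: AlleleCountTable,
    maternal_gt: GenotypeMap,
    paternal_gt: Optional[GenotypeMap] = None,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    upper_bound: float = DEFAULT_UPPER_BOUND,
    sites: Optional[Sequence[tuple[str, int]]] = None,
) -> list[InformativeSnp]:
    """Detect SNPs where the plasma carries an allele absent in the mother.

    A site qualifies when the mother is homozygous and exactly one
    non-maternal allele has a read proportion within
    ``[noise_floor, upper_bound]``; two or more non-maternal alleles above
    the floor indicate error and disqualify the site.  When paternal
    genotypes are supplied, candidate fetal alleles the father does not
    carry are flagged inconsistent (possible non-paternity or genotyping
    error) and excluded from FF estimation.
    """
    out: list[InformativeSnp] = []
    site_list = sites if sites is not None else counts.sites()
    for chrom, pos in site_list:
        gt = maternal_gt.get((chrom, pos))
        if gt is None or gt[0] != gt[1]:
            continue
        mat = gt[0]
        allele_counts = counts.counts_at(chrom, pos)
        depth = sum(allele_counts.values())
        if depth == 0:
            continue
        candidates = [
            (a, n)
            for a, n in allele_counts.items()
            if a != mat and n / depth >= noise_floor
        ]
        if len(candidates) != 1:
            continue
        allele, n = candidates[0]
        if n / depth > upper_bound:
            continue
        consistent: Optional[bool] = None
        if paternal_gt is not None and (chrom, pos) in paternal_gt:
            consistent = allele in paternal_gt[(chrom, pos)]
            if not consistent:
                out.append(
                    InformativeSnp(chrom, pos, mat, allele, n, depth, consistent)
                )
                continue
        out.append(InformativeSnp(chrom, pos, mat, allele, n, depth, consistent))
    return out


def estimate_ff(
    snps: Sequence[InformativeSnp],
    length_cutoff: Optional[int] = None,
    depth_weighted: bool = False,
) -> FFEstimate:
    """FF = 2 x (mean fetal proportion over informative SNPs).

    The unweighted mean is the primary estimator; ``depth_weighted=True``
    pools reads across SNPs instead.  SNPs flagged paternally inconsistent
    are dropped before averaging.
    """
    usable = [s for s in snps if s.paternal_consistent is not False]
    if not usable:
        raise NoInformativeSnpsError(
            "no informative SNPs: refusing to estimate the fetal fraction"
        )
    if depth_weighted:
        mean_prop = sum(s.fetal_reads for s in usable) / sum(
            s.total_reads for s in usable
        )
    else:
        mean_prop = float(np.mean([s.fetal_proportion for s in usable]))
    ff = 2.0 * mean_prop
    if ff > 1.0:
        warnings.warn("FF estimate exceeded 1; clipped", stacklevel=2)
        ff = 1.0
    return FFEstimate(
        ff=ff,
        n_snps=len(usable),
        per_snp=list(usable),
        informative_read_count=int(sum(s.total_reads for s in usable)),
        length_cutoff=length_cutoff,
    )


def iss_scan(
    table: FragmentTable,
    maternal_gt: GenotypeMap,
    grid: Optional[Sequence[int]] = None,
    paternal_gt: Optional[GenotypeMap] = None,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    upper_bound: float = DEFAULT_UPPER_BOUND,
    depth_weighted: bool = False,
) -> IssCurve:
    """Re-estimate the FF over a descending grid of length cutoffs.

    The default grid excludes fragments sequentially from 167 bp down to
    100 bp in 1 bp steps.  Each point re-applies size selection, recounts
    alleles, re-detects informative SNPs, and re-estimates the FF; points
    where no informative SNP survives are flagged invalid and the scan
    continues.
    """
    if not table.deduped:
        warnings.warn("iss_scan input is not deduplicated", stacklevel=2)
    if grid is None:
        grid = range(167, 99, -1)
    grid = sorted(set(int(g) for g in grid), reverse=True)

    def _estimate(tab: FragmentTable, cutoff: Optional[int]):
        counts = count_alleles(tab)
        snps = find_informative_snps(
            counts, maternal_gt, paternal_gt, noise_floor, upper_bound
        )
        return estimate_ff(snps, length_cutoff=cutoff, depth_weighted=depth_weighted)

    baseline = _estimate(table, None)
    points: list[IssPoint] = []
    for cutoff in grid:
        sub = size_select(table, cutoff)
        try:
            est = _estimate(sub, cutoff)
            points.append(IssPoint(cutoff, est, est.informative_read_count, True))
        except NoInformativeSnpsError:
            points.append(IssPoint(cutoff, None, 0, False))
    return IssCurve(baseline=baseline, points=points)


def select_cutoff(
    curve: IssCurve,
    min_retained_fraction: float = 0.20,
    min_reads: Optional[int] = None,
) -> CutoffChoice:
    """Pick the cutoff maximising FF subject to a read-retention constraint.

    The FF gain from size selection must be balanced against the loss of
    informative reads (and the noise that loss brings).  A scan point is
    feasible when it keeps at least ``min_retained_fraction`` of the
    unfiltered informative reads (or ``min_reads`` reads when given); among
    feasible points the largest FF wins, ties going to the larger cutoff.
    With no feasible point the unfiltered estimate is returned with a
    warning.
    """
    floor = (
        min_reads
        if min_reads is not None
        else min_retained_fraction * curve.baseline.informative_read_count
    )
    feasible = [
        p for p in curve.points if p.valid and p.informative_reads >= floor
    ]
    if not feasible:
        warnings.warn(
            "no ISS cutoff satisfies the read-retention constraint; "
            "returning the unfiltered estimate",
            stacklevel=2,
        )
        return CutoffChoice(None, curve.baseline, constrained=False)
    best = max(feasible, key=lambda p: (p.estimate.ff, p.cutoff))
    return CutoffChoice(best.cutoff, best.estimate, constrained=True)


def read_genotype_map(path) -> dict[str, dict[tuple[str, int], tuple[str, str]]]:
    """Read a parental genotype TSV: chrom, pos, parent, allele1, allele2."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "parent": str})
    required = {"chrom", "pos", "parent", "allele1", "allele2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"genotype map missing columns {sorted(missing)}")
    out: dict[str, dict[tuple[str, int], tuple[str, str]]] = {}
    for row in df.itertuples(index=False):
        if row.parent not in {"mother", "father"}:
            raise ValueError(f"unknown parent label {row.parent!r}")
        out.setdefault(row.parent, {})[(row.chrom, int(row.pos))] = (
            str(row.allele1),
            str(row.allele2),
        )
    return out
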