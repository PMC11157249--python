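"""Fetal genotype inference from plasma allele-read ratios.

At a site where the mother carries dosage ``d_m`` (0, 1 or 2 copies) of a
counted allele and the fetus dosage ``d_f``, the expected proportion of
that allele among plasma reads is

    p = (1 - f) * d_m / 2 + f * d_f / 2

with ``f`` the fetal fraction.  For a homozygous A/A mother and an A/T
fetus the maternal allele is expected at 100% - FF%/2.  Each fetal
genotype transmissible from the parental genotypes (Mendelian feasibility)
yields one expected proportion; the observed counts are scored with a
binomial log-likelihood under each hypothesis and the maximum-likelihood
genotype is called.  When the top two hypotheses are separated by less
than ``tau`` natural-log units the call is reported ambiguous and lists
both, mirroring two-genotype calls such as "G/T or T/T".

Classification by nearest expected ratio (the simplest reading of the
observed-vs-expected comparison) is available via ``method="nearest"``;
binomial maximum likelihood ranks identically when expected ratios are
equidistant at fixed depth and additionally supports the likelihood-ratio
ambiguity flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import binom

from .fragments_io import SPANNING_DEL, SPANNING_REF

__all__ = [
    "Genotype",
    "GenotypeHypothesis",
    "GenotypeCall",
    "DEFAULT_TAU",
    "DEFAULT_MIN_DEPTH",
    "P_FLOOR",
    "expected_fraction",
    "feasible_genotypes",
    "genotype_likelihoods",
    "call_genotype",
    "call_site",
    "call_deletion_site",
]

Genotype = tuple[str, str]

#: ambiguity threshold, natural-log units of likelihood ratio
DEFAULT_TAU = 2.0
#: minimum post-dedup depth for a ratio call
DEFAULT_MIN_DEPTH = 50
#: expected-fraction clamp: keeps a sequencing noise floor under
#: homozygous hypotheses whose nominal expectation is 0 (or 1)
P_FLOOR = 1e-3


def _norm_gt(gt: Sequence[str]) -> Genotype:
    a, b = gt
    return (a, b) if a <= b else (b, a)


def _dosage(gt: Sequence[str], allele: str) -> int:
    return sum(1 for a in gt if a == allele)


@dataclass(frozen=True)
class GenotypeHypothesis:
    fetal_gt: Genotype
    expected_fraction: float
    log_likelihood: float
    feasible: bool = True


@dataclass
class GenotypeCall:
    chrom: Optional[str]
    pos: Optional[int]
    method: str  # ratio | ratio_iss | haplotype | combined
    called_gt: tuple[Genotype, ...]  # one genotype, or two when ambiguous
    hypotheses: list[GenotypeHypothesis] = field(default_factory=list)
    log_likelihood_ratio: float = float("inf")
    ambiguous: bool = False
    no_call: bool = False
    reason: Optional[str] = None

    @property
    def genotype(self) -> Optional[Genotype]:
        return self.called_gt[0] if self.called_gt else None


def expected_fraction(
    maternal_gt: Sequence[str],
    fetal_gt: Sequence[str],
    counted_allele: str,
    ff: float,
) -> float:
    """Expected plasma proportion of ``counted_allele``.

    ``(1-ff) * d_m/2 + ff * d_f/2`` where ``d_m``/``d_f`` are maternal and
    fetal dosages of the counted allele.
    """
    if not 0.0 <= ff <= 1.0:
        raise ValueError(f"fetal fraction must be on [0, 1], got {ff}")
    d_m = _dosage(maternal_gt, counted_allele)
    d_f = _dosage(fetal_gt, counted_allele)
    return (1.0 - ff) * d_m / 2.0 + ff * d_f / 2.0


def feasible_genotypes(
    maternal_gt: Sequence[str], paternal_gt: Sequence[str]
) -> list[Genotype]:
    """Fetal genotypes transmissible from the parents (no de novo events)."""
    gts = {_norm_gt((m, p)) for m, p in product(maternal_gt, paternal_gt)}
    return sorted(gts)


def genotype_likelihoods(
    counts: Mapping[str, int],
    maternal_gt: Sequence[str],
    paternal_gt: Sequence[str],
    ff: float,
    counted_allele: str,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[GenotypeHypothesis]:
    """Binomial log-likelihood of the counted-allele reads per hypothesis.

    Depth is the total over the parental allele universe at the site
    (error alleles outside it do not dilute the ratio).  Refuses ``ff=0``,
    under which all hypotheses coincide at maternal-het sites, and depths
    below ``min_depth``.
    """
    if ff <= 0.0:
        raise ValueError("fetal fraction must be positive for ratio calling")
    universe = set(maternal_gt) | set(paternal_gt) | {counted_allele}
    k = int(counts.get(counted_allele, 0))
    n = int(sum(counts.get(a, 0) for a in universe))
    if n < min_depth:
        raise ValueError(f"depth {n} below minimum {min_depth}")
    hyps = []
    for gt in feasible_genotypes(maternal_gt, paternal_gt):
        p = expected_fraction(maternal_gt, gt, counted_allele, ff)
        p = min(max(p, P_FLOOR), 1.0 - P_FLOOR)
        ll = float(binom.logpmf(k, n, p))
        hyps.append(GenotypeHypothesis(gt, p, ll, feasible=True))
    return hyps


def call_genotype(
    hypotheses: Sequence[GenotypeHypothesis],
    tau: float = DEFAULT_TAU,
    chrom: Optional[str] = None,
    pos: Optional[int] = None,
    method: str = "ratio",
    selection: str = "likelihood",
    observed_proportion: Optional[float] = None,
) -> GenotypeCall:
    """Pick the top hypothesis; flag ambiguity below the ``tau`` log-LR.

    ``selection="nearest"`` ranks by |observed - expected| proportion
    instead (requires ``observed_proportion``); the log-LR and ambiguity
    flag are still computed from the likelihoods.
    """
    feas = [h for h in hypotheses if h.feasible]
    if not feas:
        raise ValueError("no feasible hypothesis to call")
    if selection == "likelihood":
        ranked = sorted(feas, key=lambda h: -h.log_likelihood)
    elif selection == "nearest":
        if observed_proportion is None:
            raise ValueError("nearest-ratio selection needs observed_proportion")
        ranked = sorted(
            feas, key=lambda h: abs(h.expected_fraction - observed_proportion)
        )
    else:
        raise ValueError(f"unknown selection {selection!r}")
    if len(ranked) == 1:
        return GenotypeCall(chrom, pos, method, (ranked[0].fetal_gt,),
                            list(ranked), float("inf"), False)
    llr = ranked[0].log_likelihood - ranked[1].log_likelihood
    ambiguous = llr < tau
    called = (
        (ranked[0].fetal_gt, ranked[1].fetal_gt) if ambiguous else (ranked[0].fetal_gt,)
    )
    return GenotypeCall(chrom, pos, method, called, list(ranked), float(llr), ambiguous)


def call_site(
    counts: Mapping[str, int],
    maternal_gt: Sequence[str],
    paternal_gt: Sequence[str],
    ff: float,
    counted_allele: str,
    tau: float = DEFAULT_TAU,
    min_depth: int = DEFAULT_MIN_DEPTH,
    chrom: Optional[str] = None,
    pos: Optional[int] = None,
    method: str = "ratio",
    selection: str = "likelihood",
) -> GenotypeCall:
    """Convenience wrapper: likelihoods then call, with no-call on refusal."""
    try:
        hyps = genotype_likelihoods(
            counts, maternal_gt, paternal_gt, ff, counted_allele, min_depth
        )
    except ValueError as exc:
        return GenotypeCall(chrom, pos, method, (), [], no_call=True,
                            reason=str(exc))
    universe = set(maternal_gt) | set(paternal_gt) | {counted_allele}
    n = sum(counts.get(a, 0) for a in universe)
    obs = counts.get(counted_allele, 0) / n if n else None
    return call_genotype(
        hyps, tau=tau, chrom=chrom, pos=pos, method=method,
        selection=selection, observed_proportion=obs,
    )


def call_deletion_site(
    spanning_counts: Mapping[str, int],
    maternal_gt: Sequence[str],
    paternal_gt: Sequence[str],
    ff: float,
    tau: float = DEFAULT_TAU,
    min_depth: int = DEFAULT_MIN_DEPTH,
    chrom: Optional[str] = None,
    pos: Optional[int] = None,
) -> GenotypeCall:
    """Genotype the 619 bp deletion as a biallelic DEL619/REF site.

    Junction-spanning fragments count for the deleted chromosome, fragments
    across or inside the intact region for the reference chromosome; other
    fragments are uninformative.  Zero informative fragments yield a
    no-call.
    """
    counts = {
        "DEL619": int(spanning_counts.get(SPANNING_DEL, 0)),
        "REF": int(spanning_counts.get(SPANNING_REF, 0)),
    }
    if counts["DEL619"] + counts["REF"] == 0:
        return GenotypeCall(chrom, pos, "ratio", (), [], no_call=True,
                            reason="no fragments informative about the deletion")
    return call_site(
        counts, maternal_gt, paternal_gt, ff, counted_allele="DEL619",
        tau=tau, min_depth=min_depth, chrom=chrom, pos=pos,
    )
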