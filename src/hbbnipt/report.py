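"""Case orchestration and report rendering.

:func:`run_case` executes the full decision logic for one family:
deduplication and fetal-fraction work when raw fragments are supplied,
ratio-based genotype calls before and after in-silico size selection,
haplotype-transmission inference when phased parental haplotypes are
available, and the combined per-site calls (an unambiguous haplotype
result overrides the single-site ratio call).  :func:`render_report`
writes the outcome as a TSV table (integer percentages, matching the
``"59C/41G"`` reporting style) and a JSON document with full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from . import fetal_fraction as ffmod
from .cases import (
    CaseBundle,
    CaseError,
    CaseSite,
    parse_ratio,
    render_genotype,
    render_ratio,
)
from .fragments_io import (
    SPANNING_DEL,
    SPANNING_REF,
    count_alleles,
    dedup_umi,
    size_select,
)
from .genotype_caller import (
    DEFAULT_MIN_DEPTH,
    DEFAULT_TAU,
    GenotypeCall,
    call_deletion_site,
    call_site,
)
from .haplotyping import (
    TransmissionResult,
    combined_call,
    infer_transmission,
    transmission_to_call,
)

__all__ = ["RunConfig", "SiteResult", "CaseReport", "run_case", "render_report"]


@dataclass
class RunConfig:
    tau: float = DEFAULT_TAU
    min_depth: int = DEFAULT_MIN_DEPTH
    iss_grid: Optional[list[int]] = None
    min_retained_fraction: float = 0.20
    noise_floor: float = ffmod.DEFAULT_NOISE_FLOOR
    upper_bound: float = ffmod.DEFAULT_UPPER_BOUND


@dataclass
class SiteResult:
    site: CaseSite
    call_pre: Optional[GenotypeCall]
    call_post: Optional[GenotypeCall]
    haplotype_call: Optional[GenotypeCall]
    combined: GenotypeCall
    concordant: Optional[bool]


@dataclass
class CaseReport:
    family: str
    ff_pre: Optional[float]
    ff_post: Optional[float]
    iss_cutoff_bp: Optional[int]
    results: list[SiteResult]
    transmission: Optional[TransmissionResult] = None

    @property
    def n_concordant(self) -> int:
        return sum(1 for r in self.results if r.concordant)


def _gt_string(call: Optional[GenotypeCall]) -> str:
    if call is None:
        return ""
    if call.no_call:
        return "no-call"
    names = [render_genotype(g) for g in call.called_gt]
    return " or ".join(names)


def _ratio_call(
    site: CaseSite, counts: Optional[dict], ff: Optional[float],
    config: RunConfig, method: str
) -> Optional[GenotypeCall]:
    if counts is None or ff is None:
        return None
    if site.is_deletion_region:
        spanning = {
            SPANNING_DEL: counts.get("DEL619", counts.get(SPANNING_DEL, 0)),
            SPANNING_REF: counts.get("REF", counts.get(SPANNING_REF, 0)),
        }
        return call_deletion_site(
            spanning, site.maternal_gt, site.paternal_gt, ff,
            tau=config.tau, min_depth=config.min_depth,
            chrom=site.chrom, pos=site.pos,
        )
    return call_site(
        counts, site.maternal_gt, site.paternal_gt, ff,
        counted_allele=site.alt, tau=config.tau, min_depth=config.min_depth,
        chrom=site.chrom, pos=site.pos, method=method,
    )


def run_case(bundle: CaseBundle, config: Optional[RunConfig] = None) -> CaseReport:
    """Execute dedup -> FF -> ISS -> ratio calls -> haplotypes -> combined.

    With raw fragments the fetal fraction is estimated from informative
    SNPs and the size-selection cutoff chosen by scanning; with ratio-only
    bundles the recorded fetal fractions and printed ratios are used
    directly.  Deterministic given its inputs.
    """
    config = config or RunConfig()
    bundle.validate()

    ff_pre, ff_post = bundle.ff_pre, bundle.ff_post
    cutoff = bundle.iss_cutoff_bp
    counts_pre_tab = counts_post_tab = None
    if bundle.fragments is not None:
        table = bundle.fragments
        if not table.deduped:
            table = dedup_umi(table)
        counts_pre_tab = count_alleles(table)
        curve = ffmod.iss_scan(
            table,
            bundle.maternal_gt_map,
            grid=config.iss_grid,
            noise_floor=config.noise_floor,
            upper_bound=config.upper_bound,
        )
        ff_pre = curve.baseline.ff
        choice = ffmod.select_cutoff(
            curve, min_retained_fraction=config.min_retained_fraction
        )
        cutoff = choice.cutoff
        if cutoff is not None:
            ff_post = choice.estimate.ff
            counts_post_tab = count_alleles(size_select(table, cutoff))

    transmission = None
    hap_available = (
        bundle.maternal_haplotypes is not None
        and bundle.paternal_haplotypes is not None
    )
    if hap_available:
        which = "post" if ff_post is not None else "pre"
        ff_for_hap = ff_post if ff_post is not None else ff_pre
        plasma = {}
        for site in bundle.sites:
            counts = _site_counts(bundle, site, which, counts_pre_tab, counts_post_tab)
            if counts is None and which == "post":
                counts = _site_counts(bundle, site, "pre", counts_pre_tab, None)
            if counts:
                plasma[site.key] = counts
        shared = [
            s for s in bundle.maternal_haplotypes.sites
            if s in bundle.paternal_haplotypes.sites and s in plasma
        ]
        if shared and ff_for_hap:
            counted = {
                s.key: s.alt for s in bundle.sites if s.key in plasma
            }
            transmission = infer_transmission(
                plasma,
                bundle.maternal_haplotypes,
                bundle.paternal_haplotypes,
                ff_for_hap,
                mutation_site=bundle.mutation_site,
                counted_alleles=counted,
                tau=config.tau,
            )

    results: list[SiteResult] = []
    for site in bundle.sites:
        counts_pre = _site_counts(bundle, site, "pre", counts_pre_tab, None)
        counts_post = _site_counts(bundle, site, "post", None, counts_post_tab)
        call_pre = _ratio_call(site, counts_pre, ff_pre, config, "ratio")
        call_post = _ratio_call(site, counts_post, ff_post, config, "ratio_iss")

        hap_call: Optional[GenotypeCall] = None
        if site.haplotype_prediction is not None:
            hap_call = GenotypeCall(
                site.chrom, site.pos, "haplotype",
                tuple(site.haplotype_prediction),
                ambiguous=len(site.haplotype_prediction) > 1,
            )
        elif transmission is not None and site.key in (
            transmission.site_genotypes or {}
        ):
            hap_call = transmission_to_call(
                transmission, site.key,
                bundle.maternal_haplotypes, bundle.paternal_haplotypes,
            )
        elif transmission is not None and transmission.uninformative:
            hap_call = transmission_to_call(
                transmission, site.key,
                bundle.maternal_haplotypes, bundle.paternal_haplotypes,
            )

        base = call_post if call_post is not None else call_pre
        if base is None:
            base = GenotypeCall(
                site.chrom, site.pos, "ratio", (), no_call=True,
                reason="no plasma counts at site",
            )
        combined = combined_call(base, hap_call)
        concordant = None
        if site.confirmed is not None:
            concordant = (
                not combined.no_call
                and not combined.ambiguous
                and combined.genotype == site.confirmed
            )
        results.append(
            SiteResult(site, call_pre, call_post, hap_call, combined, concordant)
        )
    return CaseReport(
        family=bundle.family,
        ff_pre=ff_pre,
        ff_post=ff_post,
        iss_cutoff_bp=cutoff,
        results=results,
        transmission=transmission,
    )


def _site_counts(bundle, site, which, counts_pre_tab, counts_post_tab):
    if bundle.fragments is not None:
        tab = counts_pre_tab if which == "pre" else counts_post_tab
        if tab is None:
            return None
        counts = tab.counts_at(site.chrom, site.pos)
        return counts or None
    return site.counts(which, bundle.depth)


# ---------------------------------------------------------------------------
# Rendering


_TSV_COLUMNS = [
    "family", "label", "chrom", "pos", "ref", "maternal_gt", "paternal_gt",
    "plasma_ratio", "inferred", "plasma_ratio_iss", "inferred_iss",
    "inferred_haplotype", "inferred_combined", "confirmed", "concordant",
]


def _render_counts(counts: Optional[dict], site: CaseSite) -> str:
    if not counts:
        return ""
    alleles = [a for a in (site.ref, site.alt) if a in counts]
    for a in counts:
        if a not in alleles:
            alleles.append(a)
    total = sum(counts.values())
    if total == 0:
        return ""
    pairs = [(round(100 * counts[a] / total), a) for a in alleles]
    variant_first = site.alt.startswith(("Ins", "Del", "INS", "DEL"))
    if variant_first:
        pairs = sorted(pairs, key=lambda p: p[1] != site.alt)
    return render_ratio(pairs)


def render_report(report: CaseReport):
    """Render a case report; returns ``(tsv_text, json_payload)``."""
    lines = ["\t".join(_TSV_COLUMNS)]
    json_sites = []
    for r in report.results:
        s = r.site
        counts_pre = s.counts("pre", 100) if s.ratio_pre else None
        counts_post = s.counts("post", 100) if s.ratio_post else None
        row = [
            report.family, s.label, s.chrom, str(s.pos), s.ref,
            render_genotype(s.maternal_gt), render_genotype(s.paternal_gt),
            s.ratio_pre or "", _gt_string(r.call_pre),
            s.ratio_post or "", _gt_string(r.call_post),
            _gt_string(r.haplotype_call), _gt_string(r.combined),
            render_genotype(s.confirmed) if s.confirmed else "",
            "" if r.concordant is None else str(bool(r.concordant)).lower(),
        ]
        lines.append("\t".join(row))
        json_sites.append(
            dict(
                label=s.label, chrom=s.chrom, pos=s.pos,
                maternal_gt=list(s.maternal_gt), paternal_gt=list(s.paternal_gt),
                ratio_pre=s.ratio_pre, ratio_post=s.ratio_post,
                call_pre=_call_json(r.call_pre),
                call_post=_call_json(r.call_post),
                haplotype_call=_call_json(r.haplotype_call),
                combined=_call_json(r.combined),
                confirmed=list(s.confirmed) if s.confirmed else None,
                concordant=r.concordant,
            )
        )
    payload = dict(
        family=report.family,
        ff_pre_pct=None if report.ff_pre is None else 100 * report.ff_pre,
        ff_post_pct=None if report.ff_post is None else 100 * report.ff_post,
        iss_cutoff_bp=report.iss_cutoff_bp,
        sites=json_sites,
    )
    if report.transmission is not None:
        t = report.transmission
        payload["transmission"] = dict(
            maternal_hap=t.maternal_hap,
            paternal_hap=t.paternal_hap,
            ambiguous=t.ambiguous,
            uninformative=t.uninformative,
            log_likelihood_ratio=t.log_likelihood_ratio,
            combo_logliks=[[float(x) for x in row] for row in t.combo_logliks],
        )
    return "\n".join(lines) + "\n", payload


def _call_json(call: Optional[GenotypeCall]):
    if call is None:
        return None
    return dict(
        method=call.method,
        called_gt=[list(g) for g in call.called_gt],
        ambiguous=call.ambiguous,
        no_call=call.no_call,
        reason=call.reason,
        log_likelihood_ratio=(
            None if call.log_likelihood_ratio == float("inf")
            else call.log_likelihood_ratio
        ),
        hypotheses=[
            dict(
                fetal_gt=list(h.fetal_gt),
                expected_fraction=h.expected_fraction,
                log_likelihood=h.log_likelihood,
            )
            for h in call.hypotheses
        ],
    )
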