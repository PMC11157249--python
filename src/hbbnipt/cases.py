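"""Case bundles: everything needed to genotype one family.

A :class:`CaseBundle` carries parental genotypes at the clinical mutation
site(s), plasma allele evidence before and after in-silico size selection
(either printed ratio strings with a nominal depth, or a raw fragment
table), fetal-fraction estimates, optional phased parental haplotypes, and
optional confirmed fetal genotypes (truth from chorionic villus sampling).

Two bundled reference fixtures ship with the package: seven families with
single-site evidence, and one family (IBT 42) with five phased sites where
linked-SNP ratios resolve an otherwise ambiguous mutation-site call.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .fragments_io import FragmentTable
from .genotype_caller import Genotype, _norm_gt
from .haplotyping import HaplotypePair

__all__ = [
    "CaseSite",
    "CaseBundle",
    "CaseError",
    "parse_ratio",
    "render_ratio",
    "parse_genotype",
    "render_genotype",
    "load_case",
    "seven_family_cases",
    "ibt42_case",
]

_RATIO_PART = re.compile(r"^\s*(\d+)\s*([A-Za-z0-9:]+)\s*$")


class CaseError(ValueError):
    """A case bundle is malformed or cannot be processed."""


def parse_ratio(text: str) -> list[tuple[int, str]]:
    """Parse a printed ratio string like ``"59C/41G"`` or ``"4Del/96A"``."""
    parts = []
    for piece in text.split("/"):
        m = _RATIO_PART.match(piece)
        if not m:
            raise CaseError(f"cannot parse ratio component {piece!r} in {text!r}")
        parts.append((int(m.group(1)), m.group(2)))
    if len(parts) != 2:
        raise CaseError(f"expected two alleles in ratio {text!r}")
    return parts


def render_ratio(pairs: list[tuple[int, str]]) -> str:
    return "/".join(f"{n}{a}" for n, a in pairs)


def parse_genotype(text: str) -> Genotype:
    alleles = text.split("/")
    if len(alleles) != 2:
        raise CaseError(f"cannot parse genotype {text!r}")
    return _norm_gt(tuple(alleles))


def render_genotype(gt: Genotype) -> str:
    if set(gt) == {"DEL619", "REF"} or gt == ("DEL619", "DEL619"):
        return "619 Deletion"
    return "/".join(gt)


@dataclass
class CaseSite:
    label: str
    chrom: str
    pos: int
    ref: str
    alt: str
    maternal_gt: Genotype
    paternal_gt: Genotype
    ratio_pre: Optional[str] = None
    ratio_post: Optional[str] = None
    haplotype_prediction: Optional[tuple[Genotype, ...]] = None
    confirmed: Optional[Genotype] = None
    parental_gt_reconstructed: bool = False

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def is_deletion_region(self) -> bool:
        return self.alt == "DEL619"

    def counts(self, which: str, depth: int) -> Optional[dict[str, int]]:
        """Printed ratio scaled to integer counts at the nominal depth."""
        text = self.ratio_pre if which == "pre" else self.ratio_post
        if text is None:
            return None
        pairs = parse_ratio(text)
        total = sum(n for n, _ in pairs)
        return {a: round(n / total * depth) for n, a in pairs}


@dataclass
class CaseBundle:
    family: str
    sites: list[CaseSite]
    depth: int = 2000
    ff_pre: Optional[float] = None  # fractions, not percent
    ff_post: Optional[float] = None
    iss_cutoff_bp: Optional[int] = None
    maternal_haplotypes: Optional[HaplotypePair] = None
    paternal_haplotypes: Optional[HaplotypePair] = None
    mutation_site: Optional[tuple[str, int]] = None
    fragments: Optional[FragmentTable] = None
    maternal_gt_map: dict = field(default_factory=dict)
    paternal_gt_map: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.sites and self.fragments is None:
            raise CaseError(f"case {self.family}: no plasma evidence at all")
        for site in self.sites:
            if site.maternal_gt is None or site.paternal_gt is None:
                raise CaseError(
                    f"case {self.family}: parental genotypes missing at "
                    f"{site.chrom}:{site.pos}"
                )
        if self.fragments is None:
            has_evidence = any(
                s.ratio_pre or s.ratio_post or s.haplotype_prediction
                for s in self.sites
            )
            if not has_evidence:
                raise CaseError(
                    f"case {self.family}: empty plasma table and no ratios"
                )
            if self.ff_pre is None:
                raise CaseError(
                    f"case {self.family}: a fetal fraction is required with "
                    "ratio-only evidence"
                )


def _site_from_dict(d: dict) -> CaseSite:
    hap = d.get("haplotype_prediction")
    if hap is None:
        hap_t = None
    elif isinstance(hap, str):
        hap_t = (parse_genotype(hap),)
    else:
        hap_t = tuple(parse_genotype(h) for h in hap)
    return CaseSite(
        label=d.get("label", ""),
        chrom=d["chrom"],
        pos=int(d["pos"]),
        ref=d["ref"],
        alt=d["alt"],
        maternal_gt=parse_genotype(d["maternal_gt"]),
        paternal_gt=parse_genotype(d["paternal_gt"]),
        ratio_pre=d.get("ratio_pre"),
        ratio_post=d.get("ratio_post"),
        haplotype_prediction=hap_t,
        confirmed=parse_genotype(d["confirmed"]) if d.get("confirmed") else None,
        parental_gt_reconstructed=bool(d.get("parental_gt_reconstructed", False)),
    )


def _bundle_from_dict(d: dict, depth: Optional[int] = None) -> CaseBundle:
    sites = [_site_from_dict(s) for s in d["sites"]]
    haps = d.get("haplotypes") or {}

    def _hap(parent_key: str, parent: str) -> Optional[HaplotypePair]:
        h = haps.get(parent_key)
        if h is None:
            return None
        return HaplotypePair(
            parent=parent,
            sites=[(c, int(p)) for c, p in h["sites"]],
            hap1=tuple(h["hap1"]),
            hap2=tuple(h["hap2"]),
            support1=float(h.get("support1", 0.5)),
            support2=float(h.get("support2", 0.5)),
        )

    ff_pre = d.get("ff_pre_pct")
    ff_post = d.get("ff_post_pct")
    bundle = CaseBundle(
        family=d["family"],
        sites=sites,
        depth=int(d.get("depth", depth or 2000)),
        ff_pre=None if ff_pre is None else ff_pre / 100.0,
        ff_post=None if ff_post is None else ff_post / 100.0,
        iss_cutoff_bp=d.get("iss_cutoff_bp"),
        maternal_haplotypes=_hap("mother", "mother"),
        paternal_haplotypes=_hap("father", "father"),
        mutation_site=tuple(d["mutation_site"]) if d.get("mutation_site") else None,
    )
    bundle.maternal_gt_map = {s.key: s.maternal_gt for s in sites}
    bundle.paternal_gt_map = {s.key: s.paternal_gt for s in sites}
    if bundle.mutation_site is not None:
        bundle.mutation_site = (bundle.mutation_site[0], int(bundle.mutation_site[1]))
    return bundle


def load_case(source) -> CaseBundle:
    """Build a CaseBundle from a dict or a JSON file path."""
    if isinstance(source, dict):
        return _bundle_from_dict(source)
    with open(source) as fh:
        return _bundle_from_dict(json.load(fh))


def _load_data(name: str) -> dict:
    with resources.files("hbbnipt.data").joinpath(name).open() as fh:
        return json.load(fh)


def seven_family_cases() -> list[CaseBundle]:
    """The seven bundled single-site family fixtures."""
    payload = _load_data("seven_families.json")
    return [
        _bundle_from_dict(c, depth=payload.get("depth"))
        for c in payload["cases"]
    ]


def ibt42_case() -> CaseBundle:
    """The bundled five-site phased family fixture."""
    return _bundle_from_dict(_load_data("ibt42_case.json"))
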