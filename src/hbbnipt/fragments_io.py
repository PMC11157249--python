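"""Plasma fragment observations: data model, I/O, UMI dedup, size selection.

Cell-free DNA in maternal plasma is a mixture of maternal and fetal
fragments.  Every downstream computation in this package (fetal-fraction
estimation, in-silico size selection, allele-ratio genotyping) operates on
per-fragment observations: which panel site a sequenced fragment covers,
which allele it carries there, how long the fragment is, and which unique
molecular identifier (UMI) tagged the original molecule.

Coordinates are 1-based, fully closed, GRCh37/hg19, forward strand.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelSite",
    "FragmentTable",
    "AlleleCountTable",
    "DEL619_REGION",
    "SPANNING_DEL",
    "SPANNING_REF",
    "FragmentFormatError",
    "read_fragments",
    "write_fragments",
    "dedup_umi",
    "size_select",
    "count_alleles",
]

#: hg19 coordinates of the common HBB intron 2 - exon 3 deletion.
DEL619_REGION = ("chr11", 5246486, 5247107)

#: Allele tokens used for fragments informative about the 619 bp deletion:
#: a fragment either spans the deletion junction (supporting the deleted
#: chromosome) or lies across/inside the intact region (supporting the
#: reference chromosome).
SPANNING_DEL = "SPANNING_DEL"
SPANNING_REF = "SPANNING_REF"

TSV_COLUMNS = ["read_id", "chrom", "pos", "allele", "frag_len", "umi"]


class FragmentFormatError(ValueError):
    """Raised when a fragment input file cannot be parsed."""


@dataclass(frozen=True)
class PanelSite:
    """A genomic position (or region) interrogated by the capture panel.

    ``role`` distinguishes the 436 genomic SNPs used for fetal-fraction
    estimation (``genomic_snp``), HBB-linked SNPs used for haplotype
    transmission (``hbb_snp``), and clinically causal positions
    (``mutation_site``).  Alt alleles may be SNP bases, ``INS:<seq>``,
    ``DEL:<len>``, or the special region allele ``DEL619``.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    role: str = "genomic_snp"

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"pos must be positive, got {self.pos}")
        if self.ref_allele in self.alt_alleles:
            raise ValueError(
                f"ref allele {self.ref_allele!r} duplicated in alt alleles"
            )
        if self.role not in {"genomic_snp", "hbb_snp", "mutation_site"}:
            raise ValueError(f"unknown site role {self.role!r}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele, *self.alt_alleles)


@dataclass
class FragmentTable:
    """Per-observation plasma fragment records backed by a DataFrame.

    Columns: ``read_id, chrom, pos, allele, frag_len, umi`` and optionally
    ``start`` (alignment start, used in the UMI grouping key when known).
    One row is one (read, covered panel site) observation.
    """

    df: pd.DataFrame
    deduped: bool = False
    length_cutoff: Optional[int] = None
    n_skipped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in TSV_COLUMNS if c not in self.df.columns]
        if missing:
            raise FragmentFormatError(f"fragment table missing columns {missing}")
        if len(self.df) and (self.df["frag_len"] < 1).any():
            raise FragmentFormatError("fragment lengths must be >= 1")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records: Iterable[dict], **flags) -> "FragmentTable":
        rows = list(records)
        if rows:
            df = pd.DataFrame(rows)
        else:
            df = pd.DataFrame(columns=TSV_COLUMNS)
        return cls(df=df, **flags)


@dataclass
class AlleleCountTable:
    """Per-site allele read counts (long format: chrom, pos, allele, count)."""

    df: pd.DataFrame
    length_cutoff: Optional[int] = None

    def counts_at(self, chrom: str, pos: int) -> dict[str, int]:
        sel = self.df[(self.df["chrom"] == chrom) & (self.df["pos"] == pos)]
        return dict(zip(sel["allele"], sel["count"].astype(int)))

    def depth_at(self, chrom: str, pos: int) -> int:
        return int(sum(self.counts_at(chrom, pos).values()))

    def sites(self) -> list[tuple[str, int]]:
        return list(
            self.df[["chrom", "pos"]].drop_duplicates().itertuples(index=False, name=None)
        )

    def to_tsv(self, path_or_buf=None):
        out = self.df.copy()
        depth = out.groupby(["chrom", "pos"])["count"].transform("sum")
        out["depth"] = depth.astype(int)
        return out.to_csv(path_or_buf, sep="\t", index=False)


# ---------------------------------------------------------------------------
# I/O


def read_fragments(
    path,
    format: str = "fragment_tsv",
    panel: Optional[Sequence[PanelSite]] = None,
    umi_tag: str = "RX",
) -> FragmentTable:
    """Load plasma fragment observations from a fragment TSV or SAM/BAM.

    For SAM/BAM input a ``panel`` is required: each alignment is converted
    into one observation per covered panel site.  Fragment length is the
    absolute template length when mates are paired, else the aligned read
    length (covering merged-overlap single-end reads).  Reads covering no
    panel site are counted in ``n_skipped``, not an error.
    """
    if format == "fragment_tsv":
        return _read_fragment_tsv(path, panel=panel)
    if format == "sam_bam":
        if panel is None:
            raise ValueError("SAM/BAM ingestion requires a panel definition")
        return _read_sam(path, panel=panel, umi_tag=umi_tag)
    raise ValueError(f"unknown fragment format {format!r}")


def _read_fragment_tsv(path, panel=None) -> FragmentTable:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"read_id": str, "chrom": str, "allele": str, "umi": str},
        )
    except Exception as exc:  # noqa: BLE001 - normalised into format error
        raise FragmentFormatError(f"cannot parse fragment TSV: {exc}") from exc
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FragmentFormatError(f"fragment TSV missing columns {missing}")
    df["pos"] = df["pos"].astype(int)
    df["frag_len"] = df["frag_len"].astype(int)
    df["umi"] = df["umi"].fillna("")
    n_skipped = 0
    if panel is not None:
        keys = {s.key for s in panel}
        on_panel = [
            (c, p) in keys for c, p in zip(df["chrom"], df["pos"])
        ]
        n_skipped = int(len(df) - sum(on_panel))
        df = df[np.asarray(on_panel, dtype=bool)].reset_index(drop=True)
    return FragmentTable(df=df, n_skipped=n_skipped)


def write_fragments(table: FragmentTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False, columns=TSV_COLUMNS)


def _read_sam(path, panel: Sequence[PanelSite], umi_tag: str) -> FragmentTable:
    import pysam

    snp_sites = [s for s in panel if "DEL619" not in s.alt_alleles]
    del_sites = [s for s in panel if "DEL619" in s.alt_alleles]
    by_pos: dict[tuple[str, int], PanelSite] = {s.key: s for s in snp_sites}

    records: list[dict] = []
    n_skipped = 0
    try:
        af = pysam.AlignmentFile(str(path), check_sq=False)
    except Exception as exc:  # noqa: BLE001
        raise FragmentFormatError(f"cannot open alignment file: {exc}") from exc
    with af:
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_paired and aln.is_read2:
                continue  # count each template once
            umi = aln.get_tag(umi_tag) if aln.has_tag(umi_tag) else ""
            if aln.template_length:
                frag_len = abs(aln.template_length)
            else:
                frag_len = aln.query_alignment_length or (aln.query_length or 0)
            if frag_len < 1:
                continue
            chrom = aln.reference_name
            start = aln.reference_start + 1  # to 1-based
            hits = 0
            seq = aln.query_sequence
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                site = by_pos.get((chrom, rpos + 1))
                if site is None or seq is None:
                    continue
                records.append(
                    dict(
                        read_id=aln.query_name,
                        chrom=chrom,
                        pos=site.pos,
                        allele=seq[qpos],
                        frag_len=frag_len,
                        umi=str(umi),
                        start=start,
                    )
                )
                hits += 1
            for site in del_sites:
                allele = _classify_deletion_support(aln, chrom)
                if allele is not None:
                    records.append(
                        dict(
                            read_id=aln.query_name,
                            chrom=chrom,
                            pos=site.pos,
                            allele=allele,
                            frag_len=frag_len,
                            umi=str(umi),
                            start=start,
                        )
                    )
                    hits += 1
            if hits == 0:
                n_skipped += 1
    table = FragmentTable.from_records(records)
    table.n_skipped = n_skipped
    return table


def _classify_deletion_support(aln, chrom: str, min_del: int = 50) -> Optional[str]:
    """Classify one alignment against the 619 bp deletion region.

    A deletion CIGAR operation of >= ``min_del`` bp overlapping the region
    supports the deleted chromosome; an alignment whose aligned blocks cross
    a junction or lie inside the region without such an operation supports
    the intact chromosome.  Fragments touching neither are uninformative.
    """
    region_chrom, rstart, rend = DEL619_REGION
    if chrom != region_chrom:
        return None
    ref = aln.reference_start + 1
    for op, length in aln.cigartuples or []:
        if op == 2 and length >= min_del:  # D
            dstart, dend = ref, ref + length - 1
            if dstart <= rend and dend >= rstart:
                return SPANNING_DEL
        if op in (0, 2, 3, 7, 8):  # consume reference
            ref += length
    astart, aend = aln.reference_start + 1, aln.reference_end or 0
    if astart <= rend and aend >= rstart:
        return SPANNING_REF
    return None


# ---------------------------------------------------------------------------
# Operations


def dedup_umi(table: FragmentTable) -> FragmentTable:
    """Collapse PCR duplicates sharing a UMI into one consensus observation.

    Groups observations by (umi, site, alignment start when known); the
    consensus allele is the per-group majority (ties break to the
    lexicographically smallest token, base qualities not being carried) and
    the consensus fragment length is the longest in the group, mirroring
    longest-most-accurate consensus deduplication with a minimum group size
    of one so that singleton molecules pass through.
    """
    if table.deduped:
        return table  # consensus of consensus rows is itself: idempotent
    df = table.df
    if df.empty:
        return FragmentTable(df=df.copy(), deduped=True,
                             length_cutoff=table.length_cutoff)
    key = ["umi", "chrom", "pos"]
    if "start" in df.columns:
        key = key + ["start"]
    # majority allele per group, tie -> lexicographic
    sizes = (
        df.groupby(key + ["allele"], sort=False, dropna=False)
        .agg(n=("allele", "size"), frag_len=("frag_len", "max"),
             read_id=("read_id", "first"))
        .reset_index()
    )
    sizes = sizes.sort_values(key + ["n", "allele"],
                              ascending=[True] * len(key) + [False, True])
    consensus = sizes.drop_duplicates(subset=key, keep="first")
    # consensus length = longest across the whole UMI group, not just the
    # winning allele
    group_len = df.groupby(key, sort=False, dropna=False)["frag_len"].max()
    consensus = consensus.drop(columns=["n", "frag_len"]).merge(
        group_len.rename("frag_len").reset_index(), on=key, how="left"
    )
    out = consensus[[c for c in df.columns if c in consensus.columns]]
    out = out.reset_index(drop=True)
    return FragmentTable(df=out, deduped=True, length_cutoff=table.length_cutoff)


def size_select(table: FragmentTable, max_len: int) -> FragmentTable:
    """In-silico size selection: keep fragments with length <= ``max_len``.

    Excluding fragments over a length cutoff enriches the (shorter) fetal
    component of the plasma mixture.  The boundary is inclusive.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    df = table.df[table.df["frag_len"] <= max_len].reset_index(drop=True)
    return FragmentTable(
        df=df,
        deduped=table.deduped,
        length_cutoff=max_len,
        n_skipped=table.n_skipped,
    )


def count_alleles(
    table: FragmentTable, panel: Optional[Sequence[PanelSite]] = None
) -> AlleleCountTable:
    """Tally allele observations per site.

    With a ``panel``, every panel allele is reported (zero-filled when
    unobserved) and off-panel observations are ignored; without one, counts
    cover exactly the sites present in the table.  Deletion-region sites
    accumulate ``SPANNING_DEL`` / ``SPANNING_REF`` like ordinary alleles.
    """
    df = table.df
    if df.empty:
        counts = pd.DataFrame(columns=["chrom", "pos", "allele", "count"])
    else:
        counts = (
            df.groupby(["chrom", "pos", "allele"], sort=True)
            .size()
            .rename("count")
            .reset_index()
        )
    if panel is not None:
        keys = {s.key for s in panel}
        if len(counts):
            mask = np.asarray(
                [(c, p) in keys for c, p in zip(counts["chrom"], counts["pos"])],
                dtype=bool,
            )
            counts = counts[mask]
        zero_rows = []
        have = set(
            zip(counts["chrom"], counts["pos"], counts["allele"])
        )
        for site in panel:
            alleles = (
                (SPANNING_REF, SPANNING_DEL)
                if "DEL619" in site.alt_alleles
                else site.alleles
            )
            for a in alleles:
                if (site.chrom, site.pos, a) not in have:
                    zero_rows.append(
                        dict(chrom=site.chrom, pos=site.pos, allele=a, count=0)
                    )
        if zero_rows:
            counts = pd.concat([counts, pd.DataFrame(zero_rows)], ignore_index=True)
        counts = counts.sort_values(["chrom", "pos", "allele"]).reset_index(drop=True)
    if counts.empty:
        counts = pd.DataFrame(columns=["chrom", "pos", "allele", "count"])
    counts["count"] = counts.get("count", pd.Series(dtype=int)).astype(int)
    return AlleleCountTable(df=counts, length_cutoff=table.length_cutoff)
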