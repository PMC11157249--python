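"""Synthetic plasma and amplicon data with known truth.

The plasma simulator emulates the physical mixture the pipeline sees: at
each panel SNP, cfDNA molecules are fetal with probability ``ff_true``,
carry one of their origin genotype's two alleles with equal probability,
and draw a fragment length from an origin-specific distribution — fetal
fragments are modally shorter (143 bp vs 166 bp by default, within the
plasma size range reported for cfDNA).  Sequencing error flips a read's
allele with a small probability, and PCR duplication re-reads a molecule
under a shared UMI so that consensus deduplication can be exercised.

Every generated observation is tracked back to its origin (maternal or
fetal) and the drawn genotypes, so parameter-recovery experiments can
compare estimates against planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fragments_io import FragmentTable
from .haplotyping import DEL619_ALLELE, HaplotypePair

__all__ = [
    "PlasmaSimConfig",
    "SimTruth",
    "simulate_plasma",
    "simulate_amplicon_reads",
    "synthetic_amplicon_reference",
    "write_amplicon_fastq",
    "matrix_from_fastq",
]

_BASES = np.array(list("ACGT"))


@dataclass
class PlasmaSimConfig:
    """Study conditions for a simulated plasma library.

    Defaults: 50 genomic SNPs, 2000 molecules per site, fetal fraction
    10%, fetal/maternal length modes 143/166 bp with sd 15 bp, 0.2%
    per-read allele error, no PCR duplication.  Parental genotypes are
    drawn per site with allele frequency 0.5 unless given explicitly as a
    list of (maternal_gt, paternal_gt) pairs.
    """

    ff_true: float = 0.10
    n_genomic_snps: int = 50
    depth_mean: int = 2000
    maternal_len_mode: float = 166.0
    fetal_len_mode: float = 143.0
    len_sd: float = 15.0
    error_rate: float = 0.002
    duplication_rate: float = 0.0
    parental_genotypes: Optional[Sequence[tuple[tuple[str, str], tuple[str, str]]]] = None
    forced_fetal_genotypes: Optional[dict[int, tuple[str, str]]] = None
    depth_model: str = "fixed"  # fixed | negbin
    negbin_dispersion: float = 5.0
    chrom: str = "chr11"
    pos_start: int = 1_000_000
    pos_step: int = 997
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ff_true < 0.5:
            raise ValueError("ff_true must be on [0, 0.5)")
        if self.len_sd <= 0 or self.depth_mean < 1 or self.n_genomic_snps < 1:
            raise ValueError("invalid distribution parameters")
        if self.depth_model not in {"fixed", "negbin"}:
            raise ValueError(f"unknown depth model {self.depth_model!r}")


@dataclass
class SimTruth:
    """Planted truth for a simulated plasma library."""

    ff_true: float
    sites: pd.DataFrame  # chrom, pos, maternal_gt, paternal_gt, fetal_gt
    fetal_origin: np.ndarray  # bool per FragmentTable row
    molecule_allele: np.ndarray  # error-free allele per row

    def maternal_gt_map(self) -> dict[tuple[str, int], tuple[str, str]]:
        return {
            (r.chrom, r.pos): tuple(r.maternal_gt)
            for r in self.sites.itertuples(index=False)
        }

    def paternal_gt_map(self) -> dict[tuple[str, int], tuple[str, str]]:
        return {
            (r.chrom, r.pos): tuple(r.paternal_gt)
            for r in self.sites.itertuples(index=False)
        }


def simulate_plasma(config: PlasmaSimConfig) -> tuple[FragmentTable, SimTruth]:
    """Generate a plasma fragment table plus its planted truth."""
    rng = np.random.default_rng(config.seed)
    n_sites = config.n_genomic_snps
    pos = config.pos_start + config.pos_step * np.arange(n_sites)

    # site alleles and parental genotypes
    site_rows = []
    for i in range(n_sites):
        if config.parental_genotypes is not None:
            m_gt, p_gt = config.parental_genotypes[i]
            alleles = sorted(set(m_gt) | set(p_gt))
            if len(alleles) == 1:
                alleles.append(next(b for b in "ACGT" if b != alleles[0]))
        else:
            a, b = rng.choice(4, size=2, replace=False)
            alleles = [_BASES[a], _BASES[b]]
            m_gt = tuple(rng.choice(alleles, size=2))
            p_gt = tuple(rng.choice(alleles, size=2))
        if config.forced_fetal_genotypes and i in config.forced_fetal_genotypes:
            f_gt = tuple(config.forced_fetal_genotypes[i])
        else:
            f_gt = (m_gt[rng.integers(2)], p_gt[rng.integers(2)])
        site_rows.append(
            dict(chrom=config.chrom, pos=int(pos[i]),
                 maternal_gt=tuple(m_gt), paternal_gt=tuple(p_gt),
                 fetal_gt=tuple(f_gt))
        )
    sites = pd.DataFrame(site_rows)

    if config.depth_model == "fixed":
        depths = np.full(n_sites, config.depth_mean)
    else:
        r = config.negbin_dispersion
        depths = rng.negative_binomial(r, r / (r + config.depth_mean), n_sites)
        depths = np.maximum(depths, 1)
    site_idx = np.repeat(np.arange(n_sites), depths)
    n_mol = len(site_idx)

    fetal = rng.random(n_mol) < config.ff_true
    which = rng.integers(2, size=n_mol)
    m_alleles = np.stack([
        np.array([r["maternal_gt"][0] for r in site_rows]),
        np.array([r["maternal_gt"][1] for r in site_rows]),
    ])
    f_alleles = np.stack([
        np.array([r["fetal_gt"][0] for r in site_rows]),
        np.array([r["fetal_gt"][1] for r in site_rows]),
    ])
    allele = np.where(
        fetal, f_alleles[which, site_idx], m_alleles[which, site_idx]
    )

    mode = np.where(fetal, config.fetal_len_mode, config.maternal_len_mode)
    frag_len = np.maximum(
        np.rint(rng.normal(mode, config.len_sd)).astype(int), 30
    )

    # PCR duplication: each molecule observed 1+ times under one UMI
    if config.duplication_rate > 0:
        copies = np.maximum(rng.poisson(config.duplication_rate, n_mol), 1)
    else:
        copies = np.ones(n_mol, dtype=int)
    row_mol = np.repeat(np.arange(n_mol), copies)
    n_reads = len(row_mol)

    read_allele = allele[row_mol]
    if config.error_rate > 0:
        err = rng.random(n_reads) < config.error_rate
        if err.any():
            shift = rng.integers(1, 4, size=int(err.sum()))
            base_idx = np.searchsorted(_BASES, read_allele[err])
            read_allele = read_allele.copy()
            read_allele[err] = _BASES[(base_idx + shift) % 4]

    copy_no = np.concatenate([np.arange(c) for c in copies]) if n_reads else np.array([], int)
    mol_str = row_mol.astype(str)
    df = pd.DataFrame(
        dict(
            read_id=np.char.add(np.char.add("m", mol_str), np.char.add("_", copy_no.astype(str))),
            chrom=config.chrom,
            pos=pos[site_idx[row_mol]],
            allele=read_allele,
            frag_len=frag_len[row_mol],
            umi=np.char.add("U", mol_str),
        )
    )
    truth = SimTruth(
        ff_true=config.ff_true,
        sites=sites,
        fetal_origin=fetal[row_mol],
        molecule_allele=allele[row_mol],
    )
    return FragmentTable(df=df), truth


# ---------------------------------------------------------------------------
# Long-read amplicon simulation


def simulate_amplicon_reads(
    haplotypes: HaplotypePair,
    n_reads: int = 500,
    error_rate: float = 0.05,
    deletion_hap: Optional[int] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw long reads from two parental haplotypes over amplicon sites.

    Each read copies haplotype 1 or 2 with probability 1/2; every site
    allele flips to a random different allele with ``error_rate``.  With
    ``deletion_hap`` set, that haplotype carries the 619 bp deletion and
    its reads observe ``DEL619`` at an added junction pseudo-site (the
    others observe ``REF``), while sites inside the deleted interval are
    missing from deletion-bearing reads.

    Returns the read x site allele matrix (columns ``"chrom:pos"``) and
    the true haplotype index (1/2) per read.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    origin = rng.integers(1, 3, size=n_reads)
    cols: dict[str, np.ndarray] = {}
    from .fragments_io import DEL619_REGION

    del_chrom, del_start, del_end = DEL619_REGION
    for j, (chrom, p) in enumerate(haplotypes.sites):
        a1, a2 = haplotypes.hap1[j], haplotypes.hap2[j]
        vals = np.where(origin == 1, a1, a2).astype(object)
        if error_rate > 0:
            err = rng.random(n_reads) < error_rate
            for i in np.nonzero(err)[0]:
                others = [b for b in "ACGT" if b != vals[i]] or [vals[i]]
                vals[i] = others[rng.integers(len(others))]
        if deletion_hap is not None and chrom == del_chrom and del_start <= p <= del_end:
            vals[origin == deletion_hap] = np.nan  # site deleted on that hap
        cols[f"{chrom}:{p}"] = vals
    if deletion_hap is not None:
        junction = np.where(origin == deletion_hap, DEL619_ALLELE, "REF").astype(object)
        if error_rate > 0:
            err = rng.random(n_reads) < error_rate
            flipped = np.where(junction[err] == DEL619_ALLELE, "REF", DEL619_ALLELE)
            junction[err] = flipped
        cols[f"{del_chrom}:{del_start}"] = junction
    matrix = pd.DataFrame(cols)
    return matrix, origin


def synthetic_amplicon_reference(length: int = 2252, seed: int = 7) -> str:
    """A synthetic stand-in amplicon sequence (random bases, fixed seed)."""
    rng = np.random.default_rng(seed)
    return "".join(_BASES[rng.integers(4, size=length)])


def write_amplicon_fastq(
    matrix: pd.DataFrame,
    path,
    reference: str,
    site_offsets: dict[str, int],
    quality_char: str = "I",
) -> None:
    """Render an allele matrix as full-length amplicon reads in FASTQ.

    Each read is the reference with its alleles substituted at the given
    0-based offsets (missing observations keep the reference base); reads
    carrying ``DEL619`` at a junction column are emitted with the deleted
    interval excised.  Synthetic output for exercising the FASTQ path.
    """
    from .fragments_io import DEL619_REGION

    _, del_start, del_end = DEL619_REGION
    with open(path, "w") as fh:
        for i, row in matrix.iterrows():
            seq = list(reference)
            deleted = False
            for col, allele in row.items():
                if pd.isna(allele):
                    continue
                if allele == DEL619_ALLELE:
                    deleted = True
                    continue
                if allele == "REF":
                    continue
                off = site_offsets[col]
                seq[off] = str(allele)
            if deleted:
                d0 = site_offsets.get("__del_start__", 0)
                seq = seq[:d0] + seq[d0 + (del_end - del_start + 1):]
            s = "".join(seq)
            fh.write(f"@read{i}\n{s}\n+\n{quality_char * len(s)}\n")


def matrix_from_fastq(
    path,
    site_offsets: dict[str, int],
    reference_length: int,
    deletion_length: int = 622,
) -> pd.DataFrame:
    """Naive positional extraction of site alleles from amplicon FASTQ.

    Reads are assumed to start at the amplicon 5' end (amplicon
    sequencing); full-length reads yield the base at each site offset,
    reads shorter by the deletion length are treated as deletion-bearing
    (``DEL619`` at the junction column, post-deletion offsets shifted).
    """
    from Bio import SeqIO

    del_off = site_offsets.get("__del_start__", None)
    rows = []
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = str(rec.seq)
        is_del = len(seq) <= reference_length - deletion_length + 3
        row: dict[str, object] = {}
        for col, off in site_offsets.items():
            if col == "__del_start__":
                continue
            if is_del and del_off is not None:
                if off >= del_off and off < del_off + deletion_length:
                    row[col] = np.nan
                    continue
                eff = off - deletion_length if off >= del_off + deletion_length else off
            else:
                eff = off
            row[col] = seq[eff] if eff < len(seq) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
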