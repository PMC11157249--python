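import math
from itertools import product

import pandas as pd
import pytest

from hbbnipt.fragments_io import FragmentTable


def make_table(rows, **flags) -> FragmentTable:
    """Build a FragmentTable from (read_id, chrom, pos, allele, frag_len, umi)
    tuples, or dicts."""
    records = []
    for r in rows:
        if isinstance(r, dict):
            records.append(r)
        else:
            read_id, chrom, pos, allele, frag_len, umi = r
            records.append(
                dict(read_id=read_id, chrom=chrom, pos=pos, allele=allele,
                     frag_len=frag_len, umi=umi)
            )
    return FragmentTable.from_records(records, **flags)


def oracle_call(counts, maternal_gt, paternal_gt, ff, counted_allele):
    """Brute-force maximum-likelihood fetal genotype, independent of the
    package's caller: explicit transmission enumeration and a hand-written
    binomial log-PMF via lgamma."""
    universe = set(maternal_gt) | set(paternal_gt) | {counted_allele}
    k = counts.get(counted_allele, 0)
    n = sum(counts.get(a, 0) for a in universe)

    def logpmf(k, n, p):
        p = min(max(p, 1e-3), 1 - 1e-3)
        return (
            math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
            + k * math.log(p) + (n - k) * math.log(1 - p)
        )

    best_gt, best_ll = None, -math.inf
    seen = set()
    for m in maternal_gt:
        for p in paternal_gt:
            gt = tuple(sorted((m, p)))
            if gt in seen:
                continue
            seen.add(gt)
            d_m = sum(1 for a in maternal_gt if a == counted_allele)
            d_f = sum(1 for a in gt if a == counted_allele)
            expected = (1 - ff) * d_m / 2 + ff * d_f / 2
            ll = logpmf(k, n, expected)
            if ll > best_ll:
                best_gt, best_ll = gt, ll
    return best_gt


@pytest.fixture
def tiny_counts_table():
    from hbbnipt.fragments_io import count_alleles

    rows = []
    for i, allele in enumerate(["G"] * 6 + ["T"] * 4):
        rows.append(("r%d" % i, "chr11", 5248219, allele, 150, "U%d" % i))
    return count_alleles(make_table(rows))
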