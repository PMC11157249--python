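"""Amplicon variant calling, read phasing, and transmission inference."""

import numpy as np
import pandas as pd
import pytest

from hbbnipt.genotype_caller import GenotypeCall
from hbbnipt.haplotyping import (
    DEL619_ALLELE,
    HaplotypePair,
    PhasingError,
    call_amplicon_variants,
    combined_call,
    infer_transmission,
    phase_haplotypes,
    transmission_to_call,
)
from hbbnipt.simulator import simulate_amplicon_reads


def matrix_from_haps(hap1, hap2, n_each=100, cols=None):
    cols = cols or [f"chr11:{5246200 + i * 300}" for i in range(len(hap1))]
    rows = [dict(zip(cols, hap1))] * n_each + [dict(zip(cols, hap2))] * n_each
    return pd.DataFrame(rows)


class TestCallAmpliconVariants:
    def test_balanced_site_called(self):
        m = matrix_from_haps(("A", "C"), ("G", "T"), n_each=500)
        assert len(call_amplicon_variants(m)) == 2

    def test_minor_frequency_threshold(self):
        m = matrix_from_haps(("A",), ("G",), n_each=500)
        m.iloc[:900, 0] = "A"  # 90/10 split: below the 16% minor threshold
        assert call_amplicon_variants(m) == []

    def test_indel_requires_stronger_support(self):
        col = ["A"] * 750 + ["DEL3"] * 250  # 25% minor: SNP yes, indel no
        m = pd.DataFrame({"chr11:5247993": col})
        assert call_amplicon_variants(m) == []
        col = ["A"] * 650 + ["DEL3"] * 350
        m = pd.DataFrame({"chr11:5247993": col})
        assert call_amplicon_variants(m) == ["chr11:5247993"]

    def test_low_coverage_refused(self):
        m = matrix_from_haps(("A",), ("G",), n_each=20)
        with pytest.raises(PhasingError):
            call_amplicon_variants(m)


class TestPhaseHaplotypes:
    def test_perfect_linkage_two_sites(self):
        m = matrix_from_haps(("A", "C"), ("G", "T"), n_each=250)
        pair = phase_haplotypes(m, parent="mother")
        haps = {pair.hap1, pair.hap2}
        assert haps == {("A", "C"), ("G", "T")}
        assert pair.support1 == pytest.approx(0.5, abs=0.01)
        assert pair.support2 == pytest.approx(0.5, abs=0.01)

    def test_noisy_six_site_recovery(self):
        truth = HaplotypePair(
            "mother",
            [("chr11", 5246200 + i * 300) for i in range(6)],
            ("A", "C", "G", "T", "A", "C"),
            ("G", "T", "C", "A", "G", "T"),
        )
        hits = 0
        for seed in range(10):
            m, _ = simulate_amplicon_reads(truth, n_reads=500,
                                           error_rate=0.05, seed=seed)
            pair = phase_haplotypes(m, parent="mother")
            if {pair.hap1, pair.hap2} == {truth.hap1, truth.hap2}:
                hits += 1
        assert hits >= 9

    def test_deletion_phased_with_linked_snps(self):
        truth = HaplotypePair(
            "father",
            [("chr11", 5246200), ("chr11", 5248200)],
            ("A", "C"),
            ("G", "T"),
        )
        m, origin = simulate_amplicon_reads(
            truth, n_reads=400, error_rate=0.03, deletion_hap=2, seed=1
        )
        pair = phase_haplotypes(m, parent="father")
        by_junction = {
            hap[list(pair.sites).index(("chr11", 5246486))]: hap
            for hap in (pair.hap1, pair.hap2)
        }
        del_hap = by_junction[DEL619_ALLELE]
        idx1 = pair.sites.index(("chr11", 5246200))
        idx2 = pair.sites.index(("chr11", 5248200))
        assert (del_hap[idx1], del_hap[idx2]) == ("G", "T")

    def test_unlinked_sites_impossible(self):
        rows = [{"s1": "A", "s2": np.nan} for _ in range(100)]
        rows += [{"s1": np.nan, "s2": "C"} for _ in range(100)]
        rows += [{"s1": "G", "s2": np.nan} for _ in range(100)]
        rows += [{"s1": np.nan, "s2": "T"} for _ in range(100)]
        with pytest.raises(PhasingError):
            phase_haplotypes(pd.DataFrame(rows), min_coverage=100)

    def test_balanced_supports_property(self):
        truth = HaplotypePair(
            "mother",
            [("chr11", 5246200 + i * 300) for i in range(4)],
            ("A", "C", "G", "T"),
            ("G", "T", "C", "A"),
        )
        m, _ = simulate_amplicon_reads(truth, n_reads=1000, error_rate=0.05, seed=3)
        pair = phase_haplotypes(m)
        assert 0.45 <= pair.support1 <= 0.55
        assert 0.45 <= pair.support2 <= 0.55


def _ibt42_setup():
    sites = [
        ("chr11", 5246796), ("chr11", 5247153), ("chr11", 5247829),
        ("chr11", 5248155), ("chr11", 5248330),
    ]
    mother = HaplotypePair("mother", sites, ("A", "C", "G", "C", "G"),
                           ("G", "A", "C", "G", "A"))
    father = HaplotypePair("father", sites, ("A", "C", "G", "C", "G"),
                           ("A", "C", "G", "G", "G"))
    plasma = {
        sites[0]: {"A": 472, "G": 328},
        sites[1]: {"A": 348, "C": 452},
        sites[2]: {"C": 376, "G": 424},
        sites[3]: {"C": 456, "G": 344},
        sites[4]: {"A": 344, "G": 456},
    }
    counted = {sites[0]: "G", sites[1]: "C", sites[2]: "G",
               sites[3]: "G", sites[4]: "G"}
    return sites, mother, father, plasma, counted


class TestInferTransmission:
    def test_linked_snps_resolve_mutation_site(self):
        sites, mother, father, plasma, counted = _ibt42_setup()
        res = infer_transmission(
            plasma, mother, father, ff=0.1466,
            mutation_site=sites[3], counted_alleles=counted,
        )
        assert (res.maternal_hap, res.paternal_hap) == (1, 1)
        assert res.mutation_site_gt == ("C", "C")
        assert res.site_genotypes[sites[2]] == ("G", "G")
        assert not res.ambiguous

    def test_identical_parental_haplotypes_uninformative(self):
        sites = [("chr11", 5248155)]
        mother = HaplotypePair("mother", sites, ("C",), ("C",))
        father = HaplotypePair("father", sites, ("G",), ("G",))
        res = infer_transmission(
            {sites[0]: {"C": 400, "G": 400}}, mother, father, ff=0.1
        )
        assert res.uninformative and res.maternal_hap is None

    def test_constant_site_does_not_change_argmax(self):
        sites, mother, father, plasma, counted = _ibt42_setup()
        base = infer_transmission(plasma, mother, father, 0.1466,
                                  mutation_site=sites[3],
                                  counted_alleles=counted)
        extra = ("chr11", 5248400)
        for pair in (mother, father):
            pair.sites.append(extra)
            pair.hap1 = pair.hap1 + ("T",)
            pair.hap2 = pair.hap2 + ("T",)
        plasma[extra] = {"T": 700, "A": 100}
        counted[extra] = "T"
        again = infer_transmission(plasma, mother, father, 0.1466,
                                   mutation_site=sites[3],
                                   counted_alleles=counted)
        assert (again.maternal_hap, again.paternal_hap) == (
            base.maternal_hap, base.paternal_hap
        )

    def test_likelihoods_converge_as_ff_vanishes(self):
        sites, mother, father, plasma, counted = _ibt42_setup()
        balanced = {s: {a: 400 for a in plasma[s]} for s in plasma}
        spreads = []
        for ff in (0.1, 0.01, 0.001):
            res = infer_transmission(balanced, mother, father, ff,
                                     counted_alleles=counted)
            ll = res.combo_logliks
            spreads.append(float(ll.max() - ll.min()))
        assert spreads[0] > spreads[1] > spreads[2]
        assert spreads[2] < 0.1

    def test_zero_ff_rejected(self):
        sites, mother, father, plasma, counted = _ibt42_setup()
        with pytest.raises(ValueError):
            infer_transmission(plasma, mother, father, 0.0)


class TestCombinedCall:
    def _ratio(self, ambiguous):
        gts = (("C", "G"), ("G", "G")) if ambiguous else (("C", "G"),)
        return GenotypeCall("chr11", 5248155, "ratio_iss", gts,
                            ambiguous=ambiguous)

    def test_unambiguous_haplotype_overrides(self):
        hap = GenotypeCall("chr11", 5248155, "haplotype", (("T", "T"),))
        out = combined_call(self._ratio(False), hap)
        assert out.genotype == ("T", "T") and out.method == "combined"

    def test_ambiguous_haplotype_keeps_ratio_call(self):
        hap = GenotypeCall("chr11", 5248155, "haplotype",
                           (("A", "G"), ("G", "G")), ambiguous=True)
        out = combined_call(self._ratio(False), hap)
        assert out.genotype == ("C", "G")
        assert out.reason == "haplotype transmission ambiguous"

    def test_missing_haplotype_keeps_ratio_call(self):
        out = combined_call(self._ratio(True), None)
        assert out.ambiguous and out.called_gt == (("C", "G"), ("G", "G"))

    def test_transmission_to_call_uninformative(self):
        sites = [("chr11", 5248155)]
        mother = HaplotypePair("mother", sites, ("C",), ("C",))
        father = HaplotypePair("father", sites, ("G",), ("G",))
        res = infer_transmission(
            {sites[0]: {"C": 400, "G": 400}}, mother, father, ff=0.1
        )
        call = transmission_to_call(res, sites[0], mother, father)
        assert call.no_call
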