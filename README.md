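# hbbnipt

Non-invasive prenatal genotyping of beta-hemoglobinopathies (sickle cell
disease and beta-thalassemia) from maternal plasma sequencing.

Cell-free DNA in a pregnant woman's plasma is a maternal/fetal mixture.
Given parental genotypes and deep sequencing of a capture panel over the
*HBB* region plus several hundred genomic SNPs, this package:

1. **estimates the fetal fraction (FF)** — at *informative SNPs* (mother
   homozygous, plasma carrying a paternally transmitted second allele),
   FF = 2 × mean obligate-fetal allele proportion;
2. **enriches it by in-silico size selection (ISS)** — fetal fragments are
   modally shorter, so excluding fragments above a scanned length cutoff
   raises the FF (traded against read loss);
3. **calls fetal genotypes from allele ratios** — at a site where the
   mother carries dosage d_m of an allele and the fetus dosage d_f, the
   expected plasma proportion is (1−f)·d_m/2 + f·d_f/2; each Mendelian
   fetal genotype hypothesis is scored with a binomial log-likelihood and
   calls within 2 log-units of the runner-up are reported as explicit
   ambiguities ("G/T or T/T");
4. **resolves ambiguities with parental haplotypes** — long-read amplicon
   data is phased into two haplotypes per parent (the common 619 bp *HBB*
   deletion phases as an allele), and the plasma ratios at linked SNPs are
   combined in a joint likelihood over the four possible transmissions,
   which can settle the mutation-site genotype when its own ratio cannot.

It also ships a planted-truth simulator for plasma mixtures and amplicon
reads, so every stage is testable without access to clinical data.

See `docs/methods.md` for the model, thresholds, and design decisions.

## Worked example

The bundled IBT-42 case carries five heterozygous-mother sites, plasma
ratios before/after a 140 bp size-selection cutoff (FF 8.04% → 14.66%),
and both parents' phased haplotypes:

```python
from hbbnipt.cases import ibt42_case
from hbbnipt.report import run_case

report = run_case(ibt42_case())
```

Formatting the per-site results prints:

```text
FF pre-ISS  8.04%   FF post-ISS 14.66%  (cutoff 140 bp)
SNP1  5246796  ratio  55A/44G ->  59A/41G   call A/A         ISS A/A         haplotype A/A  combined A/A  confirmed A/A
SNP2  5247153  ratio  48A/52C ->  44A/57C   call A/C or C/C  ISS C/C         haplotype C/C  combined C/C  confirmed C/C
SNP3  5247829  ratio  47C/53G ->  47C/53G   call G/G or C/G  ISS C/G or G/G  haplotype G/G  combined G/G  confirmed G/G
Mut   5248155  ratio  57C/43G ->  57C/43G   call C/C         ISS C/C         haplotype C/C  combined C/C  confirmed C/C
SNP4  5248330  ratio  47A/53G ->  43A/57G   call G/G or A/G  ISS G/G         haplotype G/G  combined G/G  confirmed G/G
transmission: maternal hap 1, paternal hap 1, log-LR 7.85
```

Reading SNP3: its 47C/53G ratio is compatible with both C/G and G/G at
either fetal fraction, so the single-site call stays ambiguous even after
size selection.  The joint likelihood over the four parental-haplotype
transmissions (log-LR 7.85 for maternal haplotype 1 + paternal haplotype
1) implies G/G at SNP3 and C/C at the disease mutation — both matching
the genotypes later confirmed from chorionic villus sampling.  SNP2 and
SNP4 show the other mechanism: ambiguous before size selection, resolved
by the enriched fetal fraction alone.

The same logic is available from the shell:

```sh
hbbnipt run-case case.json --out-prefix out     # writes out.tsv / out.json
hbbnipt simulate-plasma --seed 1 --ff 0.1 --out frags.tsv
hbbnipt estimate-ff frags.tsv genotypes.tsv
hbbnipt iss-scan frags.tsv genotypes.tsv --out curve.tsv
hbbnipt phase matrix.tsv
```

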