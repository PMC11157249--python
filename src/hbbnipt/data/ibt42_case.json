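{
  "description": "IBT-42 case bundle: five HBB-region sites (SNP1-SNP4 plus the disease-causing NC_000011.9:g.5248155C>G site) with plasma allele ratios before and after 140 bp in-silico size selection, fetal fractions 8.04% -> 14.66%, and the phased parental haplotypes. SNP1-SNP4 coordinates within the 2.2 kb amplicon are synthetic placeholders; ratios, fetal fractions, genotypes, and phase relationships follow the case narrative. Depth is a fixture choice.",
  "family": "IBT 42",
  "depth": 800,
  "ff_pre_pct": 8.04,
  "ff_post_pct": 14.66,
  "iss_cutoff_bp": 140,
  "sites": [
    {
      "label": "SNP1",
      "chrom": "chr11",
      "pos": 5246796,
      "ref": "A",
      "alt": "G",
      "maternal_gt": "A/G",
      "paternal_gt": "A/A",
      "parental_gt_reconstructed": true,
      "ratio_pre": "55A/44G",
      "ratio_post": "59A/41G",
      "haplotype_prediction": null,
      "confirmed": "A/A"
    },
    {
      "label": "SNP2",
      "chrom": "chr11",
      "pos": 5247153,
      "ref": "A",
      "alt": "C",
      "maternal_gt": "A/C",
      "paternal_gt": "C/C",
      "parental_gt_reconstructed": true,
      "ratio_pre": "48A/52C",
      "ratio_post": "44A/57C",
      "haplotype_prediction": null,
      "confirmed": "C/C"
    },
    {
      "label": "SNP3",
      "chrom": "chr11",
      "pos": 5247829,
      "ref": "C",
      "alt": "G",
      "maternal_gt": "C/G",
      "paternal_gt": "G/G",
      "parental_gt_reconstructed": true,
      "ratio_pre": "47C/53G",
      "ratio_post": "47C/53G",
      "haplotype_prediction": null,
      "confirmed": "G/G"
    },
    {
      "label": "Mut",
      "chrom": "chr11",
      "pos": 5248155,
      "ref": "C",
      "alt": "G",
      "maternal_gt": "C/G",
      "paternal_gt": "C/G",
      "parental_gt_reconstructed": true,
      "ratio_pre": "57C/43G",
      "ratio_post": "57C/43G",
      "haplotype_prediction": null,
      "confirmed": "C/C"
    },
    {
      "label": "SNP4",
      "chrom": "chr11",
      "pos": 5248330,
      "ref": "A",
      "alt": "G",
      "maternal_gt": "A/G",
      "paternal_gt": "G/G",
      "parental_gt_reconstructed": true,
      "ratio_pre": "47A/53G",
      "ratio_post": "43A/57G",
      "haplotype_prediction": null,
      "confirmed": "G/G"
    }
  ],
  "haplotypes": {
    "mother": {
      "sites": [["chr11", 5246796], ["chr11", 5247153], ["chr11", 5247829], ["chr11", 5248155], ["chr11", 5248330]],
      "hap1": ["A", "C", "G", "C", "G"],
      "hap2": ["G", "A", "C", "G", "A"],
      "support1": 0.5,
      "support2": 0.5
    },
    "father": {
      "sites": [["chr11", 5246796], ["chr11", 5247153], ["chr11", 5247829], ["chr11", 5248155], ["chr11", 5248330]],
      "hap1": ["A", "C", "G", "C", "G"],
      "hap2": ["A", "C", "G", "G", "G"],
      "support1": 0.5,
      "support2": 0.5
    }
  },
  "mutation_site": ["chr11", 5248155]
}
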