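{
  "description": "Seven-family case bundles for HBB NIPT: printed plasma allele ratios at clinical mutation sites, fetal fractions before/after in-silico size selection, parental genotypes, haplotype-based predictions, and the CVS-confirmed fetal genotypes. Parental genotypes marked reconstructed were not printed and are filled in consistently with the ratio-based and confirmed calls. Nominal post-dedup depth is a fixture choice. PST 5 maternal position appears elsewhere as 5246969 and IBT 69 maternal position as 5248389; the values below preserve the tabulated coordinates.",
  "depth": 2000,
  "cases": [
    {
      "family": "PST 5",
      "ff_pre_pct": 6.46,
      "ff_post_pct": 7.41,
      "iss_cutoff_bp": 190,
      "sites": [
        {
          "label": "maternal",
          "chrom": "chr11",
          "pos": 5246959,
          "ref": "G",
          "alt": "T",
          "maternal_gt": "G/T",
          "paternal_gt": "T/T",
          "parental_gt_reconstructed": true,
          "ratio_pre": "53G/47T",
          "ratio_post": "51G/49T",
          "haplotype_prediction": null,
          "confirmed": "G/T"
        },
        {
          "label": "paternal",
          "chrom": "chr11",
          "pos": 5248234,
          "ref": "A",
          "alt": "Del",
          "maternal_gt": "A/A",
          "paternal_gt": "A/Del",
          "parental_gt_reconstructed": true,
          "ratio_pre": "4Del/96A",
          "ratio_post": "4Del/96A",
          "haplotype_prediction": null,
          "confirmed": "A/Del"
        },
        {
          "label": "paternal",
          "chrom": "chr11",
          "pos": 5248235,
          "ref": "G",
          "alt": "Del",
          "maternal_gt": "G/G",
          "paternal_gt": "Del/G",
          "parental_gt_reconstructed": true,
          "ratio_pre": "4Del/96G",
          "ratio_post": "4Del/96G",
          "haplotype_prediction": null,
          "confirmed": "Del/G"
        }
      ]
    },
    {
      "family": "IBT 31",
      "ff_pre_pct": 6.81,
      "ff_post_pct": 4.92,
      "iss_cutoff_bp": 160,
      "sites": [
        {
          "label": "maternal",
          "chrom": "chr11",
          "pos": 5248301,
          "ref": "G",
          "alt": "T",
          "maternal_gt": "G/T",
          "paternal_gt": "T/T",
          "parental_gt_reconstructed": true,
          "ratio_pre": "48G/52T",
          "ratio_post": "49G/51T",
          "haplotype_prediction": "T/T",
          "confirmed": "T/T"
        },
        {
          "label": "paternal",
          "chrom": "chr11",
          "pos": 5248225,
          "ref": "C",
          "alt": "Ins",
          "maternal_gt": "C/C",
          "paternal_gt": "C/Ins",
          "parental_gt_reconstructed": true,
          "ratio_pre": "1Ins/100C",
          "ratio_post": "2Ins/100C",
          "haplotype_prediction": null,
          "confirmed": "C/Ins"
        }
      ]
    },
    {
      "family": "IBT 43",
      "ff_pre_pct": 22.9,
      "ff_post_pct": 26.5,
      "iss_cutoff_bp": 160,
      "sites": [
        {
          "label": "maternal",
          "chrom": "chr11",
          "pos": 5248155,
          "ref": "C",
          "alt": "G",
          "maternal_gt": "C/G",
          "paternal_gt": "C/G",
          "parental_gt_reconstructed": true,
          "ratio_pre": "56C/44G",
          "ratio_post": "59C/41G",
          "haplotype_prediction": "C/G",
          "confirmed": "C/G"
        },
        {
          "label": "paternal",
          "chrom": "chr11",
          "pos": 5248219,
          "ref": "G",
          "alt": "T",
          "maternal_gt": "G/G",
          "paternal_gt": "G/T",
          "parental_gt_reconstructed": true,
          "ratio_pre": "93G/7T",
          "ratio_post": "88G/12T",
          "haplotype_prediction": "G/T",
          "confirmed": "G/T"
        }
      ]
    },
    {
      "family": "IBT 29",
      "ff_pre_pct": 12.2,
      "ff_post_pct": null,
      "iss_cutoff_bp": null,
      "sites": [
        {
          "label": "maternal",
          "chrom": "chr11",
          "pos": 5246486,
          "ref": "REF",
          "alt": "DEL619",
          "maternal_gt": "DEL619/REF",
          "paternal_gt": "REF/REF",
          "parental_gt_reconstructed": true,
          "ratio_pre": null,
          "ratio_post": null,
          "haplotype_prediction": "DEL619/REF",
          "confirmed": "DEL619/REF"
        },
        {
          "label": "paternal",
          "chrom": "chr11",
          "pos": 5247993,
          "ref": "A",
          "alt": "Del",
          "maternal_gt": "A/A",
          "paternal_gt": "A/Del",
          "parental_gt_reconstructed": true,
          "ratio_pre": "2Del/98A",
          "ratio_post": null,
          "haplotype_prediction": "A/A",
          "confirmed": "A/A"
        }
      ]
    },
    {
      "family": "IBT 53",
      "ff_pre_pct": 8.27,
      "ff_post_pct": 15.24,
      "iss_cutoff_bp": 140,
      "sites": [
        {
          "label": "maternal/paternal",
          "chrom": "chr11",
          "pos": 5248219,
          "ref": "G",
          "alt": "T",
          "maternal_gt": "G/T",
          "paternal_gt": "G/T",
          "parental_gt_reconstructed": false,
          "ratio_pre": "54G/46T",
          "ratio_post": "58G/43T",
          "haplotype_prediction": "G/G",
          "confirmed": "G/G"
        }
      ]
    },
    {
      "family": "IBT 63",
      "ff_pre_pct": 6.27,
      "ff_post_pct": 12.91,
      "iss_cutoff_bp": 140,
      "sites": [
        {
          "label": "maternal",
          "chrom": "chr11",
          "pos": 5248389,
          "ref": "A",
          "alt": "G",
          "maternal_gt": "A/G",
          "paternal_gt": "G/G",
          "parental_gt_reconstructed": false,
          "ratio_pre": "47A/53G",
          "ratio_post": "58A/42G",
          "haplotype_prediction": "A/G",
          "confirmed": "A/G"
        },
        {
          "label": "paternal",
          "chrom": "chr11",
          "pos": 5248225,
          "ref": "C",
          "alt": "Ins",
          "maternal_gt": "C/C",
          "paternal_gt": "C/Ins",
          "parental_gt_reconstructed": true,
          "ratio_pre": "2Ins/100C",
          "ratio_post": "2Ins/100C",
          "haplotype_prediction": "C/Ins",
          "confirmed": "C/Ins"
        }
      ]
    },
    {
      "family": "IBT 69",
      "ff_pre_pct": 8.12,
      "ff_post_pct": 14.09,
      "iss_cutoff_bp": 140,
      "sites": [
        {
          "label": "maternal",
          "chrom": "chr11",
          "pos": 5238389,
          "ref": "A",
          "alt": "G",
          "maternal_gt": "A/G",
          "paternal_gt": "G/G",
          "parental_gt_reconstructed": true,
          "ratio_pre": "47A/53G",
          "ratio_post": "47A/53G",
          "haplotype_prediction": ["A/G", "G/G"],
          "confirmed": "A/G"
        },
        {
          "label": "paternal",
          "chrom": "chr11",
          "pos": 5247976,
          "ref": "A",
          "alt": "Ins",
          "maternal_gt": "A/A",
          "paternal_gt": "A/Ins",
          "parental_gt_reconstructed": true,
          "ratio_pre": "3Ins/100A",
          "ratio_post": "3Ins/100A",
          "haplotype_prediction": "A/Ins",
          "confirmed": "A/Ins"
        }
      ]
    }
  ]
}
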