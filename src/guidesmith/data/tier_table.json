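{
  "description": "Default tier ladder: tier 1 requires every positive and exclusion feature; tiers 2-6 cumulatively relax domain, conservation, efficacy, CDS position, and construct/SNP cleanliness, in that order, always requiring full specificity. Tiers 7.1-7.6 repeat the same ladder under relaxed specificity (0.25 < score <= 0.50); tier 8 collects non-specific guides. The relaxation order within tiers 2-6 is a documented package assumption, not an experimentally fitted ordering, and any ladder may be supplied in this format.",
  "full_specificity_tiers": [
    {"label": "1", "requires": ["domain", "conserved", "efficacy_ok", "cds_ok", "construct_ok", "snp_ok"]},
    {"label": "2", "requires": ["conserved", "efficacy_ok", "cds_ok", "construct_ok", "snp_ok"]},
    {"label": "3", "requires": ["efficacy_ok", "cds_ok", "construct_ok", "snp_ok"]},
    {"label": "4", "requires": ["cds_ok", "construct_ok", "snp_ok"]},
    {"label": "5", "requires": ["construct_ok", "snp_ok"]},
    {"label": "6", "requires": []}
  ],
  "relaxed_specificity_tiers": [
    {"label": "7.1", "requires": ["domain", "conserved", "efficacy_ok", "cds_ok", "construct_ok", "snp_ok"]},
    {"label": "7.2", "requires": ["conserved", "efficacy_ok", "cds_ok", "construct_ok", "snp_ok"]},
    {"label": "7.3", "requires": ["efficacy_ok", "cds_ok", "construct_ok", "snp_ok"]},
    {"label": "7.4", "requires": ["cds_ok", "construct_ok", "snp_ok"]},
    {"label": "7.5", "requires": ["construct_ok", "snp_ok"]},
    {"label": "7.6", "requires": []}
  ],
  "fallback_tier": "8"
}
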