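{
  "name": "CYP3A4 multiplex PCR-RFLP (*4 / *18B / *22)",
  "snps": [
    {"name": "CYP3A4*4", "rsid": "rs55951658", "wild_allele": "A", "variant_allele": "G"},
    {"name": "CYP3A4*18B", "rsid": "rs2242480", "wild_allele": "G", "variant_allele": "A"},
    {"name": "CYP3A4*22", "rsid": "rs35599367", "wild_allele": "C", "variant_allele": "T"}
  ],
  "tubes": [
    {"enzyme": "BsmAI", "diagnostic_snp": "CYP3A4*4", "incubation": "55C/60min"},
    {"enzyme": "RsaI", "diagnostic_snp": "CYP3A4*18B", "incubation": "37C/60min"},
    {"enzyme": "BseYI", "diagnostic_snp": "CYP3A4*22", "incubation": "37C/60min + 80C/20min inactivation"}
  ],
  "amplicon_sizes": {
    "CYP3A4*4": 244,
    "CYP3A4*18B": 331,
    "CYP3A4*22": 793
  }
}
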