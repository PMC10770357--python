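{
 "genes": ["TP53", "PIK3CA", "KRAS", "MYC", "BRCA1"],
 "mutation_rates": {"TP53": 0.4, "PIK3CA": 0.3, "KRAS": 0.1},
 "amp_rates": {"MYC": 0.3},
 "del_rates": {"BRCA1": 0.2},
 "expression_shifts": {"PIK3CA|TP53": 2.0}
}
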