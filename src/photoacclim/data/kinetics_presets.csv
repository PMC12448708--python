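preset,constant,value,units,source
tobacco,kc25,404.9,umol mol-1,"Nicotiana tabacum, Bernacchi-style Ci-based constants (standard temperature sensitivities)"
tobacco,ko25,278400,umol mol-1,"Nicotiana tabacum, Bernacchi-style Ci-based constants"
tobacco,gammastar25,42.75,umol mol-1,"Nicotiana tabacum, Bernacchi-style Ci-based constants"
tobacco,rl25,,umol CO2 m-2 s-1,"estimated from each curve fit (no fixed preset value)"
tobacco,ea_kc,79430,J mol-1,"Nicotiana tabacum, Bernacchi-style activation energy"
tobacco,ea_ko,36380,J mol-1,"Nicotiana tabacum, Bernacchi-style activation energy"
tobacco,ea_gammastar,37830,J mol-1,"Nicotiana tabacum, Bernacchi-style activation energy"
tobacco,ea_rl,46390,J mol-1,"Nicotiana tabacum, Bernacchi-style activation energy"
rice,kc25,310.0,umol mol-1,"SYNTHETIC stand-in for Oryza sativa: approximate literature magnitude, not a published table"
rice,ko25,220000,umol mol-1,"SYNTHETIC stand-in for Oryza sativa: approximate literature magnitude"
rice,gammastar25,39.5,umol mol-1,"SYNTHETIC stand-in for Oryza sativa: approximate literature magnitude"
rice,rl25,,umol CO2 m-2 s-1,"estimated from each curve fit"
rice,ea_kc,71000,J mol-1,"SYNTHETIC stand-in for Oryza sativa: approximate literature magnitude"
rice,ea_ko,33000,J mol-1,"SYNTHETIC stand-in for Oryza sativa: approximate literature magnitude"
rice,ea_gammastar,36000,J mol-1,"SYNTHETIC stand-in for Oryza sativa: approximate literature magnitude"
rice,ea_rl,46390,J mol-1,"SYNTHETIC stand-in for Oryza sativa: approximate literature magnitude"
potato,kc25,460.0,umol mol-1,"SYNTHETIC stand-in for Solanum tuberosum: approximate literature magnitude, not a published table"
potato,ko25,310000,umol mol-1,"SYNTHETIC stand-in for Solanum tuberosum: approximate literature magnitude"
potato,gammastar25,44.5,umol mol-1,"SYNTHETIC stand-in for Solanum tuberosum: approximate literature magnitude"
potato,rl25,,umol CO2 m-2 s-1,"estimated from each curve fit"
potato,ea_kc,85000,J mol-1,"SYNTHETIC stand-in for Solanum tuberosum: approximate literature magnitude"
potato,ea_ko,39000,J mol-1,"SYNTHETIC stand-in for Solanum tuberosum: approximate literature magnitude"
potato,ea_gammastar,38500,J mol-1,"SYNTHETIC stand-in for Solanum tuberosum: approximate literature magnitude"
potato,ea_rl,46390,J mol-1,"SYNTHETIC stand-in for Solanum tuberosum: approximate literature magnitude"
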