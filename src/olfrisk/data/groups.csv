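family,class,c_min,c_max,oel_15min_mg_m3,source
"Hydrocarbons, aliphatic, C6-C8",aliphatic,6,8,1400,Germany (AGS)
"Hydrocarbons, aliphatic, C9-C14",aliphatic,9,14,600,Germany (AGS)
"Hydrocarbon mixtures, aliphatic C5-C8",aliphatic,5,8,300,Latvia
"Hydrocarbons, aromatic, C9-C14",aromatic,9,14,100,Germany (AGS)
"Hydrocarbon mixtures, aromatic C7-C8",aromatic,7,8,300,Latvia
"Petroleum, industrial-heptane type",petroleum_fraction,6,8,1200,Sweden
"Petroleum, industrial-hexane type",petroleum_fraction,5,7,250,Sweden
"Petroleum, industrial-octane type",petroleum_fraction,7,9,1400,Sweden
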