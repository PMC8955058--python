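patient_id,retained,exclusion_reasons,route_group,category,fired_rule,prophylaxis_category,nk1_without_partners,combined_stage
p01,true,,intravenous_group,high,max-of-components,triple,false,III
p02,true,,intravenous_group,high,AC,serotonin_plus_dex,false,II
p03,true,,intravenous_group,high,FOLFOXIRI,triple,false,IV
p04,true,,intravenous_group,moderate,max-of-components,serotonin_plus_dex,false,III
p05,true,,intravenous_group,moderate,max-of-components,serotonin_plus_dex,false,IV
p06,true,,oral_group,minimal,max-of-components,none_of_above,false,IV
p07,true,,oral_group,low,max-of-components,dex_only,false,II
p08,true,,intravenous_group,high,AC,dex_only,false,III
p09,false,interferon_alpha,,,,,,
p10,false,same_day_surgery_or_drainage,,,,,,
p11,false,arterial_route,,,,,,
p12,false,hsct_within_3_weeks,,,,,,
p13,false,under_20,,,,,,
p14,false,no_chemo,,,,,,
p15,true,,intravenous_group,high,max-of-components,serotonin_only,true,IV
p16,true,,intravenous_group,high,FOLFIRINOX,triple,false,III
p17,true,,intravenous_group,moderate,GEM+nab-PTX,serotonin_plus_dex,false,IV
p18,true,,intravenous_group,low,max-of-components,dex_only,false,IV
p19,true,,intravenous_group,high,max-of-components,triple,false,III
p20,true,,intravenous_group,high,max-of-components,triple,false,III
p21,true,,intravenous_group,high,max-of-components,triple,false,IV
p22,true,,intravenous_group,moderate,max-of-components,serotonin_plus_dex,false,IV
p23,true,,oral_group,moderate,oral etoposide,serotonin_only,false,II
p24,true,,intravenous_group,minimal,max-of-components,none_of_above,false,I
p25,true,,oral_group,low,max-of-components,none_of_above,false,II
p26,true,,intravenous_group,unknown,unknown,none_of_above,false,IV
p27,true,,intravenous_group,high,max-of-components,triple,false,III
p28,true,,intravenous_group,high,max-of-components,serotonin_plus_dex,false,III
p29,true,,intravenous_group,moderate,max-of-components,none_of_above,false,II
p30,true,,intravenous_group,low,max-of-components,dex_only,false,II
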