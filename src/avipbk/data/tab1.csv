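study_id,species,sex,repro_state,parameter,value,unit,n_birds,dispersion_type,dispersion_value,citation,provenance
tab1-hen-tbw,chicken,female,laying,total_body_water_pct,57.3,%,,,,ref52,table=tab1;row=Total body water % of b.wt.;col=Laying hen;n_studies=1
tab1-hen-icw,chicken,female,laying,intracellular_water_pct,31.1,%,,,,ref52,table=tab1;row=Intracellular water % of b.wt.;col=Laying hen;n_studies=1
tab1-hen-ecw,chicken,female,laying,extracellular_water_pct,26.2,%,,,,ref52,table=tab1;row=Extracellular water % of b.wt.;col=Laying hen;n_studies=1
tab1-hen-plasma,chicken,female,laying,plasma_pct,4.6,%,,,,ref52,table=tab1;row=Plasma % of body weight;col=Laying hen;n_studies=1
tab1-hen-isf,chicken,female,laying,interstitial_fluid_pct,21.7,%,,,,ref52,table=tab1;row=Interstitial fluid % of b.wt.;col=Laying hen;n_studies=1
tab1-hen-co,chicken,female,laying,co_mL_min,316,mL/min,,SEM,35.6,SM1,table=tab1;row=Cardiac Output (CO) ml min-1;col=Laying hen;n_studies=7
tab1-hen-cokg,chicken,female,laying,co_mL_min_kg,176,mL/min/kg,,SEM,16.0,SM1 assuming 1.6 kg body weight,table=tab1;row=CO ml min-1 kg-1;col=Laying hen;n_studies=7
tab1-hen-heart,chicken,female,laying,rel_wt_g_100g.heart,0.446,g/100g,,SEM,0.040,SM1,table=tab1;row=Heart weight % of b.wt.;col=Laying hen;n_studies=9
tab1-hen-hct,chicken,female,laying,hematocrit_pct,27.1,%,,SEM,0.86,SM1,table=tab1;row=Hematocrit %;col=Laying hen;n_studies=10
tab1-hen-hb,chicken,female,laying,hemoglobin_g_dL,9.2,g/dL,,SEM,0.62,SM1,table=tab1;row=Blood hemoglobin g dL-1;col=Laying hen;n_studies=5
tab1-cock-hpf,chicken,male,adult_nonlaying,hepatic_portal_flow_mL_min,32.8,mL/min,,,,ref84 non-anaesthetized fed adult males,table=tab1;row=Hepatic portal blood flow ml min-1;col=Laying hen;n_studies=1
tab1-cock-hpfkg,chicken,male,adult_nonlaying,hepatic_portal_flow_mL_min_kg,14.8,mL/min/kg,,,,ref84 non-anaesthetized fed adult males,table=tab1;row=Hepatic portal blood flow ml kg-1 min-1;col=Laying hen;n_studies=1
tab1-mal-tbw,mallard,female,unknown,total_body_water_pct,68.5,%,,,,ref68,table=tab1;row=Total body water % of b.wt.;col=Mallards;n_studies=1
tab1-mal-icw,mallard,female,unknown,intracellular_water_pct,44.8,%,,,,ref68,table=tab1;row=Intracellular water % of b.wt.;col=Mallards;n_studies=1
tab1-mal-ecw,mallard,female,unknown,extracellular_water_pct,23.7,%,,,,ref68,table=tab1;row=Extracellular water % of b.wt.;col=Mallards;n_studies=1
tab1-mal-plasma,mallard,female,unknown,plasma_pct,5.3,%,,,,mean of ref40 and ref68,table=tab1;row=Plasma % of body weight;col=Mallards;n_studies=2
tab1-mal-isf,mallard,female,unknown,interstitial_fluid_pct,17.9,%,,,,ref68,table=tab1;row=Interstitial fluid % of b.wt.;col=Mallards;n_studies=1
tab1-mal-co,mallard,female,unknown,co_mL_min,1203,mL/min,,,,SM1,table=tab1;row=Cardiac Output (CO) ml min-1;col=Mallards;n_studies=2
tab1-mal-cokg,mallard,female,unknown,co_mL_min_kg,416,mL/min/kg,,,,SM1,table=tab1;row=CO ml min-1 kg-1;col=Mallards;n_studies=2
tab1-mal-heart,mallard,female,unknown,rel_wt_g_100g.heart,1.13,g/100g,,,,ref42,table=tab1;row=Heart weight % of b.wt.;col=Mallards;n_studies=1
tab1-mal-hct,mallard,female,unknown,hematocrit_pct,45.4,%,,SEM,1.82,SM1,table=tab1;row=Hematocrit %;col=Mallards;n_studies=4
tab1-mal-hb,mallard,female,unknown,hemoglobin_g_dL,15.4,g/dL,,SEM,0.93,SM1,table=tab1;row=Blood hemoglobin g dL-1;col=Mallards;n_studies=3
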