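study_id,species,sex,repro_state,parameter,value,unit,n_birds,dispersion_type,dispersion_value,citation,provenance
res-dduck-hct,domestic_duck,female,unknown,hematocrit_pct,41.0,%,,SEM,1.30,SM1,table=results;row=domesticated duck Hct;n_studies=9
res-broiler-hct,chicken,mixed,broiler_juvenile,hematocrit_pct,31.4,%,,SEM,3.24,SM1,table=results;row=young broiler Hct;n_studies=9
res-cock-hct,chicken,male,adult_nonlaying,hematocrit_pct,39.9,%,,SEM,3.24,SM1,table=results;row=adult male Hct;n_studies=3
res-broiler-cokg,chicken,mixed,broiler_juvenile,co_mL_min_kg,192,mL/min/kg,,SEM,5.6,SM1,table=results;row=broiler CO per kg;n_studies=5
res-broiler-hb,chicken,mixed,broiler_juvenile,hemoglobin_g_dL,9.33,g/dL,,SEM,0.63,SM1,table=results;row=broiler hemoglobin;n_studies=6
res-dduck-hb,domestic_duck,female,unknown,hemoglobin_g_dL,13.3,g/dL,,SEM,0.30,SM1,table=results;row=domesticated duck hemoglobin;n_studies=6
res-malF-tp,mallard,female,adult_nonlaying,plasma_protein_g_dL,4.40,g/dL,55,SEM,0.10,calc from ref18 ref24,table=results;row=non-reproductive female mallard total protein;n_studies=1
res-malM-tp,mallard,male,adult_nonlaying,plasma_protein_g_dL,4.11,g/dL,26,SEM,0.17,calc from ref18 ref24,table=results;row=male mallard total protein;n_studies=1
res-malL-tp,mallard,female,laying,plasma_protein_g_dL,6.30,g/dL,18,SEM,0.28,calc from ref24,table=results;row=laying female mallard total protein;n_studies=1
res-malF-alb,mallard,female,adult_nonlaying,albumin_g_dL,1.64,g/dL,26,SEM,0.08,calc from ref18 ref24,table=results;row=non-reproductive female mallard albumin;n_studies=1
res-malM-alb,mallard,male,adult_nonlaying,albumin_g_dL,1.83,g/dL,53,SEM,0.03,calc from ref18 ref24,table=results;row=male mallard albumin;n_studies=1
res-malL-alb,mallard,female,laying,albumin_g_dL,2.30,g/dL,18,SEM,0.08,calc from ref24,table=results;row=laying female mallard albumin;n_studies=1
res-alb-excl1,chicken,female,immature,albumin_g_dL,2.26,g/dL,,,,ref85,table=results;row=albumin study excluded by 4-SD screen;n_studies=1;flag=excluded_in_source
res-alb-excl2,chicken,female,immature,albumin_g_dL,4.8,g/dL,,,,ref93,table=results;row=albumin study excluded by 4-SD screen;n_studies=1;flag=excluded_in_source
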