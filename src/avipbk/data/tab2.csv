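study_id,species,sex,repro_state,parameter,value,unit,n_birds,dispersion_type,dispersion_value,citation,provenance
tab2-imm-hct,chicken,female,immature,hematocrit_pct,28.1,%,,SEM,1.78,SM1,table=tab2;row=Hematocrit/PCV %;col=Pullets;n_studies=4
tab2-lay-hct,chicken,female,laying,hematocrit_pct,27.1,%,,SEM,0.86,SM1,table=tab2;row=Hematocrit/PCV %;col=Laying hens;n_studies=10
tab2-imm-hb,chicken,female,immature,hemoglobin_g_dL,8.88,g/dL,,SEM,0.38,SM1,table=tab2;row=Hemoglobin %;col=Pullets;n_studies=2
tab2-lay-hb,chicken,female,laying,hemoglobin_g_dL,9.18,g/dL,,SEM,0.62,SM1,table=tab2;row=Hemoglobin %;col=Laying hens;n_studies=5
tab2-imm-tp,chicken,female,immature,plasma_protein_g_dL,3.80,g/dL,,SEM,1.0,SM1,table=tab2;row=Plasma protein g dL-1;col=Pullets;n_studies=2
tab2-lay-tp,chicken,female,laying,plasma_protein_g_dL,4.53,g/dL,,SEM,0.52,SM1,table=tab2;row=Plasma protein g dL-1;col=Laying hens;n_studies=3
tab2-imm-alb,chicken,female,immature,albumin_g_dL,1.67,g/dL,,SEM,0.098,SM1,table=tab2;row=Albumin g dL-1;col=Pullets;n_studies=5
tab2-lay-alb,chicken,female,laying,albumin_g_dL,1.19,g/dL,,SEM,0.18,SM1,table=tab2;row=Albumin g dL-1;col=Laying hens;n_studies=5
tab2-imm-igy,chicken,female,immature,igy_g_dL,0.948,g/dL,,,,ref65,table=tab2;row=IgY g dL-1;col=Pullets;n_studies=1
tab2-lay-igy,chicken,female,laying,igy_g_dL,3.66,g/dL,,SEM,1.47,SM1,table=tab2;row=IgY g dL-1;col=Laying hens;n_studies=3
tab2-imm-iga,chicken,female,immature,iga_g_dL,0.342,g/dL,,,,SM1,table=tab2;row=IgA g dL-1;col=Pullets;n_studies=1
tab2-lay-iga,chicken,female,laying,iga_g_dL,0.323,g/dL,,,,SM1,table=tab2;row=IgA g dL-1;col=Laying hens;n_studies=1
tab2-lay-igm,chicken,female,laying,igm_g_dL,1.32,g/dL,,SEM,0.40,SM1,table=tab2;row=IgM g dL-1;col=Laying hens;n_studies=2
tab2-imm-vtg,chicken,female,immature,vitellogenin_g_dL,0,g/dL,,,,ref58 ref31,table=tab2;row=Vitellogenin g dL-1;col=Pullets;n_studies=1
tab2-lay-vtg,chicken,female,laying,vitellogenin_g_dL,1.63,g/dL,,,,ref58 ref31,table=tab2;row=Vitellogenin g dL-1;col=Laying hens;n_studies=1
tab2-imm-tg,chicken,female,immature,triglyceride_g_dL,0.408,g/dL,,SEM,0.063,SM1,table=tab2;row=Triglyceride g dL-1;col=Pullets;n_studies=3
tab2-lay-tg,chicken,female,laying,triglyceride_g_dL,2.268,g/dL,,SEM,0.516,SM1,table=tab2;row=Triglyceride g dL-1;col=Laying hens;n_studies=5
tab2-imm-chol,chicken,female,immature,cholesterol_g_dL,0.101,g/dL,,SEM,0.0023,SM1,table=tab2;row=Cholesterol g dL-1;col=Pullets;n_studies=3
tab2-lay-chol,chicken,female,laying,cholesterol_g_dL,0.172,g/dL,,SEM,0.064,SM1,table=tab2;row=Cholesterol g dL-1;col=Laying hens;n_studies=5
tab2-imm-pl,chicken,female,immature,phospholipids_g_dL,0.141,g/dL,,SEM,0.040,SM1,table=tab2;row=Phospholipids g dL-1;col=Pullets;n_studies=3
tab2-lay-pl,chicken,female,laying,phospholipids_g_dL,0.453,g/dL,,SEM,0.247,SM1,table=tab2;row=Phospholipids g dL-1;col=Laying hens;n_studies=3
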