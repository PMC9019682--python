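study_id,species,sex,repro_state,parameter,value,unit,n_birds,dispersion_type,dispersion_value,citation,provenance
tab7-pres-blood,chicken,female,laying,rel_wt_g_100g.blood,6.3,g/100g,,,,present study,table=tab7;row=Blood;col=Present study;n_studies=1
tab7-pres-heart,chicken,female,laying,rel_wt_g_100g.heart,0.45,g/100g,,SEM,0.040,present study,table=tab7;row=Heart;col=Present study;n_studies=9
tab7-pres-liver,chicken,female,laying,rel_wt_g_100g.liver,2.33,g/100g,,SEM,0.10,present study,table=tab7;row=Liver;col=Present study;n_studies=23
tab7-pres-kidneys,chicken,female,laying,rel_wt_g_100g.kidneys,0.80,g/100g,,SEM,0.098,present study,table=tab7;row=Kidneys;col=Present study;n_studies=5
tab7-pres-spleen,chicken,female,laying,rel_wt_g_100g.spleen,0.16,g/100g,,SEM,0.022,present study,table=tab7;row=Spleen;col=Present study;n_studies=8
tab7-pres-gizzard,chicken,female,laying,rel_wt_g_100g.gizzard,3.21,g/100g,,SEM,1.10,present study,table=tab7;row=Gizzard;col=Present study;n_studies=7
tab7-pres-si,chicken,female,laying,rel_wt_g_100g.small_intestine,3.39,g/100g,,SEM,1.22,present study,table=tab7;row=Small intestine;col=Present study;n_studies=3
tab7-pres-ovary,chicken,female,laying,rel_wt_g_100g.ovary,2.38,g/100g,,SEM,0.21,present study,table=tab7;row=Ovary;col=Present study;n_studies=14
tab7-pres-oviduct,chicken,female,laying,rel_wt_g_100g.oviduct,2.84,g/100g,,SEM,0.22,present study,table=tab7;row=Oviduct;col=Present study;n_studies=8
tab7-pres-co,chicken,female,laying,co_L_hr_kg,10.6,L/hr/kg,,,,present study,table=tab7;row=Cardiac output L hr-1 kg-1;col=Present study;n_studies=7
tab7-pres-hct,chicken,female,laying,hematocrit_pct,27.1,%,,,,present study,table=tab7;row=Hematocrit;col=Present study;n_studies=10
tab7-ref90-blood,chicken,female,laying,rel_wt_g_100g.blood,6.3,g/100g,,SD,1.33,ref90,table=tab7;row=Blood;col=ref90;n_studies=1
tab7-ref90-heart,chicken,female,laying,rel_wt_g_100g.heart,0.30,g/100g,,SD,0.065,ref90,table=tab7;row=Heart;col=ref90;n_studies=1
tab7-ref90-liver,chicken,female,laying,rel_wt_g_100g.liver,2.49,g/100g,,SD,0.49,ref90,table=tab7;row=Liver;col=ref90;n_studies=2
tab7-ref90-kidneys,chicken,female,laying,rel_wt_g_100g.kidneys,0.76,g/100g,,SD,0.13,ref90,table=tab7;row=Kidneys;col=ref90;n_studies=2
tab7-ref90-spleen,chicken,female,laying,rel_wt_g_100g.spleen,0.15,g/100g,,SD,0.06,ref90,table=tab7;row=Spleen;col=ref90;n_studies=3
tab7-ref90-gizzard,chicken,female,laying,rel_wt_g_100g.gizzard,0.70,g/100g,,SD,0.11,ref90,table=tab7;row=Gizzard;col=ref90;n_studies=2
tab7-ref90-si,chicken,female,laying,rel_wt_g_100g.small_intestine,0.95,g/100g,,,,ref90,table=tab7;row=Small intestine;col=ref90;n_studies=1
tab7-ref90-ovary,chicken,female,laying,rel_wt_g_100g.ovary,1.91,g/100g,,SD,0.28,ref90,table=tab7;row=Ovary;col=ref90;n_studies=1
tab7-ref90-oviduct,chicken,female,laying,rel_wt_g_100g.oviduct,2.58,g/100g,,,,ref90,table=tab7;row=Oviduct;col=ref90;n_studies=3
tab7-ref90-co,chicken,female,laying,co_L_hr_kg,9.91,L/hr/kg,,,,ref90,table=tab7;row=Cardiac output L hr-1 kg-1;col=ref90;n_studies=6
tab7-ref90-hct,chicken,female,laying,hematocrit_pct,31.0,%,,,,ref90,table=tab7;row=Hematocrit;col=ref90;n_studies=5
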