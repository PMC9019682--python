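study_id,species,sex,repro_state,parameter,value,unit,n_birds,dispersion_type,dispersion_value,citation,provenance
tab3-alb-plasma,chicken,female,laying,plasma_conc_g_dL.albumin,1.67,g/dL,,,,from tab2,table=tab3;row=Albumin / alpha-livetin;col=Plasma/serum;n_studies=1
tab3-alb-yolk,chicken,female,laying,yolk_conc_g_dL.albumin,1.06,g/dL,,,,calc from ref29 ref5,table=tab3;row=Albumin / alpha-livetin;col=Egg yolk;n_studies=1
tab3-alb-ratio,chicken,female,laying,yolk_plasma_ratio.albumin,0.61,1,,,,authors' ratio,table=tab3;row=Albumin / alpha-livetin;col=Ratio plasma:yolk;n_studies=1;flag=stored_not_asserted
tab3-alb-isf,chicken,female,laying,interstitial_conc_g_dL.albumin,0.89,g/dL,,,,SM1,table=tab3;row=Albumin / alpha-livetin;col=Interstitial fluid;n_studies=1
tab3-alb-isfratio,chicken,female,laying,yolk_interstitial_ratio.albumin,1.19,1,,,,authors' ratio,table=tab3;row=Albumin / alpha-livetin;col=Ratio interstitial:yolk;n_studies=1
tab3-a2g-plasma,chicken,female,laying,plasma_conc_g_dL.alpha2_glycoprotein,0.268,g/dL,,,,SM1,table=tab3;row=alpha2-glycoprotein / beta-livetin;col=Plasma/serum;n_studies=1
tab3-a2g-yolk,chicken,female,laying,yolk_conc_g_dL.alpha2_glycoprotein,2.65,g/dL,,,,calc from ref29 ref5,table=tab3;row=alpha2-glycoprotein / beta-livetin;col=Egg yolk;n_studies=1
tab3-a2g-ratio,chicken,female,laying,yolk_plasma_ratio.alpha2_glycoprotein,9.89,1,,,,authors' ratio,table=tab3;row=alpha2-glycoprotein / beta-livetin;col=Ratio plasma:yolk;n_studies=1
tab3-a2g-isf,chicken,female,laying,interstitial_conc_g_dL.alpha2_glycoprotein,0.11,g/dL,,,,SM1,table=tab3;row=alpha2-glycoprotein / beta-livetin;col=Interstitial fluid;n_studies=1
tab3-a2g-isfratio,chicken,female,laying,yolk_interstitial_ratio.alpha2_glycoprotein,24.1,1,,,,authors' ratio,table=tab3;row=alpha2-glycoprotein / beta-livetin;col=Ratio interstitial:yolk;n_studies=1
tab3-igy-plasma,chicken,female,laying,plasma_conc_g_dL.igy,0.948,g/dL,,,,from tab2,table=tab3;row=IgY / gamma-livetin;col=Plasma/serum;n_studies=1
tab3-igy-yolk,chicken,female,laying,yolk_conc_g_dL.igy,1.59,g/dL,,,,calc from ref29 ref5,table=tab3;row=IgY / gamma-livetin;col=Egg yolk;n_studies=1
tab3-igy-ratio,chicken,female,laying,yolk_plasma_ratio.igy,1.68,1,,,,authors' ratio,table=tab3;row=IgY / gamma-livetin;col=Ratio plasma:yolk;n_studies=1
tab3-igy-isf,chicken,female,laying,interstitial_conc_g_dL.igy,0.37,g/dL,,,,SM1,table=tab3;row=IgY / gamma-livetin;col=Interstitial fluid;n_studies=1
tab3-igy-isfratio,chicken,female,laying,yolk_interstitial_ratio.igy,4.54,1,,,,authors' ratio,table=tab3;row=IgY / gamma-livetin;col=Ratio interstitial:yolk;n_studies=1;flag=stored_not_asserted
tab3-vtg-plasma,chicken,female,laying,plasma_conc_g_dL.vitellogenin,1.63,g/dL,,,,from tab2,table=tab3;row=Vitellogenin / phosvitin+lipovitellin;col=Plasma/serum;n_studies=1
tab3-vtg-yolk,chicken,female,laying,yolk_conc_g_dL.vitellogenin,10.4,g/dL,,,,calc from ref29,table=tab3;row=Vitellogenin / phosvitin+lipovitellin;col=Egg yolk;n_studies=1
tab3-vtg-ratio,chicken,female,laying,yolk_plasma_ratio.vitellogenin,6.38,1,,,,authors' ratio,table=tab3;row=Vitellogenin / phosvitin+lipovitellin;col=Ratio plasma:yolk;n_studies=1
tab3-tg-plasma,chicken,female,laying,plasma_conc_g_dL.triglyceride,2.268,g/dL,,,,from tab2,table=tab3;row=Triglyceride;col=Plasma/serum;n_studies=1
tab3-tg-yolk,chicken,female,laying,yolk_conc_g_dL.triglyceride,25.1,g/dL,,,,calc from ref29,table=tab3;row=Triglyceride;col=Egg yolk;n_studies=1
tab3-tg-ratio,chicken,female,laying,yolk_plasma_ratio.triglyceride,11.1,1,,,,authors' ratio,table=tab3;row=Triglyceride;col=Ratio plasma:yolk;n_studies=1
tab3-pl-plasma,chicken,female,laying,plasma_conc_g_dL.phospholipids,0.453,g/dL,,,,from tab2,table=tab3;row=Phospholipids;col=Plasma/serum;n_studies=1
tab3-pl-yolk,chicken,female,laying,yolk_conc_g_dL.phospholipids,5.89,g/dL,,,,calc from ref29,table=tab3;row=Phospholipids;col=Egg yolk;n_studies=1
tab3-pl-ratio,chicken,female,laying,yolk_plasma_ratio.phospholipids,13.0,1,,,,authors' ratio,table=tab3;row=Phospholipids;col=Ratio plasma:yolk;n_studies=1
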