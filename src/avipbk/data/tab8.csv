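study_id,species,sex,repro_state,parameter,value,unit,n_birds,dispersion_type,dispersion_value,citation,provenance
tab8-pres-proventriculus,chicken,male,adult_nonlaying,blood_flow_mL_min.proventriculus,5.8,mL/min,,,,present study (males),table=tab8;row=Proventriculus;col=Present report;n_studies=1
tab8-pres-gizzard,chicken,mixed,unknown,blood_flow_mL_min.gizzard,8.0,mL/min,,,,present study,table=tab8;row=Gizzard;col=Present report;n_studies=1
tab8-pres-duodenum,chicken,mixed,unknown,blood_flow_mL_min.duodenum,15.3,mL/min,,,,present study,table=tab8;row=Duodenum;col=Present report;n_studies=1
tab8-pres-heart,chicken,mixed,unknown,blood_flow_mL_min.heart,20.6,mL/min,,SEM,2.2,present study,table=tab8;row=Heart;col=Present report;n_studies=2
tab8-pres-liverart,chicken,mixed,unknown,blood_flow_mL_min.liver_arterial,26.9,mL/min,,SEM,6.4,present study,table=tab8;row=Liver arterial;col=Present report;n_studies=2
tab8-pres-liverport,chicken,mixed,unknown,blood_flow_mL_min.liver_portal,0.88,mL/min,,,,present study,table=tab8;row=Liver portal;col=Present report;n_studies=1
tab8-pres-pectoralis,chicken,mixed,unknown,blood_flow_mL_min.muscle_pectoralis,5.3,mL/min,,,,present study,table=tab8;row=Muscle pectoralis;col=Present report;n_studies=1
tab8-pres-kidneys,chicken,mixed,unknown,blood_flow_mL_min.kidneys,52.3,mL/min,,SEM,20.6,present study,table=tab8;row=Kidneys;col=Present report;n_studies=2
tab8-pres-spleen,chicken,mixed,unknown,blood_flow_mL_min.spleen,6.59,mL/min,,SEM,4.11,present study,table=tab8;row=Spleen;col=Present report;n_studies=2
tab8-pres-ovary,chicken,female,laying,blood_flow_mL_min.ovary,8.79,mL/min,,SEM,3.06,present study,table=tab8;row=Ovary;col=Present report;n_studies=5;reliability=low
tab8-pres-oviduct,chicken,female,laying,blood_flow_mL_min.oviduct,27.0,mL/min,,SEM,5.45,present study,table=tab8;row=Oviduct;col=Present report;n_studies=8
tab8-pres-infundibulum,chicken,female,laying,blood_flow_mL_min.infundibulum,0.95,mL/min,,SEM,0.056,present study,table=tab8;row=Infundibulum;col=Present report;n_studies=6
tab8-pres-magnum,chicken,female,laying,blood_flow_mL_min.magnum,19.3,mL/min,,SEM,2.11,present study,table=tab8;row=Magnum;col=Present report;n_studies=7
tab8-pres-isthmus,chicken,female,laying,blood_flow_mL_min.isthmus,2.34,mL/min,,SEM,0.36,present study,table=tab8;row=Isthmus;col=Present report;n_studies=7
tab8-pres-uterus,chicken,female,laying,blood_flow_mL_min.uterus,9.78,mL/min,,SEM,2.07,present study,table=tab8;row=Uterus or shell gland;col=Present report;n_studies=7
tab8-pres-vagina,chicken,female,laying,blood_flow_mL_min.vagina,1.00,mL/min,,SEM,0.12,present study,table=tab8;row=Vagina;col=Present report;n_studies=3
tab8-ref90-cerebrum,chicken,mixed,unknown,blood_flow_mL_min.cerebrum,0.016,mL/min,,,,ref90,table=tab8;row=Cerebrum;col=ref90;n_studies=1;reliability=low
tab8-ref90-cerebellum,chicken,mixed,unknown,blood_flow_mL_min.cerebellum,0.0027,mL/min,,,,ref90,table=tab8;row=Cerebellum;col=ref90;n_studies=1;reliability=low
tab8-ref90-proventriculus,chicken,mixed,unknown,blood_flow_mL_min.proventriculus,2.93,mL/min,,,,ref90,table=tab8;row=Proventriculus;col=ref90;n_studies=4
tab8-ref90-gizzard,chicken,mixed,unknown,blood_flow_mL_min.gizzard,2.24,mL/min,,,,ref90,table=tab8;row=Gizzard;col=ref90;n_studies=4
tab8-ref90-duodenum,chicken,mixed,unknown,blood_flow_mL_min.duodenum,12.5,mL/min,,,,ref90,table=tab8;row=Duodenum;col=ref90;n_studies=5
tab8-ref90-jejunum,chicken,mixed,unknown,blood_flow_mL_min.jejunum,12.3,mL/min,,,,ref90,table=tab8;row=Jejunum;col=ref90;n_studies=5
tab8-ref90-ileum,chicken,mixed,unknown,blood_flow_mL_min.ileum,5.6,mL/min,,,,ref90,table=tab8;row=Ileum;col=ref90;n_studies=1
tab8-ref90-colon,chicken,mixed,unknown,blood_flow_mL_min.colon,0.32,mL/min,,,,ref90,table=tab8;row=Colon;col=ref90;n_studies=2
tab8-ref90-heart,chicken,mixed,unknown,blood_flow_mL_min.heart,14.4,mL/min,,,,ref90,table=tab8;row=Heart;col=ref90;n_studies=1
tab8-ref90-liverart,chicken,mixed,unknown,blood_flow_mL_min.liver_arterial,66.7,mL/min,,,,ref90,table=tab8;row=Liver arterial;col=ref90;n_studies=6
tab8-ref90-liverport,chicken,mixed,unknown,blood_flow_mL_min.liver_portal,41.6,mL/min,,,,ref90,table=tab8;row=Liver portal;col=ref90;n_studies=2
tab8-ref90-pectoralis,chicken,mixed,unknown,blood_flow_mL_min.muscle_pectoralis,20.0,mL/min,,,,ref90,table=tab8;row=Muscle pectoralis;col=ref90;n_studies=2
tab8-ref90-lungs,chicken,mixed,unknown,blood_flow_mL_min.lungs,149.1,mL/min,,,,ref90,table=tab8;row=Lungs;col=ref90;n_studies=2;reliability=low
tab8-ref90-kidneys,chicken,mixed,unknown,blood_flow_mL_min.kidneys,53.1,mL/min,,,,ref90,table=tab8;row=Kidneys;col=ref90;n_studies=6
tab8-ref90-spleen,chicken,mixed,unknown,blood_flow_mL_min.spleen,10.7,mL/min,,,,ref90,table=tab8;row=Spleen;col=ref90;n_studies=1
tab8-ref90-ovary,chicken,female,laying,blood_flow_mL_min.ovary,43.5,mL/min,,,,ref90,table=tab8;row=Ovary;col=ref90;n_studies=1;reliability=low
tab8-ref90-oviduct,chicken,female,laying,blood_flow_mL_min.oviduct,32.3,mL/min,,,,ref90,table=tab8;row=Oviduct;col=ref90;n_studies=1
tab8-ref90-infundibulum,chicken,female,laying,blood_flow_mL_min.infundibulum,0.83,mL/min,,,,ref90,table=tab8;row=Infundibulum;col=ref90;n_studies=5
tab8-ref90-magnum,chicken,female,laying,blood_flow_mL_min.magnum,13.6,mL/min,,,,ref90,table=tab8;row=Magnum;col=ref90;n_studies=6
tab8-ref90-isthmus,chicken,female,laying,blood_flow_mL_min.isthmus,3.2,mL/min,,,,ref90,table=tab8;row=Isthmus;col=ref90;n_studies=5
tab8-ref90-uterus,chicken,female,laying,blood_flow_mL_min.uterus,14.7,mL/min,,,,ref90,table=tab8;row=Uterus or shell gland;col=ref90;n_studies=5
tab8-ref90-vagina,chicken,female,laying,blood_flow_mL_min.vagina,1.07,mL/min,,,,ref90,table=tab8;row=Vagina;col=ref90;n_studies=2
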