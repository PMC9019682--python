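study_id,species,sex,repro_state,parameter,value,unit,n_birds,dispersion_type,dispersion_value,citation,provenance
tab6-ckn-bile,chicken,mixed,unknown,bile_production_mL_hr_kg,1.157,mL/hr/kg,,SEM,0.613,SM1,table=tab6;row=Bile production;col=Chicken;n_studies=6
tab6-mam-bile,mammal:composite,mixed,unknown,bile_production_mL_hr_kg,2.034,mL/hr/kg,,SEM,0.604,SM1,table=tab6;row=Bile production;col=Mammalian;n_studies=9
tab6-mal-vh-duo,mallard,mixed,unknown,villus_height_um.duodenum,891,um,,SEM,111.7,SM1,table=tab6;row=Villus Height Duodenum;col=Mallards;n_studies=5
tab6-mal-vh-jej,mallard,mixed,unknown,villus_height_um.jejunum,862,um,,SEM,41.1,SM1,table=tab6;row=Villus Height Jejunum;col=Mallards;n_studies=3
tab6-mal-vh-ile,mallard,mixed,unknown,villus_height_um.ileum,747,um,,SEM,77.4,SM1,table=tab6;row=Villus Height Ileum;col=Mallards;n_studies=3
tab6-mam-vh-duo,mammal:composite,mixed,unknown,villus_height_um.duodenum,574,um,,SEM,61.7,SM1,table=tab6;row=Villus Height Duodenum;col=Mammalian;n_studies=9
tab6-mam-vh-jej,mammal:composite,mixed,unknown,villus_height_um.jejunum,529,um,,SEM,58.4,SM1,table=tab6;row=Villus Height Jejunum;col=Mammalian;n_studies=10
tab6-mam-vh-ile,mammal:composite,mixed,unknown,villus_height_um.ileum,370,um,,SEM,53.7,SM1,table=tab6;row=Villus Height Ileum;col=Mammalian;n_studies=9
tab6-ckn-area,chicken,mixed,unknown,absorptive_area_m2,7.78,m2,,,,calc from ref27 ref55,table=tab6;row=Absorptive area m2;col=Chicken;n_studies=1;flag=stored_not_asserted
tab6-mal-area,mallard,mixed,unknown,absorptive_area_m2,5.67,m2,,,,ref91,table=tab6;row=Absorptive area m2;col=Mallards;n_studies=1;flag=stored_not_asserted
tab6-mam-area,mammal:composite,mixed,unknown,absorptive_area_m2,15.5,m2,,SEM,5.4,eight mammal species,table=tab6;row=Absorptive area m2;col=Mammalian;n_studies=8
tab6-ckn-areakg,chicken,mixed,unknown,absorptive_area_m2_kg,4.86,m2/kg,,,,calc from ref27 ref55,table=tab6;row=Absorptive area m2 kg-1;col=Chicken;n_studies=1;flag=stored_not_asserted
tab6-mal-areakg,mallard,mixed,unknown,absorptive_area_m2_kg,7.80,m2/kg,,,,ref91,table=tab6;row=Absorptive area m2 kg-1;col=Mallards;n_studies=1;flag=stored_not_asserted
tab6-mam-areakg,mammal:composite,mixed,unknown,absorptive_area_m2_kg,18.7,m2/kg,,SEM,6.8,eight mammal species,table=tab6;row=Absorptive area m2 kg-1;col=Mammalian;n_studies=8
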