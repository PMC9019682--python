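study_id,species,sex,repro_state,parameter,value,unit,n_birds,dispersion_type,dispersion_value,citation,provenance
tab5-len-duo,chicken,mixed,unknown,length_cm.duodenum,26.6,cm,,SEM,2.1,SM1,table=tab5;row=Length Chicken cm;col=Duodenum;n_studies=10
tab5-len-jej,chicken,mixed,unknown,length_cm.jejunum,59.3,cm,,SEM,6.0,SM1,table=tab5;row=Length Chicken cm;col=Jejunum;n_studies=9
tab5-len-ile,chicken,mixed,unknown,length_cm.ileum,42.7,cm,,SEM,4.6,SM1,table=tab5;row=Length Chicken cm;col=Ileum;n_studies=10
tab5-lenkg-duo,chicken,female,laying,length_cm_kg.duodenum,15.7,cm/kg,,,,ref17,table=tab5;row=Laying hen cm kg-1;col=Duodenum;n_studies=1
tab5-lenkg-jej,chicken,female,laying,length_cm_kg.jejunum,33.7,cm/kg,,,,ref17,table=tab5;row=Laying hen cm kg-1;col=Jejunum;n_studies=1
tab5-lenkg-ile,chicken,female,laying,length_cm_kg.ileum,33.9,cm/kg,,,,ref17,table=tab5;row=Laying hen cm kg-1;col=Ileum;n_studies=1
tab5-muc-duo,chicken,female,laying,mucosa_thickness_um.duodenum,2388,um,,,,ref80,table=tab5;row=Mucosa thickness um;col=Duodenum;n_studies=1
tab5-muc-jej,chicken,female,laying,mucosa_thickness_um.jejunum,1877,um,,,,ref80,table=tab5;row=Mucosa thickness um;col=Jejunum;n_studies=1
tab5-muc-ile,chicken,female,laying,mucosa_thickness_um.ileum,1111,um,,,,ref80,table=tab5;row=Mucosa thickness um;col=Ileum;n_studies=1
tab5-dna-duo,chicken,female,laying,mucosa_dna_mg_g.duodenum,3.23,mg/g,,,,ref36,table=tab5;row=DNA mg g-1;col=Duodenum;n_studies=1
tab5-dna-jej,chicken,female,laying,mucosa_dna_mg_g.jejunum,2.74,mg/g,,,,ref36,table=tab5;row=DNA mg g-1;col=Jejunum;n_studies=1
tab5-cells-duo,chicken,female,laying,mucosa_cells_per_g.duodenum,1.474e9,1/g,,,,2.19 pg DNA per cell,table=tab5;row=Cellularity # g-1;col=Duodenum;n_studies=1
tab5-cells-jej,chicken,female,laying,mucosa_cells_per_g.jejunum,1.251e9,1/g,,,,2.19 pg DNA per cell,table=tab5;row=Cellularity # g-1;col=Jejunum;n_studies=1
tab5-cmass-duo,chicken,female,laying,mucosa_cell_mass_ng.duodenum,0.678,ng,,,,reciprocal of cellularity,table=tab5;row=Cell mass ng or volume pl;col=Duodenum;n_studies=1
tab5-cmass-jej,chicken,female,laying,mucosa_cell_mass_ng.jejunum,0.799,ng,,,,reciprocal of cellularity,table=tab5;row=Cell mass ng or volume pl;col=Jejunum;n_studies=1
tab5-vh-duo,chicken,female,laying,villus_height_um.duodenum,1357,um,,SEM,109.9,SM1,table=tab5;row=Villus height um;col=Duodenum;n_studies=19
tab5-vh-jej,chicken,female,laying,villus_height_um.jejunum,960,um,,SEM,59.0,SM1,table=tab5;row=Villus height um;col=Jejunum;n_studies=23
tab5-vh-ile,chicken,female,laying,villus_height_um.ileum,721,um,,SEM,59.9,SM1,table=tab5;row=Villus height um;col=Ileum;n_studies=20
tab5-vw-duo,chicken,female,laying,villus_width_um.duodenum,276.8,um,,SEM,74.9,SM1,table=tab5;row=Villus width um;col=Duodenum;n_studies=8
tab5-vw-jej,chicken,female,laying,villus_width_um.jejunum,148.1,um,,SEM,21.2,SM1,table=tab5;row=Villus width um;col=Jejunum;n_studies=8
tab5-vw-ile,chicken,female,laying,villus_width_um.ileum,216.2,um,,SEM,59.3,SM1,table=tab5;row=Villus width um;col=Ileum;n_studies=7
tab5-vaf-duo,chicken,female,laying,vaf.duodenum,11.62,1,,,,authors' calculation,table=tab5;row=Villus amplification factor;col=Duodenum;n_studies=1;flag=stored_not_asserted
tab5-vaf-jej,chicken,female,laying,vaf.jejunum,9.04,1,,,,authors' calculation,table=tab5;row=Villus amplification factor;col=Jejunum;n_studies=1;flag=stored_not_asserted
tab5-vaf-ile,chicken,female,laying,vaf.ileum,7.93,1,,,,authors' calculation,table=tab5;row=Villus amplification factor;col=Ileum;n_studies=1;flag=stored_not_asserted
tab5-mvl-duo,chicken,mixed,unknown,microvillus_length_um.duodenum,1.463,um,,,,ref27,table=tab5;row=Microvillus length um;col=Duodenum;n_studies=1
tab5-mvl-jej,chicken,mixed,unknown,microvillus_length_um.jejunum,1.467,um,,,,ref27,table=tab5;row=Microvillus length um;col=Jejunum;n_studies=1
tab5-mvl-ile,chicken,mixed,unknown,microvillus_length_um.ileum,1.029,um,,,,ref27,table=tab5;row=Microvillus length um;col=Ileum;n_studies=1
tab5-mvd-duo,chicken,mixed,unknown,microvillus_diameter_um.duodenum,0.0705,um,,,,ref27,table=tab5;row=Microvillus diameter um;col=Duodenum;n_studies=1
tab5-mvd-jej,chicken,mixed,unknown,microvillus_diameter_um.jejunum,0.0705,um,,,,ref27,table=tab5;row=Microvillus diameter um;col=Jejunum;n_studies=1
tab5-mvd-ile,chicken,mixed,unknown,microvillus_diameter_um.ileum,0.0787,um,,,,ref27,table=tab5;row=Microvillus diameter um;col=Ileum;n_studies=1
tab5-mvden-duo,chicken,mixed,unknown,microvillus_density_per_um2.duodenum,113.0,1/um2,,,,ref27,table=tab5;row=Microvillus density # um-2;col=Duodenum;n_studies=1
tab5-mvden-jej,chicken,mixed,unknown,microvillus_density_per_um2.jejunum,76.8,1/um2,,,,ref27,table=tab5;row=Microvillus density # um-2;col=Jejunum;n_studies=1
tab5-mvden-ile,chicken,mixed,unknown,microvillus_density_per_um2.ileum,104.1,1/um2,,,,ref27,table=tab5;row=Microvillus density # um-2;col=Ileum;n_studies=1
tab5-maf-duo,chicken,mixed,unknown,maf.duodenum,37.6,1,,,,ref27 via MAF formula,table=tab5;row=Microvillus amplification factor;col=Duodenum;n_studies=1
tab5-maf-jej,chicken,mixed,unknown,maf.jejunum,38.8,1,,,,mean of ref26 35.9 and ref55 41.7,table=tab5;row=Microvillus amplification factor;col=Jejunum;n_studies=2
tab5-maf-ile,chicken,mixed,unknown,maf.ileum,27.5,1,,,,ref27 via MAF formula,table=tab5;row=Microvillus amplification factor;col=Ileum;n_studies=1
tab5-len-ceca,chicken,mixed,unknown,length_cm.ceca,28.1,cm,,SEM,3.9,SM1,table=tab5;row=Ceca length cm (Results text);n_studies=5
tab5-len-colon,chicken,mixed,unknown,length_cm.colon,9.48,cm,,SEM,0.72,SM1,table=tab5;row=Colon/rectum length cm (Results text);n_studies=5
tab5-mvl-ceca,chicken,mixed,unknown,microvillus_length_um.ceca,0.582,um,,,,ref27,table=tab5;row=Ceca microvillus length (Results text);n_studies=1
tab5-mvd-ceca,chicken,mixed,unknown,microvillus_diameter_um.ceca,0.089,um,,,,ref27,table=tab5;row=Ceca microvillus diameter (Results text);n_studies=1
tab5-mvden-ceca,chicken,mixed,unknown,microvillus_density_per_um2.ceca,89.9,1/um2,,,,ref27,table=tab5;row=Ceca microvillus density (Results text);n_studies=1
tab5-mvl-colon,chicken,mixed,unknown,microvillus_length_um.colon,0.597,um,,,,ref27,table=tab5;row=Colon microvillus length (Results text);n_studies=1
tab5-mvd-colon,chicken,mixed,unknown,microvillus_diameter_um.colon,0.079,um,,,,ref27,table=tab5;row=Colon microvillus diameter (Results text);n_studies=1
tab5-mvden-colon,chicken,mixed,unknown,microvillus_density_per_um2.colon,86.7,1/um2,,,,ref27,table=tab5;row=Colon microvillus density (Results text);n_studies=1
tab5-silen-broiler,chicken,mixed,broiler_juvenile,small_intestine_length_cm,131.8,cm,,SEM,22.3,SM1,table=tab5;row=Small intestine length broilers (Results text);n_studies=5
tab5-silen-lay,chicken,female,laying,small_intestine_length_cm,129.4,cm,,SEM,7.4,SM1,table=tab5;row=Small intestine length laying hens (Results text);n_studies=4
tab5-mal-silenkg,mallard,mixed,unknown,length_cm_kg.duodenum,17.1,cm/kg,,,,ref41,table=tab5;row=Mallard duodenum cm kg-1 (Results text);n_studies=1
tab5-mal-jejkg,mallard,mixed,unknown,length_cm_kg.jejunum,31.5,cm/kg,,,,ref41,table=tab5;row=Mallard jejunum cm kg-1 (Results text);n_studies=1
tab5-mal-ilekg,mallard,mixed,unknown,length_cm_kg.ileum,32.8,cm/kg,,,,ref41,table=tab5;row=Mallard ileum cm kg-1 (Results text);n_studies=1
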