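genotype,treatment,bio_rep,trait,value,unit
Misr2,control,1,grain_yield,771.119700,g/m2
Misr2,control,1,h2o2,2.132943,umol/g FW
Misr2,control,1,tss,24.589913,mg/g DW
Misr2,control,1,proline,2.104772,umol/g FW
Misr2,control,1,mda,10.061009,nmol/g FW
Misr2,control,1,chl_a,1.811915,mg/g FW
Misr2,control,1,chl_b,0.798433,mg/g FW
Misr2,control,1,carotenoids,0.497688,mg/g FW
Misr2,control,1,sod_activity,8.029101,U/mg protein
Misr2,control,1,pox_activity,5.063347,U/mg protein
Misr2,control,1,cat_activity,11.762622,U/mg protein
Misr2,control,1,peroxisome_abundance,993.542772,RFU
Misr2,control,2,grain_yield,793.082993,g/m2
Misr2,control,2,h2o2,1.805376,umol/g FW
Misr2,control,2,tss,24.999373,mg/g DW
Misr2,control,2,proline,1.951218,umol/g FW
Misr2,control,2,mda,10.088685,nmol/g FW
Misr2,control,2,chl_a,1.794730,mg/g FW
Misr2,control,2,chl_b,0.797064,mg/g FW
Misr2,control,2,carotenoids,0.496036,mg/g FW
Misr2,control,2,sod_activity,7.814046,U/mg protein
Misr2,control,2,pox_activity,4.863644,U/mg protein
Misr2,control,2,cat_activity,12.051570,U/mg protein
Misr2,control,2,peroxisome_abundance,990.271675,RFU
Misr2,control,3,grain_yield,806.904806,g/m2
Misr2,control,3,h2o2,1.897988,umol/g FW
Misr2,control,3,tss,25.320894,mg/g DW
Misr2,control,3,proline,2.064713,umol/g FW
Misr2,control,3,mda,10.391123,nmol/g FW
Misr2,control,3,chl_a,1.807977,mg/g FW
Misr2,control,3,chl_b,0.801508,mg/g FW
Misr2,control,3,carotenoids,0.498908,mg/g FW
Misr2,control,3,sod_activity,7.884176,U/mg protein
Misr2,control,3,pox_activity,5.028662,U/mg protein
Misr2,control,3,cat_activity,12.096219,U/mg protein
Misr2,control,3,peroxisome_abundance,993.247168,RFU
Misr2,stress,1,grain_yield,412.462380,g/m2
Misr2,stress,1,h2o2,4.551511,umol/g FW
Misr2,stress,1,tss,45.741791,mg/g DW
Misr2,stress,1,proline,5.920918,umol/g FW
Misr2,stress,1,mda,18.117465,nmol/g FW
Misr2,stress,1,chl_a,1.679321,mg/g FW
Misr2,stress,1,chl_b,0.738315,mg/g FW
Misr2,stress,1,carotenoids,0.459478,mg/g FW
Misr2,stress,1,sod_activity,14.110961,U/mg protein
Misr2,stress,1,pox_activity,9.580912,U/mg protein
Misr2,stress,1,cat_activity,18.117937,U/mg protein
Misr2,stress,1,peroxisome_abundance,1579.059383,RFU
Misr2,stress,2,grain_yield,399.672624,g/m2
Misr2,stress,2,h2o2,4.725936,umol/g FW
Misr2,stress,2,tss,44.227657,mg/g DW
Misr2,stress,2,proline,5.887149,umol/g FW
Misr2,stress,2,mda,18.658901,nmol/g FW
Misr2,stress,2,chl_a,1.687970,mg/g FW
Misr2,stress,2,chl_b,0.745944,mg/g FW
Misr2,stress,2,carotenoids,0.457967,mg/g FW
Misr2,stress,2,sod_activity,13.994048,U/mg protein
Misr2,stress,2,pox_activity,9.459491,U/mg protein
Misr2,stress,2,cat_activity,17.956174,U/mg protein
Misr2,stress,2,peroxisome_abundance,1640.058198,RFU
Misr2,stress,3,grain_yield,403.687043,g/m2
Misr2,stress,3,h2o2,4.547228,umol/g FW
Misr2,stress,3,tss,45.034454,mg/g DW
Misr2,stress,3,proline,6.009120,umol/g FW
Misr2,stress,3,mda,17.765157,nmol/g FW
Misr2,stress,3,chl_a,1.680072,mg/g FW
Misr2,stress,3,chl_b,0.740969,mg/g FW
Misr2,stress,3,carotenoids,0.464465,mg/g FW
Misr2,stress,3,sod_activity,13.995366,U/mg protein
Misr2,stress,3,pox_activity,9.416868,U/mg protein
Misr2,stress,3,cat_activity,18.451095,U/mg protein
Misr2,stress,3,peroxisome_abundance,1596.313974,RFU
Line4,control,1,grain_yield,613.134753,g/m2
Line4,control,1,h2o2,2.090576,umol/g FW
Line4,control,1,tss,23.900976,mg/g DW
Line4,control,1,proline,2.217180,umol/g FW
Line4,control,1,mda,11.586989,nmol/g FW
Line4,control,1,chl_a,1.774610,mg/g FW
Line4,control,1,chl_b,0.790653,mg/g FW
Line4,control,1,carotenoids,0.497509,mg/g FW
Line4,control,1,sod_activity,8.310805,U/mg protein
Line4,control,1,pox_activity,5.488375,U/mg protein
Line4,control,1,cat_activity,11.640365,U/mg protein
Line4,control,1,peroxisome_abundance,511.244988,RFU
Line4,control,2,grain_yield,632.503453,g/m2
Line4,control,2,h2o2,2.115696,umol/g FW
Line4,control,2,tss,23.268404,mg/g DW
Line4,control,2,proline,2.174626,umol/g FW
Line4,control,2,mda,11.600952,nmol/g FW
Line4,control,2,chl_a,1.796561,mg/g FW
Line4,control,2,chl_b,0.792245,mg/g FW
Line4,control,2,carotenoids,0.501093,mg/g FW
Line4,control,2,sod_activity,8.114769,U/mg protein
Line4,control,2,pox_activity,5.104616,U/mg protein
Line4,control,2,cat_activity,12.964100,U/mg protein
Line4,control,2,peroxisome_abundance,486.804580,RFU
Line4,control,3,grain_yield,641.605402,g/m2
Line4,control,3,h2o2,2.242118,umol/g FW
Line4,control,3,tss,23.527682,mg/g DW
Line4,control,3,proline,2.260834,umol/g FW
Line4,control,3,mda,10.344681,nmol/g FW
Line4,control,3,chl_a,1.786992,mg/g FW
Line4,control,3,chl_b,0.791937,mg/g FW
Line4,control,3,carotenoids,0.496437,mg/g FW
Line4,control,3,sod_activity,8.356734,U/mg protein
Line4,control,3,pox_activity,5.205725,U/mg protein
Line4,control,3,cat_activity,12.627895,U/mg protein
Line4,control,3,peroxisome_abundance,436.599736,RFU
Line4,stress,1,grain_yield,278.351280,g/m2
Line4,stress,1,h2o2,5.265125,umol/g FW
Line4,stress,1,tss,34.335707,mg/g DW
Line4,stress,1,proline,3.985644,umol/g FW
Line4,stress,1,mda,22.324748,nmol/g FW
Line4,stress,1,chl_a,1.632466,mg/g FW
Line4,stress,1,chl_b,0.714884,mg/g FW
Line4,stress,1,carotenoids,0.447205,mg/g FW
Line4,stress,1,sod_activity,8.907448,U/mg protein
Line4,stress,1,pox_activity,7.914595,U/mg protein
Line4,stress,1,cat_activity,16.969905,U/mg protein
Line4,stress,1,peroxisome_abundance,786.941834,RFU
Line4,stress,2,grain_yield,318.265942,g/m2
Line4,stress,2,h2o2,5.291452,umol/g FW
Line4,stress,2,tss,34.419054,mg/g DW
Line4,stress,2,proline,4.003358,umol/g FW
Line4,stress,2,mda,21.882594,nmol/g FW
Line4,stress,2,chl_a,1.632941,mg/g FW
Line4,stress,2,chl_b,0.719545,mg/g FW
Line4,stress,2,carotenoids,0.451439,mg/g FW
Line4,stress,2,sod_activity,8.948772,U/mg protein
Line4,stress,2,pox_activity,8.054988,U/mg protein
Line4,stress,2,cat_activity,17.282829,U/mg protein
Line4,stress,2,peroxisome_abundance,815.904084,RFU
Line4,stress,3,grain_yield,258.633966,g/m2
Line4,stress,3,h2o2,5.200677,umol/g FW
Line4,stress,3,tss,34.860421,mg/g DW
Line4,stress,3,proline,4.179977,umol/g FW
Line4,stress,3,mda,22.810526,nmol/g FW
Line4,stress,3,chl_a,1.625024,mg/g FW
Line4,stress,3,chl_b,0.714013,mg/g FW
Line4,stress,3,carotenoids,0.453641,mg/g FW
Line4,stress,3,sod_activity,9.107785,U/mg protein
Line4,stress,3,pox_activity,8.172919,U/mg protein
Line4,stress,3,cat_activity,17.364650,U/mg protein
Line4,stress,3,peroxisome_abundance,781.618630,RFU
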