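stratum,element,depth_m,stock_Pg,std_Pg,decimals
hyperarid,organic_C,0.3,11,1,0
hyperarid,organic_C,1.0,22,1,0
hyperarid,organic_C,2.0,31,1,0
hyperarid,inorganic_C,0.3,20,2,0
hyperarid,inorganic_C,1.0,65,3,0
hyperarid,inorganic_C,2.0,127,5,0
hyperarid,total_N,0.3,1.3,0.1,1
hyperarid,total_N,1.0,2.9,0.1,1
hyperarid,total_N,2.0,4.5,0.2,1
arid,organic_C,0.3,45,3,0
arid,organic_C,1.0,91,3,0
arid,organic_C,2.0,127,3,0
arid,inorganic_C,0.3,63,2,0
arid,inorganic_C,1.0,241,5,0
arid,inorganic_C,2.0,487,9,0
arid,total_N,0.3,4.9,0.2,1
arid,total_N,1.0,10.9,0.2,1
arid,total_N,2.0,17.3,0.3,1
semiarid,organic_C,0.3,100,2,0
semiarid,organic_C,1.0,190,3,0
semiarid,organic_C,2.0,259,3,0
semiarid,inorganic_C,0.3,48,2,0
semiarid,inorganic_C,1.0,207,4,0
semiarid,inorganic_C,2.0,456,7,0
semiarid,total_N,0.3,9.3,0.1,1
semiarid,total_N,1.0,19.6,0.2,1
semiarid,total_N,2.0,30.0,0.2,1
dry_subhumid,organic_C,0.3,91,3,0
dry_subhumid,organic_C,1.0,167,4,0
dry_subhumid,organic_C,2.0,228,6,0
dry_subhumid,inorganic_C,0.3,15,1,0
dry_subhumid,inorganic_C,1.0,66,2,0
dry_subhumid,inorganic_C,2.0,168,4,0
dry_subhumid,total_N,0.3,7.1,0.2,1
dry_subhumid,total_N,1.0,14.3,0.2,1
dry_subhumid,total_N,2.0,21.4,0.3,1
dry,organic_C,0.3,248,6,0
dry,organic_C,1.0,470,7,0
dry,organic_C,2.0,646,9,0
dry,inorganic_C,0.3,145,4,0
dry,inorganic_C,1.0,578,8,0
dry,inorganic_C,2.0,1237,15,0
dry,total_N,0.3,22.6,0.4,1
dry,total_N,1.0,47.7,0.5,1
dry,total_N,2.0,73.2,0.6,1
humid,organic_C,0.3,502,12,0
humid,organic_C,1.0,955,19,0
humid,organic_C,2.0,1401,36,0
humid,inorganic_C,0.3,28,3,0
humid,inorganic_C,1.0,107,5,0
humid,inorganic_C,2.0,321,9,0
humid,total_N,0.3,36.1,0.7,1
humid,total_N,1.0,72.6,1.1,1
humid,total_N,2.0,111.1,1.6,1
global,organic_C,0.3,750,15,0
global,organic_C,1.0,1425,21,0
global,organic_C,2.0,2047,39,0
global,inorganic_C,0.3,173,5,0
global,inorganic_C,1.0,686,10,0
global,inorganic_C,2.0,1558,19,0
global,total_N,0.3,58.6,0.8,1
global,total_N,1.0,120.4,1.3,1
global,total_N,2.0,184.2,1.9,1
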