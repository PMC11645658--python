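name,charge_class,pka_values,logp,fu_p,psa,mw,hbd,hba,observed_mp,observed_fum,transporters,hh_class,pub_year
labetalol,base,7.4,2.7,0.5,95.6,328.4,4,4,1.0,,,,1985
zolpidem,base,6.2,3.02,0.08,37.6,307.4,0,3,0.13,,,,1989
mirtazapine,base,7.7,2.9,0.15,19.4,265.4,0,3,0.76,,,,2007
propylthiouracil,acid,7.8,0.53,0.18,48.7,170.2,2,1,0.13,,,,1980
atenolol,base,9.6,0.16,0.95,84.6,266.3,3,4,2.9,,,,1983
caffeine,neutral,,-0.07,0.64,58.4,194.2,0,3,0.75,,,,1984
nitrofurantoin,acid,7.2,-0.47,0.4,118.0,238.2,1,6,6.2,,BCRP,,2005
metformin,base,12.4,-2.64,1.0,91.5,129.2,4,5,0.63,,OCT1;OCT3,,2005
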