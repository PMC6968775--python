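compound,genotype,dose_iv_mg_kg,dose_oral_mg_kg,auc_iv,auc_po_pv,auc_po_sys,cltot,vdss,t_half_iv,ka,fafg_pct,fh_pct,ba_pct
ciprofloxacin,WT,1.0,1.0,886,489,306,3.41,3.55,1.41,1.63,46.5,74.3,34.5
ciprofloxacin,BcrpKO,1.0,1.0,1200,564,365,2.51,4.36,1.75,1.85,50.6,59.9,30.3
ciprofloxacin,Mdr1a1bKO,1.0,1.0,1290,896,601,2.33,3.70,1.49,2.18,75.0,61.9,46.4
nitrofurantoin,WT,1.0,2.0,1840,2550,1840,2.28,1.94,2.87,5.80,63.7,78.3,49.9
nitrofurantoin,BcrpKO,1.0,2.0,1840,3410,2560,2.28,1.45,1.41,6.89,77.1,90.0,69.4
nitrofurantoin,Mdr1a1bKO,1.0,2.0,1950,3180,2350,2.15,1.36,1.17,7.20,75.2,79.9,60.0
topotecan,WT,1.0,1.0,994,577,370,2.20,2.59,1.26,2.33,56.8,65.6,37.3
topotecan,BcrpKO,1.0,1.0,1490,1510,1140,1.47,2.21,1.49,5.18,103,74.0,76.3
topotecan,Mdr1a1bKO,1.0,1.0,1020,589,358,2.13,2.19,1.08,3.68,63.8,54.8,34.9
sulfasalazine,WT,1.0,5.0,3820,2200,1940,0.66,0.59,1.95,1.40,16.9,60.1,10.2
sulfasalazine,BcrpKO,1.0,5.0,60500,290000,288000,0.04,0.19,3.57,0.49,130,73.2,95.2
sulfasalazine,Mdr1a1bKO,1.0,5.0,4280,2770,2450,0.59,0.45,1.63,0.93,20.6,55.6,11.5
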