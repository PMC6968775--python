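compound,ka_wt,ka_bcrp,ka_pgp,aq_bcrp,aq_pgp,fafg_wt,fafg_bcrp,fafg_pgp,r_bcrp,r_pgp
ciprofloxacin,1.63,1.85,2.18,0.09,0.19,0.47,0.51,0.75,0.05,0.36
nitrofurantoin,5.80,6.89,7.20,0.13,0.14,0.64,0.77,0.75,0.15,0.13
topotecan,3.18,5.18,3.68,0.35,0.08,0.57,1.03,0.64,0.42,0.06
sulfasalazine,1.40,0.49,0.93,,,0.16,1.30,0.30,0.79,0.09
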