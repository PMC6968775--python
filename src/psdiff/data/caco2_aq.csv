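compound,transporter,aq_in_vitro,r_in_vivo
ciprofloxacin,BCRP,0.03,0.05
ciprofloxacin,Pgp,0.13,0.36
nitrofurantoin,BCRP,0.37,0.15
nitrofurantoin,Pgp,0.09,0.13
topotecan,BCRP,0.61,0.42
topotecan,Pgp,0.14,0.06
sulfasalazine,BCRP,0.59,0.79
sulfasalazine,Pgp,0.05,0.09
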