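# psdiff

Portal–systemic blood-concentration-difference pharmacokinetics: estimating
how much of an oral drug dose reaches the portal blood, and how much of that
absorption is limited by the intestinal efflux transporters BCRP (Abcg2) and
P-gp (Mdr1a/1b).

## The problem

For an orally dosed drug, systemic plasma exposure confounds three serial
processes: intestinal absorption (Fa·Fg), hepatic first pass (Fh) and
systemic elimination. The portal–systemic (P-S) difference method separates
them by sampling blood from the portal vein *and* the systemic circulation
after an oral dose. Everything absorbed from the gut must transit the portal
vein, so the excess of portal over systemic exposure, scaled by portal blood
flow Q<sub>pv</sub> and the blood/plasma ratio R<sub>b</sub>, is a direct
mass balance for the absorbed amount:

```
FaFg = Qpv · Rb · (AUC_pv − AUC_sys) / Dose          (fraction of oral dose)
F    = (AUC_oral / AUC_iv) · (Dose_iv / Dose_oral)   (bioavailability)
Fh   = F / FaFg                                      (hepatic availability)
```

with Q<sub>pv</sub> in L/h/kg, AUCs in nmol·h/L and the dose converted to
nmol/kg via the molar mass of the dosed form.

Running the study in wild-type, Bcrp(−/−) and Mdr1a/1b(−/−) mice gives a
per-genotype triplet of FaFg (extent) and of the first-order absorption rate
constant k<sub>a</sub> (rate, from a Bateman fit with k<sub>e</sub> fixed
from the iv arm). The normalised knockout deltas score each transporter's
contribution — the **rate of contribution** R from FaFg and the in vivo
**absorptive quotient** AQ from k<sub>a</sub>:

```
R_bcrp = (FaFg_bcrp − FaFg_wt) / [FaFg_wt + (FaFg_bcrp − FaFg_wt) + (FaFg_pgp − FaFg_wt)]
```

and analogously for P-gp and for AQ. Scores ≥ 0.4 on both the in vitro
(Caco-2 AQ) and in vivo (R) axes classify a compound–transporter pair as a
concordant true positive; the packaged reference tables for ciprofloxacin,
nitrofurantoin, topotecan and sulfasalazine all fall on the concordant
diagonal.

The package provides: per-profile non-compartmental analysis (λz, t½,
AUC/AUMC to infinity, MRT, CL<sub>tot</sub>, V<sub>dss</sub>, MAT), the P-S
difference estimators, the Bateman k<sub>a</sub> fit, the AQ/R scoring and
quadrant classification, a closed-form recirculatory simulator with known
ground truth for parameter-recovery testing, and a CLI.

## Worked example

```python
import psdiff

# Published topotecan FaFg triplet: WT 0.57, Bcrp(-/-) 1.03, Mdr1a/1b(-/-) 0.64
trip = psdiff.GenotypeTriplet(0.57, 1.03, 0.64)
res = psdiff.r_contribution(trip)
print(f"R_bcrp = {res.r_bcrp:.2f}, R_pgp = {res.r_pgp:.2f}")

# Wild-type FaFg from the portal/systemic AUCs (577 vs 370 nmol·h/L),
# 1 mg/kg dosed as the HCl salt (MW 457.9), Rb 0.94, Qpv 106.6 mL/min/kg
dose = psdiff.dose_to_nmol_per_kg(1.0, 457.9)
fafg = psdiff.fafg(577, 370, rb=0.94, qpv=106.6, dose_oral_nmol_per_kg=dose)
print(f"FaFg = {fafg:.1%}")
print(psdiff.classify_quadrant(0.61, res.r_bcrp))   # in vitro AQ_bcrp = 0.61
```

prints

```
R_bcrp = 0.42, R_pgp = 0.06
FaFg = 57.0%
Quadrant.T_pos
```

i.e. BCRP knockout accounts for 42% of topotecan's unrestricted absorption
while P-gp contributes 6%; 57% of the oral dose reaches the portal blood in
wild-type mice; and the in vitro Caco-2 score agrees with the in vivo call
(true positive at the 0.4 criterion).

The full pipeline runs from a study table. `PSDifferenceModel` is built
from a long-format concentration–time CSV plus compound constants, and
`fit()` returns a results object with the NCA, absorption and contribution
tables, `summary()`, quadrant classification and plotting:

```python
model = psdiff.PSDifferenceModel.from_csv("study.csv", compounds)
results = model.fit()
print(results.summary())
```

Equivalent CLI (here simulating a noise-free study first):

```sh
psdiff simulate --out demo --seed 7 --cv 0.0
psdiff report demo/simulated_study.csv --config demo.yaml --out demo
```

which recovers the simulated ground truth (WT FaFg 50%, Bcrp-KO 100%,
Mdr1a/1b-KO 60%, ka 2.0/h) and reports R_bcrp = 0.45, R_pgp = 0.09.

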