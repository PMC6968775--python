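# Methods

## Model and assumptions

The portal–systemic (P-S) difference method rests on a single mass balance:
in a recirculatory system every molecule absorbed from the gut lumen passes
the portal vein exactly once, so the cumulative absorbed amount per kg is

    A = Qpv · Rb · ∫₀^∞ (C_pv(t) − C_sys(t)) dt ,

where C_pv and C_sys are portal and systemic *plasma* concentrations,
R_b (blood/plasma concentration ratio) converts them to blood, and Q_pv is
portal blood flow. Dividing by the molar oral dose gives the apparent
fraction absorbed into the portal blood, FaFg. The method cannot separate
Fa (fraction crossing the apical membrane) from Fg (gut-wall availability);
only their product is identified. Bioavailability F is the dose-normalised
systemic exposure ratio oral/iv, and hepatic availability is defined as
Fh = F / FaFg, so F = FaFg·Fh holds exactly by construction.

Assumptions: linear pharmacokinetics over the dose range; Q_pv and R_b
constant over the sampling window and across genotypes; portal sampling
does not perturb flow; elimination parameters shared between the oral and
iv occasions of one genotype.

## Pipeline stages

1. **NCA** (`psdiff.nca`). The terminal elimination rate constant λz is the
   negative slope of ln C vs t over the last `n_terminal` (default 3)
   positive-concentration points; the window shrinks toward 2 points if the
   tail contains values ≤ 0, and a non-negative slope is an estimation
   error, not a number. t½ = ln2/λz. AUC/AUMC use the linear trapezoid over
   observed points — C(0) = 0 after oral dosing, C(0) = C0 (exp of the
   intercept of a log-linear fit through the first two points) after iv —
   plus tails C_last/λz and C_last·t_last/λz + C_last/λz². A log-linear
   trapezoid variant exists but is off by default. CLtot = Dose/AUC_iv and
   Vdss = (AUMC_iv/AUC_iv)·CLtot on iv arms; MRT = AUMC/AUC and
   MAT = MRT_oral − MRT_iv (the standard moment identities; a negative MAT
   is flagged, never clamped). Concentrations at or below a configurable
   LLOQ can be censored before analysis; the default keeps everything.

2. **FaFg / F / Fh** (`psdiff.absorption`). Fractions are held on the 0–1
   scale internally and rendered as percent only in reports. FaFg > 1 is
   reported as computed with a `supra_unity` flag (near-complete absorbers
   legitimately print above 100% from sparse-AUC noise); AUC_pv < AUC_sys
   yields a negative value with a `nonphysical` flag so batch runs surface
   arm mix-ups instead of crashing. Doses are converted mg/kg → nmol/kg via
   the molar mass of the **dosed form** (e.g. topotecan hydrochloride,
   457.9 g/mol): dose and AUC must share a molar scale for Eq. dimensions
   to close, and only the dosed-form mass reproduces the published
   clearance and FaFg anchors.

3. **ka fit** (`psdiff.kafit`). One-compartment first-order absorption, no
   lag. The oral systemic curve is fitted with the Bateman function with
   k_e *fixed* to the same genotype's iv terminal slope — fixing k_e
   resolves the flip-flop ambiguity (k_a and k_e are exchangeable on a
   single oral curve). Free parameters are k_a ∈ [10⁻³, 10³] h⁻¹ and the
   scale S = F·D/V. Weighting is uniform by default; 1/Ĉ ("inverse_pred")
   is available for assay error proportional to concentration. Multistart
   from k_a⁰ ∈ {1/Tmax, 3/Tmax, 10·k_e}, deterministic order, best SSE
   wins, ties to the smaller k_a. The k_a = k_e degeneracy is handled by an
   expm1-based form continuous through the limit. A profile that rises to
   its last sample has no identifiable absorption phase and raises; a fit
   ending on a bound is flagged.

4. **Contribution scores** (`psdiff.contribution`). For a readout x
   measured in wild-type and the two single-knockout genotypes, with
   Δb = x_bcrp − x_wt, Δp = x_pgp − x_wt and D = x_wt + Δb + Δp, the scores
   are Δb/D and Δp/D (AQ when x = k_a, R when x = FaFg). When both deltas
   are ≥ 0, the scores lie in [0,1] and satisfy
   score_b + score_p + x_wt/D = 1 — D estimates the readout with both
   efflux barriers removed, and the three terms partition it. A negative
   delta breaks the partition; the raw quotient is still reported together
   with `not_estimable` and `negative_delta_*` flags (sulfasalazine's k_a
   triplet is the published example). The in vitro/in vivo quadrant
   criterion is **closed** at 0.4 (≥ counts as transporter-limited on both
   axes); the source material uses "more than" and "above" interchangeably,
   so one boundary convention had to be declared, and it is tested.

## The simulator and what it does (not) emulate

`psdiff.simulate` draws from a closed-form recirculatory model:
one-compartment disposition (V, k_e), iv bolus C_sys = D/V·e^(−ke·t) with
portal ≡ systemic; oral absorption input Ra(t) = FaFg·D·k_a·e^(−ka·t), a
Bateman systemic curve scaled by Fh, and portal excess modelled as
instantaneous flow dilution C_pv = C_sys + Ra/(Qpv·Rb). That last choice —
no explicit portal mixing compartment — makes the defining mass balance
Qpv·Rb·∫(C_pv−C_sys) = FaFg·D hold *analytically*, so the FaFg estimator
has an exact oracle and any pipeline error is attributable to quadrature
and regression, not to the generator. Noise is multiplicative lognormal,
C_obs = C·exp(ε), ε ~ N(0, √ln(1+CV²)), independent per sample; one integer
seed drives deterministic per-(genotype, route, site, animal) substreams.

Default study conditions: the sparse 7-point schedule 0.083–8 h, 2 animals
per arm, three genotype arms with FaFg 0.5 (WT), 1.0 (Bcrp-KO), 0.6
(P-gp-KO) and mildly reduced knockout clearance; k_a 2 h⁻¹, k_e 0.5 h⁻¹,
V 2.5 L/kg, Fh 0.7, R_b 1.0, Q_pv 106.6 mL/min/kg, CV 10% (no noise
magnitude is published; 10% is this package's declared assay-like default
and is swept in tests).

Not emulated: enterohepatic recirculation, colonic bacterial degradation
(relevant to sulfasalazine in vivo), inter-animal random effects beyond
residual noise, LLOQ censoring by default (available as an option), or an
explicit portal compartment. Passing recovery tests therefore demonstrate
estimator correctness under the stated model, not robustness to those
real-data features.

## Numerical choices

- Linear trapezoid by default (log-trapezoid opt-in). On the sparse
  schedule the convex-decay overestimate of the trapezoid is a few percent
  and is inherent to sparse NCA, not a defect; oracle tests use dense grids
  where the error is quadratic in the step.
- Dense oracle grids include t = 0: the portal curve steps to its maximum
  at 0⁺, and a grid starting later with an assumed zero origin loses
  ≈ k_a·h/2 of the absorbed dose in the first interval.
- The terminal-slope no-decay test uses a −10⁻¹⁰ slope tolerance so
  exactly-flat profiles are rejected despite float jitter.
- λz r² is reported but never used as an automatic acceptance gate: a
  7-point schedule leaves no room for terminal-window model selection.
- Replicates at a time point are arithmetically averaged before analysis
  (arm-mean profiles, as sparse destructive-sampling designs report).
- Study CSVs are re-read with round-trip float parsing so write/read
  preserves every (time, concentration) pair bit-exactly.

## Problem sizes used by the test and acceptance suites

Published-table regressions are desk-scale (triplet algebra, single AUC
expressions). Recovery suites use: noiseless dense grids (Δt = 0.05 h,
0–24 h) for the ≤2% FaFg / ≤10⁻⁴ k_a checks, and 200 seeded replicates of
the full sparse-schedule study at CV 10% for the median-bias (<5%) check;
the whole suite runs in well under a minute on one core.

## Known limitations

- Fa and Fg are not separately estimable; no intestinal-segment resolution.
- AQ/R are point scores; no uncertainty propagation is attempted (the
  source tables publish point values only, n = 2–3 animals).
- The published per-arm tables are internally inconsistent in two cells
  (topotecan WT k_a printed as 2.33 in the per-arm table vs 3.18 in the
  triplet summary; AQ_pgp cells not reproducible from the rounded printed
  k_a): the packaged fixtures carry each table verbatim and the regression
  tolerances (±0.01 on scores) absorb input rounding, but those specific
  cells are anchored to the triplet-summary values.
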