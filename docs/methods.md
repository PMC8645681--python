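# Methods

## Scope and model structure

The package simulates the plasma pharmacokinetics of apatinib in virtual
adults and the change in its exposure under co-medication (DDI) and under
hepatic or renal impairment (DDZI).  One subject is a system of 40 ODE
states: 18 gut-lumen states (solid and dissolved drug in nine segments),
12 perfusion-limited tissue amounts, venous and arterial blood, four
cumulative elimination ledgers (hepatic metabolism, gut-wall metabolism,
renal excretion, fecal loss) and four enzyme-turnover states (hepatic
CYP3A4/3A5/2D6 and enterocyte CYP3A4).  All drug states are amounts in mg,
so every flux is conservative and the mass balance
`dose = Σ amounts + Σ ledgers` is checked on the reporting grid of every
simulation (it closes to well below 0.1%).

Assumptions worth stating explicitly:

* all tissues are perfusion-limited; no transporters, no lymphatics;
* blood:plasma ratio, fu, log P, pKa and microsomal Vmax/Km are consumed as
  inputs, not predicted; no intersystem (ISEF-like) scalar is applied to
  the microsomal rates, which are treated as HLM-derived;
* the perpetrator is an analytic one-compartment oral forcing function
  (superposition over its dosing calendar); its unbound plasma
  concentration drives hepatic and gut interactions alike, i.e. no separate
  enterocyte inhibitor concentration is modelled;
* the victim's unbound liver concentration uses the fu/Kp convention
  `Cu = C_liver · fu / Kp_liver`, equivalent at equilibrium to the unbound
  plasma concentration of the well-stirred model;
* itraconazole's inhibitory metabolite is ignored; perpetrator
  auto-induction is ignored;
* fasted-state physiology only; single-dose victim regimens (the multiple-
  dose DDZI case is deliberately out of scope).

## Absorption model

Nine segments (stomach, duodenum, jejunum ×2, ileum ×3, caecum, colon) with
first-order transit.  Both solid and dissolved drug transit; dissolution is
Noyes–Whitney-like, `rate = k_d · M_solid · (1 − C/S)`, first order in the
remaining solid (surface ∝ mass for a polydisperse powder) and linear in
the saturation driving force.  The rate is signed: a supersaturated segment
re-precipitates onto the transiting solid, which is how drug dissolved in
the acidic stomach (solubility capped at 2 mg/mL for the mesylate) is
handled when it reaches neutral intestine.  Segment solubility follows the
diprotic-base relation `S(pH) = S0/f_neutral(pH)` with
`f_neutral = 1/(1 + 10^(pKa1−pH) + 10^(pKa1+pKa2−2pH))`.

Uptake is `ka = 2 Peff / R` per segment, with Peff from the single-point
Caco-2 anchor (factor 0.80e-4/6.81e-6, chosen so the measured pair maps
exactly).  The caecum and colon absorb at 5% and 2% of the small-intestinal
permeability: apatinib's carrier-free colonic absorption is taken as
negligible, which concentrates absorption into the ~3 h small-intestinal
window and reproduces the early observed Tmax.  Absorbed flux passes a
gut-wall extraction step `Eg = CLg/(Qgut + CLg)` with `Qgut` = 18 L/h and a
baseline enterocyte CYP3A4 CLint of 6 L/h (baseline Fg = 0.75), the lever
through which CYP3A4 DDIs act on first pass.

The dissolution/solubility surface (`S0` = 0.050 mg/mL free base,
`k_d` = 0.15 h⁻¹, the luminal fluid volumes and effective radii in
`gut.yaml`) is an explicit calibration surface: it was fitted once so that
the simulated healthy-volunteer exposures land within the acceptance band
at both dose levels and the 750/250 mg AUC ratio is sub-proportional
(≈2, below the dose ratio 3), as observed.  A purely linear absorption
model cannot produce that sub-proportionality; partial saturation of the
luminal solubility at 750 mg is the assumed mechanism.  Users with a
measured dissolution profile can replace the mechanistic surrogate by
editing these parameters.

## Distribution

Kp values come from the original tissue-composition (neutral lipid /
phospholipid / water) formulation with P = 10^logP, the vegetable-oil
surrogate `log Pvo:w = 1.115 logP − 1.35` for adipose, the 0.5-dilution
relation for tissue binding, and the reported uniform Kp scalar 0.7.  The
composition table is a packaged fixture of literature-typical human values.
Vss sums plasma, erythrocyte (from B:P and hematocrit) and Kp-weighted
tissue volumes; with the packaged mean physiology it evaluates to
≈2.62 L/kg against the reported 2.684 L/kg (within the ±25% the method can
be expected to deliver given compositional differences between sources).

## Elimination and interactions

Organ Vmax (mg/h) = Vmax[pmol/min/mg] × MPPGL × liver weight × abundance
scalar × 60 × MW × 1e-12.  With MPPGL 45 mg/g and a 1.70 L liver the summed
unbound intrinsic clearance is ≈128 L/h, giving a hepatic clearance of
≈8.7 L/h (extraction ratio ≈0.11) plus ≈0.5 L/h renal filtration — a
low-extraction compound whose oral AUC is controlled by fu·CLint, as the
impairment results require.  Enzyme turnover uses k_deg = 0.0193 h⁻¹ for
hepatic CYP3A4/3A5, 0.0136 h⁻¹ for CYP2D6 and 0.029 h⁻¹ for gut CYP3A4.

Perpetrator files package one-compartment PK (ka, V/F, CL/F, fu) and
unbound-referenced interaction constants.  Mechanism assignment follows the
pathway labels of the simulated designs: itraconazole, fluvoxamine and
quinidine competitive; erythromycin, verapamil and paroxetine
mechanism-based inactivators; rifampin, carbamazepine, efavirenz and
phenytoin inducers (rifampin also weakly competitive).  None of these
constants is reported with the victim data, so they are the second declared
calibration surface: starting from literature-typical values, each drug's
constants were adjusted once so that the paired-trial AUC ratios reproduce
the reference interaction magnitudes (the packaged 10x10 trials yield
itraconazole ≈2.6, rifampin ≈0.31, erythromycin ≈3.3, verapamil ≈2.0,
paroxetine ≈1.26, quinidine ≈1.15, fluvoxamine ≈1.0, carbamazepine ≈0.32,
efavirenz ≈0.39, phenytoin ≈0.33).  They should be read as effective,
model-consistent values, not as independent in vitro measurements.

## Virtual populations

The healthy Chinese adult mean (61 kg, cardiac output 330 L/h, GFR
110 mL/min, organ volumes and flow fractions in
`physiology_healthy_chinese.yaml`) is perturbed per subject by
mean-preserving log-normal draws: CV 30% for clearance-related parameters
(MPPGL, enzyme abundances, enterocyte CYP3A4), 20% for volumes, flows and
GFR, 15% for body size, 5% for hematocrit.  The reference study does not
report its variability model; these defaults are field-typical and fully
configurable.  After sampling, organ flows are renormalised so their sum
equals cardiac output exactly.  Sampling is deterministic in
(seed, subject index), so a trial is a pure function of its configuration.

Disease stages are multiplier overlays applied after sampling
(`impairment.yaml`): Child–Pugh A/B/C progressively reduce liver volume
(0.94/0.82/0.70), hepatic CYP3A4 abundance (0.88/0.42/0.28, with milder
CYP3A5/2D6 reductions), enterocyte CYP3A4, serum albumin (fu is rescaled as
`fu' = 1/(1 + a(1−fu)/fu)`), hematocrit and portal flow; renal stages set
absolute GFR (45 / 20 mL/min), reduce albumin, and apply the modest hepatic
CYP3A4 reduction reported in uremia (0.93 / 0.85).  These multipliers are
literature-shaped but, like the perpetrator constants, were finalised
against the reference exposure ratios (the packaged 10x10 trials yield
Child–Pugh B ≈2.1, C ≈2.8, renal stages ≈1.0) and are judged at the
0.5–2.0 fold level, not per parameter.

What the generator deliberately does not emulate: age/sex covariate
structure, genotype-resolved CYP2D6/3A5 phenotypes, correlated organ sizes,
portal-systemic shunting, or disease-altered gastric emptying.  Passing
population tests therefore demonstrate correctness of the sampling and
scaling machinery under the stated variability model, not faithfulness to
any particular clinical population's dispersion.

## Trial designs and statistics

DDI trials are paired: the same seeded subjects are simulated with and
without the perpetrator, mirroring the crossover clinical designs and
removing sampling noise from the ratios.  The control arm doses the victim
at t = 0; the treatment arm follows the design calendar (e.g. erythromycin
250 mg qid days 1–6 with apatinib 750 mg on day 4; inducers days 1–10 with
apatinib on day 8; rifampin verification with apatinib on day 6).  Before
the first victim dose only the four enzyme states are integrated (the drug
states are identically zero), which keeps multi-day pretreatment cheap.
DDZI trials compare an impaired population with healthy controls sampled
from matched seeds.  Reported ratios are ratios of arithmetic means across
all 100 subjects (means of per-subject ratios are also emitted; for these
paired designs the two conventions differ by well under 1%).

Exposures are Cmax, Tmax (earliest time of the maximum on the grid) and
AUC0–96h by linear trapezoid on the 0.1 h reporting grid, with no
extrapolated tail.  Study size follows the simulated designs: 10 trials ×
10 subjects per arm.

## Numerics

LSODA with rtol 1e-6 and atol 1e-9 mg; halving the tolerances moves AUC by
<0.1%.  Oral doses are instantaneous stomach-solid additions at dose times;
integration is segmented at every dose event.  Dissolution uses
`max(amount, 0)` guards so transient integrator undershoot cannot feed back
as negative mass, and a state more negative than 1e-6 mg raises an error.
Tie-break: Tmax is the earliest grid time attaining the maximum.  Degenerate
inputs (zero dose, zero permeability, inert perpetrators) are exercised in
the test suite and produce the obvious limits exactly.

## Limitations

* The Caco-2→Peff regression, in vitro dissolution profile, perpetrator
  compound files and disease physiology of the original commercial platform
  are not public; the corresponding fixtures here are open re-derivations
  calibrated at the stated endpoints, so per-parameter agreement with that
  platform is not claimed anywhere.
* The simulated Cmax sits on the low side of its acceptance band while AUC
  sits on the high side: with the reported Vss and microsomal clearance the
  model's terminal decline is slower than observed, a structural trade-off
  documented rather than hidden by inflating clearance beyond defensible
  scaling values.
* Kp values are computed once from healthy plasma binding; disease-altered
  binding affects unbound liver concentration and renal filtration but not
  the Kp map itself.
* Apatinib as a perpetrator (on nifedipine, warfarin, gefitinib) is out of
  scope, as are transporter DDIs and multiple-dose disease simulations.
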