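# Methods

## The model

`nanomsc_pkpd` implements a mechanism-based PK–PD model for tumor-targeted
delivery of paclitaxel (PTX) by nano-engineered mesenchymal stem cells
(nano-MSCs) in an orthotopic mouse lung-tumor model. The drug exists in
three physical forms — free PTX, PTX encapsulated in PLGA nanoparticles
(NPs), and PTX inside MSCs — and each form is a parallel three-compartment
"layer" (central / tumor / peripheral, amounts in ng PTX-equivalent).

Small-molecule layers (free PTX and NPs) exchange with the tumor through
two parallel Krogh-cylinder routes with a common driving force
`(C_central·E − C_tumor)`:

* vascular exchange, conductance `2·P·R_cap/R_Krogh²·VT` (permeation across
  the capillary endothelium), and
* surface exchange, conductance `6·D/R_tumor²·VT` (diffusion across the
  tumor surface),

plus ordinary central–peripheral distribution (`CLD`) and linear
elimination from the central compartment (`CL`). The cell layer moves by
two unidirectional extravasation processes out of its central compartment
(`K_ct` to tumor, `K_cp` to peripheral) and has no volumes in its
differential equations. The layers are connected by first-order transfer:
drug release `K_rel` (NP→free and MSC→free, the same constant — release
from the internalized NPs is rate-limiting) and exocytosis `K_exo`
(MSC→NP, on a PTX-mass basis after scaling by the drug loading,
0.148 mg PTX/mg NP).

Tumor growth is exponential with per-arm rate `Kg0` on the bioluminescence
scale TV (1e6 photon/s), opposed by three kill terms driven by tumor-site
concentrations: Emax kills for free PTX and NP-bound PTX (`Kmax`, `IC50`)
and a linear, unsaturable kill for the MSC form (`K_MSC`):

    dTV/dt = [Kg0 − Kmax_PTX·C_P/(IC50_PTX+C_P)
                  − Kmax_NP·C_N/(IC50_NP+C_N) − K_MSC·C_M] · TV

During PD integration the tumor geometry is dynamic: `VT = a·TV^b`
(power-law bioluminescence→volume calibration; always positive) and
`R_tumor = (3·VT/4π)^{1/3}` (sphere), re-evaluated at every right-hand-side
call; during PK fitting and disposition simulation a static `VT = 0.3 mL`
is used. A configurable floor `TV ≥ 1e-6` guards the power map near zero
burden.

Observation model (the source tables list no explicit one; this is the only
scaling consistent with the parameter set): measured plasma PTX is
`f_u·A_central/V_central` summed over the small-molecule layers present in
an arm plus `A_MSCcentral/V_MSCcentral` for the cell layer (which has no
plasma-to-blood ratio); measured lung PTX is the total tumor-compartment
amount over `VT`.

## Parameters

The canonical set (`paper_2021()`) carries the published estimates and
literature constants, in the units used throughout: clearances mL/h,
volumes mL, rate constants 1/h, permeability cm/h, diffusivity cm²/h,
concentrations ng/mL, burden 1e6 photon/s, time h. Highlights:

| symbol | value | meaning |
|---|---|---|
| CL_PTX / CL_NP | 0.909 / 0.241 mL/h | clearances of free and NP-bound PTX |
| P_PTX, D_PTX, E_PTX | 0.0875, 0.01, 0.44 | free-drug tumor-exchange constants (literature, fixed) |
| K_rel | 0.0085 /h | drug release (fit to in-vitro release data) |
| K_exo | 0.081 /h | exocytosis, PTX-mass basis (0.56 /h NP-mass × 0.148 loading, then profiled) |
| K_ct, K_cp | 1.45, 10.2 /h | MSC extravasation (plasma half-life ≈ 3.5 min) |
| Kg0 (control) | 0.00339 /h | exponential growth, ~8.5 days doubling |
| eta_TVBL | 0.964 | log-scale SD of the baseline random effect |
| sigma (PK/PD) | 0.49–1.16 | proportional residual CVs per tissue/arm |

Body weight defaults to 0.02 kg (implied by the 5 µg ≡ 0.25 mg/kg dose
equivalence) and is configuration-overridable; 1e6 MSCs carry 25 µg PTX.

### Bioluminescence calibration

The calibration coefficients of `VT = a·TV^b` were never published; only
the fitting procedure (log–log least squares on n = 8
bioluminescence/tumor-weight pairs at 1 g/mL) is reproducible. The package
default, chosen once, is `a = 0.3, b = 0.3`. Rationale: the dynamic
geometry creates positive feedback (kill shrinks TV → shrinks VT → raises
tumor concentrations → more kill), so the calibration scale decides whether
the standard nano-MSC regimen eradicates the tumor or merely slows it. The
published simulations show net growth under the standard regimen, complete
remission only at the 2×10⁶-cell maintenance dose, a strong `K_exo` effect
and a weak `K_rel` effect; `a = 0.3, b = 0.3` reproduces exactly this
regime while giving physically plausible sizes (baseline tumors ≈ 0.19 mL,
end-stage ≈ 1 g, and the static-PK volume 0.3 mL corresponding to an
early-study burden TV = 1). No quantitative target was tuned — none exists
for these scans.

## Synthetic studies (the stated world)

* **PK study** — destructive sampling: 3 arms (solution / NP / nano-MSC,
  single 5000 ng IV bolus into the arm's top layer) × times {2, 24, 48,
  120, 288} h × 3 mice × {plasma, lung}; proportional error with the
  published per-tissue, per-arm CVs; every record a distinct subject;
  records at or below the quantification limit (default 0) are excluded,
  as in the source data.
* **PD study** — 4 arms × 8 animals, twice-weekly imaging over 63 days
  (0–1512 h, 84 h spacing); log-normal baseline `TVBL·e^η`,
  `η ~ N(0, ω²)`; regimens: none (control), 40 mg/kg on days 0/4/8
  (solution and NP arms), 1e6 MSCs on day 0 + 0.5e6 every 14 d (nano-MSC).
  Dropout is deterministic given the latent trajectory: an animal is
  observed up to and including the first scheduled time its latent burden
  exceeds the threshold (default 100×1e6 photon/s ≈ where untreated
  burdens plateau by death) and never afterwards. The generator returns
  both the observable table and the latent truth.
* **In-vitro** — cumulative release `100·(1−e^{−K_rel·t})` at
  {4, 24, 72, 168, 336} h and NP retention `100·e^{−K_exo·t}` at 0.5–24 h,
  10% proportional noise; calibration pairs with log-normal (σ = 0.2)
  noise, TV log-uniform on [0.5, 200].

What a green test does *not* establish: the generators share the fitted
model's structural assumptions (exponential growth, baseline-only BSV,
proportional normal error, first-order release). Recovery tests therefore
validate the estimation machinery, not the model's adequacy for real data;
real bioluminescence noise is heavier-tailed and dropout is not a clean
threshold rule.

## Estimation

* **PK layers** ("layer by layer"): naive-pooled maximum likelihood — with
  one sample per animal there are no between-subject effects and the
  first-order method reduces to exact ML. Each layer's structural
  parameters and two residual CVs are estimated on log scale (L-BFGS-B,
  5 jittered starts, Nelder–Mead polish); literature constants and all
  lower-layer estimates stay fixed, and the result records which and why.
  The static-geometry system is linear, so predictions are exact matrix
  exponentials.
* **PD**: all four arms jointly, one log-normal random effect on baseline,
  Laplace-approximate marginal likelihood. Censoring follows the modified
  M3 rule: the per-animal maximum observation becomes that animal's upper
  limit (the maximum itself stays continuous — it was observed; ties at
  the limit likewise); scheduled-but-missing times after the last
  observation enter as categorical records with probability
  `1 − Φ((UL − f)/(σ·f))`.
* **Uncertainty**: covariance from a central-difference Hessian of the OFV
  on log parameters (RSE% = 100·SE(log θ) by the delta method; indefinite
  directions yield per-parameter NaNs, not failure), and
  sampling-importance-resampling CIs (multivariate normal proposal at the
  estimates, covariance inflated ×1.5, single iteration, weighted
  resampling without replacement via Gumbel top-k; resample well below the
  proposal count or the tails under-disperse).

### Numerical scheme for the PD likelihood

The coupled system is stiff (the free-PTX tumor compartment equilibrates on
a ~2e-3 h timescale against a ~300 h growth timescale), so trajectories use
LSODA (or an L-stable TR-BDF2 with analytic Jacobian, compiled, validated
against LSODA in the tests). The burden is integrated as log TV, which
keeps near-remission trajectories smooth instead of hitting sign
constraints. Tolerances: rtol 1e-8/atol 1e-10 for simulation and data
generation, rtol 1e-6/atol 1e-5 inside estimation (trajectory error ~1e-4,
three orders below the residual noise).

Evaluating the marginal likelihood naively requires one ODE solve per
(parameter, animal, random-effect) triple. Two structural facts make it
cheap: (i) animals within an arm share dynamics and differ only in their
baseline, so per arm the log-trajectory is precomputed on a monotone-cubic
(PCHIP) interpolation grid in log TV0, refined adaptively where adjacent
node trajectories differ by more than 1.1 log units (treated arms have a
remission separatrix — small baselines eradicate, large ones grow — and
the map is steep there); (ii) the per-animal inner optimization over the
scalar random effect is then interpolation-only (vectorized grid scan +
ternary search to 1e-2, Laplace curvature by central differences at
5e-3 — both steps must stay deterministic or the outer line searches see a
noisy objective). The control arm is analytic throughout. Validation:
surface and direct-ODE likelihoods agree to well under 1 OFV unit at
realistic parameters, and the Laplace OFV is checked against 64-node
adaptive Gauss–Hermite quadrature.

The outer optimization is block coordinate descent: baselines, error terms
and the control growth rate never invalidate the trajectory surfaces
(cache hits only), while the treated-arm growth rates and kill
coefficients force re-solves and run in short, evaluation-capped rounds.
Variables are rescaled so a quasi-Newton unit step is a ~5% parameter
change (otherwise the first line search jumps into the infeasible barrier),
and finite-difference steps (1e-4 log units) sit well above the ODE-solver
noise floor. Parameters of arms absent from a data set are left at their
starting values. Residual CVs are bounded below at 1e-3.

## Design decisions and open points, resolved

* `V_MSCperipheral` appears in no differential equation; it is carried in
  the parameter set and reports but never used (flagged as such).
* "Free PTX dominates the lung" is read as exceeding *each* other form,
  not their sum; the crossover is located by bisection on the exact linear
  solution between bracketing grid points (spacing ≤ 0.5 h).
* Scenario summaries show between-subject variability only (no residual
  error), matching the published simulation protocol; a flag adds residual
  error for predictive-check use.
* pcVPC bins are the nominal sampling times (fixed schedule; no data-driven
  binning), prediction-correcting by the bin-median population prediction.
  Simulated replicates re-simulate dropout from the threshold rule
  (endogenous censoring), not from the observed dropout times.
* Monte-Carlo recovery examples for the 5-point in-vitro designs are read
  as unbiasedness of the central (median) estimate across replicates: with
  10% noise on five points the plateau–rate trade-off makes single-replicate
  rate estimates scatter far beyond 15% while their median stays within a
  few percent.
* The exocytosis grid-profile utility (`profile_parameter`) reproduces the
  published tie-break procedure (fixing `K_exo` at the grid value with the
  lowest OFV); the original tie-break data are unavailable.

## Known limitations

* First-order release only; matrix-release kinetics (e.g. Higuchi) are out
  of scope.
* Exactly one scalar random effect (baseline) is supported — as in the
  final published model — not a general NLME engine; no covariates, no
  FOCE-I.
* The Laplace approximation carries an irreducible skewness error of order
  0.01–0.03 OFV units per animal at the study's noise levels; the AGQ
  oracle quantifies it.
* Monte-Carlo acceptance checks in the default test run use reduced
  replicate counts (PK clearance recovery 60 of 100; PD recovery 5 of 50)
  to stay within the suite's time budget; the M3-vs-drop comparison runs at
  its full 25 replicates.
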