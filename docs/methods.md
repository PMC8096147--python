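# Methods

This note documents the models implemented in `deazarna`, their
assumptions, the defaults that matter, what the synthetic-data
generators do and do not emulate, and the numerical choices made where
the design was genuinely open.

## Two-state melting thermodynamics (`deazarna.melt`)

**Model.** A strand populates exactly two states, folded and unfolded,
with a temperature-independent ΔH° and ΔS° (no ΔCp correction), so
K(T) = exp(−(ΔH° − TΔS°)/RT) with R = 1.987 cal mol⁻¹ K⁻¹.
Molecularity fixes the mass-action link between K, the folded fraction
θ and total strand concentration c_T:

| molecularity | K(θ) | T_m relation (θ = ½) |
|---|---|---|
| unimolecular hairpin | θ/(1−θ) | T_m = 1000·ΔH°/ΔS° |
| self-complementary duplex | θ/(2c_T(1−θ)²) | 1/T_m = (R ln c_T + ΔS°)/(1000·ΔH°) |
| non-self duplex (1:1 mix) | 2θ/(c_T(1−θ)²) | 1/T_m = (R ln(c_T/4) + ΔS°)/(1000·ΔH°) |

(ΔH° in kcal/mol, ΔS° in cal mol⁻¹ K⁻¹; both strands of a non-self
duplex at c_T/2; θ is the fraction of strands in duplex.) The
bimolecular θ is the stable root
θ = 2a/((2a+1) + √(4a+1)) of aθ² − (2a+1)θ + a = 0 with a = 2c_T·K
(self) or a = c_T·K/2 (non-self); this form avoids cancellation for
a → 0 and overflow is prevented by clipping the K exponent at ±500.

**Observation model.** Absorbance is a θ-weighted mix of two linear
baselines, A(T) = A_f(T)·θ + A_u(T)·(1−θ), unfolded above folded
(hypochromicity: stacking lowers UV absorbance, so melting raises it).

**Estimation.** Two independent routes, as is standard:

1. *Single-curve van't Hoff* (`TwoStateMeltModel`): nonlinear least
   squares of A(T) over six parameters — ΔH°, T_m and the four
   baseline coefficients. The fit is parameterised by (ΔH°, T_m)
   rather than (ΔH°, ΔS°) because T_m is directly identified by the
   transition midpoint, which keeps the optimiser well conditioned;
   ΔS° is derived through the closed-form T_m relation and its
   standard error by the delta method from the Jacobian covariance.
   Starting values: T_m from the first-derivative estimate, ΔH° = −60
   kcal/mol, baselines from the edge windows.
2. *T_m versus concentration* (`TmConcentrationModel`): linear
   regression of 1/T_m on ln c_T (self) or ln(c_T/4) (non-self);
   slope = R/(1000·ΔH°), intercept = ΔS°/(1000·ΔH°), errors by the
   delta method from the coefficient covariance. Requires ≥ 3
   concentrations; a non-negative slope (implying ΔH° ≥ 0) is flagged
   as non-two-state. Hairpin input is rejected: a unimolecular T_m
   carries no concentration information.

Every report records which route produced it (`source` field).

**Derivative T_m.** dA/dT by Savitzky–Golay filtering (default window
11 points, order 3, configurable) on a uniform grid, maximum refined by
parabolic interpolation. The derivative is taken on raw absorbance by
default; pass a baseline-corrected θ to use the folded fraction
instead. Note that for a true two-state curve the maximum of dA/dT
sits slightly *below* T_m (the 1/T² factor in dθ/dT skews it; ≈0.23 °C
for ΔH° = −52.8 kcal/mol), within the ±0.3 °C accuracy usually quoted
for derivative T_m readings. A derivative maximum falling inside the
smoothing half-window at either range edge raises a no-transition
error.

**Baselines.** Default windows are the coolest and hottest 15 % of
points, overridable per curve; degenerate (coinciding) baselines are an
error and baseline crossing inside the range a warning. For broad
transitions whose upper baseline is never reached inside the measured
window, window-fitted baselines are biased — the global six-parameter
fit is the better route there and is what `van_t_hoff_fit` uses.

**Replicates.** `aggregate_replicates` reports per-parameter means with
95 % confidence half-widths t(0.975, n−1)·sd/√n (the standard
t-interval; plain sd and t·sd variants are options). Melting studies of
this kind typically use three independent measurements per duplex and
five per hairpin; a single fit yields no interval and warns.

**Scope.** No multi-state melting, no ΔCp, no nearest-neighbour
prediction, no buffer-dependence modelling.

## CLEANEX-PM exchange kinetics (`deazarna.cleanex`)

**Model.** Magnetisation transferred from water to a labile imino
proton during mixing time τ follows the two-site transfer build-up

    I/I₀(τ) = k/(R₁A + k − R₁w) · [exp(−R₁w τ) − exp(−(R₁A + k) τ)],

with k the proton–water exchange rate, R₁w the longitudinal water
relaxation rate and R₁A an apparent imino relaxation rate (a
combination of longitudinal and transverse contributions) that floats
during fitting. At the removable singularity R₁A + k = R₁w the limit
k·τ·exp(−R₁w τ) is used. The initial slope equals k exactly and the
curve peaks at τ* = ln((R₁A+k)/R₁w)/(R₁A+k−R₁w).

**Fitting.** Nonlinear least squares over (k, R₁A) with bounds
k ∈ [0, 100] s⁻¹, R₁A ∈ (0, 200] s⁻¹ and tight convergence tolerances;
R₁w is fixed from an independent saturation-recovery measurement of
water T1 (M(t) = M0(1 − e^(−t/T1)); values near 3.0–3.1 s are typical
at these conditions) — it is *not* floated, since it is measured per
sample. Repeated mixing times (the standard duplex schedule 5, 25, 50,
50, 100, 100, 150, 200, 300, 400, 400, 500 ms repeats three points)
enter as independent observations. Starting values: k from the
two-point initial slope, R₁A = 20 s⁻¹. Boundary solutions are flagged.

**Errors.** Parametric Monte-Carlo: refit n (default 1000) synthetic
datasets model(τ) + N(0, σ̂²) with σ̂ the residual standard deviation;
the parameter standard deviations across refits are the reported
errors. Deterministic for a fixed seed; a nonparametric residual
bootstrap is available as an option; more than 5 % failed refits is an
error.

**Attainable precision.** The build-up amplitude scales as k/R₁A, so at
fixed intensity noise the information on k collapses as R₁A grows: at
σ(I/I₀) = 0.005 on the 12-point schedule the median relative error on
k ∈ [0.6, 1.7] s⁻¹ is ≈3 % at R₁A = 5 s⁻¹, ≈5 % at 10 s⁻¹, ≈11 % at
20 s⁻¹ and ≈27 % at 40 s⁻¹. The recovery and coverage studies in the
test suite and acceptance script therefore use R₁A = 10 s⁻¹, an
apparent imino relaxation consistent with clearly measurable build-ups
at this noise level.

**Scope.** Intensities are inputs: no peak picking, no radiation
damping or NOE/ROE corrections, no pulse-sequence simulation.

## pKₐ titration (`deazarna.pka`)

**Model.** Single-site fast exchange:
δ_obs(pH) = (δ_deprot·10^(pH−pKₐ) + δ_prot)/(1 + 10^(pH−pKₐ)); strictly
monotone when the end-point shifts differ, midpoint at pH = pKₐ.
Biphasic (multi-site) data are out of scope; a flat series makes pKₐ
unidentifiable and raises.

**Fitting.** Least squares over (pKₐ, δ_prot, δ_deprot) with standard
errors from the Jacobian covariance. A fitted pKₐ outside the sampled
pH window ± 1 is reported but flagged *extrapolated* — relevant for
very basic sites like c³G, whose pKₐ (12.3) sits at the edge of aqueous
titration. C2- and C6-type reporter nuclei are fitted separately by
default; `fit_titration_joint` offers a shared-pKₐ joint fit.

**Gap analysis.** The built-in reference table holds the
Watson–Crick-site pKₐ values {A•H⁺ 3.7, c³A•H⁺ 6.8, c⁷A•H⁺ 5.3, U 9.2,
G 9.5, c³G 12.3, c⁷G 10.3, C•H⁺ 4.1} (overridable via config) and the
gap of a pair is pKₐ(donor) − pKₐ(acceptor): A–U 5.5, c⁷A–U 3.9,
c³A–U 2.4, G–C 5.4, c⁷G–C 6.2, c³G–C 8.2. Gaps near 5.4–5.5 mark the
natural, efficiently pairing combinations. `protonated_fraction` gives
the Henderson–Hasselbalch fraction 1/(1+10^(pH−pKₐ)); c³A (pKₐ 6.8) is
≈39 % protonated at pH 7.0.

**Scope.** No electrode calibration, ionic-strength or temperature
corrections, no structure-based pKₐ prediction.

## Structure comparison (`deazarna.structure`)

**Superposition.** Rigid-body least squares by the Kabsch/SVD
construction (proper rotation enforced, det = +1; ≥ 3 non-collinear
pairs required). Atoms are paired by (residue number, atom name) over
the resolved selections; the default selection is all non-hydrogen,
non-water atoms. An `atom_map` such as `{"C3": "N3"}` pairs a
3-deazapurine's C3 with the parent purine's N3 — the isosteric
replacement. RMSD is symmetric and invariant to rigid pre-transforms;
tests verify it against an exhaustive rotation-grid search and against
an independent library alignment.

**Altloc policy.** All conformers are read and retained; whenever one
atom per site is needed (distances, superposition, hydration) the
highest-occupancy conformer wins, ties going to altloc "A".

**Hydration.** `minor_groove_waters` reports every ordered water whose
oxygen lies within a cutoff (default 3.6 Å, the generous end of
hydrogen-bond geometry) of a minor-groove-face atom of the chosen base
pair: purine N3 — or the C3 that replaces it in a 3-deazapurine —
purine 2′-OH, pyrimidine O2 and pyrimidine 2′-OH. Waters below 0.5
occupancy are excluded by default (partial sites are not part of the
ordered spine); each water appears once with its nearest contact,
sorted ascending; distances are meaningful to ~0.1 Å. The report is
monotone in the cutoff by construction.

The main-text pairing partner of the modified adenosine in the
sarcin–ricin loop is given inconsistently in the source material
(C2650 in prose, U2650 in the figure); the module takes residue
numbers as explicit input and does not resolve this.

**Scope.** No refinement, no electron density, no base-pair step
parameters, no Mg²⁺ analysis.

## Synthetic data (`deazarna.synth`)

Each generator is the exact forward model of its fitter, so zero-noise
fit∘generate identity holds to solver tolerance — the package's central
self-consistency suite. Noise is Gaussian i.i.d. on the observable
(least-structured choice consistent with least-squares fitting) and
seeded: identical seeds give identical data.

Defaults chosen as the study conditions:

* **Melting** — five concentrations log-spaced over 1–100 μM;
  temperature grid 20–90 °C in 0.5 °C steps (141 points); baselines
  +0.0003/+0.0005 AU/°C with 20 % hyperchromicity (folded 1.00 AU,
  unfolded 1.20 AU — typical of RNA UV melts); recovery studies use
  noise σ = 0.3 % of the 0.2 AU transition amplitude and truths
  ΔH°/ΔS° = −52.8/−153 (hairpin), −64.6/−172 (self-complementary),
  −79.7/−212 (non-self) kcal/mol and cal mol⁻¹ K⁻¹.
* **CLEANEX** — the 12-point duplex mixing schedule above, R₁w =
  1/3.03 s⁻¹, intensity noise σ = 0.005, exchange-rate truths
  0.62–1.68 s⁻¹, R₁A = 10 s⁻¹ (see the precision discussion).
* **Titration** — ¹³C-scale end-point shifts (protonation moves a ring
  carbon by ~5 ppm; the recovery truth is pKₐ 6.8, 110/105 ppm), shift
  noise σ = 0.05 ppm, 10 points spanning pKₐ ± 2.
* **Toy base pairs** — idealized planar AU/GC pairs (synthetic
  stand-ins, not crystallographic data) with field-standard atom names
  and waters placed at exact requested distances; placements within
  1.5 Å of a solute atom are rejected as clashes.

What the generators do **not** emulate: instrument artifacts (lamp
drift, temperature lag), spectral overlap and peak-picking error,
correlated or heteroscedastic noise, non-two-state melting, biphasic
titrations, and real crystallographic coordinates (sugar pucker,
propeller twist, a full hydration shell). Passing recovery tests
therefore demonstrate correctness of the estimators under their own
assumptions, not robustness to every pathology of real data.

## Problem sizes and runtime

The recovery studies use 50 seeds × 3 molecularities (melting, one
curve per seed at 10 μM), 4 rates × 12 seeds plus 200 replicates × 150
Monte-Carlo refits (exchange), and 50 seeds (titration) — sizes at
which the medians and the coverage estimate are stable to well within
the margins being tested, while the whole suite and the acceptance
script each finish in about a minute on one CPU.

## Known limitations

* Single-curve van't Hoff ΔH° inherits the usual 10–15 % systematic
  uncertainty from the two-state and temperature-independent-enthalpy
  assumptions; the package checks internal consistency
  (ΔG°₂₉₈ = ΔH° − 298.15·ΔS°/1000 holds exactly for every fit) but
  cannot validate two-state behaviour itself.
* The molecularity heuristic in `seqmod` cannot distinguish a hairpin
  from a self-dimer of a non-palindromic strand; the melting models
  therefore always take molecularity explicitly.
* The hydration census is purely geometric (distance to the
  minor-groove face); it does not check hydrogen-bond angles or
  energetics.
* The comparison against deposited crystal structures needs the wwPDB
  coordinate files locally (under `data/`); they are not bundled.
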