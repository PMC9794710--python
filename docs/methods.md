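# Methods

## Scope and data model

The package analyses a congeneric series of fifteen benzyloxy chalcones
(B1–B15) with activity against the two human monoamine oxidase isoforms.
The structures are reconstructed SMILES: the chalcone core
Ar–C(=O)–CH=CH–Ar′ is fixed, the B-ring carries a benzyloxy ether at the
*ortho* or *para* position, and the A-ring varies (methylenedioxyphenyl,
benzodioxanyl, methylsulfonyl-, thiomethyl-, trifluoromethyl- and
ethoxyphenyl, thiophenyl and 5-bromothiophenyl). A-ring substituents on
phenyl rings are placed *para* to the acyl carbon, and the *ortho*
benzyloxy attachment is drawn at position 2 of the B-ring; these are the
conventional readings of the synthesis scheme, and the SMILES live in one
table (`registry.COMPOUND_SMILES`) so a correction propagates everywhere.

IC₅₀ values above the assay ceiling are stored as censored lower bounds
("> 40 µM"). Censoring is propagated, not discarded: a selectivity index
with a censored numerator is itself a lower bound, and a censored
denominator (or a censored pIC₅₀ input) raises an error, because no usable
bound exists in that direction.

## Descriptors

**Barysz/VE family.** The Barysz matrix is the heavy-atom weighted distance
matrix with Sanderson electronegativities (shipped as package data;
missing elements fail loudly). Diagonal entries are `1 − w_C/w_i`; each
bond contributes `w_C²/(π_b·w_i·w_j)` with conventional bond order π_b
(aromatic = 1.5); the off-diagonal entry sums bond contributions along the
topological (fewest-bond) shortest path. Where two equal-hop paths differ
in weight (possible across substituted rings), the smaller weight sum is
taken — a deterministic tie-break that coincides with the plain definition
on trees and on all fixture compounds. VE1 is the absolute coefficient sum
of the unit-norm eigenvector of the *largest* eigenvalue (sign ambiguity
removed by the absolute values), VE2 = VE1/n and VE3 = ln(0.1·n·VE1).
The eigen-solver is cross-checked in the tests against an independent
shifted power iteration at 1e-10.

**TPSA and fragment counts.** Topological polar surface area uses the
published N/O fragment-contribution scheme (S/P terms behind an explicit
flag, off by default) as implemented in RDKit; the para-hydroxylation site
count is the published RDKit fragment-catalogue pattern. Note the
catalogue pattern requires an activating (O/N/alkyl-chain-specific)
attachment with an unsubstituted para CH: anisole counts one site, toluene
none. On these structures the count discriminates *ortho*- (1) from
*para*-benzyloxy (0) compounds.

Only 2D-computable descriptors are offered; the pipeline is
conformation-free and deterministic.

## Regression and validation

The model is ordinary least squares on raw descriptor scales,
pIC₅₀ = b₀ + Σ bⱼxⱼ, with σ = √(RSS/(n−p−1)). Subset selection is
exhaustive where C(p,k) ≤ 1e5 or by a seeded genetic algorithm
(population 50, generations 100, bit-flip mutation 0.05, elitism 2,
tournament 3, fixed-k repair); elitism makes the best fitness
non-decreasing. Fitness is Q²_loo by default (R² optional); the choice is
recorded in `model.json`.

Validation statistics follow the conventional definitions listed in the
module docstring. Choices worth calling out:

* **LOO** uses the exact hat-matrix shortcut `e₍₋ᵢ₎ = eᵢ/(1−hᵢᵢ)`; the test
  suite verifies equality with explicit refitting to 1e-10.
* **LMO** (default: leave 30% out, 1000 iterations, seeded) defines each
  iteration's score as `1 − Σ(y_out − ŷ)²/Σ(y_out − ȳ_retained)²` and
  averages; the mean-reference choice is stated because conventions vary.
* **Y-scrambling** (default 1000 iterations, seeded) excludes identity
  permutations and retains the full R²/Q² distributions for plotting.
* **LOF** uses the Friedman form `(RSS/n)/(1 − (c + d·p)/n)²` with
  c = p+1 terms and smoothing d = 0.5 (configurable). LOF and the
  Kxx/ΔK multivariate-correlation indices are reported as indicative;
  published values for these two may rest on slightly different constants.
* **Applicability domain**: leverages from the training (X′X)⁻¹ with
  intercept, warning threshold h* = 3(p+1)/n, outliers at |standardized
  residual| > 3. External/query rows reuse the training inverse (an
  Insubria-style screen for unmeasured compounds).
* The Golbraikh–Tropsha battery evaluates the printed thresholds
  (R²_tr ≥ 0.6, Q²_loo ≥ 0.5, Q²_LMO ≥ 0.6, R² > Q², R²_ex ≥ 0.6,
  RMSE_tr < RMSE_cv, ΔK ≥ 0.05, CCC ≥ 0.80, r²m ≥ 0.6, (1−r²/r²o) < 0.1
  or primed, 0.9 ≤ k ≤ 1.1 or primed, |r²o − r′²o| < 0.3).

**Headline-statistic ensemble.** The published training statistics belong
to one specific (unrecoverable) 70:30 split and one specific descriptor
toolchain. The package therefore reports R²_tr and Q²_loo as a seeded
ensemble over ≥ 50 random splits, with the median and the 5–95% envelope,
and flags whether a supplied reference value falls outside the envelope.
With the in-house VE3 dialect the ensemble median sits well below the
published headline values and the flag is raised; the sign pattern of the
full-set coefficients (−, +, −) does reproduce. This is the documented
descriptor-dialect sensitivity: eigenvector-index descriptors are only
comparable within one implementation's conventions.

## Enzyme kinetics

Velocity models (S in mM, I and Ki in µM, mixed with cooperativity α):
competitive `v = Vmax·S/(Km(1+I/Ki)+S)`, uncompetitive
`v = Vmax·S/(Km+S(1+I/Ki))`, mixed
`v = Vmax·S/(Km(1+I/Ki)+S(1+I/(αKi)))`. All three are fitted by nonlinear
least squares. Mode selection compares the two 3-parameter models by
small-sample-corrected AIC and promotes to the nesting 4-parameter mixed
model only when the extra-sum-of-squares F-test is significant at
p < 0.01 — a looser promotion level would, by construction, mislabel that
fraction of genuinely simple-mode datasets. Lineweaver–Burk lines per
inhibitor level and the secondary slope-vs-[I] line (x-intercept = −Ki)
are reported as diagnostics only, since linearisation distorts the error
structure.

Dose-response curves use a 4-parameter logistic with bottom ≥ 0, top near
the observed maximum and free Hill slope, multi-started on a log-spaced
IC₅₀ grid; fitting refuses when no activity falls below half of the top,
mirroring the 10 µM screening rule. Reversibility is classified from
dialysis recovery relative to reference compounds: relative recovery
ρ ≥ 0.5 with an absolute gain > 10 percentage points is reversible, gain
≤ 5 points irreversible, otherwise indeterminate. The ρ/band thresholds
are package decisions; the underlying comparison is conventionally made by
eye against the reference inhibitors.

## PAMPA

`Pe = −ln(1 − C_A/C_eq)/(A·(1/V_D+1/V_A)·t)` with
`C_eq = (C_D·V_D + C_A·V_A)/(V_D+V_A)`; the operator grouping is the
standard PAMPA expression, which reproduces the correct limits (Pe → 0 as
C_A → 0, Pe → ∞ at equilibrium). Defaults: V_D = 0.27 mL, V_A = 0.20 mL,
A = 0.3 cm², t = 18 h (64 800 s; configurable — the incubation time is an
assay choice). Boundary convention: Pe strictly above 4.0×10⁻⁶ cm/s is
CNS+, strictly below 2.0×10⁻⁶ is CNS−, the closed interval between is
uncertain.

## Synthetic generators

The generators emulate the *shapes* of the study's inputs with known
ground truth: correlated-Gaussian descriptor tables with a linear
response; 5-substrate × 4-inhibitor velocity designs at
Vmax = 100, Km = 0.29 mM, Ki = 0.030 µM with multiplicative (constant-CV)
noise; 4PL dose-response grids with additive noise; PAMPA wells obtained
by inverting the permeability equation under mass conservation. Every
generator round-trips its fitter exactly at zero noise, and all
randomness flows from one seeded generator per call.

What they do **not** emulate: real descriptor distributions (no molecular
structures are generated), instrument drift or heteroscedastic assay
error, substrate depletion, tight-binding regimes, or membrane retention
in PAMPA. Passing the recovery tests therefore demonstrates correctness of
the estimators under the stated error model, not robustness to every
bench artefact.

## Problem sizes

Default analysis sizes are those of the study design: 15 compounds,
3-descriptor models, 70:30 splits, 5×4 kinetic designs. Ensemble and
replicate counts (50 split seeds, 200 kinetics replicates, 1000
scrambling/LMO iterations) are the package's defaults, chosen to make
Monte-Carlo error small relative to the tolerances tested.

## Known limitations

* The reconstructed SMILES carry the regiochemistry assumptions above;
  descriptor values inherit them.
* VE3 values are implementation-dialect specific (eigenvalue choice,
  bond-order convention, tie-break); cross-toolchain numeric agreement is
  not expected and not claimed.
* Censored activity rows are excluded from response construction only in
  the sense that the MAO-B IC₅₀s used as responses are all exact in the
  packaged table; a censored response would be rejected, not imputed.
* No bootstrap confidence intervals, no regularised or PLS regression,
  no Morrison tight-binding correction, no membrane-retention correction.
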