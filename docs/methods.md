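# Methods

## Kinetic models

**Serum.** Both the bispecific antibody and the radiolabeled hapten follow a
linear two-compartment model with zero-order infusion input and first-order
elimination from the central compartment:

    dA_c/dt = R(t) − (k_el + k_cp) A_c + k_pc A_p
    dA_p/dt = k_cp A_c − k_pc A_p

with `R(t)` the infusion rate (default duration 0.5 h, configurable per
infusion, reflecting 30–60 min clinical infusions). The central volume is a
dependent parameter, `Vc = vol_per_m2 × BSA` — the body-surface-area
covariate that removes most between-subject volume variability. Rate
constants are named by direction (`k_pc`: peripheral→central, `k_cp`:
central→peripheral) because published tables are inconsistent in how the
indices of `k_2,1`/`k_1,2` map onto directions; each fixture loader applies
and records the mapping that reproduces the published half-lives
(`io.load_table4/5`: printed k₂,₁ → k_pc; `io.load_table6`: printed k₂,₁ →
k_cp).

The solution is evaluated analytically through the eigendecomposition of the
rate matrix, with each infusion contributing its convolution integral in
closed form (`expm1`-stable, so the bolus limit and the λ→0 limit are
exact). Multiple infusions superpose linearly. When the eigenbasis is
numerically defective (near-repeated eigenvalues, a measure-zero parameter
set) a piecewise Runge–Kutta fallback at rtol 1e-11 is used. Mass balance
(central + peripheral + eliminated = infused) holds to ~1e-15 relative and
is asserted in the tests.

Hybrid rates are λ_{α,β} = [s ± √(s² − 4 k_el k_pc)]/2 with
s = k_el + k_cp + k_pc; half-lives are ln 2/λ. When both exchange rates are
zero the model degenerates to one compartment and both half-lives equal
ln 2/k_el; when only `k_el·k_pc = 0` the terminal phase does not decay and
`halflives` raises rather than returning an infinity.

**Covariate law.** The molar ratio MR = n_hapten /(C_antibody(t_inj) × Vc)
is computed from the fitted antibody curve extrapolated to the hapten
injection time. Hapten clearance follows CL = A·MRᴮ; the regression is
unweighted OLS on (ln MR, ln CL), with A = exp(intercept) and R² reported on
the log scale (the scale of fitting). This choice reproduces the published
coefficients exactly from the bundled individual records, which indicates
the source values were obtained the same way. Nonlinear least squares on the
natural scale would weight large-MR records more; it is deliberately not the
default.

**Whole body and organs.** Whole-body (decay-corrected) activity is the sum
of the central and distribution compartments of a two-compartment system
whose elimination rate is k_el = A_WB·MR^B_WB. Organ activity is

    A_organ(t) = fraction × m_organ × C_central(t) + D(t)
    dD/dt = k_on A_central(t) − k_off D(t),   D(0) = 0

the minimal linear realization consistent with a "fraction of central
activity plus a tissue distribution compartment" description and with
`fraction` carrying L/kg: the fraction term needs a central volume to
convert amount to concentration, supplied as an explicit `central_volume`
argument (in practice the hapten serum Vc). The uptake term does not deplete
the central compartment — each organ sees the whole-body input function, so
organ models are independent and the sum of modeled organs can be checked
against, but never exceeds, whole-body activity for physically consistent
parameters. The three-state system (central, peripheral, organ trap) is
solved with the same closed-form machinery.

## Estimation

Residual error is multiplicative lognormal (σ = 0.10 by default), the
natural choice for concentrations and quantified activities spanning three
decades. For uncensored data, maximum likelihood under this model is least
squares on log concentrations, solved by Levenberg–Marquardt in
log-parameter space (all parameters positive by construction). Values below
the quantification limit enter the likelihood as lognormal CDF terms; such
records are fitted by direct likelihood minimisation (Nelder–Mead). Starting
values come from curve heuristics (Cmax → volume, AUC → clearance, terminal
slope → λ_β).

Population analysis is a global two-stage scheme with lognormal random
effects: unpenalised individual fits, then iterated MAP refits with a normal
prior on log parameters whose mean/SD are updated from the current
individual estimates, until the population means move < 1e-4 (relative).
Between-subject SDs are floored at 0.02 on the log scale to keep the prior
proper when estimates collapse. Population summary rows (mean, sample SD,
CV%) are computed from the individual estimates, matching the convention of
the source tables. One patient record may span several sessions fitted with
a shared parameter set (the antibody, whose kinetics is dose-independent);
hapten administrations are fitted per record because each has its own MR.
This scheme is not FOCE/SAEM; it reproduces population means, individual
estimates and CVs well under the trial's design but understates shrinkage
relative to a full mixed-effects treatment.

Tissue parameters (k_on, k_off, fraction) are estimated by log-residual
least squares per organ, either shared across records ("population", used
for normal organs) or per record ("individual", required for tumors, whose
kinetics is too variable to pool). All-zero curves short-circuit to
k_on = fraction = 0.

## Dosimetry

Organ time–activity curves (decay-corrected to injection) are condensed to
nonnegative sums of exponentials: monoexponential below four points,
biexponential from four points up — the threshold at which four unknowns are
identifiable. Physical decay re-enters at integration:
Ã = Σ cᵢ/(λᵢ + λ_phys), the exact integral from 0 to ∞ of the fitted
function times the decay factor (integration from time zero, not from the
first imaging point, is a stated convention). Translating a pretherapeutic
(¹¹¹In) estimate to the therapy radionuclide (¹⁷⁷Lu) substitutes the other
physical decay constant in the same integral, valid because the biological
rates are label-independent. Default half-lives (67.32 h / 159.53 h) are
configuration values.

Absorbed dose: D(target) = Σ_source Ã(source)·S(target←source), with the
self-dose S scaled by (reference mass / patient mass) — electron self-dose
scales inversely with the absorbing mass — and photon cross-terms left at
reference values. Normalized dose divides by administered activity and is
invariant to it. The bundled S-factor table is **synthetic**: self-dose
values derive from a 0.147 MeV mean beta energy absorbed locally and
cross-terms are small plausible magnitudes; it exists so the pipeline runs
end to end and must be replaced for real analyses.

Session comparison uses Spearman rank correlation with an exact permutation
p-value for n ≤ 8 (all n! permutations, mid-ranks for ties; the t
approximation above), the Wilcoxon signed-rank test for paired dose vectors,
and Kruskal–Wallis across dosing cohorts.

## Synthetic cohorts

The generator draws virtual patients around the published population values:
BSA from a truncated normal (1.9 ± 0.2 m², bounds 1.4–2.4); kinetic
parameters as lognormal random effects with the between-subject CVs of the
corresponding individual-estimate tables (the volume CV uses the 4%
covariate-adjusted value); organ masses around adult reference masses (10%
CV). The three dosing-cohort presets encode the trial design (antibody
44/88 nmol/m² imaging, 240/480 nmol/m² therapy; hapten 4.4/24 nmol/m²;
185 MBq / 1.1 GBq/m²; delay 48 or 24 h); the mg→nmol correspondence (7 mg/m²
≡ 44 nmol/m²) is taken from the published scheme rather than an assumed
molar mass. Serum sampling follows the trial's schedule with "2–4 h"
realised as 3 h and the four late samples as 48/96/120/168 h; imaging
defaults to five points at 1–168 h. Noise is multiplicative lognormal (10%
serum, 15% imaging). The antibody quantification limit defaults to
0.005 nmol/L (≈0.8 ng/mL for a ~157 kDa protein, the sensitivity implied by
serum curves followed over seven days); it censors the latest low-dose
session samples, exercising the censored-likelihood path. Tumor parameter
dispersion is a free configuration knob (80% CV default) because only
qualitative variability is reported for tumors.

Within a session the antibody is infused at t = 0 and the hapten at
t = delay; the hapten's true elimination derives from the patient's true MR
through the power law, so cohorts with higher antibody doses have lower MR
and slower hapten clearance by construction. Because the trial kept the
hapten/antibody dose ratio equal across sessions, a patient's two sessions
share the same MR, making the imaging session exactly predictive of the
therapy session in the noise-free limit — the property the end-to-end tests
assert.

What the generator does not emulate: assay drift and inter-scanner
calibration differences, imaging quantification error structure
(reconstruction, partial-volume and registration effects are not
multiplicative lognormal), target-mediated antibody disposition, tumor
burden effects on kinetics, and patient dropout. Passing recovery tests
therefore validate the estimation machinery under the stated error model,
not robustness to those real-data effects.

## Problem sizes and determinism

Recovery experiments use 8-patient cohorts (the number of evaluable trial
patients) at the trial's sampling schedule, and 200-replicate Monte-Carlo
calibrations for single-record bias checks; all are seeded. Fixture-derived
checks (half-life transforms, clearance identities, covariate regressions)
are deterministic closed-form computations on the bundled tables.

## Known limitations

- Global two-stage is an approximation to full nonlinear mixed-effects;
  with very sparse or heavily censored designs its stage-1 estimates can be
  biased in ways shrinkage does not repair.
- The biexponential time–activity fit enforces nonnegative coefficients and
  so cannot represent an uptake (rising) phase; organ curves dominated by
  late uptake are better served by the compartmental tissue model.
- Bone-marrow dosimetry from vertebral segmentation and voxel-level
  dosimetry are out of scope; the S-factor path covers organ-level MIRD
  only.
- The exact Spearman permutation test enumerates n! permutations and is
  capped at n = 8 by default.
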