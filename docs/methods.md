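# Methods

## Model scope and structure

The model describes two endothelial cells (ECs) competing for the tip
position of an angiogenic sprout. Each cell carries six pathway modules —
VEGF-VEGFR, Notch, oxygen sensing (HIF), Akt-eNOS, Raf-MEK-ERK, and
Ca²⁺/NO cycling — encoded as a reaction network over the three kinetic-law
families mass action, Michaelis-Menten (MM) and Hill. Regulatory
modulation that is not itself a binding event is expressed as a
multiplicative factor on a reaction rate: `(1 + (A/Ka)^n)` for an
activator, `1/(1 + (I/Ki)^n)` for an inhibitor (n = 1 unless stated). The
default build has 120 species (56 per cell plus the shared environment
species for O₂, extracellular Ca²⁺ and the two VEGF reservoirs), 208
reactions and 137 global parameters shared by the two structurally
identical cells. These counts are a deliberate module-level reduction:
each pathway is represented by its signal-carrying backbone rather than
every known intermediate.

**Units.** Concentrations are µM throughout; rate constants are per-second
(bimolecular: µM⁻¹s⁻¹); user-facing time is hours and is converted at the
simulation boundary. A single internal time unit avoids mixed-rate bugs
when modules with second-scale (Ca²⁺) and hour-scale (HIF, receptor
turnover) dynamics share one state vector.

**Initial conditions.** Surface receptor levels come from receptor counts
at a 1 pL cell volume: 6000 VEGFR2/cell → 0.0099 µM, 2000 VEGFR1/cell →
0.0033 µM, ~40,000 NRP1/cell → 0.0664 µM. Notch1 starts at the
VEGFR2-like 0.0099 µM; Dll4 protein and the Dll4/Notch1 mRNAs start at
zero, so ligand expression is entirely stimulus-driven. All remaining
initials are assumed baselines that a 24 h normoxic, VEGF-free
pre-equilibration relaxes to a quasi-steady state before any stimulus is
applied; stimuli (VEGF boluses, an O₂ step, DAPT) act at t = 0 on that
baseline. Boluses are instantaneous set-values of constant reservoir
species — receptor binding does not deplete the extracellular pool.

## The patterning circuit

The only interaction between the cells is trans Dll4→Notch1 binding.
Within a cell, phospho-VEGFR2 drives PLCγ/Ca²⁺, Akt and ERK; phospho-ERK
induces Dll4 mRNA through a Hill term (gain `teta_ERKDll4`); γ-secretase
(blocked competitively by DAPT, Ki 0.02 µM) releases NICD from
ligand-bound Notch1; NICD induces Hes1 (Hill, n = 4); and Hes1 represses
both surface-VEGFR2 production (Hill exponent `n_HesR2`) and Dll4 mRNA
while upregulating VEGFR1. This closes a mutual-inhibition loop whose
small-signal gain around the symmetric operating point was deliberately
placed modestly above 1 (the trans binding runs sub-saturated at
`ktrans_DllNotch` = 0.01 µM⁻¹s⁻¹ so NICD stays responsive to neighbour
Dll4, and the Hes1 and Hes1⊣Dll4 Hill terms sit near their steep centres).
Consequences, all exercised by the tests:

- a 2:1 VEGF asymmetry (0.0012 vs 0.0006 µM, the tip/stalk doses implied by
  a 3.5%-per-10-µm linear VEGF decay along a 100 µm cell with 10 µm
  filopodia) is amplified over ~12 h into a committed tip/stalk pattern;
- exactly equal stimulation stays symmetric: the growth rate of the
  antisymmetric mode is small enough that float-roundoff asymmetries
  (~1e-16) remain far below the 5% pattern-call threshold over 12 h;
- DAPT (20 µM) breaks the loop: the residual ECPI separation is only the
  direct, deliberately compressed ERK→Dll4 transmission of the dose
  difference (the ERK→Dll4 Hill operates near saturation at stimulated
  pERK levels), which stays under the 5% threshold.

Oxygen enters twice: HIFα degradation is MM in [O₂] (fast at 209 µM
normoxia, ~8-fold slower at 9.95 µM), and a Na⁺/Ca²⁺-exchanger Ca²⁺ influx
is O₂-inhibited. HIF1α and HIF2α drive VEGFA mRNA additively (two
parallel reactions). Autocrine VEGFA translated from that mRNA activates
only the same cell's Akt arm and the VEGFR1 decoy — never VEGFR2 — so
hypoxia alone upregulates the HIF arm without creating a pattern.

The Endothelial Cell Pattern Index, ECPI = Hes1·VEGFR1/(Dll4·VEGFR2), uses
total surface receptor pools (free + ligand-bound + phosphorylated for
VEGFR2; free + bound for VEGFR1). The pattern call averages each cell's
ECPI over the final 25% of the window and requires a 5% relative
separation; both numbers are explicit, testable conventions for what the
eye does on a plot.

**Parameter provenance.** The registry houses every named rate the
sensitivity analysis discusses (kdeg_He, kp_Dll, n_HesR2, kNotchR1,
teta_ERKDll4, …, O2, Caext). Values are the package's own defaults,
flagged `status="assumed"`: binding on-rates 1-10 µM⁻¹s⁻¹, protein
half-lives 0.5-8 h, Hill centres placed at the species' stimulated
operating ranges. They are configuration, not measurements, and the
patterning conclusions depend on them in the way the sensitivity analysis
quantifies. `kNotchR1` is implemented as the activation constant of the
Hes1→VEGFR1 production factor (smaller = stronger upregulation); Hes1's
effect on VEGFR1 is direct rate modulation, not a delayed mRNA step.

## Numerics

The network compiles once into a generated flux function;
`dy/dt = N·flux` holds by construction (N the integer stoichiometry matrix
with constant-species rows zeroed). Default integrator: BDF with
rtol 1e-8, atol 1e-12 µM and the analytic Jacobian sparsity pattern;
fluxes are evaluated on the state clamped at zero, and clamped calls are
counted. Halving the tolerances moves the 12 h ECPI by <1e-6 relative.
For the small fixture networks used in calibration experiments the
predictor defaults to LSODA at the same tolerances (~10× faster at that
scale). Mid-run events split the integration and re-start the solver at
the event time; the post-event state is reported at the event instant.
Equal-stimulation symmetry is exact up to summation order (~1e-15);
relabeling the cells reproduces the swapped trajectories to ~1e-12.

## Sensitivity and identifiability

PRCC: inputs and output are rank-transformed; the coefficient for input j
is the Pearson correlation of the residuals of rank(x_j) and rank(y) after
regression on all other ranked inputs, with p from the t-approximation on
n − k − 1 degrees of freedom and no multiple-testing correction (raw
0.2/0.05 cutoffs). Collinear input columns and constant outputs yield NaN,
never a silently wrong number. The global analysis varies parameters in
[v/1.5, 1.5v] (Latin hypercube, default n = 500, seed mandatory) and
scores each cell's ECPI at 1 h and 12 h under normoxia-equal,
normoxia-differential, and hypoxia-differential stimulation; failed
integrations are dropped (not imputed) and >10% failures abort.

The influence screen keeps parameters with |PRCC| > 0.2 or p < 0.05 on at
least one output. The collinearity screen finds reaction pairs that are
exact reverses of one another (reversible bindings,
phosphorylation/dephosphorylation cycles), confirms the antagonism by
opposite-signed finite-difference effects on the pair's net flux at a
positive reference state (zero initials replaced by 0.01 µM), and retains
the forward (first-registered) member. Group classification assigns each
fittable parameter to the stage (VEGF vs hypoxia) whose observables it
influences most, ties going to the VEGF stage, which is fitted first.

Local sensitivity of Hes1 to the receptor initials uses central
differences (default 1%) of d ln Hes1/d ln R₀ per cell and horizon,
simulated from the assigned initial state without pre-equilibration —
the receptor initials are themselves the quantity under study, and
equilibration would erase them.

## Calibration

Data are max-normalized time courses (value = concentration / max over the
window), the natural scale for semi-quantitative Western-blot data; the
simulation is normalized over the same window before residuals are formed.
The objective is Σ w·(sim − data)² with default weights 1/(points per
experiment) so each pooled study counts once. Optimisation is canonical
global-best PSO (swarm 30, inertia 0.729, cognitive = social = 1.49445,
300 iterations by default), run in log-parameter space because the bounds
are multiplicative (one decade above/below baseline), positions clamped to
bounds, followed by a Nelder-Mead polish of the swarm optimum. Failed
simulations return a large finite penalty so the swarm survives them.
Fitting is staged: the VEGF-group parameters are fitted against the
VEGF/normoxia-labelled datasets with the hypoxia group frozen at baseline,
then frozen at their estimates while the hypoxia group is fitted against
the hypoxia-labelled datasets.

Goodness of fit is the Wald-Wolfowitz runs test on time-ordered residuals
per observable: runs above/below the mean, exact combinatorial null for
n ≤ 30 (two-sided tail by distance of the run count from its expectation),
normal approximation with continuity correction beyond; h = 1 iff
p < 0.05.

Uncertainty: case-resampling bootstrap. Records are resampled with
replacement within each (observable, condition, source) group, each
replicate refitted with a reduced budget (default swarm 10, 40 iterations
— a documented fidelity/cost trade-off), and the band is the percentile
interval of replicate predictions; n_boot = 1 degenerates to a single
refit. The bootstrap restart policy is user-driven: replicates start from
the point estimate rather than re-running a full multi-start search.

## Synthetic data and what passing tests mean

The generator simulates a model at known "true" parameters, applies
multiplicative lognormal noise (default σ 0.05-0.15, the constant-CV error
structure of densitometry; additive Gaussian available for robustness
checks), max-normalizes, and clamps to [0, 1]. Sample times default to a
typical Western-blot grid (0, 0.25, 0.5, 1, 2, 4, 8, 12, 24 h).

Two properties of max-normalized data shaped the validation experiment
designs, and are worth knowing when fitting real data:

- **Scale coupling.** Normalizing by the maximum of a *noisy* series
  injects that one draw's error into every point. When several samples sit
  on a plateau near the max, the realized scale is systematically inflated
  (a max over several lognormals), which biases shape fits. The
  parameter-recovery experiment therefore probes two stimulus levels per
  stage (different enzyme/substrate saturation), which is also what makes
  kcat/Km pairs identifiable from shape-only data at all; the
  bootstrap-coverage experiment uses a peaked transient whose single,
  isolated maximum makes the scale error zero-median, and pools four
  independently normalized sources so it averages out.
- With those designs, staged PSO recovers 6/6 cascade parameters within a
  factor of 2 at 5% noise across seeds, reaches objective <1e-6 (in
  practice ~1e-20) on noiseless data, and the nominal-95% bootstrap band
  covers the noise-free truth at ~90% of time points over 10 seeds.

These experiments validate the *pipeline* under its own noise model; they
do not certify the EC model against real Western-blot data, whose
between-study heterogeneity, cell-line differences and detection
nonlinearity the generator does not emulate.

## Interchange

SBML Level 3 export writes compartments, species (µM initial
concentrations, constant/boundary flags), global parameters, and reactions
with canonical content MathML for the three law families, plus a
package-namespace annotation carrying the structured law description,
parameter metadata and observables — so an export→import round trip is
exact (identical simulations). Import without the annotation falls back to
structural MathML classification (mass-action products, canonical MM and
Hill ratios, one enzyme factor); anything else — e.g. an arbitrary
rational law — raises an error naming the reaction. Models and protocols
also serialize to a documented YAML schema (`tipstalk.config`).

## Known limitations

- Absolute NO concentrations are not calibrated (production starts from
  zero NO and a lumped eNOS/CaM activation); only relative NO differences
  between cells and across Dll4 levels are meaningful.
- No Jagged1, angiopoietin, cis-inhibition, or spatial/agent-based
  extension; one ligand (VEGFA-165-like), one gradient geometry.
- The ERK cascade is a three-tier MM chain without scaffolding or
  feedback adaptation; its dose-compression at saturation is a tuned
  property, not a measured one.
- Structural identifiability is out of scope; the SBML export exists
  partly so external tools can perform it.
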