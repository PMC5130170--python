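# Methods

## The model

`erknoise` analyses how intrinsic (reaction-timing) and extrinsic
(protein-abundance) noise shape single-cell responses in EGF signalling. Its
core is a mass-action kinetic model of the pathway from ligand binding to
nuclear translocation of ERK, with 78 chemical species and 150 elementary
reactions:

* **Receptor layer.** EGF binds EGFR; ligand-bound receptors dimerize and
  trans-autophosphorylate. A receptor phosphatase, internalization,
  recycling and slow degradation shape the phospho-receptor (RP) level.
* **Adaptor layer.** RP recruits Grb2–Sos either directly or through
  phosphorylated Shc (both arms of the classical scheme are present, with
  all binary complexes explicit).
* **Ras layer.** Receptor-bound Sos complexes act as exchange factors
  converting RasGDP to RasGTP; hydrolysis is mostly Ras-intrinsic with a
  smaller GAP-mediated component.
* **Raf layer.** Raf binds RasGDP weakly and RasGTP strongly; only the
  RasGTP–Raf complex passes through an activation intermediate that releases
  active Raf. A Raf phosphatase deactivates it.
* **MEK/ERK layer.** Distributive two-step phosphorylation cycles with
  explicit enzyme–substrate complexes. The second ERK phosphorylation step
  is faster than the first, so the doubly phosphorylated route (quadratic in
  ppMEK) dominates the phospho-ERK response. Cytoplasmic and nuclear ERK
  phosphatase pools are separate. Doubly phosphorylated ERK phosphorylates
  Sos, a negative feedback that linearizes the phospho-ERK dose response.
* **Nuclear pore layer.** ERK crosses the nuclear envelope through explicit
  transport complexes with the nuclear pore complex (NPC). Phosphorylated
  ERK is import-biased. Nuclear ppERK phosphorylates the pore in two steps
  (NPC → pNPC → ppNPC, reactions 137–144); the doubly phosphorylated pore
  translocates ERK **unidirectionally** from nucleus to cytoplasm. This
  negative autoregulation caps nuclear ERK accumulation and converts its
  dose response from graded to switch-like.

The state unit is molecule count in all engines, so deterministic initial
conditions, stochastic propensities and extrinsic sampling share one
representation. Bimolecular rate constants are stored volume-scaled
(1/(molecule·s)); compartment volumes (membrane shell 0.1 pL equivalent,
cytoplasm 1 pL, nucleus 0.22 pL) are recorded in the model file for
reference. EGF is a clamped (buffered) species: the extracellular dose,
expressed in ng/mL (≈ 99.6 clamped molecules per ng/mL at the model's volume
convention), enters rate laws but is never consumed.

### Provenance of the rate constants

The packaged model (`erknoise/models/egf_erk_npc.json`) is a **synthetic,
calibrated reconstruction**, not a transcription of measured constants. The
architecture follows the literature scheme above; the rate constants were
calibrated, by deterministic simulation, against published dose–response
characteristics of this pathway:

| target                                   | published | this model |
|------------------------------------------|-----------|------------|
| Hill n, peak phospho-ERK                 | 1.46      | 1.46       |
| Hill n, peak nuclear-ERK fold change     | 2.99      | 2.96       |
| nuclear-ERK EC10 (ng/mL)                 | 0.02      | 0.020      |
| nuclear-ERK EC90 (ng/mL)                 | 0.12      | 0.108      |
| Hill n, nuclear ERK after pore knockout  | 1.46      | 1.54       |
| knockout EC90 (ng/mL)                    | 1.00      | 0.57       |
| basal fold-change CV (both noises)       | 0.35%     | ≈0.33%     |

The knockout EC90 is the one target this parameterization does not reach:
the knockout curve saturates together with the phospho-ERK ceiling near
0.6–0.8 ng/mL, and extending the receptor's high-dose tail far enough to
push it to 1.0 degrades every fitted Hill coefficient. We report the
computed value rather than forcing it.

Two calibration mechanisms are worth recording. The graded phospho-ERK
coefficient is set almost entirely by the strength of the ERK→Sos negative
feedback (stronger feedback flattens the curve). The nuclear-ERK switch
requires a *sharp threshold* for pore phosphorylation: the model uses a
small, saturable pore-phosphatase pool working at zero order, so ERK-driven
pore phosphorylation wins abruptly once nuclear ppERK exceeds the
phosphatase's maximal velocity; closure speed then sets the fold-change cap.

## Observables

* `pERK` — total singly plus doubly phosphorylated ERK, including every
  complex containing a phospho-ERK moiety (units: molecules).
* `nERK` — nuclear ERK fold change: total nuclear ERK (free, phosphatase- or
  pore-phosphorylation-bound; pore *transport* complexes excluded as
  "in transit") divided by its own pre-stimulus value. Dimensionless;
  exactly 1 at t = 0 by construction.

Peak responses are maxima over the output grid (default 3600 s at 10 s
resolution — the transient peaks at roughly 200–900 s depending on dose).
Peak nuclear ERK rises with dose through the transition and declines
mildly (~5%) above saturation, where faster pore closure clips the
transient; peak phospho-ERK is monotone throughout.
At dose 0 the fold change is a stationary quantity, so basal ensembles use
the end-point value rather than the peak: the per-cell peak of a stationary
fluctuation has mean > 1 and would bias the basal distribution.

## Simulation engines

**Deterministic.** LSODA with an analytic mass-action Jacobian, rtol 1e-8 /
atol 1e-6 molecules for single trajectories and dose-response curves
(halving tolerances moves peaks by < 1e-6 relative). Before stimulation the
model is relaxed at dose 0 until the largest relative rate falls below
1e-9 — nuclear-ERK fold change is normalized to this state. Per-cell
ensemble runs use rtol 1e-6 / atol 1e-2 and a 1e-7 equilibration criterion;
the measured peak difference against the strict settings is < 1e-6
relative, and the speedup is what makes thousand-cell ensembles practical
on one core.

**Stochastic.** The exact direct-method SSA with an incremental propensity
update (dependency graph) and sparse stoichiometry columns. Paths are
sampled onto a regular grid with last-event hold; a vanishing total
propensity is absorbing, not an error. Homodimerization uses the n(n−1)/2
propensity (n²/2 deterministically); at the model's molecule numbers the
difference is negligible. For stimulated full-model runs an adaptive
tau-leaping variant (Cao–Gillespie step bound, ε = 0.03, Poisson leaps with
rejection on negativity, exact stepping for small leaps) is available and is
validated against the direct method on a reduced cascade; ensembles default
to it because the stimulated model fires ~1e5 events/s. Per-cell RNG streams
are spawned from the master seed with `numpy.random.SeedSequence`, so
ensembles are order-independent and bitwise reproducible.

## Noise regimes

Extrinsic noise multiplies each free protein pool (16 groups: the nine
signalling proteins EGFR/Shc/Grb2/Sos/Ras/GAP/Raf/MEK/ERK, the five
phosphatase pools, the pore phosphatase and the pore itself; ERK's
cytoplasmic and nuclear pools share one factor) by a log-normal factor with
mean exactly 1 and a chosen CV (moment-matched: σ² = ln(1+CV²),
μ = −σ²/2). Complexes start at their nominal values and re-equilibrate
during the per-cell pre-stimulus relaxation. `covariation="full"` replaces
the independent factors by one shared factor per cell (the modeled extreme
of correlated expression capacity); a correlation parameter ρ interpolates.
Intrinsic noise is reaction-timing stochasticity via the SSA. The four
regimes (none / intrinsic / extrinsic / both) follow from the two flags.

Default noise conditions: extrinsic CV 30% for the
intrinsic-versus-extrinsic comparison, 25% for one-at-a-time attribution
and for the pseudo-experimental truth, measurement-error CV 4.4%, basal
simulated CV ≈ 0.35%.

## Apparent measurement error (AME)

Observed single-cell distributions include measurement variance. The AME is
modeled as multiplicative Gaussian noise on the fold change, mean 1, CV
`cv_ame`, independent of dose, composing in quadrature:
CV_obs² = CV_sim² + CV_ame². It is estimated from the unstimulated
condition — least-squares Gaussian fits (Freedman–Diaconis binning) to the
simulated basal distribution (CV ≈ 0.35%) and the observed basal
distribution (CV 4.4%) give cv_ame = √(0.044² − 0.0035²) ≈ 4.39%. A
multiplicative (rather than additive) form keeps fold changes positive and
is indistinguishable from additive noise near mean 1. AME is applied to
simulated responses before any comparison with (pseudo-)experimental data;
it dominates at low dose, where biological variability is small, and is
negligible at high dose.

## Protein-variability recovery

`ProteinVariabilityModel` recovers the cell-to-cell protein CV by grid
search over {0, 5, …, 50}%: for each candidate CV it simulates extrinsic
ensembles across the experimental dose set, applies the AME, computes the
CV-versus-dose profile and scores the residual sum of squares against the
observed profile. The same master seed is used at every grid point (common
random numbers), so the RSS profile is smooth in the candidate CV. The
deterministic per-cell engine stands in for the both-noise ensemble here:
at 1e4–1e6 molecules per pool, intrinsic noise contributes ≈0.3% CV against
the ≥5% extrinsic signal being scored. At the package's desk scale
(200 observed cells/dose, 80 simulated cells/condition, 6 doses) the search
returns the generating 25% exactly, with a convex RSS profile.

## Mutual information

I(R;S) between the dose label S (uniform marginal over the tested doses)
and the response R uses the plug-in estimator on a binned response,
debiased by subsample extrapolation: plug-in estimates at fractions
{1, ½, ¼} of the data (stratified per dose, 5 repeats below full size) are
extrapolated linearly in 1/n to infinite sample size, and the response bin
count is the smallest at which doubling the bins changes the extrapolated
estimate by < 2% (0.005-bit floor near zero). The estimate is clipped at 0.
On an independent channel at n = 5000 the procedure returns < 0.02 bits;
on channels with known discrete MI it is accurate to ~5%. This
subsample-extrapolation scheme is this package's concrete reading of
"bin-size optimization plus jackknife debiasing"; the original recipe's
exact parameters are not public, so only the estimator's *properties* are
guaranteed, not numerical identity with other implementations.

## Synthetic (pseudo-experimental) data

No public single-cell nuclear-ERK dataset is available for this analysis,
so `erknoise.synthetic` generates datasets with the
statistical structure of such measurements: per-dose fold-change samples at
{0, 0.01, 0.05, 0.1, 0.5, 50} ng/mL (basal/transition/saturating coverage),
an approximately Gaussian basal distribution (mean 1, CV 4.4% after AME),
switch-like dose dependence, extrinsic variability and multiplicative
measurement error. Default 1000 cells per dose (desk scale; reduced in the
tests and acceptance runs, stated where used). Every dataset carries its
full generating parameter set and seed; regeneration is bitwise identical.
A model-free Hill surrogate (`fast_surrogate_generator`) provides cheap
fixtures for the estimator stages; it mimics the statistics, not the
mechanism. What passing recovery/MI tests show is that the estimators
recover the truth *under the generator's assumptions* (log-normal abundance
variation, dose-independent multiplicative error, no cell-cycle or
microenvironment structure, no temporal drift); real measurements violate
these in ways synthetic data cannot reveal.

## Heterogeneity attribution

One-at-a-time sweeps vary a single protein's abundance (CV 25%, others at
nominal) across doses and record the nuclear-ERK CV. Species are grouped
by where their variability matters: type 1, elevated inside the
[EC10, EC90] transition window; type 2, elevated above EC90; type 3, flat.
"Elevated" means the species' regional maximum CV exceeds 20% of the
largest CV anywhere in the matrix; a species elevated in both regions is
type 2 (persistent high-dose heterogeneity is the more specific signature).
A within-region median threshold was tried first and discarded: when most
species are elevated in one region, the region median is itself elevated
and the rule becomes unstable to hair-width differences. On the packaged
model the sweep yields type 1 = {EGFR, Ras, Raf, MEK, Sos}, type 2 =
{ERK}, type 3 = {GAP, Grb2, Shc}: the upstream amplification chain drives
all-or-none heterogeneity in the transition; total ERK scales the saturated
response; GAP and Grb2 are non-influential because hydrolysis is mostly
Ras-intrinsic and Grb2 saturates its receptor sites. The published grouping
places Sos with ERK in the high-dose class; reproducing that would require
a different high-dose bottleneck than this parameterization has, and is a
known limitation.

## Numerical and design choices

* EC values quoted for simulated curves are read off the raw curve by
  monotone (PCHIP) interpolation in log dose; the closed Hill form
  EC_f = K·(f/(1−f))^{1/n} is used when starting from a fitted `HillFit`.
  Simulated curves are not exactly Hill-shaped, so the two differ — the
  published EC10/EC90 values are only consistent with curve-reading, which
  is therefore the default for reporting.
* Hill fits are least squares with the floor fitted (one code path for
  absolute pERK and fold-change nERK), multi-start over n ∈
  {0.5, 1, 2, 4}, K parameterized on the log scale.
* Dose grid: 0 plus 24 log-spaced doses in [1e-4, 50] ng/mL.
* The basal SSA horizon is 120 s (the nuclear pool decorrelates with
  τ ≈ 40 s); basal ensembles use 200 cells.
* Degenerate inputs: all-equal samples fit CV 0 with a warning; zero
  nominal counts ignore extrinsic CV with a warning; zero total propensity
  holds the state; negative ODE excursions are clipped at 0 in rate
  evaluations and on output.

## Known limitations

* The rate constants are calibrated, not measured; individual parameter
  values should not be interpreted biologically, only the collective
  dose-response behaviour.
* The knockout EC90 and the Sos attribution class deviate from the
  published values (see tables above).
* No receptor synthesis: the model is valid for single-stimulus transients
  (hours), not chronic signalling.
* Ligand depletion, spatial gradients, cell-cycle and microenvironment
  covariates are out of scope.
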