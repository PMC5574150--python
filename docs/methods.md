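# Methods

## Model

The model tracks 17 cell concentrations (cells/µL, time in days): stem cells
(HSC); progenitor, marrow/tissue, circulating and marginal-pool states for
neutrophils and monocytes; progenitor, thymus/tissue and circulating states
for lymphocytes (no lymphocyte marginal pool — it is physiologically much
smaller than the myeloid ones); activated macrophages and apoptotic debris;
and a three-state cancer clone (progenitor, marrow, circulating) mirroring the
monocyte lineage. Every state equation is a sum of production, movement and
loss terms.

**Asymmetric self-renewal.** A dividing pool with self-renewal fraction `a`
and mitosis rate `mr` gains `(2·a_eff − 1)·mr·X` cells/µL/day and exports
`2·(1 − a_eff)·mr·X` to the next stage, where `a_eff = a·φ` and `φ` is the
product of the Michaelis–Menten feedback factors acting on that pool; the two
fluxes always sum to the total production `mr·X`. Progenitors additionally
carry an explicit differentiation rate `s`, so the isolated net growth rate of
a progenitor is `(2a−1)·mr − s − d`.

**Feedback wiring.** Cytokines are not explicit species; regulator abundance
is proportional to the secreting population and enters as `k/(k+C)`
(inhibition) or `C/(k+C)` (activation):

* every movement is inhibited by the same-lineage concentration already in
  its destination pool (the lineage constants `kN`, `kL`, `kM` govern
  movement into the circulating blood; `kNmp`/`kMmp` margination;
  `kNbm`/`kMbm`/`kLt` recruitment into marrow/tissue). Same-lineage rather
  than whole-compartment crowding keeps one Michaelis constant per lineage
  governing both self-renewal and blood entry, and it makes the uni-lineage
  sub-models unbiased sub-systems of the integrated model — with
  whole-compartment crowding the integrated model systematically suppresses
  every lineage relative to its sub-model, which degenerates cohort
  generation;
* progenitor self-renewal is inhibited by the same-lineage mature circulating
  concentration through the same lineage constant;
* stem-cell self-renewal is inhibited jointly by the stem concentration
  (`kHSC`) and the total marrow concentration (`kBM`), which keeps the marrow
  below its packing capacity (3×10⁵ cells/µL, a geometric estimate treated as
  a structural constant);
* debris activates monocyte→macrophage conversion and macrophage
  proliferation (`kA`); macrophages enhance recruitment of mature cells into
  tissue and accelerate debris clearance (`kMAC`).

**Chemotherapy.** One-compartment pharmacokinetics: constant infusion over
day −7..0 with first-order elimination (`chElim`), and a linear log-kill
`chKill·D(t)·X` on every stem, progenitor and mature state (macrophages and
debris are exempt; the mask is configurable). Killed cells route into the
debris state, which fuels the macrophage clearance loop. The induction window
is fixed at 7 days.

**Cancer.** Cancer states obey the monocyte-lineage equations with every
homeostatic feedback removed and no recruitment back into tissue; their four
parameters (death `dMc`, self-renewal `aMc2`, mitosis `mrMc2`, mobilization
`mbMc`) equal the monocyte values in the healthy baseline. "Growth stops at
the theoretical marrow capacity" is implemented as a termination condition:
integration stops once the cancer concentration in marrow or blood passes the
death threshold (3×10⁵ cells/µL). A dynamic logistic brake with ceiling equal
to the death threshold would make that threshold an unreachable asymptote, so
no virtual patient would ever die; unbraked exponential growth with
event-stopped integration reproduces the intended behaviour exactly.

## Parameters

51 named parameters: 7 death rates fixed from literature ranges (progenitors
0.1/d; mature neutrophils 2/d; thymic lymphocyte selection 0.3/d; circulating
lymphocytes 0.02/d; marrow monocytes 0.1/d; circulating monocytes 0.6/d;
macrophages 0.02/d) and 44 uncertain parameters, sampled in cohort generation
(log-uniform between 1/5 and 5× nominal for rates and Michaelis constants;
linear on [0.5, 1] for self-renewal fractions; the chemotherapy kill and
elimination rates are included among the uncertain 44 — chemotherapy response
genuinely varies between patients). The marrow capacity and the four cancer
parameters sit outside the 51-parameter count, the former as a structural
constant and the latter as derived quantities.

**Nominal calibration.** The nominal values are never hand-entered: they are
back-solved from steady-state flux balance at a clinically normal operating
point (neutrophils 4000, lymphocytes 2000, monocytes 400 cells/µL circulating,
marginal pools equal to circulating, marrow reserves 2×, stem cells
10 cells/µL), given the fixed death rates and a small set of design choices
(progenitor mitosis rates 2.0/1.0/1.5 per day for N/L/M, differentiation
rates 0.5/0.2/0.3, raw self-renewal fractions 0.70/0.70/0.65, effective
demargination 1/day, Michaelis-constant multipliers). Marginal-pool and blood
balances fix the traffic rates, marrow balance fixes each progenitor pool,
and each progenitor's effective self-renewal is pinned just below
self-sufficiency with the deficit covered by the stem differentiation flux
(splits 0.55/0.25/0.20). The raw self-renewal choices set the feedback gain:
higher values steepen the feedback and under-damp the post-chemotherapy
recovery; 0.70/0.70/0.65 give second recovery peaks that decay well beyond
the 18% damping criterion. The calibrated set and its equilibrium are stored
as a versioned JSON fixture and regenerate bit-identically.

## Acceptability criteria

Applied to the day −7..300 protocol simulation (daily sampling through day
150, then every 30 days): (1) total circulating leukocytes recover above
80 cells/µL; (2) stem cells end in [1, 100] cells/µL and recover at least 5%
off their nadir (the recovery clause applies only when chemotherapy actually
depleted the pool); (3) each circulating lineage ends within its clinically
acceptable range — by default the full normal ranges 1500–8000 / 1000–4800 /
100–1000 cells/µL for neutrophils / lymphocytes / monocytes; (4) each
marginal pool ends within one order of magnitude of its circulating pool;
(5) every evaluated state is below 20% of baseline at the end of the 7-day
course; (6) the post-chemotherapy overshoot peak is < 12× the value five days
later; (7) oscillations are damped: with at least two detectable
post-chemotherapy peaks (a peak must clear the final value by 1%, a noise
guard), the second amplitude must sit at least 18% below the first.
Criterion 7 rejects sustained or growing oscillations and passes strongly
damped recoveries; the symmetric variant (second peak within ±18% of the
first) is available as a configuration switch but inverts the criterion's
purpose and is not the default. Criteria 5–7 are evaluated on each
circulating lineage state and on stem cells; any failure fails the criterion.
Criteria referencing absent states pass vacuously in uni-lineage screens.

## Cohort generation and separatrix constraints

Uni-lineage screens sample the focal lineage block, the stem-cell core and
the chemotherapy pharmacodynamics (18–21 parameters); the other lineages are
absent (states pinned at zero, their stem influx discarded). Each sample is
integrated to equilibrium (convergence: relative state change < 1e−7 over a
trailing 100-day window within 2000 days; stiffness failures are flagged and
rejected, mirroring the known stiffness of the monocyte sub-model), treated,
and scored. The separatrix stage then (i) bounds every sampled parameter to
the range the accepted sets occupied (in log10 space) and (ii) fits
corner-cut half-planes on 10×10 bin grids for the pairwise relationships
(self-renewal vs mitosis per progenitor type and stem cells; neutrophil
self-renewal vs the neutrophil blood feedback constant): a bin is acceptable
when it holds more than (accepted count)/100 points, maximal corner-anchored
staircases of unacceptable bins are replaced by one least-squares half-plane
each, translated toward the corner so no staircase-boundary vertex is
excluded (conservativeness). The multi-lineage screen re-samples inside the
range-constrained bounds and rejection-filters proposals on the corner cuts
only — rejection against the original 44-dimensional box would have
acceptance ~1e−10 and is infeasible.

## Clustering and representatives

Accepted multi-lineage protocol trajectories are resampled onto a 162-point
grid (daily day −7..150, then days 180, 210, 240, 270 — the stated grid size
is arithmetically inconsistent with coarse sampling "until day 300", so the
grid is configurable and this default keeps 162 points), normalized per state
by that simulation's own maximum, flattened (17×162) and clustered with
k-means (k-means++ seeding, 10 restarts, fixed seed). k = 13 is pinned to
mirror the study (capped by cohort size at smoke scale); a
silhouette-maximizing scan is available instead. Because a centroid has no
generating parameter set, each cluster's representative is the member nearest
its centroid — it can be re-simulated.

## Sensitivity analysis

PRCC of every sampled parameter against the final (day-300) concentrations of
stem cells and the three circulating lineages: rank-transform everything,
partial out all other parameters by linear regression on ranks, correlate the
residuals; p-values from the t statistic with n − 2 − (p − 1) degrees of
freedom, Benjamini–Hochberg adjusted across parameters per output. Constant
or duplicated parameter columns are flagged undefined rather than computed.

## AML screens and survival

AML is seeded as one cancer stem cell (2×10⁻⁴ cells/µL ≈ one cell in 5 L of
blood) into a healthy equilibrium and integrated on a daily grid until the
death threshold or 550 days. Diagnosis is the first day blasts exceed 20% of
marrow or blood AND cancer progenitors exceed 1 cell/µL, and must occur
within 365 days of initiation — the leukemia is allowed one year of clonal
accumulation, so indolent clones are never diagnosed; this window is what
bounds post-diagnosis survival (a diagnosed clone has grown ~7 orders of
magnitude within a year, hence its net growth rate forces death within a few
months). Death is the first crossing of 3×10⁵ cells/µL in marrow or blood
(first crossings linearly interpolated). Survival = death − diagnosis.

The cancer-parameter screen draws Latin Hypercube samples of (dMc, aMc2,
mrMc2, mbMc) within the published bounds — death and mobilization
1e−4×..1× the healthy monocyte rates, self-renewal 0.01×aM2..1, mitosis
0.5×..30× mrM2 (the printed upper bound "30" is read as a multiple of the
monocyte mitosis rate for dimensional consistency; an absolute 30/day
override exists). One shared reference table (the nominal fixture's monocyte
rates) is used for all representatives; per-representative references are
available but let each cluster's pinned mitosis rate set its own survival
scale, which buries the pooled self-renewal correlation under between-cluster
variance. Correlations with survival are Spearman rank correlations
(log10 for rates, raw for the self-renewal fraction): survival is roughly
inversely proportional to the net growth rate, so it is strongly non-linear
in the log-sampled rates and Pearson correlations understate the monotone
association; Pearson is available via configuration. Per-cluster and pooled
values are reported with p ≥ 0.05 cells masked. The neutrophil-derived
variant repeats the screen with neutrophil reference rates.

## Synthetic data

The clinical transplant-recovery counts behind the overshoot and damping
thresholds are IRB-protected and are emulated, never reproduced: pseudo-panels
simulate accepted parameter sets through the protocol, subsample daily over
~60 days, apply multiplicative lognormal noise of configurable CV (default
emulating ~25–30% count variability), and give a Bernoulli(15%) subset a
transient neutrophil overshoot bounded below the 12× rule. These panels
emulate nadir/recovery/overshoot shapes and measurement noise; they do not
emulate transfusions, infections, growth-factor support or irregular sampling,
so tests passing on them show the pipeline's logic is correct, not that the
model fits any real patient. Separatrix and clustering oracles are synthetic
with stored ground truth (a known linear log-space boundary; planted dynamic
families).

## Problem sizes

The study's screens use 10⁵ Latin Hypercube samples per stage and 625 cancer
samples per representative. This package's default analyses, tests and the
acceptance script run the same pipeline at desk scale — 1200–1500 samples per
uni-lineage screen, 500–1000 constrained multi-lineage samples, and ≥100
cancer samples per representative — chosen so a full run completes in minutes
on one CPU while leaving every stage statistically interpretable. Acceptance
counts therefore differ from the study's; the qualitative properties
(accepted fractions below 10%, the inverse self-renewal/mitosis relationship,
overshoot damping in the multi-lineage cohort, the survival correlations) are
the reproduction targets. Where the cohort yields fewer than 13 accepted
patients, k is capped at the cohort size.

## Numerical choices

LSODA (stiff-capable) with rtol 1e−6, atol 1e−9 cells/µL; sub-tolerance
negative excursions (> −1e−6) are floored to zero, larger ones mark the
trajectory as failed; right-hand-side singularities from runaway states are
caught and flagged as solver failures. Equilibria are classified trivial when
all states end below 0.01 cells/µL. The compiled (numba) and pure-Python
right-hand sides are the same function; results do not depend on which is
active. All randomness flows from per-stage seeds spawned deterministically
from one master seed.

## Known limitations

No explicit cytokine species, no transplantation or donor infusion, no
lymphocyte sub-types, no spatial marrow structure, no chemotherapy of the
simulated AML (survival screens are untreated by design). Desk-scale
constraint learning (tens of accepted sets rather than thousands) keeps the
separatrix boxes wide: acceptance fractions are lower than the study's, the
accepted cohort includes virtual patients with low (cytopenic) final counts
when the one-sided clinical bounds are in force, and the multi-lineage
overshoot-damping comparison is under-powered at these arm sizes — the effect
shows in the distribution tails but the rank test does not reliably reach
significance with a few dozen overshooting trajectories per arm.
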