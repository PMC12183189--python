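# Methods

## Kinematic model and its assumptions

The kinematic stage treats root growth as steady: the spatial pattern of
expansion is constant over the two-day observation window, so material
derivatives reduce to spatial ones. Under that assumption the cell flux
(cells per file per hour crossing any position) is constant along a cell
file and equals the meristematic production rate, which justifies the
velocity reconstruction v(x) = (E/ℓ_final)·ℓ(x) from a cortical
cell-length profile ℓ(x) and the overall elongation rate E. E itself is
the difference between mean axial lengths at the day-15 and day-17
harvests divided by two days; destructive harvesting means different
plants at each day, so E carries sampling noise of order
σ·√(2/n)/2 cm day⁻¹ for plant-to-plant SD σ.

The displacement-velocity curve is the four-parameter logistic
v(x) = a₂ + (a₁−a₂)/(1+(x/x₀)^p). Fitting is bounded least squares
(`scipy.optimize.curve_fit`) with a₂ > a₁ ≥ 0 and x₀, p > 0,
initialised at a₁ = min v, a₂ = max v, x₀ at the half-range crossing,
p = 4, with a fixed schedule of up to four perturbed restarts. The
goodness-of-fit R is the Pearson correlation between observed and fitted
velocities; the alternative reading √R² of the regression is numerically
indistinguishable here and the choice is surfaced in the fit object. The
relative elongation rate is the analytic derivative of the fitted curve,
never a numerical derivative of noisy data.

Radial plus tangential expansion follows the classical continuum
formulation r(x) = v·d ln A/dx with A = πd²/4 from the diameter profile;
because d ln A/dx amplifies measurement noise, the gradient is taken
after a short boxcar smooth (default width 5 grid points; width 1
disables it). Root volume per unit length is taken equal to the
cross-sectional area (cylindrical element), so the volumetric expansion
rate is (REL + radtan)·A. The identities relvol = rel + radtan and
volrate = relvol·area are enforced at container construction, not merely
tested. Profile algebra happens on a common 0.1 mm grid over the apical
12 mm; integrals use the trapezoid rule. Positions are mm from the
root-cap junction; the root cap itself carries no kinematic grid and
belongs to region R1 only for sampling bookkeeping.

Growth-zone extent is defined as the first position beyond the REL peak
where REL falls below 5% of its peak (linearly interpolated between grid
points). A monotone REL profile has no deceleration phase and is an
error, not a zero.

## Water relations and the deposition framework

Turgor is Ψ_P = Ψ_W − Ψ_S. Osmotic adjustment between treatments is the
drop in Ψ_S; it is "complete" when turgor changes by at most 0.05 MPa, a
package tolerance chosen at roughly the resolution of psychrometric
measurements (no published tolerance exists for this call). The
solute-deposition computation D(x) = d(c·A·v)/dx is a steady-state
continuity framework for separating "more solute deposited" from "less
water deposited": it is exercised on synthetic fields only and is
flagged as a framework, not a reproduced measurement. Its per-region
integrals are checked against the flux differences across region
boundaries (fundamental theorem of calculus) on every run.

## Omics statistics

Metabolite preprocessing is locked to impute → median-scale → ln:
missing cells take the feature's observed minimum, every feature is
divided by its median (making the post-scaling median exactly 1), and
the natural log prepares the values for t-testing. Running the steps in
another order changes results, so `preprocess` warns when asked to.
Group comparison uses Welch's unequal-variance two-sample t-test with
Welch–Satterthwaite degrees of freedom (the two-sided p-value), BH
step-up FDR within each region across features, and a fold change
computed as the ratio of WD to WW arithmetic means on the scaled,
imputed, pre-log data (a geometric-mean option exists). The differential
gate is p < 0.05 AND q < 0.10 AND (FC ≥ 1.5 OR FC ≤ 1/1.5). Transcript
tables arrive as per-region log2FC values (upstream read mapping and
normalisation are out of scope) and are only thresholded and counted;
the transcription-factor filter (log2FC ≥ 1.2, mean count ≥ 5) is
two-sided by default with a one-sided flag. PCA is centered (optionally
scaled), computed with the exact SVD solver for reproducibility.

## Pathway topology analysis

Enrichment is the upper-tail hypergeometric probability of the overlap
between the hit list and pathway members within the measured-compound
universe, BH-adjusted across pathways. Impact is the sum of relative
betweenness-centrality weights of the hit members: betweenness is
computed on the (possibly multi-component) pathway graph, isolated
members receive a uniform floor 1/|members| so compounds absent from the
edge list still contribute (configurable), and weights are normalized to
sum to 1 per pathway. Dominance requires −log₁₀p > 2, impact > 0.1 and
FDR < 0.1; the stricter raw-p < 0.01 gate used in some tools is the
first of these and both are exposed as named thresholds. Pathway
libraries are user-supplied as GMT membership plus a TSV edge list; the
packaged six-pathway library is a synthetic toy over the 21
effect-carrying metabolites, sufficient for exercising the engine, and
no live database is queried.

## Concordance classification

The transcript–metabolite integration is formalized as a
direction-consistency rule over mapped enzymatic steps. The enzyme map
is data, not code: each record names a metabolite, a step, a role
(synthesis, degradation, or competing — a branch that diverts precursor
flux away from the metabolite) and its transcripts, so pathway logic
like "competing branch attenuated ⇒ supports accumulation" is encoded
by the map. A step supports an accumulating metabolite when a synthesis
transcript rises or a degradation/competing transcript falls past the
threshold (default |log2FC| ≥ 1, the relaxed transcript tier), mirrored
for depleting metabolites. The packaged transcript table for the mapped
enzymes is a constructed synthetic stand-in (so named in its filename)
encoding the qualitative pattern of the study system: proline-synthesis
steps up, the competing pipecolate branch down, the saccharopine-forming
step unchanged.

## The synthetic-data generator

The generator produces every pipeline input as a pure function of
(scenario, seed), using independent sub-streams per generator so adding
one draw never perturbs another. What it emulates, and the packaged
calibration:

* **Cohorts** — two harvests (days 15/17) of distinct plants; lengths
  Gaussian with SD 1.0 cm around a 10 cm day-15 mean, 9 plants per day.
  WW elongation 3.08, WD 3.13 cm day⁻¹.
* **Cell-length profiles** — ℓ(x) = ℓ_final·v(x)/E from the scenario's
  logistic truth, clipped to ℓ_final beyond the plateau start, with
  optional multiplicative lognormal noise. Mature cell lengths are
  derived from the printed rates and fluxes: 156.9 µm (WW,
  1.28333 mm h⁻¹ ÷ 8.18 cells h⁻¹) and 169.8 µm (WD).
* **Velocity truth** — a₁ = 0.05 mm h⁻¹, a₂ = E. The WW (x₀ = 3.24228,
  p = 2.90058) and WD (x₀ = 4.63656, p = 3.77406) shape parameters were
  solved end-to-end through the measurement path (noiseless profile →
  velocity → fit → REL) so that the *measured* WW geometry lands at a
  REL peak of 2.5 mm and a growth-zone extent of 10.0 mm, and the WD
  volumetric-expansion peak sits 1.5 mm basal of WW with an 11.5 mm
  extent. The basal shift is carried phenomenologically by the WD
  velocity curve, since the underlying treatment differences are not
  published as profiles.
* **Diameter profiles** — exponential taper from d_tip to d_mature
  (WW 0.90→1.10 mm over 4 mm; WD 0.95→1.18 mm over 5 mm, wider than WW
  at every position).
* **Metabolomes** — three lognormal replicates per treatment × region
  with CV 0.10, WD/WW geometric-mean ratios equal to the packaged
  per-region fold-change table (21 metabolites), 548 unaffected
  background compounds padding the universe to the study scale of 569
  identified compounds, and 5% missing-at-random masking.
* **Transcript tables** — 45,764 transcripts per region assigned to
  up/down tiers with probabilities matching the packaged per-region
  tier counts, magnitudes drawn per tier (2 + Exp(0.7) beyond the
  |log2FC| ≥ 2 tier, uniform on [1, 2) in the relaxed tier, clipped
  Gaussian background), plus lognormal mean counts for count filters.

Noise magnitudes are free parameters, not estimates — replicate-level
variances are not published. Noise families were fixed once: additive
Gaussian for lengths (differences of means are the estimand),
multiplicative lognormal for strictly positive measurements. The
generator does not emulate abundance-dependent missingness; under
missing-at-random masking, minimum imputation occasionally injects a
control-level value into a stressed group and genuinely strong effects
can drop below significance in a 3-replicate demo run — a faithful cost
of the imputation scheme, visible in the demo report. Nor does it
emulate images, raw spectra, sequencing reads, or correlated noise
across metabolites; passing tests demonstrate correctness of the
estimators under the stated noise model, not robustness to structured
artefacts of real instruments.

## Numerical choices and degenerate inputs

Logistic fitting rejects flat profiles and fewer than five points;
non-convergence after the restart schedule is an error. Betweenness
weights of a single-member pathway are 1; a graph with no interior nodes
gets uniform weights. Welch's test with two zero-variance groups is an
error unless the means are equal (then t = 0, p = 1); inside the
differential driver a zero-variance unequal-means feature is treated as
infinitely significant rather than aborting the scan. Fold changes
require a positive control mean. BH is applied within region across
features (metabolites) and across pathways (enrichment). Hypergeometric
tails use the exact distribution, validated against rational-arithmetic
enumeration for all universes up to 25.

## Problem sizes

The test suite and acceptance script run at the study's own scale
(9-plant cohorts, 121-point profiles, 3 replicates × 569 metabolites,
45,764 transcripts × 3 regions) except where estimator convergence is
the point: fold-change recovery uses 300 replicates and cohort-rate
recovery 1,000 plants, both completing in seconds. The full demo
pipeline runs in about two seconds on one core.

## Known limitations

Time-resolved (non-steady) kinematics, marker-tracking velocimetry,
psychrometer calibration, water-deposition-rate estimation, read
alignment and GO/KEGG database queries are out of scope. The concordance
rule is a deliberate formalization of a narrative integration; its
threshold and the enzyme map determine the calls, and both are exposed
as data/configuration. Pathway results on the packaged toy library
exercise the engine but are not biological claims.
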