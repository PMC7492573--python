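# Methods

## Scope and data model

The package consumes already-quantified PTR-TOF-MS output: per-cycle
concentrations in ppb for each m/z channel. Instrument-side processing —
counts-to-ppb calibration, mass-axis calibration, peak integration — is out
of scope. A measurement (`SampleRun`) is a background block (VOC-free N₂,
180 cycles ≈ 3 min by default) followed by a sample block (2,700 cycles ≈
45 min), matching the acquisition scheme the pipeline's windows assume.

## Synthetic experiments

The generator emulates the statistical structure the analysis relies on,
not the instrument physics.

**Trace shapes.** Headspace depletion under flushing motivates an
exponential decay c(t) = c₀·e^(−kt); the default k = ln 2 / 2700 halves a
trace over the sample block, large enough for the kinetics classifier's
δ = 0.2 to detect (observed ρ ≈ −0.49) yet slow enough that the cycle-21–80
window still sees ≈ 0.99 c₀. Constant traces are flat at c₀; rising traces
ramp linearly from 0 to c₀. These shapes are stand-ins — real fungal
emission kinetics are more varied — so passing tests demonstrate the
pipeline's behaviour on its stated assumptions, not instrument fidelity.

**Noise.** Additive Gaussian, independent per cycle and channel, with a
default SD of 0.02 ppb in both blocks (configurable per compound). This is
the simplest model consistent with characterizing background noise by its
standard deviation; real PTR noise is count-based and
intensity-dependent. Negative excursions are kept unclipped so the
net-negative filter is exercised. With the default SD the LOQ is ≈ 0.2 ppb,
an order of magnitude below the weakest planted isotopologue (≈ 0.35 ppb),
which is what makes exact recovery the expected outcome rather than a
coin flip.

**Roster (default scenario, 400 channels).** 8 decaying fungal compounds at
3–20 ppb; four carry formulas (C₂H₆S, C₄H₈O₂, C₆H₄O, C₈H₈O₂) and emit ¹³C
isotopologue companions at +1.003355 Th with the natural-abundance M+1/M
ratio, giving 12 decaying fungal channels — the planted set. 18 fungal
constant/rising channels exercise the kinetics filter; 60 plant compounds
and 300 ubiquitous ~1–3 ppb nuisance compounds populate the matrix; 10 junk
channels (out-of-range m/z, exclusion-list masses, empty channels) exercise
each reduction flag. Unstructured m/z values are drawn once from a fixed
internal generator: the roster is part of the experimental design and does
not vary with the measurement-noise seed.

**Treatments.** Plant control, fungal control and co-cultivation, three
replicates each, expressed as per-association multipliers (fungal compounds
are absent from plant controls, present at 0.7 in co-cultivation, i.e.
intermediate). Additional isolates or media are additional treatments.
Per-run seeds derive from the scenario seed by fixed integer arithmetic.

## Reduction conventions

* Cycle indexing is 1-based: "the first 60 cycles excluding a 20-cycle
  stabilization period" are cycles 21–80 inclusive.
* The background SD uses the population estimator (divisor n): the LOQ
  characterizes the noise of a fixed window rather than estimating a parent
  population. Configurable via `sd_ddof`.
* The LOQ comparison applies to the net (background-subtracted)
  concentration, and the m/z range [15.993, 300.066] is inclusive at both
  ends.
* The shipped exclusion list (H₃O⁺ and its water clusters, O₂⁺, NO⁺, CO₂H⁺,
  NO₂H⁺, a calibrant-gas fragment; tolerance 0.005 Th) is a placeholder for
  the instrument-specific list, which is fully user-overridable.
* Feature-matrix fill-in: a channel retained in at least one sample
  contributes its net concentration to every sample where that value is
  computable, even if sub-LOQ or negative there, else 0. This preserves the
  geometry the ordination sees; zeroing filtered cells would manufacture
  artificial contrasts.

## Selection conventions

* Scaling uses the population variance, the classic ordination
  normalization; with n samples the correlation matrix has trace p, so each
  compound's cos² sums to 1 over all components — a tested invariant.
* "Loading" means the variable coordinate (correlation with the component,
  eigenvector × √eigenvalue), the convention of the ordination toolkits
  this threshold style comes from. Raw eigenvector entries are available
  via `loading_kind="eigvec"`.
* The cos² criterion is the **sum** over dimensions 1–2 (a per-dimension
  AND variant is available via `cos2_mode="each"`); the boundary value 0.25
  is kept, while the loading threshold −0.20 is strict (a coordinate of
  exactly −0.20 is discarded).
* PCA axes are sign-ambiguous, so dimension 1 is oriented to make the mean
  fungal score negative before the signed threshold is applied; selection
  is invariant to eigensolver sign flips and to sample order (both tested).
* Kinetics are judged on the mean trace across fungal-control replicates
  (plant-side channels never reach this stage because they fail the loading
  filter). δ = 0.2 and ε = 1e−9 are configurable; δ is small enough to
  catch a halving decay (ρ ≈ −0.5) and large enough that window noise
  (SE ≈ 0.003 ppb) cannot flip a constant channel.
* With only 9 samples, unstructured channels have appreciable random cos²
  (expected ≈ 0.25 in the dim-1/2 plane), so the intermediate funnel counts
  run larger than the structured-channel counts alone; the kinetics stage
  is what makes the final set exact.

## Formula assignment

Enumeration is exhaustive over element-count bounds (default C≤20, H≤40,
N≤3, O≤6, S≤2), constrained by H ≤ 2C + 2 + N and RDBE = C − H/2 + N/2 + 1
≥ 0, with candidates ordered by |mass error|, then fewer heteroatoms, then
ascending C. The default tolerance of 5 mTh absorbs realistic
measured-vs-theoretical discrepancies of a few mTh. The proton mass
(1.007276 Da, not the H-atom mass) is added because PTR transfers a bare
proton. Reported m/z round half away from zero to 3 decimals. The isotope
model is ¹³C-only; ²H/¹⁷O/³³S contribute < 1 % of M+1 for these species.
Formula assignment is tentative by construction — isomers (e.g. dimethyl
sulfide vs ethanethiol) are indistinguishable — and fragment ions are not
predicted.

## Phenotyping

Fv/Fm = (Fm − F0)/Fm on a plant mask, with pixels below an Fm floor
excluded (the floor stands in for the commercial software's opaque
background masking); out-of-[0,1] values indicate corrupt input and are
returned unclipped. The anthocyanin index is the modified anthocyanin
reflectance index (1/R550 − 1/R700)·R_NIR with configurable band names,
since the camera's exact band centers are unpublished. The chlorophyll
index formula is likewise unpublished; the default (1/R700 − 1/R_NIR)·R_NIR
is an explicit stand-in and any per-band expression can be injected. Class
distributions use half-open classes with a closed final class and clip
out-of-range pixels into the end classes, so fractions always sum to 1.
Default edges (five Fv/Fm classes on [0,1], eight classes for the
reflectance indices) are overridable.

## Growth statistics

Fold changes are reported as max/min of the two means with an explicit
direction, rounded half away from zero to one decimal (24.8/3.5 = 7.0857 →
7.1); the unrounded ratio is always retained. Routing is a pure function of
the assumption p-values: any per-group Shapiro-Wilk p ≤ α or Levene p ≤ α
sends the data down the non-parametric branch (per-group checking rather
than residual checking is a documented choice, switchable in principle by
pre-transforming the table). Component tests are delegated to scipy and
statsmodels; Dunn's post hoc (rank-based z with tie correction, Bonferroni
adjustment) is implemented here because no installed library provides it.
One-sided tests take the direction of the observed difference, the
convention for treatment-vs-control growth claims. Groups need ≥ 3
replicates (Shapiro-Wilk is undefined below that). Compact letter displays
derive from the pairwise significance matrix by insert-and-absorb.

## Problem sizes and determinism

Tests and the acceptance script run the full cascade at the scenario's
native size (9 runs × 400 channels × 2,880 cycles, ≈ 0.5 s per experiment)
over 20 seeds, and use smaller matrices (≤ 8×8) where a dense
eigendecomposition oracle is the point. All randomness flows from explicit
seeds; hypothesis-based property tests are derandomized.

## Known limitations

* The generator's kinetic and noise models are deliberately minimal; exact
  recovery of the planted set shows the pipeline implements its rules
  correctly, not that the rules are optimal for real headspace data.
* The exclusion list and the phenotyping class edges ship as plausible
  placeholders for unpublished instrument-specific values.
* Intermediate funnel counts depend on sample size through the random-cos²
  effect noted above; only the final decaying-compound set is a stable
  quantity at n = 9.
* No GC-MS spectral matching or retention-time confirmation: identification
  stops at formula candidates plus isotopologue support.
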