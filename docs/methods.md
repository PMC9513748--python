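# Methods

This note documents the models, parameter choices and numerical
decisions behind `sersev`, what the synthetic cohorts do and do not
emulate, and the package's known limitations.

## Data model

The unit of analysis is a single-vesicle SERS fingerprint: an
intensity vector on a shared, uniform, endpoint-inclusive wavenumber
grid, by default 553–1581 cm⁻¹ with 1023 points (spacing ≈ 1.006
cm⁻¹).  A cohort stacks fingerprints with per-spectrum metadata
(spectrum id, donor id, group ∈ {GC, control}, fluid ∈ {tissue, blood,
saliva}); invariants enforced at construction are unique spectrum ids,
one group per donor, finite intensities and grid agreement.  Tables
are plain CSV (long or wide dialect) written with shortest
round-tripping float reprs and read with round-trip float parsing, so
I/O is bit-exact; a JSON manifest (grid, counts) accompanies each
table.  Spectra from other instruments can be brought onto the grid by
linear interpolation only — smoothing belongs to preprocessing, and
extrapolation outside the native span is refused.

## Preprocessing

Per spectrum, in order:

1. **ALS baseline** (Eilers-style asymmetric least squares): the
   baseline z minimizes Σᵢ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)², with weights
   iteratively reset to p where y > z and 1−p elsewhere, solved
   sparsely (second-difference penalty matrix is pentadiagonal).
   Defaults λ = 1e5, p = 0.01, 10 iterations; iteration stops early
   when the weight vector is unchanged.  λ = 1e5 is a standard
   operating point for broad fluorescence under ~1 cm⁻¹-spaced Raman
   spectra: stiff enough to ignore bands a few tens of cm⁻¹ wide,
   compliant enough to follow the fluorescence envelope.
2. **Savitzky–Golay smoothing**, window 11, polynomial order 3 —
   narrow Raman bands (~10 cm⁻¹ ≈ 10 points) survive while
   pixel-level noise is averaged out.  Edges are handled by evaluating
   the polynomial fitted to the first/last full window off-center.
   This choice (rather than padding) preserves the filter's defining
   property everywhere: *any* polynomial of degree ≤ 3 passes through
   unchanged; reflect-style padding would break that at the edges.
3. **Min–max normalization** to [0, 1] (exact 0 minimum and 1
   maximum), making fingerprints comparable across the large
   enhancement-factor variation between hotspots.  Normalization is
   affine-invariant, so the arbitrary intensity scale of each
   measurement drops out.

A spectrum that is constant (relative peak-to-peak ≤ 1e-12) carries no
fingerprint; it is dropped before the chain runs and counted in the
preprocessing log, rather than being mapped to zeros that would
corrupt every distance downstream.  The near-constancy check sits on
the *raw* spectrum because an exactly constant input leaves a
numerically-almost-constant residual after baseline subtraction, which
a strict max > min check would happily normalize into amplified solver
noise.

## Fingerprint similarity and the threshold τ

Euclidean distance on preprocessed fingerprints is the default metric
(1 − Pearson correlation is available as the pluggable alternative).
Hierarchical clustering uses scipy's agglomerative linkage; `hcluster`
defaults to average linkage.

The single data-driven knob of the pipeline is
**τ = the 95th percentile of leave-self-out nearest-neighbor
distances within the control group**.  Two control fingerprints closer
than τ are "as similar as control vesicles typically are to each
other"; τ therefore operationalizes "shares common spectral features"
and adapts automatically to the cohort's noise level.  τ is reused as
the relabeling threshold, the type-clustering cut height and (averaged
over fluids) the cross-fluid matching tolerance.

## Label correction (PP extraction)

Patient samples are mixtures of disease-specific and normal vesicles.
For each biofluid separately, every patient fingerprint is compared to
the control set: nearest-control-neighbor distance ≤ τ ⇒ the spectrum
is a normal vesicle and is relabeled "control"; otherwise it belongs
to the patient-unique population (PP ≡ PT/PB/PS per fluid) and keeps
"GC".  The correction is a single deterministic pass — no EM-style
iteration — and is monotone in τ (PP only shrinks as τ grows).
Relabeled spectra stay in the training set as controls rather than
being discarded: they are informative examples of normal vesicles.

**Evaluating the benefit.**  `compare_relabel_cv` runs both label
schemes over identical 80/20 splits (stratified by raw donor group so
the splits cannot depend on the scheme) and scores both against the
*corrected* labels, which are the best available spectrum-level truth:
a normal vesicle from a patient genuinely is not a cancer marker, and
counting its "control" prediction as an error would punish the right
answer.  Under this convention the correction changes little where
label noise is small (tissue-like mixing, 70% patient-unique) and
helps substantially where normal vesicles dominate patient samples
(blood- and saliva-like mixing) — the clinically expected pattern.

## Classification

RBF-kernel SVM with fixed hyperparameters (no search):

* C = 1.0 on a **size-invariant penalty scale**: per-sample weights
  are inverse class frequencies normalized so each class contributes a
  total weight of 100 (an "effective n" of 200).  Besides compensating
  the class imbalance that relabeling creates, this makes the fitted
  decision function independent of dataset duplication — duplicating
  every training row changes nothing, which a plain per-point C would
  not guarantee.  Solver tolerance 1e-6 keeps that invariance tight.
* kernel bandwidth γ = 1 / (2·median²) with the median taken over
  pairwise distances of the unique training fingerprints (evenly
  strided subsample above 800 rows) — the standard median heuristic,
  deterministic, and computed from the training fold only.

Accuracy is the plain fraction of correct predictions.
Cross-validation draws, per round, an independent stratified 80/20
split per class, trains on the 80% and scores the disjoint 20%;
defaults are 20 rounds.  Round r uses the counter-based child RNG
`default_rng([seed, r])`, so reports are reproducible and rounds
independent.  LDA for visualization uses the eigen solver with
shrinkage 0.1 on the within-class scatter — with p = 1023 ≫ n the
unregularized scatter is singular, so some shrinkage is not optional.

## Donor-level validation (leave-a-pair-of-samples-out)

Spectrum-level CV lets one donor's spectra straddle the split, which
flatters accuracy.  The donor-level protocol holds out one GC and one
control donor per fold; τ, the relabeling, the bandwidth and the SVM
are all recomputed from the remaining donors, and each held-out
*sample* is scored by the mean signed margin of its spectra
(fraction-of-positive-calls is available as an alternative
aggregator).  Pairs are drawn uniformly without replacement until
every donor has been left out once — with 15 donors per group, 15
pairs per round, 150 evaluations over the default 10 rounds — and
ROC/AUC is computed per round over that round's 30 sample scores, then
averaged.  Equal group sizes are required (pairing is otherwise
ill-defined); unbalanced cohorts are rejected rather than silently
truncated.  Each evaluation records its held-out pair, training donor
set, τ and γ, so leakage absence is auditable after the fact.  If a
fold's relabeling leaves no PP spectra (τ from a very small training
control set can exceed every patient NN distance), that fold falls
back to raw labels with a warning instead of failing on a one-class
training set.

## Cross-fluid tracking

Within each fluid, PP fingerprints are clustered into vesicle types
and a tissue type is *tracked* when it has a mutually-nearest centroid
match within τ_track in blood **and** saliva; types present in fewer
than all three fluids are never reported.  Mutual nearest-ness
prevents chained many-to-one matches.  Two deliberate choices:

* **Single linkage, cut at τ**, for the type clustering.  τ is a
  percentile of *nearest-neighbor* distances; single-linkage merge
  heights are exactly nearest-neighbor distances between clusters, so
  the cut yields the connected components of the "within τ of a
  neighbor" graph — the same semantics τ has in relabeling.
  Average-linkage heights are mean pairwise distances, systematically
  larger, so an average-linkage cut at τ fragments the types (verified
  on generator output: 74 fragments for ~20 planted types, and only
  6/9 circulating types recovered, versus exact 9/9 recovery with
  single linkage at default noise).
* Mean spectra are computed on preprocessed (normalized) fingerprints,
  i.e. the count-weighted mean of the per-fluid centroids.

## Raman map analysis

A fine map scan is a rectangular lattice of stage positions (default
step 0.1 µm) with one spectrum each.  Band intensity is the
trapezoidal integral of the baseline-subtracted signal over
center ± halfwidth (default halfwidth 8 cm⁻¹); integration, not peak
height, is robust to one-point shift jitter.  Window edges between
grid points are included by linear interpolation.  Hotspot
localization takes the maximum after 3×3 mean smoothing; among
smoothed ties the highest raw pixel wins (so an isolated bright pixel
is still located exactly), then the lowest (row, column).
Co-localization is the Pearson correlation of flattened band maps.
The synthetic scene model convolves point emitters with an isotropic
Gaussian beam (default σ = 0.42 µm, making the spot ~1 µm across, the
diameter of a tightly focused laser).

## The synthetic cohort generator

What it emulates: two groups of 15 donors; 50–70 spectra per donor
sample; vesicle subtypes as sets of 4–8 Lorentzian bands drawn from a
29-band library spanning the grid (including the 1123 / 1270 / 1341
cm⁻¹ marker bands); shared, patient-unique and control-unique
subtypes, with 9 patient-unique types circulating in all three fluids
plus single-fluid distractors; per-fluid patient-unique fractions
0.7 / 0.4 / 0.15 (tissue / blood / saliva), modelling the dilution of
tumor vesicles in circulation; per-donor random subtype subsets
(carry probability 0.8), so no subtype is guaranteed pan-patient;
measurement effects — smooth random fluorescence baseline (quadratic
plus a broad Gaussian bump), lognormal global amplitude (σ = 0.25) and
per-peak height jitter (σ = 0.25), Gaussian peak-position jitter
(σ = 1.5 cm⁻¹) and additive white noise (σ = 0.05).

Control samples draw control-unique types with a fixed probability
0.1 rather than the per-fluid unique fraction: healthy donors are
dominated by the shared normal vesicle types, with only an
idiosyncratic minority.  The jitter/noise defaults were set once so
that relabeled cross-validated accuracy lands in the high-80s-to-90s
percent range typical of single-vesicle SERS diagnostics, with the
tissue > blood > saliva separability ordering driven entirely by the
unique fractions.  A `SimConfig.low_noise()` preset (jitter and noise
roughly 5× smaller) provides the well-separated regime used by
recovery tests whose ground-truth comparison assumes within-type
spread well below between-type distances.

What it does **not** emulate — and hence what passing tests cannot
show about real data: instrument wavenumber-calibration drift, cosmic
ray spikes, substrate-to-substrate enhancement heterogeneity beyond a
global amplitude factor, correlated (non-white) noise, hotspot
occupancy statistics of vesicle deposition, and any real biochemical
structure of vesicle spectra (the subtype templates are random band
sets, not measured fingerprints).  Recovery results on synthetic
cohorts demonstrate the *pipeline's* correctness under its stated
assumptions, not clinical performance.

Everything is deterministic under the master seed: donor-level child
RNGs are spawned as `default_rng([seed, salt, group, donor])`, so
cohorts, ground truth and map scans are byte-identical on rerun.

## Problem sizes used by tests and the acceptance script

SVM training dominates runtime, so the simulation-heavy checks use
scaled-down per-sample spectrum counts while keeping the full 15+15
donor design: the relabeling-recovery check runs the full 50–70
spectra/sample design (≈ 5 400 spectra); the cross-validation and
tracking checks use 20–28 spectra/sample (≈ 720 per fluid); the
leave-pair-out runs (150 SVM fits per cohort) use 12–16
spectra/sample (≈ 420 per fluid).  The relabeling-benefit and
recovery statistics quoted here are insensitive to these sizes beyond
wider round-to-round spread.

## Known limitations

* The "customized distance metrics" of the clustering step are
  exposed only as a plug-in point (euclidean, 1−Pearson); no claim is
  made about which metric best separates real vesicle types.
* Spectrum-level PP extraction matches individual spectra, not
  cluster-to-cluster; type-level matching can be composed manually
  from `fingerprint.assign_subtypes` but its behavior is not asserted.
* Donor-level ROC uses one aggregate score per sample; spectrum-level
  ROC is available behind a flag but conflates within- and
  between-donor variation.
* The LPOSO protocol requires equal group sizes by design.
* No probability calibration, hyperparameter search, confidence bands
  on ROC curves, or corrections for multiple biofluid comparisons.
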