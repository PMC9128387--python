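# Methods

## Scope and data model

`frnet` operates downstream of HFO detection: its inputs are per-patient
event catalogs (contact, onset time, subtype ∈ {RonO, RonS, fRonO, fRonS,
sharp_spike}, peak spectral frequency, peak power, duration), contact tables
(MNI coordinates in mm, anatomical region, SOZ flag) and patient metadata
(outcome, analyzed recording minutes). Raw iEEG parsing, event detection,
artifact review, electrode localization and montage handling are out of
scope; the catalog is treated as the single authoritative event list.

Contacts are the node unit. The headline event filter keeps fast-ripple
subtypes (fRonO, fRonS combined) with peak frequency **strictly** above
350 Hz — an event at exactly 350.0 Hz is excluded. Rates are exact event
counts divided by the analyzed duration in minutes.

Outcome labels: `responder`, `non_responder`, `no_resection_rns`,
`unknown`. The `no_resection_rns` category covers patients treated with
responsive neurostimulation only or not offered resection; they are mapped
to the non-responder class for binary classification (they did not have the
opportunity to respond to a resection) but kept distinct so the SVM-2
training profile can exclude them. The package uses this single category
for both roles; a registry distinguishing treatment from outcome at finer
grain would need an extra field.

## Networks

Three symmetric, non-negative, zero-diagonal weighted graphs per patient:

* **distance** (mm): complete Euclidean graph over FR-generating contacts;
* **rate–distance** (mm·events/min): `w_ij = d_ij (r_i + r_j)/2`; node rule
  = at least one filtered event; a second variant restricts nodes to the
  non-SOZ;
* **MI** (bits): pairwise mutual information between event-onset trains;
  node rule = at least `min_events_per_contact` (default 5) filtered
  events, operationalizing "too few events". Patients with fewer than two
  eligible nodes have no MI network; the three MI measures then propagate
  as missing values (NaN), and imputation handles them at classification.

### MI estimator

The estimator is this package's definition (the per-cell statistic for
spike-train MI is genuinely underdetermined — counts, presence or interval
values are all defensible — so the scheme is isolated behind
`estimate_mi` / `MIConfig` for replacement):

1. pool both trains' onsets; let `m` be the pooled count;
2. lay a uniform grid of `n = ⌊m / target_events_per_cell⌋` cells between
   the first and last pooled event (cell width =
   `target_events_per_cell` × mean pooled inter-event interval; the outer
   cells absorb the tails), default target 4;
3. per cell record whether each train fired (presence indicators);
4. return plug-in MI of the empirical joint presence distribution in
   log base 2.

Properties, all tested: exact symmetry in the arguments (entropies are
computed label-free, so the result is bit-identical under swapping); exact
invariance to a common time shift (the grid is anchored at the first pooled
event); `MI(x, x)` equals the plug-in entropy of x's presence distribution;
independent Poisson trains give ≤0.05 bits at 600 events/train (plug-in
bias ≈ 1/(2·n_cells·ln 2)); and MI responds monotonically to common-input
coupling strength.

Two designs considered and rejected. (a) Cells holding *exactly* the target
number of pooled events (boundaries at pooled-event midpoints): fixing the
per-cell total makes one train's count a deterministic complement of the
other's, so independent trains score ≈ H(count) ≈ 2 bits and coupling
*lowers* the statistic — measured, not hypothesized. (b) Raw counts on the
uniform adaptive grid: unbiased direction, but the joint count support
inflates the plug-in bias to ≈0.1 bits at realistic event numbers, swamping
weak coupling. Binary presence keeps the 2×2 support, and the adaptive
width self-normalizes the marginal firing probability to ≈ 1 − e^(−target/2)
regardless of rate, making edges comparable across contacts.

Short trains (a handful of events, the regime near the 5-event node
threshold) yield MI estimates dominated by small-sample noise; MI-network
contrasts at cohort scale are driven more by node composition and summed
strength than by individual edge precision.

## Graph measures

Path-based measures run on edge lengths: for distance and rate–distance
networks the weight *is* the length; for MI (correlational) networks length
= 1/weight, the standard conversion; zero weight = no edge. All-pairs
shortest paths via Dijkstra (`scipy.sparse.csgraph`); brute-force
Floyd–Warshall implementations live in the tests and the acceptance script
as independent oracles.

* **radius** = min over nodes of eccentricity (max shortest-path length).
  The graph-theoretic shortest-path definition is the default; a
  direct-adjacency variant (`radius_method="direct"`) is exposed because
  the two coincide on Euclidean distance networks but not on rate–distance
  networks. Conventions: empty or single-node network → 0 (a patient with
  no FR > 350 Hz has minimal network extent, not a missing value);
  disconnected network → radius of the largest connected component.
* **characteristic path length** = mean finite off-diagonal shortest-path
  length (infinite pairs excluded, i.e. largest-component convention);
  NaN below two nodes. These conventions keep every patient's features
  finite wherever a network exists.
* **local efficiency** (weighted): for node u with neighbourhood N(u),
  `E_loc(u) = Σ_{j≠h∈N(u)} (w_uj · w_uh / d_jh^{N(u)})^{1/3} / (k(k−1))`,
  where `d^{N(u)}` are shortest paths inside the induced neighbourhood
  subgraph — the standard cube-root weighted formulation; < 2 neighbours
  → 0.
* **nodal strength** = sum of incident edge weights.
* **MI strength difference** = Σ non-SOZ strengths − Σ SOZ strengths,
  unnormalized by default (a per-node-mean variant is exposed via
  `normalize_strength_diff`). Mean local efficiency is averaged over
  non-SOZ nodes; a constructible MI network with no non-SOZ nodes scores 0
  (no non-SOZ connectivity), distinct from the NaN of a missing network.

## Synthetic cohorts

The generator emulates the statistical skeleton of clinical stereo-EEG FR
catalogs; it makes no attempt at anatomical realism, raw voltage, seizures
or artifact structure, so passing tests demonstrate the pipeline's
correctness and discriminative behavior under the modelled structure — not
performance on real recordings, where rate magnitudes, non-Poisson
clustering (e.g. sleep-cycle modulation), detector false positives and
montage effects all intrude.

* **Geometry**: 8–16 linear depth electrodes × 7–15 contacts at 5 mm
  spacing (configurable) inside a ±70 mm MNI box; regions cycle through a
  fixed coding table that also supplies the mixed models' numeric location
  covariate. SOZ contacts (round(soz_fraction × n), default 10%) are
  clustered on the fewest electrodes that hold them (responder phenotype)
  or spread over ≥3 electrodes (non-responder).
* **Event trains**: per contact, homogeneous Poisson background plus
  events copied from a latent mother Poisson process by independent
  thinning with Gaussian timing jitter — a common-input construction whose
  expected rate is `base + p·mother_rate` and whose dependence is
  controlled by the thinning probability `p`. Hub-centred coupling (one
  mother, responders) concentrates dependence in the SOZ (thinning 0.4 SOZ
  vs 0.05 non-SOZ); decentralized coupling (three mothers assigned
  round-robin by electrode, non-responders) spreads it over the non-SOZ
  (0.3 vs 0.1). Mother rate 0.5/min, jitter 10 ms, 60 min records.
* **Rates**: responders 1.5/min SOZ vs 0.2/min non-SOZ; non-responders
  0.8/min everywhere. These magnitudes are calibration choices (per-contact
  FR rates by phenotype are not published quantities).
* **Peak frequency**: log-normal, σ = 0.15 log-Hz, intercept 5.470 with
  SOZ shift +0.178 (responders) and 5.646 with −0.352 (non-responders) on
  the natural-log Hz scale, plus a per-patient random intercept
  (σ = 0.05). By default samples are truncated (by resampling) to the
  250–600 Hz fast-ripple detector band.

One `numpy` SeedSequence per cohort, spawned per patient, makes every
emitted file a pure function of the spec; reruns are byte-identical.

### Band truncation vs parameter recovery

The detector band censors the frequency distribution: with intercepts near
log(250 Hz), a substantial fraction of each phenotype's log-normal mass
falls at or below the band edge, and a mixed model fitted to the truncated
data attenuates the SOZ shift by more than the recovery tolerance — an
analytic property of truncated normals, not an implementation artifact.
Real detectors censor identically, which is worth remembering when
interpreting fitted shifts near band edges. Parameter-recovery experiments
therefore generate with `freq_band=None` (truncation disabled) so the
fitted coefficient has a well-defined generative truth; default cohorts
keep the band.

## Statistics

* **AUC** = Mann–Whitney pair probability with ties counted ½; the
  threshold-sweep curve (all thresholds retained) integrates to the same
  value to machine precision, which is asserted.
* **Bootstrap CIs**: percentile 2.5/97.5 over 1000 resamples, stratified
  within label class (degenerate single-class resamples are impossible
  under stratification; a redraw guard remains for pathological inputs).
  The paired AUC-difference test reports the two-sided sign fraction of the
  resampled difference. Percentile (not BCa) is the simplest method
  consistent with a "1000-replica bootstrap" description.
* **Mixed models**: Gaussian LMM on log-transformed responses (frequency,
  power or duration — intercepts ≈5.5 are natural-log Hz of band events,
  so log-scale Gaussian modelling with identity link is the consistent
  reading), random intercept per patient, fixed effects SOZ + numeric
  location code, REML. Singular or non-convergent fits (including the
  single-patient case, where the random-intercept variance is
  unidentifiable) fall back to fixed-effects OLS, flagged in the result;
  the fallback provably coincides with the mixed estimate at zero
  between-patient variance.
* **Rank-sum + Holm**: two-sided Wilcoxon rank-sum (exact null for small
  untied samples), Bonferroni–Holm step-down over the declared comparison
  family, α = 0.05.
* **PCA**: SVD of the column-standardized measure matrix; patients with
  missing MI measures are excluded and listed; deterministic sign
  convention (largest-|loading| positive per component).
* **Binomial CIs**: Clopper–Pearson (exact beta quantiles). Printed CIs in
  small clinical test sets do not uniquely identify an interval variant;
  exactness and conservatism motivated the choice.

## Classifier

Predictors: SOZ radius, FR distance radius, FR rate–distance radius, and
the three MI global measures. Training z-scores features with training-set
statistics, sets the RBF bandwidth γ = 1/(2·median²) from the median
pairwise distance between standardized training points (operationalizing an
"automatically scaled" kernel), fits an SVC (C = 1), and calibrates a
sigmoid on the training decision scores (L2-regularized logistic fit, which
stays finite under perfect separation) so the 0.5 probability threshold is
meaningful; raw margin thresholding remains available via
`TrainedModel.decision_function`. Missing MI features are filled by the
training median (default) or a constant sentinel, with the imputation mask
retained; feature columns with no observed training value at all are
dropped, so a cohort without any constructible MI network degrades
gracefully to the radii. Profiles: `svm1` trains on all training patients;
`svm2` excludes `no_resection_rns` patients from training; `exclude_zero_fr`
drops patients with no FR network extent. Test patients never influence
imputation, standardization, bandwidth or calibration (asserted via the
training manifest). Models serialize to a versioned JSON bundle with the
kernel evaluated from stored support vectors, so loaded models reproduce
predictions bit-for-bit without pickling.

## Problem sizes and numerical choices

Cohort-scale experiments use 35 patients (21 responders + 14
non-responders; 110 contacts each, 60 min records) with a 22/13
train/test split — matching a realistic two-site cohort — and 50 seeds for
the discrimination Monte-Carlo; the mixed-model recovery runs on ≥20 000
events and its null calibration on 100 six-patient replicates; bootstrap
coverage uses 200 outer replicates of a binormal sample with true AUC 0.8
at n = 200/200; oracle equivalence uses 200 random graphs of ≤10 nodes at
1e-9 tolerance. Ties in SVM scores at exactly the threshold classify
positive (`≥`); shortest-path ties are irrelevant to the measures (only
lengths enter); the Holm implementation enforces monotonicity explicitly.

## Known limitations

* Poisson/common-input trains lack refractoriness, burstiness and state
  modulation of real FR processes.
* Under default phenotypes, responders rarely generate non-SOZ FR > 350 Hz
  nodes, so their non-SOZ MI local-efficiency feature is usually 0 and
  their non-SOZ rate–distance radius near 0 — a sharper separation than
  clinical cohorts show; classification numbers on synthetic cohorts are
  upper bounds, not forecasts.
* The MI estimator's plug-in values at the 5-event node threshold are
  noisy; edge-level inferences should use longer records.
* The location covariate is a numeric region index, a deliberately crude
  stand-in for anatomical effect coding; the coding table is replaceable.
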