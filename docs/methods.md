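# Methods notes

These notes record the modelling and analysis choices behind `somatomap`,
the reasoning where the design was genuinely open, and what the synthetic
cohorts do and do not establish.

## Homeostatic scaling model

The model is deliberately minimal: a linear read-out of bell-shaped
connection weights plus one multiplicative homeostatic correction. There is
no Hebbian or use-dependent learning, no spiking, and no time-resolved
dynamics — the homeostatic equilibrium is computed in closed form and
applied once. The claim the model supports is qualitative: a single
synaptic-scaling rule, combined with peripheral reorganisation and
inhomogeneous input statistics, reproduces the observed *pattern* of group
differences (peak shifts toward the deprived hand territory, raised
amplitudes, and the medial-to-lateral amplitude gradient). It is not fitted
to human data.

Parameters (per `ModelConfig`):

| parameter | default | units | role |
|---|---|---|---|
| `n_neurons` | 50 | nodes | length of the S1 strip |
| `peak_positions` | 5·(rank − ½) | nodes | bell centres, uniform in homuncular order |
| `bell_width` | 4.0 | nodes | tuning-curve SD |
| `offset` | 0.05 | weight | universal weak connectivity floor |
| `hand_gain` | 3.0 | — | palm/finger bell multiplier (dense hand innervation) |
| `cld_attenuation` | 0.15 | — | residual-nerve bell multiplier in CLD |
| `mna_hom` | 0.5 | activity | homeostatic target |
| stimulation `P` | 0.05 / 0.15 | probability | everyday input statistics (hand elevated) |

Choices worth recording:

* **Bell width and hand gain.** The qualitative observations constrain
  these jointly. Narrow bells (SD ≲ 3 nodes) make the group difference in
  the homeostatic scale factor at the foot/leg positions smaller than
  float64 resolution, so the predicted (real, but tiny) lateral shifts of
  distant body parts become numerically undefined; a hand gain below ~3
  fails to produce the amplitude dip of the upper face relative to the
  lower face in the CLD group. The defaults (SD 4.0, gain 3.0) sit in the
  interior of the region where all four observations replicate, with
  comparison margins at least 10⁶ × machine epsilon.
* **CLD attenuation spares the offset.** The 0.15 attenuation applies to
  the palm/finger bells only, not the constant offset. The offset encodes
  the universal weak connectivity of every body part to every node;
  attenuating it would impose a spatially uniform MNA deficit in CLD whose
  only topographic consequence is an artefactual tilt of all profiles
  toward the low-MNA medial strip edge — opposite to anything the
  deprivation itself produces.
* **Sub-node peak positions.** Observation checks compare parabolic
  (three-point) interpolated peak positions rather than integer argmax.
  The homeostatic tilt at body parts far from the hand moves the continuous
  peak by far less than one node (~10⁻⁴ nodes at the foot), which integer
  argmax cannot register. The integer `peak_node` (ties broken to the most
  medial node) is still reported on every profile.
* **Peripheral reorganisation and the MNA.** By default the CLD
  equilibrium uses the same independent stimulation probabilities as CTR
  (residual palm/finger nerves keep their 0.15), and the co-activation of
  residual nerves by arm stimulation affects only evaluation. The
  alternative reading — everyday arm use also fires the residual nerves
  during homeostatic adjustment — is available as `mna_costimulation=True`,
  which adds the arm probability to the residual-nerve probabilities in the
  MNA only.
* **Rudimentary variant.** No peripheral reorganisation (CLD palm/finger
  bells removed; offset floor kept), uniform probabilities 0.05, no hand
  gain, no co-activation. It reproduces the three group-difference
  observations but not the CLD amplitude gradient — the comparison that
  motivates the richer main model.
* **Hand centre.** The midpoint of the palm and finger bell centres
  (node 30 by default) anchors all "closer to the hand" comparisons.

## Topography

* Bins are indexed 0 (most medial) to n−1 (most lateral); tables carry the
  MNI-x coordinate per bin so the orientation is verifiable. Hemispheres
  may have unequal bin counts (49/48); mirroring matches by nearest |MNI-x|.
* A profile with no positive z anywhere is excluded (flagged, never
  silently dropped).
* **Double peaks.** A local maximum counts as a rival peak when its
  topographic prominence reaches 20% of the profile's global maximum; when
  rivals exist and a group-reference peak is available, the candidate
  nearest the reference wins (flagged `double_peak_resolved`). This
  mechanises a judgement made visually in practice, and the 20% threshold
  is a stand-in with no empirical calibration. The global argmax is always
  a candidate: by the prominence definition a peak riding the strip edge
  can earn arbitrarily little prominence despite being the governing
  maximum. Plateaus resolve to their most medial bin.
* The hand ROI is the mirrored thumb-peak bin plus eight bins medial and
  one lateral (10 bins); at strip edges it is clipped with a warning.

## Crossnobis RSA

* Distances average cross-products over all ordered pairs of runs, which
  makes the RDM exactly symmetric and unbiased under the null (estimates
  may be negative; only their distribution around zero is meaningful).
* Noise covariance is estimated from run-wise residuals (demeaned per run,
  pooled), shrunk toward its diagonal with the analytic optimal intensity
  (Schaefer–Strimmer); the intensity can be fixed via `shrinkage`
  (1.0 gives the diagonal-only estimator). Zero-variance voxels receive a
  small ridge and a warning.
* Distances are divided by the voxel count so values are comparable across
  ROI sizes; this convention is fixed here and recorded in the output
  metadata of the CLI.

## Behaviour indices

* Overlapping bouts of the same body part are merged before any duration
  is summed; simultaneous use of different parts counts fully toward each.
* **Co-use index.** The exponential Shannon entropy (Hill order-1 number)
  of per-task usage proportions, averaged over tasks. It equals the number
  of parts under perfectly even use, is lowered by uneven use, and sits
  just above 2 for consistently bimanual behaviour — the properties the
  index is described to have. The exact published formula is not available,
  so this specific functional form is a reasoned reconstruction; treat
  absolute values (not orderings) with care when comparing to published
  numbers.
* The 5×5 co-use matrix covers the five compensatory parts (residual arm,
  torso, lower face, legs, feet); the part set is a parameter.
* Mouth/chin use is analysed separately: a Pearson chi-square (no
  continuity correction) on the users/non-users × group table, and a
  pooled two-sample bootstrap (two-sided, add-one-smoothed p) for usage
  scores among users.

## Brain–behaviour analysis

* Behavioural deviance: participant minus peer-group mean usage percentage
  per part. The peer group is the age-matched controls; if a peer table
  containing the participant is supplied, their row is left out of the
  mean.
* Brain position deviance: |peak bin − mirrored thumb bin| divided by the
  control peer mean of the same quantity (ratio < 1 ⇒ shifted toward the
  hand). Parts with a zero control mean are dropped pairwise with a
  warning.
* Participant coupling: Spearman rho over the five paired deviances
  (average ranks for ties); zero-variance vectors give an undefined rho
  and the participant is excluded from group tests with a logged count.
* **Permutation tests.** Group-mean rho: within each participant the
  brain values are re-paired with the behavioural values independently per
  iteration; one-sided p against "greater than zero". Group difference:
  Welch two-sample t on participant rhos with a group-label-shuffling
  null, one-sided. Both use the add-one convention
  p = (1 + #{null ≥ obs}) / (1 + n_iter), so p is never zero and is
  floor-limited at 1/(n_iter + 1). The choice of Welch t as the observed
  difference statistic is ours; published difference statistics computed
  differently are not expected to be numerically reproduced.

## Synthetic cohorts

The generator reproduces the *statistical structure* the analyses assume,
at the study's sample-size skeleton (imaging 15/16/20/15; behaviour
16/15/17/16; 49 bins; 15 tasks):

* Bin profiles: Gaussian bumps (width 3 bins) with group-dependent centres
  (CLD shifted toward the hand anchor by 2–4 bins per part) and amplitudes
  (CLD 4.0 vs CTR 3.0 z), participant jitter (SD 0.8 bins), and spatially
  smooth AR(1) bin noise (lag-1 correlation 0.9, marginal SD 0.25 z).
  Smooth noise mimics profiles extracted from smoothed maps; with i.i.d.
  bin noise nearly every profile acquires a spurious rival peak, while the
  smooth default keeps the double-peak flag rate at the few-percent scale
  actually observed in such data.
* Usage tables: per task, each part's usage time is a clipped Gaussian
  around group-level mean fractions, realised as one bout per part. The
  group means were set so the recovered co-use indices land where the
  groups are described (controls just above 2, CLD children approaching 3,
  with CLD children > CLD adults > control adults).
* Pattern sets: condition means embedded by classical MDS so expected
  crossnobis distances equal the requested targets; betas and residual
  streams share the requested noise covariance.
* Coupled cohorts: a per-participant, per-part latent perturbs usage
  fractions and (with latent correlation `coupling`) displaces the same
  parts' peaks away from the hand, so behavioural deviance and the
  distance ratio correlate positively within participants.
  `coupling_for_target_rho` inverts the finite-sample expected Spearman
  for 5 pairs (Moran's formula), so record-level cohorts hit a requested
  mean rho; the full pipeline (bout coding → percentages; profiles → peak
  bins → ratios) attenuates the realised rho by roughly 0.1–0.2 through
  bin quantisation and measurement noise.

What the synthetic cohorts do **not** emulate: haemodynamics and GLM
estimation, anatomical surface geometry (bins are abstract), inter-rater
coding noise, covariance between body parts in usage, and real
distributional quirks of usage data (zero-inflation beyond the clipping,
heavy tails). Passing recovery tests therefore shows the estimators are
correct and calibrated under the assumed structure, not that the published
effect sizes would be recovered from real recordings.

## Calibration problem sizes

Simulation-based checks use sizes chosen to make their Monte-Carlo error
small relative to the tested tolerance: 2000 null pattern sets for
crossnobis calibration (mean within 3 SE of zero), 1000 record-level null
cohorts at 500 permutation iterations for the type-I error (95% binomial
band around 0.05), 200 cohorts for power at a true mean rho of 0.6
(threshold 90%), and four cohort replicates for peak-shift recovery
(within 2 SEM). The acceptance script re-runs all of these from a single
seed.

## Known limitations

* The model's distant-part peak shifts are orders of magnitude smaller
  than the empirical ones; the model explains direction and ordering, not
  magnitude.
* The co-use index and the double-peak prominence threshold are reasoned
  reconstructions of procedures that are not fully specified publicly.
* The brain-deviance ratio is undefined where a control group's mean
  distance is zero (a body part whose typical peak coincides with the
  thumb bin); such pairs are dropped rather than imputed.
* Peak positions are bin-quantised; sub-bin topographic effects are
  invisible to the empirical pipeline (unlike the model's sub-node
  interpolation, which operates on noiseless curves).
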