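# Methods

## Analysis model

The pipeline treats each electrode (probe) as a one-dimensional readout of
cortical population activity: after preprocessing, a probe's response to a
stimulus is a single scalar — the average band power in a post-stimulus
window divided by the average power in the −500…−100 ms baseline. The
representational geometry of a probe is therefore the matrix of absolute
scalar differences `RDM_ij = |r_i − r_j|` (the Euclidean distance between
scalars); the geometry of a network layer is the matrix of Euclidean
distances between its activation vectors. This per-probe RDM construction is
deliberate: depth recordings typically provide one electrode per subject per
area, so population RDMs are not available.

Mapping statistic: ρ_l = Spearman rank correlation between the probe RDM and
layer-l RDM upper triangles (average-rank ties). Spearman makes the mapping
invariant to any positive monotone renormalisation applied uniformly to a
probe's responses — important because "baseline normalisation" could equally
be a ratio, dB, or z-score convention; ranks are unaffected.

Significance: the response vector is reshuffled (destroying the
stimulus–response pairing while preserving the response distribution), the
probe RDM rebuilt, and ρ recomputed per layer. One permutation set is shared
across layers per probe, which keeps the layer profile comparable and halves
nothing statistically (nulls are exchangeable across layers). The empirical
p uses the plus-one convention, p = (1 + #{ρ_null ≥ ρ}) / (1 + n_perm), so
p is never zero and the minimum attainable p with n_perm = 1000 is
1/1001 < 0.001. Flags require p < α (default 0.001) which, one-sided,
implies ρ > 0; negative correlations are never summed into the mapping.

Implementation note: the RDM of a permuted response vector equals a joint
row/column permutation of the original RDM, so the upper-triangle rank
vector of every permuted RDM is a permutation of the original rank vector.
Each null correlation is then a dot product between standardised rank
vectors, which vectorises over permutations and layers; the observed ρ is
computed by the same formula (it matches `scipy.stats.spearmanr` to 1e-12,
and the Monte-Carlo p matches full enumeration for n ≤ 7 within Monte-Carlo
error — both asserted in the test suite).

Aggregation: cell (a, l) of the mapping matrix is the sum of significant
ρ of area-a probes at layer l divided by the number of area-a probes
significant for *at least one* layer (a probe significant at several layers
adds to several cells but counts once in the denominator). The alternative
normalisation — by all responsive probes in the area — is available via
`normalization="responsive"`; the two conventions coexist in the field and
differ only by a per-area positive factor, leaving argmax layers and
alignment unchanged.

Alignment: every significant (probe, layer) pair contributes one
(area code, layer code) point; areas are coded 0–4 in ventral-stream order,
layers 0–8. ρ_align is the Spearman correlation of those two integer
vectors, and its one-sided p comes from permuting the layer codes against
the area codes (assumption-free for heavily tied integer data; the analytic
large-sample Spearman test is available as `method="analytic"`). A
"best-layer-only" pairing (`pairs="best"`) is provided because a probe
significant at several layers can legitimately be read either way; the
default uses all significant pairs.

Volume is the plain sum of significant ρ over an area × layer subset —
additive over disjoint areas and monotone under subset enlargement. Visual
specificity divides ventral-stream volume by total volume. The complexity
ratio divides volume at {conv5, fc6, fc7} by volume at
{conv1–3, conv5, fc6, fc7}; conv4 (a transition layer) and fc8 (class
read-out, not a visual representation) are excluded from both sums. Zero
denominators yield NaN with a warning rather than an exception: a band
window with no significant activity is an expected outcome, not an error.

ROI comparison: per ROI (band × window), the alignment is recomputed on 1000
random probe subsets of half the mapped probes; subsets whose significant
pairs collapse to a single area or layer are redrawn (count reported).
Ordered ROI pairs are tested one-sided with Mann–Whitney U; the Bonferroni
correction uses m = n_roi² (for 15 ROIs, 0.005/225 ≈ 2.2e-5), counting
self-pairs and both directions, which matches the printed thresholds this
grid is conventionally reported with.

## Spectral preprocessing

Fixed stage order (permuting rejection and re-referencing changes σ
estimates and is forbidden by contract):

1. **Detrend + artifact rejection.** Each epoch is linearly detrended
   (least squares). Per probe, σ is the standard deviation over all samples
   of all its epochs; any epoch containing |x| ≥ 10σ is masked. The
   threshold is per probe, so global gain differences between probes are
   irrelevant.
2. **Bipolar re-referencing.** Contact k on a shaft is referenced to its
   inward (deeper) neighbour k−1; the deepest contact yields no channel.
3. **Morlet decomposition.** P(t, f₀) = |w(t, f₀) ∗ s(t)|² with a complex
   Morlet wavelet of temporal width σ_t = cycles/(2π f₀), truncated at
   ±5σ_t and L2-normalised. Cycles: 3 (θ), 4 (α), 5 (β), 6 (γ), 6 (Γ).
   Samples within 2σ_t of an epoch edge are flagged unreliable; with the
   −500…1000 ms epoch all three analysis windows (50–250, 150–350,
   250–450 ms) are reliable even at θ. Frequencies are averaged on a
   discrete grid (default 1 Hz step) within the band edges.
4. **Band power + normalisation.** Response = mean post-window power / mean
   baseline power. The ratio form is positive, dimensionless and
   gain-invariant; downstream statistics are rank-based, so any other
   positive monotone convention would give identical results.
5. **Responsiveness screen.** Two-sided Wilcoxon signed-rank over the
   per-stimulus (post, baseline) pairs (one trial per stimulus, so the n
   pairs are the n stimuli), Benjamini–Hochberg across probes at q = 0.05
   (the FDR level is a configurable default; no canonical value exists),
   keeping probes with corrected p < q *and* positive median difference —
   negative responders are dropped by design.

A memory-bounded variant (`band_power_from_epochs`) streams one frequency at
a time and accumulates window means, so the full probe × stimulus × freq ×
time power array is never materialised in grid runs.

## Synthetic data: what it emulates and what it does not

The generator plants a known area → layer mapping so that recovery can be
verified end to end.

- **Layer hierarchy.** Latent stimulus factors follow a unit-variance AR(1)
  chain over layers, F_l = c·F_{l−1} + √(1−c²)·ε (default c = 0.9),
  re-initialised after layer 5 to mimic the convolutional / fully-connected
  split: within-block layer RDMs correlate more strongly than cross-block
  ones. Each layer adds idiosyncratic latent-space noise (default scale 1.0
  relative to the shared factors) and embeds the result isometrically into
  its own feature space (feature counts decreasing from 4·n_latent to
  n_latent). Two deliberate choices deserve note. First, idiosyncratic
  noise is added *in the latent space*: high-dimensional white feature
  noise concentrates and barely perturbs distance ranks, producing no layer
  distinctness. Second, the latent space is anisotropic (component k has
  variance k^(−1), n_latent = 32): real network-layer representations are
  dominated by a few principal components, and without that anisotropy a
  scalar (one-dimensional) probe readout would carry almost no rank
  information about the layer's geometry. With c = 1 and zero noise all
  layers share one geometry exactly (isometric embeddings preserve
  distances), which pins the generator's calibration.
- **Probes.** Probes are laid out round-robin on shafts of 5 contacts over
  the ordered areas {17, 18, 19, 37, 20}; each probe targeting layer l
  responds with r = X_l·u/‖X_l·u‖ plus Gaussian noise of variance
  var(signal)/snr, where u is a seeded random unit direction. snr is this
  package's construct (no noise model exists for the original recordings);
  the default 10 represents a strongly stimulus-driven electrode.
  Distractor-area probes emit pure noise.
- **Epochs.** Raw epochs carry a carrier at the band's geometric-mean
  frequency with unit baseline amplitude, scaled to √response inside a
  0–500 ms burst (20 ms cosine ramps), over weak 1/f background noise
  (amplitude 0.05). Because power scales with amplitude², the planted
  response *is* the post/baseline band-power ratio, giving an exact
  analytic oracle for the spectral stage. Scalar responses are mapped to
  positive power ratios by a per-probe positive affine transform before
  epoch synthesis; absolute-difference RDMs are invariant to that
  transform, so planted rank structure survives the spectral round trip.

Not emulated: evoked-potential morphology, cross-frequency coupling,
between-probe correlated noise, non-stationary artifacts, and anything about
real images. Passing tests therefore demonstrate the *pipeline's*
correctness and calibration, not the physiological claim itself.

In the synthetic end-to-end grid, bipolar re-referencing is off by default:
the generator plants per-probe signals that are already local, and
differencing adjacent synthetic probes would destroy the planted structure.
The operation itself is exercised by its own unit tests.

## Numerical and design notes

- All generators and tests are pure functions of their arguments and a
  seed; the pipeline derives every stage seed from one master seed through
  a fixed `SeedSequence` spawn order recorded in the run manifest.
- Degenerate cases are explicit: a constant probe RDM is flagged and
  excluded from correlation (distinct from ρ = 0); alignment over pairs
  spanning a single area or layer raises; zero baseline power is an error.
- Random-weight control: a feed-forward stack of rectified random linear
  maps with weights ~ N(0, 0.01²) ("N(0, 0.01)" is read as a standard
  deviation; configurable). It is a generic untrained hierarchy, not an
  architectural replica — the pipeline consumes only activation matrices,
  and the control's role is "hierarchy without learned features".
  Pretrained-network activations enter the same way, as matrices via the
  documented file layout; no deep-learning runtime is involved.
- Default problem sizes in the bundled demo configuration (60 stimuli,
  4 probes/area, 1000 permutations, 100 subsets) are chosen so the full
  5-band × 3-window grid completes in well under a minute per ROI on one
  CPU; the full-scale defaults (250 stimuli, 10,000 permutations, 1000
  subsets) are the canonical study conditions.
- Known limitations: with ~50 probes and α = 0.001, occasional genuine
  realization-level correlations between a probe and a non-target layer
  pass the permutation screen (the test is correctly calibrated — the
  correlation is real in that realization); a single such far-off pair can
  pull ρ_align a few hundredths below its typical value on some seeds.
  Larger stimulus counts shrink this effect (at 250 stimuli the planted
  layer is recovered for ≥95% of probes).
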