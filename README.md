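# rsalign

Representational-similarity mapping of band-limited intracranial responses
onto the layer hierarchy of a deep network.

## The problem

Object recognition unfolds along the ventral visual stream (Brodmann areas
17 → 18 → 19 → 37 → 20) as a sequence of increasingly complex feature
transformations. Deep convolutional networks implement an analogous
hierarchy (pixels, conv1–conv5, fc6–fc8). Given depth-electrode recordings
— one scalar, baseline-normalised band-power response per probe per
stimulus — the question is *which frequency bands, in which post-stimulus
windows, carry activity whose representational geometry climbs the network
hierarchy in step with the cortical hierarchy*.

`rsalign` is for researchers who have (or simulate) such recordings and
layer activation matrices, and want the full analysis chain: spectral
preprocessing, per-probe representational similarity analysis (RSA) with
permutation significance, area × layer mapping matrices, and the aggregate
alignment / volume / specificity / complexity statistics — plus a
synthetic-data module that plants known structure so every stage is
verifiable without restricted patient data.

## The method

For a probe *p* with scalar responses *r₁…r_n* to *n* stimuli, the probe RDM
is `RDM_ij = |r_i − r_j|`; for a layer *l* with activation vectors *v*, the
layer RDM holds Euclidean distances `‖v_i − v_j‖`. Each probe is mapped to
the hierarchy through

ρ_l^p = Spearman(RDM^p, RDM^l),  l = 0 … 8,

computed over the RDM upper triangles. Significance is assessed by
reshuffling the response vector (10,000 permutations by default), rebuilding
the probe RDM each time, and taking the one-sided empirical
p = (1 + #{ρ_null ≥ ρ}) / (1 + n_perm); a correlation is kept when
p < 0.001. Significant correlations are aggregated per (area, layer) cell,
normalised by the number of significantly correlating probes in the area.

The headline statistic codes each significant (probe, layer) pair by the
probe's area rank A ∈ {0…4} and the layer index L ∈ {0…8} and computes

ρ_align = Spearman(A_align, L_align),

with a one-sided permutation test. Supporting quantifiers: **volume**
(total significant correlation in an area × layer subset), **visual
specificity** (volume fraction in ventral-stream areas), and the
**complexity ratio** (volume in {conv5, fc6, fc7} over volume in
{conv1–3, conv5, fc6, fc7}). Region-of-interest comparisons (5 bands ×
3 windows) use 1000 half-size probe subsets per ROI and one-sided
Mann–Whitney tests at a Bonferroni threshold of 0.005/225 ≈ 2.2e-5.

Raw epochs (−500…1000 ms) are processed in a fixed order: linear detrend and
rejection of epochs containing samples ≥ 10σ of the probe, bipolar
re-referencing along each electrode shaft, complex Morlet time-frequency
decomposition (σ_t = cycles/(2π f₀); 3/4/5/6/6 cycles for θ/α/β/γ/Γ),
band-power averaging in the analysis window normalised by the −500…−100 ms
baseline, and a Wilcoxon + Benjamini–Hochberg screen that keeps only
positively responsive probes.

## Worked example

```python
import rsalign as ra
from rsalign.mapping import _LayerRDMBank

layers = ra.make_layer_hierarchy(n_stimuli=100, seed=0)
plan, truth = ra.make_probe_plan(
    {"17": 1, "18": 2, "19": 4, "37": 6, "20": 7},
    probes_per_area=10, snr=10.0, seed=1,
)
responses = ra.simulate_band_responses(layers, plan, seed=2)

mapping = ra.map_probes(responses, _LayerRDMBank.from_layers(layers), plan,
                        n_perm=1000, alpha=0.001, seed=3)
agg = ra.aggregate_area_layer(mapping)
align = ra.alignment_score(mapping, n_perm=10_000, seed=4)

print(agg.scores.round(2).to_string())
print(f"rho_align = {align.rho:.3f}  (p = {align.p:.2e}, {align.n_pairs} pairs)")
print(f"visual specificity = {ra.visual_specificity(mapping):.2f}")
print(f"complexity ratio   = {ra.complexity_ratio(mapping):.2f}")
```

Output:

```
      0     1     2    3     4    5     6     7    8
17  0.0  0.21  0.02  0.0  0.00  0.0  0.00  0.00  0.0
18  0.0  0.00  0.26  0.0  0.00  0.0  0.00  0.00  0.0
19  0.0  0.00  0.02  0.0  0.23  0.0  0.00  0.00  0.0
37  0.0  0.00  0.00  0.0  0.00  0.0  0.22  0.00  0.0
20  0.0  0.00  0.00  0.0  0.00  0.0  0.00  0.21  0.0
rho_align = 0.987  (p = 1.00e-04, 36 pairs)
visual specificity = 1.00
complexity ratio   = 0.51
```

The mapping matrix recovers the planted diagonal: each area's strongest
aggregate correlation sits at its planted layer, and the alignment score is
near 1 with the smallest attainable permutation p. The complexity ratio of
0.51 reflects that the planted map places areas 37 and 20 on
high-complexity layers (fc6, fc7) and areas 17–19 on low ones.

A command-line surface wraps the same stages:

```
rsalign run-all --seed 0 --out results/demo
rsalign synth --out data/synthetic
```

`run-all` executes the full band × window grid on synthetic data and writes
the alignment table, per-ROI mapping matrices, subsample comparisons, and a
manifest with every derived seed.

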