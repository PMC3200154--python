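# Methods notes

## Model and procedure

The predictor treats an ensemble of 3D structural models for one target as
repeated noisy observations of the same contact map. Each model is reduced
to one representative point per residue — the Cβ atom, Cα for glycine — and
two residues are in contact when these points are strictly closer than
8 Å. Pooling works by counting each pair across all models and dividing by
the ensemble size, so a prediction score is directly interpretable as "the
fraction of models containing this contact". The assumption doing the work
is that model errors are diverse: a wrong conformation misplaces different
segments in different models, so spurious contacts are scattered, while
contacts of the true topology recur. The method consequently degrades when
the pool is small, homogeneous, or uniformly wrong — consensus frequency
then measures pipeline bias, not correctness.

Sequence-separation bands follow the community convention: medium range
12 ≤ |j − i| ≤ 23, long range |j − i| ≥ 24. Short-range pairs are extracted
and stored (they matter for model scoring and coverage) but excluded from
prediction output, which is where the signal of a fold lies.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `distance_threshold` | 8.0 Å | contact cutoff on representative atoms, strict `<` |
| `medium_lo..medium_hi` | 12–23 | medium-range separation band (residues) |
| `long_lo` | 24 | long-range threshold (residues) |
| `top_fraction` | 1/5 | prediction depth as a fraction of domain length L |
| `delta` | 0–2 | ±residue tolerance in neighborhood evaluation |
| `cluster_linkage` | 4 | single-linkage radius for contact clustering (residues) |

Prediction depth is `max(1, floor(L × fraction))`; L always comes from the
domain definition, never from the residues a model happens to resolve.

## Numerical and tie-breaking choices

* **Threshold boundary.** A pair at exactly 8.000 Å is not a contact. The
  k-d tree ball query is inclusive, so an exact strict-`<` post-filter is
  applied to candidate pairs.
* **Normalisation denominator.** Counts are divided by the number of models
  (not by the maximum count). Ranking is identical either way; the chosen
  convention makes scores comparable across ensembles of different sizes.
  Models that omit residues still count in the denominator for every pair.
* **Sorting.** Frequency descending, ties by (i, j) ascending. All outputs
  are byte-deterministic for fixed inputs.
* **Proximity metric.** "Within δ residues" between two contacts means
  Chebyshev distance on ordered endpoint pairs:
  `max(|i₁−i₂|, |j₁−j₂|) ≤ δ` — both endpoints must be close, and δ = 0
  collapses to equality. The same metric backs δ-evaluation, clustering,
  representative filtering and cluster coverage. A one-endpoint reading
  would make δ-neighborhoods asymmetric and is not used.
* **Matching.** Evaluation judges each prediction independently; one true
  contact may validate several nearby predictions. No bipartite matching is
  attempted. Recall is defined at δ = 0 only (neighborhood recall would
  double-count) and is computed over the same truncated prediction list as
  precision.
* **Empty denominators.** Evaluating an empty prediction list reports
  precision 0.0 with `defined=False` rather than NaN; an empty prediction
  range contributes 0 to both of its satisfaction fractions.
* **Random baseline median.** For even-sized pools the lower median is
  used, deterministically.
* **PDB handling.** Residue sequence numbers are taken verbatim as 1-based
  target positions (the CASP server-model convention). Insertion codes are
  rejected. First-listed altloc wins. Only the first MODEL of a multi-model
  file is read. A non-glycine residue without a Cβ is skipped unless
  `--ca-fallback` substitutes its Cα.

## Model ranking

A model's score is the sum of four fractions in [0, 1]: predicted
medium-range contacts satisfied exactly, medium within 1 residue, long
exactly, long within 1 residue. The medium list is the top L consensus
entries. For the long list, an unbounded "all consensus entries" policy was
measured to rank *worse* than the random baseline on graded synthetic pools:
weakly supported near-threshold pairs reward models for reproducing
ensemble noise rather than topology. The default is therefore the top L
long-range entries — the same depth as the medium list — with `all`,
`top:N` and `min-count:k` available via `ranking_prediction_sets`.

Selection loss is `max(quality over pool) − quality(top-ranked)`; quality
comes from a user-supplied table (GDT-TS or any monotone stand-in) and is
never computed here.

## What the synthetic generator emulates — and what it does not

`make_reference` builds idealised traces: an antiparallel helical bundle
(2.3 Å helix radius, 1.5 Å rise, 100°/residue, axes 9.5 Å apart on a
circle, 3-residue connecting loops) or a self-avoiding random coil with a
2 Å clash floor. The bundle guarantees a deep pool of inter-helix
long-range contacts. `make_ensemble` adds i.i.d. Gaussian noise per
coordinate and, in a configurable fraction of models, rigidly shifts a
random contiguous segment (default a third of the chain by 15 Å) —
emulating pools in which some predictors misplace a whole helix. With
`sigma_range` set, each model draws its own noise level uniformly from a
range, producing the quality-graded pools used for ranking experiments.
The quality table scores a model by the fraction of reference contacts it
retains, a superposition-free stand-in for GDT-TS.

Default study conditions (80 residues, 50 models, σ = 1.0 Å, 20% corrupted,
shift 15 Å; grading range 0.3–3.0 Å) are desk-scale: small enough that the
whole suite runs in seconds, large enough that long-range pairs, corruption
and consensus margins all exist. These sizes are the package's own choice
of fixture scale.

What passing tests on this generator show: the pipeline recovers recurrent
planted contacts, separates them from scattered spurious pairs, and ranks
less-perturbed models higher. What they do not show: performance on real
model pools, whose errors are correlated (shared templates, shared
alignment mistakes), whose contacts involve side-chain geometry rather than
isotropic noise, and whose quality scores come from superposition. Real
near-threshold contacts also flicker across models in ways isotropic noise
only crudely imitates.

## Known limitations

* Single-chain models only; no mmCIF, no HETATM, no occupancy weighting.
* Contact definition is fixed to representative-atom distance; no
  heavy-atom minimum-distance variant.
* Consensus frequency is not a calibrated probability; it is a ranking
  score written into the RR probability column.
* The reference-first ranking guarantee holds for prediction lists drawn
  from the planted truth; with consensus-derived lists a near-perfect model
  can legitimately outscore the reference on spurious near-threshold
  entries.
* Cluster coverage histograms report exact counts and cumulative fractions;
  with few clusters the histogram is coarse.
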