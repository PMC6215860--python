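# polysyn

Fully automatic **polyadic synapse prediction** for isotropic volumetric EM
(FIB-SEM-style data), with **connectome-level evaluation metrics** and a
seeded **EM-phantom generator** for testing without any data download.

In *Drosophila*, synapses are mostly polyadic: one presynaptic site (a
"T-bar", named for its pedestal-plus-platform shape) contacts several
postsynaptic partners, each marked by a postsynaptic density (PSD).
`polysyn` detects synapses in two stages and then asks the question that
actually matters for connectomics: *how good is the resulting wiring
diagram?*

1. **T-bar detection** (segmentation-independent). Sparse point annotations
   are dilated into dense voxel labels (every voxel within radius *r* of an
   annotation is positive), a voxel classifier produces a probability map,
   and Gaussian smoothing + local-maximum selection + greedy non-maxima
   suppression yield point predictions. Predictions are finally shifted to
   the brightest voxel within a small radius, away from the electron-dense
   regions where segmentations are least reliable.
2. **Partner prediction** (segmentation-aware). For each T-bar, candidate
   bodies are the segments intersecting a sphere around it (the host body is
   excluded — no autapses). The host/candidate contact interface is
   estimated by dilating both bodies by varying amounts and intersecting;
   27 image statistics pooled over each of 5 interfaces give a
   135-dimensional feature vector, classified by an MLP with one hidden
   layer of 50 units (cross-entropy loss). Dark voxels are masked out of the
   segmentation first, since membranes and T-bars are where automated
   segmentations misassign labels.

## Connectome metrics

With the connectome as a directed weighted graph (edge weight = synapse
count), for ground truth *g* and prediction *p*:

- **weighted PR** — recall = Σₑ min(g(e), p(e)) / Σₑ g(e), and symmetrically
  for precision: predicting weight 7 for a true weight-9 edge is equivalent
  to wholly missing a weight-2 edge;
- **thresholded (unweighted) PR** — both graphs binarized at weight ≥ t;
  t = 1 is plain unweighted PR;
- **asymmetric (t₁, t₂) PR**, t₁ ≥ t₂ — a strict threshold on the side
  supplying the positives and a lenient one on the other side:
  recall = Σₑ [p(e) ≥ t₂ ∧ g(e) ≥ t₁] / Σₑ [g(e) ≥ t₁],
  precision = Σₑ [p(e) ≥ t₁ ∧ g(e) ≥ t₂] / Σₑ [p(e) ≥ t₁].
  This isolates clear, strong errors and upper-bounds symmetric PR at t₁;
- **connections missed / added** — strong edges of one graph weak or absent
  (< t₂) in the other, normalized by the number of strong ground-truth
  edges, so normalized-missed + asymmetric recall = 1 exactly;
- plus synapse-level PR with one-to-one T-bar matching (distance and
  optional same-segment constraints), orphan-fragment filtering, undirected
  views, and a **body-proximity baseline** (random boundary samples with a
  coin-flip direction) that contact-area-as-proxy arguments can be tested
  against.

## Worked example

Generate a small phantom, train both detectors on its ground truth, and run
the pipeline end to end:

```python
import json
from polysyn.synthetic_data import PhantomConfig, generate_phantom
from polysyn.pipeline import PipelineConfig, train_models, run_pipeline, json_default

cfg = PipelineConfig()
phantom = generate_phantom(PhantomConfig(shape=(64, 64, 64), n_segments=8,
                                         n_synapses=4, seed=7))
tbar_model, psd_model = train_models(phantom.volume, phantom.clean_labels,
                                     phantom.gt_records, cfg)
result = run_pipeline(phantom.volume, phantom.clean_labels, cfg,
                      tbar_model, psd_model, phantom.gt_records)
print(json.dumps(result.report, indent=1, sort_keys=True, default=json_default))
```

prints

```json
{
 "asymmetric_precision": 1.0,
 "asymmetric_recall": 1.0,
 "asymmetric_t1": 10,
 "asymmetric_t2": 5,
 "n_connections_added": 0,
 "n_connections_missed": 0,
 "n_partner_entries": 7,
 "n_tbars_predicted": 4,
 "normalized_added": 0.0,
 "normalized_missed": 0.0,
 "synapse_level_break_even": 1.0,
 "tbar_threshold": 0.2,
 "unweighted_precision": 1.0,
 "unweighted_recall": 1.0,
 "unweighted_t": 1,
 "weighted_precision": 1.0,
 "weighted_recall": 1.0
}
```

All 4 planted T-bars and all 7 planted (T-bar, partner) pairs are recovered
(this in-sample run is a smoke check; the test suite trains and evaluates on
*separate* phantoms). `weighted_*` scores every individual synapse;
`unweighted_*` scores binary edges; the `asymmetric_*` entries and the
normalized added/missed fractions report strong-edge errors at t₁=10, t₂=5;
`synapse_level_break_even` is the best min(precision, recall) over the
confidence sweep of (T-bar, partner) pairs.

The same pipeline is available from the shell:

```sh
polysyn simulate --out-dir fixtures/ --seed 7
polysyn run --volume fixtures/volume.h5 --labels fixtures/labels_clean.h5 \
            --synapses fixtures/synapses.json --train --out-dir out/ --seed 7
polysyn baseline --labels fixtures/labels_clean.h5 --n-samples 1000 --seed 0 \
            --out baseline.csv
```

(Subcommands also exist for each stage separately: `train-tbar`,
`predict-tbar`, `train-psd`, `predict-psd`, `build-graph`, `evaluate`.)

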