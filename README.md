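# odorref — functional reference mapping for odour-evoked activity

`odorref` normalizes odour-evoked neural activity patterns recorded from
*different individuals* into one common multidimensional space, so that
stimuli can be classified across individuals even when no anatomical
registration is possible.

The motivating system is calcium imaging of olfactory receptor neurons
on the insect antenna: receptor types occupy individually scrambled
spatial patches, and light scattering mixes their signals into pixels
with animal-specific weights.  Spatial activity maps are therefore not
comparable between animals — but responses to a fixed panel of
*reference odorants* are, because the same receptors are activated in
every animal.  `odorref` implements this *functional registration*
end to end, together with a synthetic-cohort simulator so the whole
chain is testable without recordings.

## The method

For each animal *i*:

1. Each recording (s = 80 frames, 4 Hz, two 1-s stimulus pulses) is
   converted to relative fluorescence change
   ΔF/F = (f_j − f₀)/f₀, with f₀ the mean over a fixed pre-stimulus
   window (frames 3–22).
2. All recordings are concatenated into the (m × p) movie matrix
   **A**_i (p = pixels).  A subset of c pixel columns **F**_i is chosen
   by convex-cone analysis: minimize ‖**A**_i − **F**_i **X**_i‖_F with
   **X**_i ≥ 0, so that columns inside the convex cone of the selection
   are reconstructed exactly.  Selected pixels are denoised by averaging
   over contiguous, correlated neighbours.
3. t = 10 peri-stimulus time points (5 per pulse) are kept, each
   dimension is standardized (autoscaling), and each odorant response
   becomes a vector of length q = t·c.
4. The r reference-odorant response vectors are stacked into the
   (r × q) matrix **P**_i, which defines the animal-specific transform

       S_i = (P_iᵀ)⁺ = (P_i P_iᵀ)⁻¹ P_i

   (Moore–Penrose pseudoinverse).  Any response vector maps to the
   animal-independent reference space as

       v_global = S_i · v_local ,

   the least-squares coordinates of the response in the basis of the
   animal's own reference responses.
5. Global vectors from many animals are pooled; a Manhattan-distance
   k-NN (or SVM) classifier is trained on some animals and evaluated on
   the held-out ones, over every C(n, n_train) animal split.

The key invariance: if animal B's measurement space is any full-rank
linear image of animal A's, responses in the span of the reference
responses receive *identical* global coordinates in both animals.
Responses driven by receptors that no reference odorant touches fall
outside that span and cannot be mapped consistently — classification
then drops to chance.

## Worked example

Mapping into the reference space is exact for in-span responses:

```python
import numpy as np
from odorref import ReferenceProjection, compute_transform, map_to_global

rng = np.random.default_rng(0)
P = ReferenceProjection(P=rng.normal(size=(3, 20)),
                        reference_labels=("refA", "refB", "refC"),
                        animal_id="fly1")
T = compute_transform(P)
v_local = P.P.T @ np.array([0.5, 1.0, -0.2])   # a response in the span
v_global = map_to_global(T, v_local)
print("condition number:", round(T.condition_number, 3))
print("global coordinates:", np.round(v_global.values, 6))
```

prints

```
condition number: 2.805
global coordinates: [ 0.5  1.  -0.2]
```

— the response is recovered in reference-odour coordinates regardless of
the 20-dimensional measurement basis it was recorded in.

A small synthetic cohort, processed by the full pipeline (simulation →
ΔF/F → convex-cone selection → autoscaling → reference mapping →
animal-wise cross-validation):

```python
from odorref import scenarios
from odorref.crossval import run_experiment

cohort, design = scenarios.five_odorant_experiment(seed=1, n_animals=4,
                                                   n_train=2)
result = run_experiment(cohort, design)
print(f"splits: {len(result.per_split)}")
print(f"mean accuracy: {result.mean_accuracy:.3f} +/- {result.accuracy_sd:.3f}")
print(result.pooled_confusion.as_dataframe())
```

prints

```
splits: 6
mean accuracy: 1.000 +/- 0.000
       testX  testY
testX     60      0
testY      0     60
```

Two test odorants, measured at five concentrations in every animal, are
classified perfectly across animals from their 3-dimensional global
coordinates: 60 = 2 test animals × 5 concentrations × 6 splits per
class.

## Command line

```
odorref simulate        --config cfg.yaml --out movies/
odorref select-features --config cfg.yaml --movies movies/ --out feats/
odorref preprocess      --config cfg.yaml --movies movies/ --out responses.csv
odorref map             --config cfg.yaml --responses responses.csv --out global.csv
odorref crossval        --config cfg.yaml --responses responses.csv --out results/
odorref pipeline        --config cfg.yaml --movies movies/ --out results/
```

Configuration is one YAML file covering all stages (see
`PipelineConfig`).  Exit codes: 2 validation, 3 numerical failure
(e.g. rank-deficient reference matrix), 4 I/O.

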