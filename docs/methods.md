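# Methods

## Model and assumptions

The package assumes the standard linear-mixing picture of wide-field
antennal calcium imaging: each pixel's fluorescence trace is a
non-negative linear combination of the underlying receptor-type
time courses, with mixing weights that differ between animals (scattered
light, individually scrambled sensillum patches).  Under that
assumption, an animal's measurement space is a linear image of a common
receptor space, and two consequences drive the whole design:

1. **Convex-cone structure.**  The ΔF/F movie matrix has its columns in
   the convex cone generated by the receptor time courses; a column
   subset that spans this cone reconstructs every other column exactly
   with non-negative coefficients.  This is why feature selection
   minimizes ‖A − F X‖_F with X ≥ 0.
2. **Mixing invariance.**  If P collects the reference-odorant response
   vectors of one animal and S = (Pᵀ)⁺, then S·v is the least-squares
   coordinate vector of v in the basis of reference responses.  For any
   full-rank re-mixing M of the measurement space, (P Mᵀ) and (M v)
   yield the same coordinates, so global vectors are comparable across
   animals — *exactly* for responses in the row space of P, and not at
   all for components orthogonal to it.  The out-of-span residual
   ‖Pᵀ v_global − v_local‖ quantifies the second case and is exposed by
   `refmap.out_of_span_residual`.

A note on the transform: dimensionally, the only (r × q) map is
S = (P Pᵀ)⁻¹ P, the pseudoinverse of Pᵀ, and that is what
`compute_transform` computes (by SVD; an explicit-inverse route exists
behind `method="explicit"` for cross-checking).  A product written in
the other order would be (q × r) and could not act on a q-vector.

## Synthetic-data generator

`odorref.simulate` produces cohorts with exactly the structure above:

* **Stimulus protocol** — 20 s at 4 Hz (s = 80 frames), two 1-s pulses
  at 6 s and 9 s (onset frames 25 and 37, 1-based), second pulse scaled
  by an adaptation factor (default 0.8, in (0, 1]).
* **Indicator kernel** — difference of exponentials with 0.2 s rise and
  2 s decay, peak-normalized; pulses enter as impulses at onset, so the
  response waveform is a sum of shifted kernels.  These constants model
  a slow GCaMP-class indicator and are configurable.
* **Receptor tuning** — a non-negative (receptors × odorants) gain
  matrix; every odorant drives at least one receptor (combinatorial
  coding).  Dose scaling is gain × (conc/conc_ref)^h with h = 0.25 by
  default: a compressive power law standing in for the saturating,
  roughly logarithmic dose-response of receptor neurons, chosen so that
  decadic dilutions from 1e-6 to 1e-2 span one decade of response
  amplitude rather than four.
* **Animal mixing** — each receptor occupies one (configurable: more)
  rectangular patch of pixels at an animal-specific position, with
  uniform(0.5, 1.5) weights inside the patch.  Patches are separated by
  at least one pixel of unresponsive "cuticle"; this keeps receptor
  identity recoverable from spatial contiguity and keeps neighbourhood
  pooling from bridging two receptor patches whose time courses happen
  to correlate.  Default grid 80 × 60 (p = 4800).
* **Noise** — additive Gaussian noise on the fluorescence signal
  (default sd 0.5 on a baseline of 100, i.e. 0.5% of baseline per pixel
  per frame, a realistic figure for 8×8-binned camera frames), plus an
  optional per-frame multiplicative bleaching decay (default off).
  Shot noise is deliberately not modelled.

What the generator does **not** emulate: receptor–ligand kinetics and
saturation dynamics, antennal morphology and movement (movies are
generated still; the stabilizer is exercised on synthetically shifted
frames), correlated/structured noise, indicator nonlinearity, and
concentration-dependent *pattern* changes (activation patterns scale
multiplicatively with dose here, whereas real patterns can recruit new
receptors at high concentration).  Passing cohort tests therefore show
that the pipeline is correct under its own assumptions — not that real
antennal data satisfies those assumptions.

## Pipeline choices

* **ΔF/F first.**  Each recording is normalized per pixel against the
  mean of frames 3–22 before any pooling or selection, so the movie
  matrix holds relative changes; the baseline term (and any
  multiplicative gain) cancels and the linear-mixing ground truth holds
  exactly for noise-free data.  A zero baseline mean raises an error
  naming the offending feature.
* **Time points.**  t = 10 frames: 5 consecutive frames from each pulse
  onset, delayed by one frame by default (`timepoint_offset = 1`).  The
  onset frame itself carries no indicator signal (the kernel starts at
  zero), so the delayed window brackets the response peak ~0.5 s after
  onset.  Any fixed peri-stimulus choice is admissible as long as it is
  identical across animals; the offset is configurable.
* **Autoscaling population.**  Each (time point, feature) dimension is
  standardized across all odorant responses of one animal (population
  sd, ddof = 0; zero-variance dimensions map to 0).  Per-animal scaling
  is required because it must precede assembly of that animal's P and
  must not mix animals; a per-response policy (`within_sample`) exists
  for comparison.  A useful side effect: standardization removes the
  per-feature mixing gain, tightening cross-animal comparability.
* **Convex-cone selection.**  Two phases.  (i) A forward pass hunts
  *extreme rays* of the data cone: at each step, the residual direction
  of the worst-represented column is scored against every candidate by
  the scale-invariant linear-fractional criterion (r·a)/(d·a) with d a
  strictly positive functional (the mean data column); by the mediant
  inequality the maximizer over non-negative combinations is an extreme
  ray, so on exact cone data the pass returns the generating columns.
  A plain "add the column that most reduces the refit error" greedy
  does not have this property — its first pick is typically a central
  mixture column, after which exact reconstruction is unreachable.
  (ii) Swap refinement then minimizes the Frobenius objective by
  single-column replacements until no swap improves (bounded sweeps);
  for c = 1 this coincides with exhaustive search.  All NNLS fits are
  per-column (the Frobenius objective separates) and are reduced
  through a thin QR of the basis, with the out-of-span residual norm
  computed explicitly to avoid cancellation.  Ties break toward the
  lowest pixel index.  Candidate and scoring columns can be subsampled
  for very large p (off by default).
* **Pooling.**  Selected pixels are replaced by the mean over the
  4-connected region of pixels whose trace correlates with the seed at
  ≥ 0.8 (default) within a Chebyshev radius of 3; the seed always
  belongs, constant pixels never do.  Pooling operates on the same
  (ΔF/F) matrix as selection: ΔF/F is a per-column affine transform
  within a recording, which leaves Pearson correlations essentially
  unchanged, and a single matrix keeps the pipeline honest about what
  was selected.
* **Reference matrix.**  Default aggregation averages all measured
  concentrations of a reference odorant into one row (r = number of
  reference odorants); `stack_all` keeps one row per measurement.  Row
  order is fixed (sorted labels by default) so axes agree across
  animals.
* **Conditioning.**  The condition number of P Pᵀ is always reported;
  above 1e8 the transform raises, naming the most collinear pair of
  reference rows, rather than silently regularizing.  An explicit ridge
  term is available but off by default.
* **Classification.**  k-NN uses the Manhattan distance with k = 1 by
  default (k is not prescribed by the protocol; the runner records it).
  Vote ties go to the tied label with the closest member, then to
  lexicographic order, making predictions deterministic.  The SVM is a
  linear-kernel soft-margin classifier (C = 1, one-vs-one for
  multiclass) — a low-variance choice given the small r and n.
* **Cross-validation.**  Every animal's own reference responses build
  its transform — reference measurements are calibration and exist in
  every animal, so they are never "held out"; only test-odorant labels
  are.  Because the mapping does not depend on the split, it is
  computed once and the classifier is retrained per split on training
  animals only.  Reported are the mean ± sd (ddof = 1) of per-split
  accuracies and the pooled confusion matrix.

## Problem sizes

Synthetic cohort experiments run on a 16 × 12 pixel grid with
c = n_receptors (5–6) selected features; the method's structure
(non-negative patchy mixing, shared tuning, per-animal scrambling) does
not depend on grid size, and the full 80 × 60 geometry is exercised
where the protocol constants matter.  The five-odorant design uses 7
animals, 3 reference odorants at the lowest and highest of five decadic
concentrations, and 2 test odorants at all five; the mixture panel uses
10 animals, 3 references and 4 test classes measured once each.

## Known limitations

* Registration is translation-only with integer shifts (nearest-value
  edge fill); rotation and sub-pixel motion are not estimated.
* The reference mapping is linear; responses outside the span of the
  reference responses are irrecoverably projected (this is a property
  of the method, demonstrated by the disjoint-receptor experiment, not
  a bug).
* The linear SVM under-performs k-NN on the five-odorant design here:
  global vectors of one class lie along a concentration-scaled ray, and
  a max-margin hyperplane fitted only at the extreme concentrations
  generalizes worse along the ray than nearest-neighbour look-up.
* Greedy-plus-swap selection is a local method; on noisy matrices it is
  only guaranteed not to beat the exhaustive optimum, and the
  exhaustive comparison is feasible only for small p and c.
* The explained-norm figure depends on the matrix it is computed on: on
  raw fluorescence (norm dominated by baseline structure) a
  receptor-sized basis explains > 99% of the norm; on ΔF/F matrices the
  per-pixel noise floor across all p columns bounds the fraction lower
  at small scale, and only the zero-noise case reaches 1 exactly.
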