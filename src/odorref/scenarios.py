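"""Predefined synthetic study designs.

Two cohort designs mirror the structure of the method's evaluation
experiments:

* ``five_odorant`` — 7 animals, 5 odorants, 5 decadic concentrations
  (1e-6 .. 1e-2).  Three odorants serve as references, measured at the
  highest and lowest concentration only; the remaining two are test
  odorants measured at all concentrations.  Training uses the test
  odorants of the training animals at the highest and lowest
  concentration, evaluation uses all concentrations of the held-out
  animals, over all C(7, 4) = 35 splits.  Two receptor-tuning variants
  exist: ``shared`` (test odorants drive receptors that the references
  also drive — the regime where reference mapping works) and ``disjoint``
  (test odorants drive only receptors untouched by any reference — the
  stated failure mode, where cross-animal mapping collapses to chance).

* ``mixture_panel`` — 10 animals, 3 reference odorants plus 4 complex
  test classes measured once each (4 test measurements per animal, 40 in
  total), evaluated over all animal splits for a chosen training-set
  size.

Desk-scale default: a 16 x 12 pixel grid (the statistical structure —
patchy non-negative mixing, shared tuning, per-animal scrambling — is
grid-size independent; a smaller grid keeps feature selection fast).
The full-scale acquisition geometry (80 x 60) remains the generator
default elsewhere.
"""

from __future__ import annotations

import numpy as np

from .crossval import CohortResponses, ExperimentDesign
from .pipeline import PipelineParams, process_cohort
from .simulate import AnimalMixing, NoiseModel, ReceptorTuning, \
    StimulusProtocol, make_cohort, simulate_recording

__all__ = [
    "five_odorant_tuning",
    "mixture_panel_tuning",
    "simulate_cohort_responses",
    "five_odorant_experiment",
    "mixture_panel_experiment",
    "CONCENTRATIONS",
]

CONCENTRATIONS = (1e-6, 1e-5, 1e-4, 1e-3, 1e-2)

REFERENCES_5 = ("refA", "refB", "refC")
TESTS_5 = ("testX", "testY")

REFERENCES_MIX = ("ref1", "ref2", "ref3")
TESTS_MIX = ("mixA", "mixB", "mixC", "mixD")


def five_odorant_tuning(variant: str = "shared") -> ReceptorTuning:
    """Receptor gains for the 5-odorant design (5 receptor types).

    ``shared``: every receptor driven by a test odorant is also driven by
    at least one reference.  ``disjoint``: references drive only receptors
    R0-R2, test odorants only R3-R4.
    """
    odorants = REFERENCES_5 + TESTS_5
    if variant == "shared":
        amps = np.array([
            #  refA refB refC testX testY
            [1.0, 0.0, 0.2, 0.7, 0.1],   # R0
            [0.3, 1.0, 0.0, 0.5, 0.2],   # R1
            [0.0, 0.3, 1.0, 0.1, 0.8],   # R2
            [0.2, 0.0, 0.3, 0.2, 0.3],   # R3
            [0.0, 0.2, 0.1, 0.1, 0.2],   # R4
        ])
    elif variant == "disjoint":
        amps = np.array([
            [1.0, 0.3, 0.0, 0.0, 0.0],
            [0.3, 1.0, 0.3, 0.0, 0.0],
            [0.0, 0.3, 1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.9, 0.3],
            [0.0, 0.0, 0.0, 0.3, 0.9],
        ])
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return ReceptorTuning(amplitudes=amps, odorants=odorants)


def mixture_panel_tuning() -> ReceptorTuning:
    """Receptor gains for the 4-class mixture panel (6 receptor types).

    The four test classes are broad, overlapping activation patterns,
    emulating complex odorant mixtures judged against pure-chemical
    references.
    """
    odorants = REFERENCES_MIX + TESTS_MIX
    amps = np.array([
        # ref1 ref2 ref3 mixA mixB mixC mixD
        [1.0, 0.2, 0.0, 0.6, 0.5, 0.1, 0.3],   # R0
        [0.3, 1.0, 0.2, 0.4, 0.1, 0.6, 0.3],   # R1
        [0.0, 0.3, 1.0, 0.2, 0.5, 0.4, 0.1],   # R2
        [0.2, 0.0, 0.3, 0.5, 0.2, 0.2, 0.6],   # R3
        [0.1, 0.2, 0.0, 0.1, 0.4, 0.3, 0.2],   # R4
        [0.0, 0.1, 0.2, 0.3, 0.1, 0.2, 0.4],   # R5
    ])
    return ReceptorTuning(amplitudes=amps, odorants=odorants)


def simulate_cohort_responses(tuning: ReceptorTuning,
                              stimuli: list[tuple[str, float]],
                              n_animals: int, seed: int,
                              shape: tuple[int, int] = (16, 12),
                              noise: NoiseModel | None = None,
                              protocol: StimulusProtocol | None = None,
                              params: PipelineParams | None = None,
                              ) -> CohortResponses:
    """Simulate a cohort and run the full processing pipeline in memory."""
    protocol = protocol or StimulusProtocol()
    noise = noise if noise is not None else NoiseModel()
    if params is None:
        params = PipelineParams(c=tuning.n_receptors, pooling_radius=2)
    cohort = make_cohort(n_animals, tuning, protocol, noise, seed=seed,
                         shape=shape)
    ss = np.random.SeedSequence(seed + 1)
    seeds = iter(ss.generate_state(n_animals * len(stimuli)) % (2 ** 31))
    movies_by_animal = {}
    for animal in cohort:
        movies = []
        for odorant, conc in stimuli:
            movies.append(simulate_recording(
                animal, tuning, odorant, conc, protocol, noise,
                seed=int(next(seeds))))
        movies_by_animal[animal.animal_id] = movies
    return process_cohort(movies_by_animal, params)


def five_odorant_experiment(seed: int, variant: str = "shared",
                            n_animals: int = 7, n_train: int = 4,
                            classifier: str = "knn",
                            shape: tuple[int, int] = (16, 12),
                            noise: NoiseModel | None = None,
                            ) -> tuple[CohortResponses, ExperimentDesign]:
    """Cohort responses and design for the 5-odorant experiment."""
    tuning = five_odorant_tuning(variant)
    lo, hi = CONCENTRATIONS[0], CONCENTRATIONS[-1]
    stimuli = [(o, c) for o in REFERENCES_5 for c in (lo, hi)]
    stimuli += [(o, c) for o in TESTS_5 for c in CONCENTRATIONS]
    cohort = simulate_cohort_responses(tuning, stimuli, n_animals, seed,
                                       shape=shape, noise=noise)
    design = ExperimentDesign(
        reference_odorants=REFERENCES_5, test_odorants=TESTS_5,
        n_train_animals=n_train, train_concentrations=(lo, hi),
        test_concentrations=None, classifier=classifier)
    return cohort, design


def mixture_panel_experiment(seed: int, n_animals: int = 10,
                             n_train: int = 7, classifier: str = "knn",
                             shape: tuple[int, int] = (16, 12),
                             noise: NoiseModel | None = None,
                             concentration: float = 1e-2,
                             ) -> tuple[CohortResponses, ExperimentDesign]:
    """Cohort responses and design for the 4-class mixture panel."""
    tuning = mixture_panel_tuning()
    stimuli = [(o, concentration) for o in REFERENCES_MIX + TESTS_MIX]
    cohort = simulate_cohort_responses(tuning, stimuli, n_animals, seed,
                                       shape=shape, noise=noise)
    design = ExperimentDesign(
        reference_odorants=REFERENCES_MIX, test_odorants=TESTS_MIX,
        n_train_animals=n_train, classifier=classifier)
    return cohort, design
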