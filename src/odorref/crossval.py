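"""Leave-animals-out cross-validation over the reference-mapped cohort.

The experiment runner mirrors the evaluation design of the method: every
animal's own reference responses define its transform ``S_i`` (reference
odours must be measured in every animal — they are the calibration, not
part of the held-out information); test-odorant responses are mapped into
the common reference space; a classifier is trained on the global vectors
of the training animals and evaluated on those of the held-out animals,
for every one of the C(n, n_train) animal splits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ConfusionMatrix, LabeledSet, confusion, knn_predict, \
    svm_train_predict
from .errors import NumericalError, ValidationError
from .preprocess import ResponseVector
from .refmap import GlobalVector, build_reference_matrix, compute_transform, \
    map_to_global

__all__ = [
    "CohortResponses",
    "ExperimentDesign",
    "CrossvalResult",
    "enumerate_splits",
    "map_cohort_to_global",
    "run_split",
    "run_experiment",
]


@dataclass
class CohortResponses:
    """All processed response vectors of a cohort, one per
    (animal, odorant, concentration) measurement."""

    records: list[ResponseVector]

    @property
    def animals(self) -> list[str]:
        seen = dict.fromkeys(r.animal for r in self.records)
        return list(seen)

    def for_animal(self, animal: str) -> list[ResponseVector]:
        return [r for r in self.records if r.animal == animal]

    def without_animals(self, animals) -> "CohortResponses":
        drop = set(animals)
        return CohortResponses([r for r in self.records if r.animal not in drop])

    def to_csv(self, path) -> None:
        rows = []
        for r in self.records:
            row = {"animal": r.animal, "odorant": r.odorant,
                   "concentration": r.concentration, "t": r.t, "c": r.c}
            row.update({f"v{i}": x for i, x in enumerate(r.values)})
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortResponses":
        df = pd.read_csv(path)
        vcols = [c for c in df.columns if c.startswith("v")]
        records = []
        for _, row in df.iterrows():
            records.append(ResponseVector(
                values=row[vcols].to_numpy(dtype=float),
                animal=str(row["animal"]), odorant=str(row["odorant"]),
                concentration=float(row["concentration"]),
                t=int(row["t"]), c=int(row["c"])))
        return cls(records)


@dataclass
class ExperimentDesign:
    """One cross-validation experiment: odorant roles, concentration
    policies, split size and classifier."""

    reference_odorants: tuple[str, ...]
    test_odorants: tuple[str, ...]
    n_train_animals: int
    train_concentrations: tuple[float, ...] | None = None
    test_concentrations: tuple[float, ...] | None = None
    classifier: str = "knn"
    knn_k: int = 1
    svm_kernel: str = "linear"
    svm_regularization: float = 1.0
    aggregation: str = "mean_per_odorant"

    def __post_init__(self) -> None:
        self.reference_odorants = tuple(self.reference_odorants)
        self.test_odorants = tuple(self.test_odorants)
        if set(self.reference_odorants) & set(self.test_odorants):
            raise ValidationError(
                "reference and test odorant sets must be disjoint"
            )
        if not self.reference_odorants or not self.test_odorants:
            raise ValidationError("odorant role sets may not be empty")
        if self.classifier not in ("knn", "svm"):
            raise ValidationError(f"unknown classifier {self.classifier!r}")
        for pol in (self.train_concentrations, self.test_concentrations):
            if pol is not None and len(pol) == 0:
                raise ValidationError("concentration policies may not be empty")


@dataclass
class CrossvalResult:
    """Per-split confusion matrices plus aggregates."""

    per_split: list[tuple[tuple[str, ...], tuple[str, ...], ConfusionMatrix]]
    mean_accuracy: float
    accuracy_sd: float
    pooled_confusion: ConfusionMatrix
    condition_numbers: dict[str, float] = field(default_factory=dict)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([cm.accuracy for _, _, cm in self.per_split])

    def per_split_table(self) -> pd.DataFrame:
        rows = [{"train_animals": ";".join(tr), "test_animals": ";".join(te),
                 "accuracy": cm.accuracy, "n_test": cm.total}
                for tr, te, cm in self.per_split]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "n_splits": len(self.per_split),
            "mean_accuracy": float(self.mean_accuracy),
            "accuracy_sd": float(self.accuracy_sd),
            "pooled_accuracy": float(self.pooled_confusion.accuracy),
            "condition_numbers": {k: float(v)
                                  for k, v in self.condition_numbers.items()},
        }


def enumerate_splits(animal_ids, n_train: int
                     ) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All C(n, n_train) unordered train/test splits, lexicographic."""
    ids = sorted(animal_ids)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate animal ids")
    if not 1 <= n_train < len(ids):
        raise ValidationError(
            f"need 1 <= n_train < n_animals={len(ids)}, got {n_train}"
        )
    splits = []
    for train in itertools.combinations(ids, n_train):
        test = tuple(a for a in ids if a not in train)
        splits.append((train, test))
    return splits


def map_cohort_to_global(cohort: CohortResponses, design: ExperimentDesign
                         ) -> tuple[list[GlobalVector], dict[str, float]]:
    """Build each animal's own ``P_i``/``S_i`` from its reference-odorant
    responses and map its test-odorant responses into the common space."""
    vectors, conds = [], {}
    for animal in cohort.animals:
        recs = cohort.for_animal(animal)
        refs = [r for r in recs if r.odorant in design.reference_odorants]
        missing = set(design.reference_odorants) - {r.odorant for r in refs}
        if missing:
            raise ValidationError(
                f"animal {animal!r} lacks reference odorant(s) {sorted(missing)}"
            )
        tests = [r for r in recs if r.odorant in design.test_odorants]
        missing_t = set(design.test_odorants) - {r.odorant for r in tests}
        if missing_t:
            raise ValidationError(
                f"animal {animal!r} lacks test odorant(s) {sorted(missing_t)}"
            )
        P = build_reference_matrix(refs, aggregation=design.aggregation,
                                   label_order=None, animal_id=animal)
        try:
            transform = compute_transform(P)
        except NumericalError as exc:
            raise NumericalError(
                f"reference matrix of animal {animal!r} failed: {exc}"
            ) from exc
        conds[animal] = transform.condition_number
        for r in tests:
            vectors.append(map_to_global(transform, r))
    return vectors, conds


def _concentration_mask(conc: float, policy) -> bool:
    if policy is None:
        return True
    return any(np.isclose(conc, c, rtol=1e-9) for c in policy)


def _classify(design: ExperimentDesign, train: LabeledSet, test_vectors):
    if design.classifier == "knn":
        return knn_predict(train, test_vectors, k=design.knn_k)
    return svm_train_predict(train, test_vectors, kernel=design.svm_kernel,
                             regularization=design.svm_regularization)


def run_split(global_vectors: list[GlobalVector], design: ExperimentDesign,
              split: tuple[tuple[str, ...], tuple[str, ...]]
              ) -> ConfusionMatrix:
    """Train on the training animals' global vectors, evaluate on the
    held-out animals'.  No test-animal vector influences training."""
    train_animals, test_animals = set(split[0]), set(split[1])
    train_rows = [g for g in global_vectors
                  if g.animal in train_animals
                  and _concentration_mask(g.concentration,
                                          design.train_concentrations)]
    test_rows = [g for g in global_vectors
                 if g.animal in test_animals
                 and _concentration_mask(g.concentration,
                                         design.test_concentrations)]
    if not train_rows or not test_rows:
        raise ValidationError("empty training or test set for split")
    train = LabeledSet(np.vstack([g.values for g in train_rows]),
                       [g.odorant for g in train_rows])
    test_mat = np.vstack([g.values for g in test_rows])
    predicted = _classify(design, train, test_mat)
    class_order = tuple(sorted(design.test_odorants))
    return confusion([g.odorant for g in test_rows], predicted, class_order)


def run_experiment(cohort: CohortResponses, design: ExperimentDesign
                   ) -> CrossvalResult:
    """Run every animal split and aggregate.

    The per-animal mapping does not depend on the split (each animal is
    calibrated by its own reference responses only), so it is computed
    once.  The mean/sd are over per-split accuracies (sample sd); the
    pooled confusion matrix sums counts over splits.
    """
    global_vectors, conds = map_cohort_to_global(cohort, design)
    splits = enumerate_splits(cohort.animals, design.n_train_animals)
    per_split = []
    for train_ids, test_ids in splits:
        cm = run_split(global_vectors, design, (train_ids, test_ids))
        per_split.append((train_ids, test_ids, cm))
    accs = np.array([cm.accuracy for _, _, cm in per_split])
    pooled_counts = np.sum([cm.counts for _, _, cm in per_split], axis=0)
    pooled = ConfusionMatrix(counts=pooled_counts,
                             class_order=per_split[0][2].class_order)
    sd = float(accs.std(ddof=1)) if len(accs) > 1 else 0.0
    return CrossvalResult(per_split=per_split,
                          mean_accuracy=float(accs.mean()),
                          accuracy_sd=sd, pooled_confusion=pooled,
                          condition_numbers=conds)
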