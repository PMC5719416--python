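"""Reference-space projection: the core cross-individual normalization.

For each animal ``i``, the response vectors to ``r`` predetermined
reference odorants are stacked into the ``(r x q)`` reference projection
matrix ``P_i``.  The animal-specific transform

    S_i = (P_i^T)^+ = (P_i P_i^T)^{-1} P_i        (r x q)

is the Moore-Penrose pseudoinverse of ``P_i^T``; applied to any local
response vector it yields the least-squares coordinates of that response
in the (generally non-orthogonal) basis of the animal's own reference
responses:

    v_global = S_i v_local                        (length r)

Because every animal's reference axes represent the *same* stimuli, these
coordinates are comparable across animals: if animal B's measurement space
is any full-rank linear image of animal A's, vectors in the span of the
reference responses receive identical global coordinates in both animals.
Responses outside that span lose their out-of-span component; the residual
``||P^T v_global - v_local||`` quantifies how much.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NumericalError, ValidationError
from .preprocess import ResponseVector

__all__ = [
    "ReferenceProjection",
    "ReferenceTransform",
    "GlobalVector",
    "build_reference_matrix",
    "compute_transform",
    "map_to_global",
    "out_of_span_residual",
]


@dataclass
class ReferenceProjection:
    """``(r x q)`` stack of one animal's reference-odour response vectors."""

    P: np.ndarray
    reference_labels: tuple[str, ...]
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2:
            raise ValidationError("P must be 2-D (r x q)")
        if self.P.shape[0] > self.P.shape[1]:
            raise ValidationError(
                f"r={self.P.shape[0]} must not exceed q={self.P.shape[1]}"
            )

    @property
    def r(self) -> int:
        return self.P.shape[0]

    @property
    def q(self) -> int:
        return self.P.shape[1]


@dataclass
class ReferenceTransform:
    """The ``(r x q)`` map into the reference odour space for one animal."""

    S: np.ndarray
    condition_number: float
    reference_labels: tuple[str, ...]
    animal_id: str = ""

    @property
    def r(self) -> int:
        return self.S.shape[0]

    @property
    def q(self) -> int:
        return self.S.shape[1]


@dataclass
class GlobalVector:
    """Animal-independent ``r``-dimensional odour representation."""

    values: np.ndarray
    animal: str = ""
    odorant: str = ""
    concentration: float = 1.0

    @property
    def r(self) -> int:
        return self.values.size


def build_reference_matrix(reference_responses: list[ResponseVector],
                           aggregation: str = "mean_per_odorant",
                           label_order: tuple[str, ...] | None = None,
                           animal_id: str = "") -> ReferenceProjection:
    """Stack reference-odour responses into ``P``.

    ``mean_per_odorant`` (default) averages all responses of one reference
    odorant (e.g. over its measured concentrations) into one row, giving
    ``r`` = number of reference odorants.  ``stack_all`` keeps one row per
    measurement, giving ``r`` = number of measurements.  Row order follows
    ``label_order`` (default: sorted labels) so it is identical across
    animals.
    """
    if aggregation not in ("mean_per_odorant", "stack_all"):
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    if not reference_responses:
        raise ValidationError("no reference responses given")
    qs = {v.values.size for v in reference_responses}
    if len(qs) > 1:
        raise ValidationError(f"inconsistent response lengths: {sorted(qs)}")
    labels = sorted({v.odorant for v in reference_responses})
    if label_order is not None:
        missing = set(label_order) - set(labels)
        if missing:
            raise ValidationError(
                f"no responses for reference odorant(s) {sorted(missing)}"
            )
        labels = list(label_order)

    rows, row_labels = [], []
    for lab in labels:
        group = [v for v in reference_responses if v.odorant == lab]
        if aggregation == "mean_per_odorant":
            rows.append(np.mean([v.values for v in group], axis=0))
            row_labels.append(lab)
        else:
            for v in sorted(group, key=lambda v: v.concentration):
                rows.append(v.values)
                row_labels.append(lab)
    return ReferenceProjection(P=np.vstack(rows),
                               reference_labels=tuple(row_labels),
                               animal_id=animal_id)


def _near_collinear_rows(P: np.ndarray, labels) -> str:
    """Name the pair of reference rows with the highest cosine overlap."""
    norms = np.linalg.norm(P, axis=1)
    norms[norms == 0] = 1.0
    unit = P / norms[:, None]
    cos = np.abs(unit @ unit.T)
    np.fill_diagonal(cos, 0.0)
    i, j = np.unravel_index(np.argmax(cos), cos.shape)
    li = labels[i] if i < len(labels) else str(i)
    lj = labels[j] if j < len(labels) else str(j)
    return f"{li!r} and {lj!r} (|cos| = {cos[i, j]:.6f})"


def compute_transform(P: ReferenceProjection,
                      condition_cap: float = 1e8,
                      method: str = "svd",
                      ridge: float = 0.0) -> ReferenceTransform:
    """Compute ``S = (P^T)^+`` and the condition number of ``P P^T``.

    The default route is the SVD-based pseudoinverse (numerically stable);
    ``method="explicit"`` forms ``(P P^T)^{-1} P`` literally, retained for
    fidelity checks.  A condition number of ``P P^T`` above
    ``condition_cap`` raises, naming the most nearly collinear pair of
    reference rows; ``ridge > 0`` instead solves
    ``(P P^T + ridge I)^{-1} P`` (off by default).
    """
    if method not in ("svd", "explicit"):
        raise ValidationError(f"unknown method {method!r}")
    mat = P.P
    sv = np.linalg.svd(mat, compute_uv=False)
    if sv[-1] == 0:
        raise NumericalError(
            "reference matrix is rank deficient; most collinear rows: "
            + _near_collinear_rows(mat, P.reference_labels)
        )
    cond = (sv[0] / sv[-1]) ** 2          # condition number of P P^T
    if ridge > 0:
        gram = mat @ mat.T + ridge * np.eye(P.r)
        S = np.linalg.solve(gram, mat)
    else:
        if cond > condition_cap:
            raise NumericalError(
                f"condition number {cond:.3e} of P*P^T exceeds cap "
                f"{condition_cap:.1e}; most collinear reference rows: "
                + _near_collinear_rows(mat, P.reference_labels)
            )
        if method == "explicit":
            S = np.linalg.inv(mat @ mat.T) @ mat
        else:
            S = np.linalg.pinv(mat.T)
    return ReferenceTransform(S=S, condition_number=float(cond),
                              reference_labels=P.reference_labels,
                              animal_id=P.animal_id)


def map_to_global(transform: ReferenceTransform, v_local) -> GlobalVector:
    """Project a local response vector into the reference odour space."""
    if isinstance(v_local, ResponseVector):
        vec = v_local.values
        meta = dict(animal=v_local.animal, odorant=v_local.odorant,
                    concentration=v_local.concentration)
    else:
        vec = np.asarray(v_local, dtype=float)
        meta = dict(animal=transform.animal_id)
    if vec.size != transform.q:
        raise ValidationError(
            f"local vector length {vec.size} != q = {transform.q}"
        )
    return GlobalVector(values=transform.S @ vec, **meta)


def out_of_span_residual(P: ReferenceProjection, v_local,
                         v_global: GlobalVector) -> float:
    """``||P^T v_global - v_local||``: zero iff the local response lies in
    the span of the reference responses."""
    vec = v_local.values if isinstance(v_local, ResponseVector) else np.asarray(v_local)
    return float(np.linalg.norm(P.P.T @ v_global.values - vec))
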