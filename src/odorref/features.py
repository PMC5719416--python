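"""Convex-cone column selection and pixel pooling.

Unsupervised feature selection: choose ``c`` pixel columns of the movie
matrix ``A`` such that fitting every column of ``A`` by non-negative
linear combinations of the selected columns minimizes the Frobenius-norm
reconstruction error ``||A - F X||_F`` with ``X >= 0``.  Columns inside
the convex cone spanned by the selection are reconstructed exactly;
columns outside contribute to the error.

Selection has two phases.  The forward pass hunts extreme rays of the
data cone: at each step the residual direction of the worst-represented
column is taken, and the column maximizing a linear-fractional score
(residual correlation divided by a strictly positive functional of the
column) joins the basis — a scale-invariant criterion whose maximum over
a finitely generated cone is attained at an extreme ray (mediant
inequality), so on exact cone data the pass recovers the generating
columns.  A swap-refinement pass then locally minimizes the Frobenius
objective ``||A - F X||`` by trying single-column replacements until no
swap improves; for ``c = 1`` this coincides with exhaustive search over
single columns.  NNLS is separable per column under the Frobenius norm;
each column solve is reduced through a thin QR factorization of the
basis, so one fit costs one small NNLS per column.

Selected features are denoised by pooling: the seed pixel's trace is
replaced by the mean over the spatially contiguous (4-connected) pixels
whose trace correlates with the seed above a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import qr
from scipy.optimize import nnls

from .errors import ValidationError
from .imaging_io import MovieMatrix

__all__ = [
    "FeatureBasis",
    "convex_cone_select",
    "pool_similar_pixels",
    "explained_norm_fraction",
]


@dataclass
class FeatureBasis:
    """Result of convex-cone selection.

    ``indices`` are the selected pixel-column ids (in selection order),
    ``F`` the ``(m x c)`` selected columns, ``X`` the ``(c x p)``
    non-negative coefficients, and ``norm_error = ||A - F X||_F``.
    """

    indices: tuple[int, ...]
    F: np.ndarray
    X: np.ndarray
    norm_error: float
    total_norm: float

    @property
    def c(self) -> int:
        return len(self.indices)

    @property
    def explained_fraction(self) -> float:
        if self.c == 0:
            return 0.0
        return 1.0 - self.norm_error / self.total_norm

    def summary(self) -> dict:
        return {"c": self.c, "norm_error": float(self.norm_error),
                "explained_fraction": float(self.explained_fraction)}


def _as_values(A) -> np.ndarray:
    if isinstance(A, MovieMatrix):
        return A.values
    return np.asarray(A, dtype=float)


def _nnls_residuals(basis: np.ndarray, targets: np.ndarray,
                    want_coefficients: bool = False):
    """Sum of squared NNLS residuals fitting every target column by the
    basis columns; optionally also the coefficient matrix.

    Reduces each ``min ||a - B x||, x >= 0`` through the economy QR of
    ``B``: the residual splits into the in-span part solved by NNLS on
    ``(R, Q^T a)`` plus the constant out-of-span norm.
    """
    Q, R = qr(basis, mode="economic")
    Qta = Q.T @ targets                       # (k, n_targets)
    # out-of-span component computed explicitly (a difference of squared
    # norms cancels catastrophically for in-span columns)
    perp = targets - Q @ Qta
    perp_sq = np.einsum("ij,ij->j", perp, perp)
    k = basis.shape[1]
    coef = np.zeros((k, targets.shape[1])) if want_coefficients else None
    total = 0.0
    residuals = np.empty(targets.shape[1])
    for j in range(targets.shape[1]):
        x, rnorm = nnls(R, Qta[:, j])
        r_sq = rnorm ** 2 + perp_sq[j]
        residuals[j] = r_sq
        total += r_sq
        if want_coefficients:
            coef[:, j] = x
    if want_coefficients:
        return total, residuals, coef
    return total, residuals


def _forward_extreme_rays(values: np.ndarray, c: int,
                          candidates: np.ndarray,
                          targets: np.ndarray) -> list[int]:
    """Forward pass: pick ``c`` columns that are extreme rays of the cone.

    At each step the residual direction ``r`` of the worst-represented
    target column is scored against every candidate column ``a`` by the
    linear-fractional criterion ``(r . a) / (d . a)`` with ``d`` a
    strictly positive functional on the data cone (the mean data column).
    The criterion is scale invariant and, by the mediant inequality,
    maximized over non-negative combinations at an extreme ray.
    Candidates on which ``d`` is not safely positive fall back to a
    norm-normalized score.  Ties break toward the lowest column index.
    """
    m, p = values.shape
    d = values.mean(axis=1)
    if np.linalg.norm(d) == 0:
        d = values[:, int(np.argmax(np.linalg.norm(values, axis=0)))]
    d_dot = d @ values                             # (p,)
    col_norms = np.linalg.norm(values, axis=0)
    safe = d_dot > 1e-9 * np.linalg.norm(d) * np.maximum(col_norms, 1e-30)

    selected: list[int] = []
    resid = targets.copy()
    for _ in range(c):
        free = np.array([j for j in candidates if j not in selected])
        resid_norms = np.einsum("ij,ij->j", resid, resid)
        r = resid[:, int(np.argmax(resid_norms))]
        if np.linalg.norm(r) <= 1e-12 * max(np.linalg.norm(targets), 1.0):
            # cone already covers every target; any remaining column keeps
            # the error at zero — take the lowest free index
            selected.append(int(free.min()))
        else:
            corr = r @ values[:, free]
            with np.errstate(divide="ignore", invalid="ignore"):
                score = np.where(safe[free], corr / d_dot[free],
                                 corr / np.maximum(col_norms[free], 1e-30))
            best = free[int(np.argmax(score))]
            selected.append(int(best))
        _, res_sq, coef = _nnls_residuals(values[:, selected], targets,
                                          want_coefficients=True)
        resid = targets - values[:, selected] @ coef
    return selected


def convex_cone_select(A, c: int, *, max_candidates: int | None = None,
                       score_columns: int | None = None,
                       refine_sweeps: int = 4,
                       seed: int = 0) -> FeatureBasis:
    """Convex-cone selection of ``c`` columns of ``A``.

    Parameters
    ----------
    A
        ``(m x p)`` movie matrix (or :class:`MovieMatrix`).
    c
        Number of columns to select, ``1 <= c <= p``.
    max_candidates, score_columns
        Optional subsampling of the candidate pool and of the columns used
        for scoring, for large ``p``; the final coefficient fit always uses
        all columns.  Deterministic given ``seed``.
    refine_sweeps
        Maximum number of swap-refinement sweeps over the selection.

    Ties are broken toward the lowest column index.
    """
    values = _as_values(A)
    if values.ndim != 2 or values.size == 0:
        raise ValidationError("A must be a non-empty 2-D matrix")
    m, p = values.shape
    if not 1 <= c <= p:
        raise ValidationError(f"need 1 <= c <= p={p}, got c={c}")
    total_norm = float(np.linalg.norm(values))
    if total_norm == 0:
        raise ValidationError("A has zero norm; nothing to select")

    rng = np.random.default_rng(seed)
    if score_columns is not None and score_columns < p:
        score_idx = np.sort(rng.choice(p, size=score_columns, replace=False))
    else:
        score_idx = np.arange(p)
    targets = values[:, score_idx]
    if max_candidates is not None and max_candidates < p:
        candidates = np.sort(rng.choice(p, size=max_candidates,
                                        replace=False))
    else:
        candidates = np.arange(p)

    selected = _forward_extreme_rays(values, c, candidates, targets)
    current_err, _ = _nnls_residuals(values[:, selected], targets)

    # swap refinement of the Frobenius objective
    tol = 1e-10 * max(current_err, 1.0)
    for _ in range(refine_sweeps):
        improved = False
        for pos in range(c):
            best_j, best_err = selected[pos], current_err
            for j in candidates:
                if j in selected:
                    continue
                trial = list(selected)
                trial[pos] = int(j)
                err, _ = _nnls_residuals(values[:, trial], targets)
                if err < best_err - tol:
                    best_j, best_err = int(j), err
            if best_j != selected[pos]:
                selected[pos] = best_j
                current_err = best_err
                improved = True
        if not improved:
            break

    F = values[:, selected]
    total_sq, _, X = _nnls_residuals(F, values, want_coefficients=True)
    return FeatureBasis(indices=tuple(selected), F=F, X=X,
                        norm_error=float(np.sqrt(total_sq)),
                        total_norm=total_norm)


def pool_similar_pixels(movie_matrix, feature_index: int,
                        similarity_threshold: float = 0.8,
                        max_radius: int = 3,
                        shape: tuple[int, int] | None = None) -> np.ndarray:
    """Mean trace over the contiguous patch of pixels similar to a seed.

    Starting from the seed pixel, a region is grown by 4-connectivity,
    admitting neighbours whose Pearson correlation with the seed trace is
    at least ``similarity_threshold`` and whose Chebyshev distance from
    the seed is at most ``max_radius``.  The seed always belongs to the
    pool; constant (zero-variance) neighbours never do.
    """
    if isinstance(movie_matrix, MovieMatrix):
        values, (h, w) = movie_matrix.values, movie_matrix.shape
    else:
        values = np.asarray(movie_matrix, dtype=float)
        if shape is None:
            raise ValidationError("shape required for a bare matrix")
        h, w = shape
    if not -1.0 <= similarity_threshold <= 1.0:
        raise ValidationError("similarity threshold must be in [-1, 1]")
    p = values.shape[1]
    if not 0 <= feature_index < p:
        raise ValidationError(f"feature index {feature_index} outside [0, {p})")

    seed_trace = values[:, feature_index]
    seed_sd = seed_trace.std()
    sr, sc = divmod(feature_index, w)

    def similar(idx: int) -> bool:
        if seed_sd == 0:
            return False
        other = values[:, idx]
        if other.std() == 0:
            return False
        r = np.corrcoef(seed_trace, other)[0, 1]
        return bool(r >= similarity_threshold)

    pool = {feature_index}
    frontier = [(sr, sc)]
    while frontier:
        r0, c0 = frontier.pop()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            r1, c1 = r0 + dr, c0 + dc
            if not (0 <= r1 < h and 0 <= c1 < w):
                continue
            if max(abs(r1 - sr), abs(c1 - sc)) > max_radius:
                continue
            idx = r1 * w + c1
            if idx in pool:
                continue
            if similar(idx):
                pool.add(idx)
                frontier.append((r1, c1))
    return values[:, sorted(pool)].mean(axis=1)


def explained_norm_fraction(basis: FeatureBasis, A) -> float:
    """Fraction of ``||A||_F`` explained: ``1 - ||A - F X||_F / ||A||_F``."""
    values = _as_values(A)
    norm = float(np.linalg.norm(values))
    if norm == 0:
        raise ValidationError("A has zero norm")
    if basis.c == 0:
        return 0.0
    resid = float(np.linalg.norm(values - basis.F @ basis.X))
    return 1.0 - resid / norm
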