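"""Raw traces to response vectors: dF/F, time-point selection, autoscaling.

The processing chain per animal is: relative fluorescence change
(dF/F against a fixed pre-stimulus baseline window), selection of the
t = 10 peri-stimulus time points covering both pulse responses,
per-dimension standardization ("autoscaling") across all of the animal's
odorant responses, and row-major reshaping of each (t x c) block into a
length q = t*c response vector.

Frame indices are 1-based; the default baseline window is frames 3-22,
i.e. the 20 time points preceding the first stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "ResponseBlock",
    "ResponseVector",
    "delta_f_over_f",
    "select_timepoints",
    "autoscale",
    "reshape_to_vector",
    "vector_to_block",
    "DEFAULT_BASELINE_WINDOW",
]

DEFAULT_BASELINE_WINDOW = (3, 22)


@dataclass
class ResponseBlock:
    """One odorant response: ``(t x c)`` values at selected time points."""

    values: np.ndarray
    time_indices: tuple[int, ...]
    feature_ids: tuple[int, ...]
    animal: str = ""
    odorant: str = ""
    concentration: float = 1.0

    @property
    def t(self) -> int:
        return self.values.shape[0]

    @property
    def c(self) -> int:
        return self.values.shape[1]


@dataclass
class ResponseVector:
    """One odorant response flattened to length ``q = t*c``."""

    values: np.ndarray
    animal: str = ""
    odorant: str = ""
    concentration: float = 1.0
    t: int = 0
    c: int = 0

    @property
    def q(self) -> int:
        return self.values.size


def delta_f_over_f(trace_matrix: np.ndarray,
                   baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
                   feature_ids=None) -> np.ndarray:
    """Per-column relative fluorescence change ``(f_j - f0) / f0``.

    ``f0`` is each column's mean over the (1-based, inclusive) baseline
    window.  A column whose baseline mean is zero is reported by name.
    """
    values = np.asarray(trace_matrix, dtype=float)
    if values.ndim != 2:
        raise ValidationError("trace matrix must be 2-D (frames x features)")
    s = values.shape[0]
    lo, hi = baseline_window
    if not (1 <= lo <= hi <= s):
        raise ValidationError(
            f"baseline window [{lo}, {hi}] outside frames [1, {s}]"
        )
    f0 = values[lo - 1:hi, :].mean(axis=0)
    bad = np.flatnonzero(f0 == 0)
    if bad.size:
        names = ([feature_ids[i] for i in bad[:5]] if feature_ids is not None
                 else bad[:5].tolist())
        raise ValidationError(
            f"zero baseline mean for feature(s) {names}; dF/F undefined"
        )
    return (values - f0) / f0


def select_timepoints(trace_matrix: np.ndarray,
                      pulse_frames: tuple[int, ...] = (25, 37),
                      t: int = 10, offset: int = 0
                      ) -> tuple[np.ndarray, tuple[int, ...]]:
    """Pick ``t/2`` consecutive frames from each pulse onset.

    The two windows must lie within the recording and not overlap.
    ``offset`` delays both windows (e.g. to centre on the indicator peak).
    Returns the ``(t x c)`` sub-matrix and the chosen 1-based frame indices.
    """
    values = np.asarray(trace_matrix, dtype=float)
    if values.ndim != 2:
        raise ValidationError("trace matrix must be 2-D (frames x features)")
    if len(pulse_frames) != 2:
        raise ValidationError("exactly two pulse-onset frames expected")
    if t < 2 or t % 2:
        raise ValidationError(f"t must be a positive even count, got {t}")
    s = values.shape[0]
    half = t // 2
    windows = []
    for pf in pulse_frames:
        start = pf + offset
        stop = start + half - 1
        if not (1 <= start and stop <= s):
            raise ValidationError(
                f"time-point window [{start}, {stop}] exceeds frames [1, {s}]"
            )
        windows.append(range(start, stop + 1))
    if set(windows[0]) & set(windows[1]):
        raise ValidationError("pulse windows overlap")
    indices = tuple(list(windows[0]) + list(windows[1]))
    rows = np.array(indices) - 1
    return values[rows, :], indices


def autoscale(blocks: list[ResponseBlock],
              axis_policy: str = "across_samples",
              ) -> list[ResponseBlock]:
    """Standardize response blocks to zero mean, unit variance.

    ``across_samples`` (default): each (time point, feature) dimension is
    standardized over the population of blocks — all odorant responses of
    one animal.  ``within_sample``: each block is standardized over its own
    entries.  The population standard deviation (``ddof=0``) is used;
    zero-variance dimensions are set to 0 rather than dividing by zero.
    """
    if axis_policy not in ("across_samples", "within_sample"):
        raise ValidationError(f"unknown axis_policy {axis_policy!r}")
    if axis_policy == "within_sample":
        out = []
        for b in blocks:
            v = b.values
            if v.size < 2:
                raise ValidationError("autoscale needs >= 2 values per block")
            sd = v.std()
            z = np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd
            out.append(ResponseBlock(z, b.time_indices, b.feature_ids,
                                     b.animal, b.odorant, b.concentration))
        return out

    if len(blocks) < 2:
        raise ValidationError(
            "autoscale across samples needs >= 2 response blocks"
        )
    shapes = {b.values.shape for b in blocks}
    if len(shapes) > 1:
        raise ValidationError(f"blocks of mixed shape: {sorted(shapes)}")
    stack = np.stack([b.values for b in blocks])    # (n, t, c)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0)
    z = np.where(sd == 0, 0.0, (stack - mean) / np.where(sd == 0, 1.0, sd))
    return [ResponseBlock(z[i], b.time_indices, b.feature_ids,
                          b.animal, b.odorant, b.concentration)
            for i, b in enumerate(blocks)]


def reshape_to_vector(block: ResponseBlock) -> ResponseVector:
    """Flatten a ``(t x c)`` block row-major (time-major) to length t*c."""
    return ResponseVector(values=block.values.reshape(-1).copy(),
                          animal=block.animal, odorant=block.odorant,
                          concentration=block.concentration,
                          t=block.t, c=block.c)


def vector_to_block(vector: ResponseVector,
                    time_indices: tuple[int, ...] = (),
                    feature_ids: tuple[int, ...] = ()) -> ResponseBlock:
    """Inverse of :func:`reshape_to_vector`."""
    if vector.t * vector.c != vector.q:
        raise ValidationError("vector does not carry a consistent (t, c)")
    return ResponseBlock(values=vector.values.reshape(vector.t, vector.c),
                         time_indices=time_indices, feature_ids=feature_ids,
                         animal=vector.animal, odorant=vector.odorant,
                         concentration=vector.concentration)
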