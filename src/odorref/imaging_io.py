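"""Movie stacks: reading/writing TIFF, rigid stabilization, matrix assembly.

A :class:`Movie` is one recording (``s`` frames of ``h x w`` fluorescence
values) for one (animal, odorant, concentration) triple.  All recordings of
one animal are concatenated row-wise into a :class:`MovieMatrix` whose
columns are pixels; downstream feature selection and response extraction
operate on that matrix.

Frame indices are 1-based throughout, matching the acquisition convention
in which the baseline window is "time points 3 to 22".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .errors import InputOutputError, ValidationError

__all__ = [
    "Movie",
    "MovieMatrix",
    "read_movie",
    "write_movie",
    "stabilize",
    "assemble_movie_matrix",
]


@dataclass
class Movie:
    """One fluorescence recording.

    Parameters
    ----------
    frames
        Array of shape ``(s, h, w)``; raw fluorescence in arbitrary units.
    frame_rate
        Acquisition rate in Hz.
    stimulus_frames
        1-based frame indices of the stimulus pulse onsets.
    animal, odorant
        Identity labels.
    concentration
        Dilution fraction of the odorant (e.g. ``1e-4``).
    """

    frames: np.ndarray
    frame_rate: float = 4.0
    stimulus_frames: tuple[int, ...] = (25, 37)
    animal: str = ""
    odorant: str = ""
    concentration: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValidationError(
                f"movie frames must be (s, h, w) with s >= 1, got {self.frames.shape}"
            )
        s = self.frames.shape[0]
        for f in self.stimulus_frames:
            if not (1 <= f <= s):
                raise ValidationError(
                    f"stimulus frame {f} outside [1, {s}]"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape ``(h, w)``."""
        return self.frames.shape[1:]

    @property
    def n_pixels(self) -> int:
        h, w = self.shape
        return h * w

    def as_matrix(self) -> np.ndarray:
        """Frames flattened row-major to ``(s, h*w)``."""
        return self.frames.reshape(self.n_frames, -1)


@dataclass
class MovieMatrix:
    """Per-animal concatenation of recordings: ``m`` rows by ``p`` pixels.

    ``row_index`` has one row per matrix row with columns
    (odorant, concentration, frame); ``pixel_coords`` holds the (row, col)
    grid position of each pixel column, in row-major order.
    """

    values: np.ndarray
    row_index: pd.DataFrame
    pixel_coords: np.ndarray
    shape: tuple[int, int]
    animal: str = ""
    frame_rate: float = 4.0
    stimulus_frames: tuple[int, ...] = (25, 37)
    recording_lengths: list[int] = field(default_factory=list)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def recordings(self):
        """Iterate over (odorant, concentration, row-slice) per recording."""
        start = 0
        for length in self.recording_lengths:
            sl = slice(start, start + length)
            odo = self.row_index["odorant"].iloc[start]
            conc = self.row_index["concentration"].iloc[start]
            yield odo, conc, sl
            start += length

    def to_csv(self, path) -> None:
        """Export as CSV with a header row of pixel coordinates."""
        cols = [f"px_{r}_{c}" for r, c in self.pixel_coords]
        df = pd.DataFrame(self.values, columns=cols)
        out = pd.concat([self.row_index.reset_index(drop=True), df], axis=1)
        out.to_csv(path, index=False)


def read_movie(path, frame_rate: float = 4.0,
               stimulus_frames: tuple[int, ...] = (25, 37),
               animal: str = "", odorant: str = "",
               concentration: float = 1.0) -> Movie:
    """Read a multi-frame TIFF into a :class:`Movie`.

    Values are taken as stored; a single-frame file yields ``s = 1``.
    """
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise InputOutputError(f"cannot read TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise InputOutputError(
            f"TIFF {path} has unexpected dimensionality {data.ndim}"
        )
    return Movie(frames=data.astype(float), frame_rate=frame_rate,
                 stimulus_frames=stimulus_frames, animal=animal,
                 odorant=odorant, concentration=concentration)


def write_movie(movie: Movie, path) -> None:
    """Write a movie as a multi-frame float TIFF."""
    try:
        tifffile.imwrite(path, movie.frames.astype(np.float64))
    except OSError as exc:  # pragma: no cover - disk errors
        raise InputOutputError(f"cannot write TIFF {path}: {exc}") from exc


def _integer_shift(reference: np.ndarray, frame: np.ndarray) -> tuple[int, int]:
    """Integer translation to apply to ``frame`` to align it to ``reference``.

    The full circular cross-correlation is computed by FFT; among indices
    within 1e-9 (relative) of the maximum the smallest shift wins
    (by L1 magnitude, then lexicographically), so a featureless frame maps
    to (0, 0).
    """
    f_ref = np.fft.fft2(reference)
    f_frm = np.fft.fft2(frame)
    cc = np.fft.ifft2(f_ref * np.conj(f_frm)).real
    peak = cc.max()
    tol = 1e-9 * max(abs(peak), 1.0)
    ties = np.argwhere(cc >= peak - tol)
    h, w = cc.shape

    def signed(idx, n):
        return idx - n if idx > n // 2 else idx

    candidates = [(signed(r, h), signed(c, w)) for r, c in ties]
    candidates.sort(key=lambda s: (abs(s[0]) + abs(s[1]), s[0], s[1]))
    return candidates[0]


def stabilize(movie: Movie, reference_frame: int = 1
              ) -> tuple[Movie, np.ndarray]:
    """Rigid (translation-only) movement correction.

    Each frame is shifted by the integer translation maximizing its
    cross-correlation with the reference frame.  Edges are filled with the
    nearest value.  Returns the corrected movie and the applied
    ``(s, 2)`` array of (dy, dx) shifts.
    """
    s = movie.n_frames
    if s < 2:
        raise ValidationError("stabilize requires at least 2 frames")
    if not (1 <= reference_frame <= s):
        raise ValidationError(
            f"reference frame {reference_frame} outside [1, {s}]"
        )
    ref = movie.frames[reference_frame - 1]
    out = np.empty_like(movie.frames)
    shifts = np.zeros((s, 2), dtype=int)
    for j in range(s):
        dy, dx = _integer_shift(ref, movie.frames[j])
        shifts[j] = (dy, dx)
        if dy == 0 and dx == 0:
            out[j] = movie.frames[j]
        else:
            out[j] = ndimage.shift(movie.frames[j], (dy, dx), order=0,
                                   mode="nearest")
    return replace(movie, frames=out), shifts


def assemble_movie_matrix(movies: list[Movie]) -> MovieMatrix:
    """Stack all recordings of one animal into an ``(m x p)`` matrix.

    Rows are stacked in the given recording order; every value of every
    input movie appears exactly once.
    """
    if not movies:
        raise ValidationError("assemble_movie_matrix: empty movie list")
    animals = {m.animal for m in movies}
    if len(animals) > 1:
        raise ValidationError(f"mixed animals in one matrix: {sorted(animals)}")
    shapes = {m.shape for m in movies}
    if len(shapes) > 1:
        raise ValidationError(f"mixed frame shapes: {sorted(shapes)}")
    h, w = movies[0].shape

    blocks, rows = [], []
    for mv in movies:
        blocks.append(mv.as_matrix())
        for j in range(1, mv.n_frames + 1):
            rows.append((mv.odorant, mv.concentration, j))
    values = np.vstack(blocks)
    row_index = pd.DataFrame(rows, columns=["odorant", "concentration", "frame"])
    coords = np.array([(r, c) for r in range(h) for c in range(w)])
    return MovieMatrix(
        values=values,
        row_index=row_index,
        pixel_coords=coords,
        shape=(h, w),
        animal=movies[0].animal,
        frame_rate=movies[0].frame_rate,
        stimulus_frames=movies[0].stimulus_frames,
        recording_lengths=[m.n_frames for m in movies],
    )
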