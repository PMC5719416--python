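"""Synthetic antennal calcium-imaging recordings.

The generator emulates the statistical structure that functional reference
mapping assumes in real antenna data:

* combinatorial receptor tuning — each odorant activates a subset of
  receptor types with graded, non-negative gains;
* animal-specific spatial mixing — each receptor type loads onto a
  spatially contiguous patch of pixels whose placement differs between
  animals, so every pixel trace is a non-negative linear combination of
  receptor time courses;
* slow indicator dynamics — pulse responses are difference-of-exponential
  transients (GCaMP-like), with the second pulse partially adapted;
* multiplicative concentration scaling over decadic dilutions, via a
  power-law (compressive) dose term;
* additive Gaussian noise on a positive fluorescence baseline, with
  optional per-frame photobleaching decay.

With zero noise and zero bleaching, each pixel's relative fluorescence
change is exactly a non-negative combination of the receptor time courses,
which is the ground truth that convex-cone feature selection recovers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .imaging_io import Movie, write_movie

__all__ = [
    "StimulusProtocol",
    "ReceptorTuning",
    "AnimalMixing",
    "NoiseModel",
    "indicator_kernel",
    "make_cohort",
    "simulate_recording",
    "write_cohort_recordings",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing of one recording: 20 s at 4 Hz with two 1-s pulses.

    ``adaptation_factor`` scales the amplitude of the second (and any
    later) pulse relative to the first, modelling the partially adapted
    state of the repeated stimulus.
    """

    frame_rate: float = 4.0
    duration: float = 20.0
    pulse_onsets: tuple[float, ...] = (6.0, 9.0)
    pulse_duration: float = 1.0
    adaptation_factor: float = 0.8
    rise_time: float = 0.2
    decay_time: float = 2.0

    def __post_init__(self) -> None:
        n = self.frame_rate * self.duration
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValidationError(
                f"duration x frame_rate must be a positive integer, got {n}"
            )
        if not 0 < self.adaptation_factor <= 1:
            raise ValidationError("adaptation_factor must be in (0, 1]")
        for onset in self.pulse_onsets:
            f = self.onset_frame(onset)
            if not 1 <= f <= round(n):
                raise ValidationError(f"pulse onset {onset}s outside recording")

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration))

    def onset_frame(self, onset_s: float) -> int:
        """1-based frame index of a pulse onset: floor(onset * rate) + 1."""
        return int(math.floor(onset_s * self.frame_rate)) + 1

    @property
    def pulse_frames(self) -> tuple[int, ...]:
        return tuple(self.onset_frame(o) for o in self.pulse_onsets)

    @property
    def frame_times(self) -> np.ndarray:
        """Time of each frame in seconds; frame 1 is t = 0."""
        return np.arange(self.n_frames) / self.frame_rate


def indicator_kernel(times: np.ndarray, rise: float = 0.2,
                     decay: float = 2.0) -> np.ndarray:
    """Difference-of-exponentials calcium-indicator impulse response.

    ``k(x) = (exp(-x/decay) - exp(-x/rise)) / peak`` for ``x >= 0``, zero
    before, normalized so its continuous-time maximum equals 1.
    """
    if not 0 < rise < decay:
        raise ValidationError("kernel requires 0 < rise < decay")
    x = np.asarray(times, dtype=float)
    t_peak = rise * decay / (decay - rise) * math.log(decay / rise)
    peak = math.exp(-t_peak / decay) - math.exp(-t_peak / rise)
    out = np.where(x >= 0, np.exp(-x / decay) - np.exp(-x / rise), 0.0)
    return out / peak


def pulse_response(protocol: StimulusProtocol) -> np.ndarray:
    """Per-frame response waveform: shifted kernels at each pulse onset,
    later pulses scaled by ``adaptation_factor`` per preceding pulse."""
    t = protocol.frame_times
    g = np.zeros_like(t)
    for k, onset in enumerate(protocol.pulse_onsets):
        g += (protocol.adaptation_factor ** k) * indicator_kernel(
            t - onset, protocol.rise_time, protocol.decay_time)
    return g


@dataclass(frozen=True)
class ReceptorTuning:
    """Non-negative response gains of receptor types to odorants.

    ``amplitudes[r, o]`` is the peak relative-fluorescence response of
    receptor type ``r`` to odorant ``odorants[o]`` at
    ``reference_concentration``.  Dose scaling is a compressive power law,
    ``gain * (conc / reference_concentration) ** hill_exponent``, standing
    in for the saturating log-like dose-response of receptor neurons.
    """

    amplitudes: np.ndarray
    odorants: tuple[str, ...]
    hill_exponent: float = 0.25
    reference_concentration: float = 1e-2

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "odorants", tuple(self.odorants))
        if amps.ndim != 2 or amps.shape[1] != len(self.odorants):
            raise ValidationError(
                "amplitudes must be (n_receptors x n_odorants) matching labels"
            )
        if (amps < 0).any():
            raise ValidationError("receptor amplitudes must be non-negative")
        silent = np.flatnonzero(amps.max(axis=0) == 0)
        if silent.size:
            bad = [self.odorants[i] for i in silent]
            raise ValidationError(
                f"every odorant must activate >= 1 receptor; silent: {bad}"
            )

    @property
    def n_receptors(self) -> int:
        return self.amplitudes.shape[0]

    def activation(self, odorant: str, concentration: float) -> np.ndarray:
        """Per-receptor activation for one odorant at one concentration."""
        if odorant not in self.odorants:
            raise ValidationError(f"unknown odorant {odorant!r}")
        if concentration <= 0:
            raise ValidationError("concentration must be > 0")
        col = self.amplitudes[:, self.odorants.index(odorant)]
        dose = (concentration / self.reference_concentration) ** self.hill_exponent
        return col * dose


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise on a positive fluorescence baseline."""

    baseline_fluorescence: float = 100.0
    additive_sd: float = 0.5
    bleach_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_fluorescence <= 0:
            raise ValidationError("baseline fluorescence must be > 0")
        if not 0 <= self.bleach_rate < 1:
            raise ValidationError("bleach_rate must be in [0, 1)")
        if self.additive_sd < 0:
            raise ValidationError("additive_sd must be >= 0")


@dataclass(frozen=True)
class AnimalMixing:
    """Spatial loading of receptor types onto pixels for one animal.

    ``weights`` is ``(p_pixels x n_receptors)``, non-negative; each
    receptor occupies ``patch_count`` rectangular, spatially contiguous
    patches whose placement is sampled per animal.
    """

    weights: np.ndarray
    shape: tuple[int, int]
    layout_seed: int
    patch_count: int = 1
    animal_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        h, wid = self.shape
        if w.shape[0] != h * wid:
            raise ValidationError("weights rows must equal h*w pixels")
        if (w < 0).any():
            raise ValidationError("mixing weights must be non-negative")

    @property
    def n_pixels(self) -> int:
        return self.weights.shape[0]

    @property
    def n_receptors(self) -> int:
        return self.weights.shape[1]


def _sample_patch(rng: np.random.Generator, occupied: np.ndarray,
                  patch_hw: tuple[int, int]) -> tuple[slice, slice]:
    """Place one rectangular patch on free grid cells (rejection sampling).

    Patches keep a one-pixel halo of unoccupied cells between each other,
    emulating the non-responsive cuticle separating sensillum groups; this
    also makes receptor identity recoverable from spatial contiguity.
    """
    h, w = occupied.shape
    ph = int(rng.integers(patch_hw[0], patch_hw[1] + 1))
    pw = int(rng.integers(patch_hw[0], patch_hw[1] + 1))
    ph, pw = min(ph, h), min(pw, w)
    for _ in range(2000):
        r0 = int(rng.integers(0, h - ph + 1))
        c0 = int(rng.integers(0, w - pw + 1))
        halo = (slice(max(r0 - 1, 0), min(r0 + ph + 1, h)),
                slice(max(c0 - 1, 0), min(c0 + pw + 1, w)))
        if not occupied[halo].any():
            return (slice(r0, r0 + ph), slice(c0, c0 + pw))
    raise ValidationError(
        "could not place non-overlapping receptor patches; grid too small"
    )


def make_cohort(n_animals: int, tuning: ReceptorTuning,
                protocol: StimulusProtocol | None = None,
                noise: NoiseModel | None = None, seed: int = 0,
                shape: tuple[int, int] = (80, 60),
                patch_size: tuple[int, int] | None = None,
                patch_count: int = 1,
                weight_range: tuple[float, float] = (0.5, 1.5),
                ) -> list[AnimalMixing]:
    """Sample per-animal spatial mixing models sharing one receptor tuning.

    Animals share ``tuning`` but receive independent, non-overlapping
    rectangular receptor patches at animal-specific locations, emulating
    the individually scrambled sensillum patches on the antenna.
    Deterministic given ``seed``.
    """
    if n_animals < 1:
        raise ValidationError("n_animals must be >= 1")
    del protocol, noise  # layout does not depend on them; kept for symmetry
    h, w = shape
    if patch_size is None:
        lo = max(2, min(h, w) // 6)
        hi = max(lo, min(h, w) // 4)
        patch_size = (lo, hi)
    ss = np.random.SeedSequence(seed)
    cohort = []
    for a, child in enumerate(ss.spawn(n_animals)):
        layout_seed = int(child.generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(layout_seed)
        occupied = np.zeros(shape, dtype=bool)
        weights = np.zeros((h * w, tuning.n_receptors))
        grid = np.arange(h * w).reshape(shape)
        for r in range(tuning.n_receptors):
            for _ in range(patch_count):
                sl = _sample_patch(rng, occupied, patch_size)
                occupied[sl] = True
                idx = grid[sl].ravel()
                weights[idx, r] = rng.uniform(*weight_range, size=idx.size)
        cohort.append(AnimalMixing(weights=weights, shape=shape,
                                   layout_seed=layout_seed,
                                   patch_count=patch_count,
                                   animal_id=f"animal{a}"))
    return cohort


def simulate_recording(animal: AnimalMixing, tuning: ReceptorTuning,
                       odorant: str, concentration: float,
                       protocol: StimulusProtocol | None = None,
                       noise: NoiseModel | None = None,
                       seed: int = 0) -> Movie:
    """Simulate one recording of one odorant presentation.

    Pixel fluorescence at frame ``j`` (1-based) is::

        baseline * (1 - bleach)**(j-1) * (1 + sum_r W[px, r] * act_r * g_j)
        + N(0, additive_sd)

    where ``g`` is the pulse-response waveform (unit-peak indicator kernel
    at each onset, second pulse scaled by the adaptation factor) and
    ``act`` the concentration-scaled receptor activations.
    """
    protocol = protocol or StimulusProtocol()
    noise = noise or NoiseModel()
    act = tuning.activation(odorant, concentration)
    if animal.n_receptors != tuning.n_receptors:
        raise ValidationError("mixing model and tuning disagree on receptors")
    g = pulse_response(protocol)                      # (s,)
    drive = np.outer(g, animal.weights @ act)         # (s, p)
    decay = (1.0 - noise.bleach_rate) ** np.arange(protocol.n_frames)
    signal = noise.baseline_fluorescence * decay[:, None] * (1.0 + drive)
    if noise.additive_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise.additive_sd, size=signal.shape)
    h, w = animal.shape
    frames = signal.reshape(protocol.n_frames, h, w)
    return Movie(frames=frames, frame_rate=protocol.frame_rate,
                 stimulus_frames=protocol.pulse_frames,
                 animal=animal.animal_id, odorant=odorant,
                 concentration=concentration)


def write_cohort_recordings(out_dir, cohort: list[AnimalMixing],
                            tuning: ReceptorTuning,
                            stimuli: list[tuple[str, float]],
                            protocol: StimulusProtocol | None = None,
                            noise: NoiseModel | None = None,
                            seed: int = 0) -> pd.DataFrame:
    """Simulate and write one TIFF per (animal, odorant, concentration),
    plus a ``metadata.csv`` sidecar table; returns the metadata frame."""
    from pathlib import Path

    protocol = protocol or StimulusProtocol()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(len(cohort) * len(stimuli)) % (2 ** 31))
    for animal in cohort:
        for odorant, conc in stimuli:
            rec_seed = int(next(seeds))
            movie = simulate_recording(animal, tuning, odorant, conc,
                                       protocol, noise, seed=rec_seed)
            fname = f"{animal.animal_id}_{odorant}_{conc:.0e}.tif"
            write_movie(movie, out / fname)
            rows.append({"animal": animal.animal_id, "odorant": odorant,
                         "concentration": conc, "seed": rec_seed,
                         "file": fname,
                         "pulse_frames": ";".join(map(str, protocol.pulse_frames))})
    meta = pd.DataFrame(rows)
    meta.to_csv(out / "metadata.csv", index=False)
    return meta
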