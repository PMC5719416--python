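"""End-to-end orchestration: movies -> response vectors -> cross-validation.

Stage order per animal: (optional) stabilization, dF/F per recording,
concatenation into the movie matrix, convex-cone feature selection with
pixel pooling, peri-stimulus time-point selection, autoscaling across the
animal's responses, reshaping to response vectors.  The cross-validation
runner then consumes the pooled cohort.

Feature selection (the most expensive stage) is cached on disk keyed by a
content hash of the movie matrix and the selection parameters, so
re-running with a different classifier does not recompute it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .crossval import CohortResponses, CrossvalResult, ExperimentDesign, \
    run_experiment
from .errors import ValidationError
from .features import convex_cone_select, pool_similar_pixels
from .imaging_io import Movie, MovieMatrix, assemble_movie_matrix, stabilize
from .preprocess import DEFAULT_BASELINE_WINDOW, ResponseBlock, autoscale, \
    delta_f_over_f, reshape_to_vector, select_timepoints

__all__ = ["PipelineParams", "PipelineConfig", "process_animal",
           "process_cohort", "run_crossval"]


@dataclass
class PipelineParams:
    """Processing parameters shared by all animals."""

    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW
    t: int = 10
    # one-frame delay so the 5-frame windows straddle the indicator peak
    # (~0.5 s after onset) instead of starting on the zero-signal onset frame
    timepoint_offset: int = 1
    c: int = 300
    pooling_threshold: float = 0.8
    pooling_radius: int = 3
    max_candidates: int | None = None
    score_columns: int | None = None
    stabilize: bool = False
    axis_policy: str = "across_samples"
    selection_seed: int = 0

    def validate(self, p: int | None = None) -> None:
        lo, hi = self.baseline_window
        if not 1 <= lo <= hi:
            raise ValidationError("invalid baseline window")
        if self.t < 2 or self.t % 2:
            raise ValidationError("t must be a positive even count")
        if self.c < 1:
            raise ValidationError("c must be >= 1")
        if p is not None and self.c > p:
            raise ValidationError(f"c={self.c} exceeds pixel count p={p}")
        if not -1 <= self.pooling_threshold <= 1:
            raise ValidationError("pooling threshold must be in [-1, 1]")


def _matrix_digest(A: MovieMatrix, params: PipelineParams) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(A.values).tobytes())
    h.update(repr((params.c, params.pooling_threshold, params.pooling_radius,
                   params.max_candidates, params.score_columns,
                   params.selection_seed)).encode())
    return h.hexdigest()


def _select_features(A: MovieMatrix, params: PipelineParams,
                     cache_dir: Path | None):
    """Convex-cone selection + pooling, cached by content hash."""
    key = _matrix_digest(A, params) if cache_dir else None
    if cache_dir is not None:
        cache_file = Path(cache_dir) / f"features_{key}.npz"
        if cache_file.exists():
            data = np.load(cache_file)
            return tuple(int(i) for i in data["indices"]), data["pooled"]
    basis = convex_cone_select(A, params.c,
                               max_candidates=params.max_candidates,
                               score_columns=params.score_columns,
                               seed=params.selection_seed)
    pooled = np.column_stack([
        pool_similar_pixels(A, idx,
                            similarity_threshold=params.pooling_threshold,
                            max_radius=params.pooling_radius)
        for idx in basis.indices
    ])
    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        np.savez(cache_file, indices=np.array(basis.indices), pooled=pooled)
    return basis.indices, pooled


def process_animal(movies: list[Movie], params: PipelineParams,
                   cache_dir: Path | None = None) -> list:
    """Full per-animal processing; returns one response vector per movie."""
    if not movies:
        raise ValidationError("no movies for animal")
    params.validate(p=movies[0].n_pixels)
    if params.stabilize:
        movies = [stabilize(m)[0] if m.n_frames > 1 else m for m in movies]
    dff = []
    for mv in movies:
        vals = delta_f_over_f(mv.as_matrix(), params.baseline_window)
        dff.append(dataclasses.replace(mv, frames=vals.reshape(mv.frames.shape)))
    A = assemble_movie_matrix(dff)
    indices, pooled = _select_features(A, params, cache_dir)

    blocks = []
    for odorant, conc, sl in A.recordings():
        traces = pooled[sl, :]
        sub, time_idx = select_timepoints(
            traces, A.stimulus_frames, t=params.t,
            offset=params.timepoint_offset)
        blocks.append(ResponseBlock(values=sub, time_indices=time_idx,
                                    feature_ids=indices, animal=A.animal,
                                    odorant=odorant, concentration=conc))
    blocks = autoscale(blocks, axis_policy=params.axis_policy)
    return [reshape_to_vector(b) for b in blocks]


def process_cohort(movies_by_animal: dict[str, list[Movie]],
                   params: PipelineParams,
                   cache_dir: Path | None = None) -> CohortResponses:
    records = []
    for animal in movies_by_animal:
        records.extend(process_animal(movies_by_animal[animal], params,
                                      cache_dir))
    return CohortResponses(records)


def run_crossval(cohort: CohortResponses, design: ExperimentDesign
                 ) -> CrossvalResult:
    return run_experiment(cohort, design)


@dataclass
class PipelineConfig:
    """Serializable configuration covering all pipeline stages."""

    params: PipelineParams = field(default_factory=PipelineParams)
    design: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        payload = {
            "params": dataclasses.asdict(self.params),
            "design": self.design,
            "simulate": self.simulate,
            "paths": self.paths,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        raw = payload.get("params", {}) or {}
        known = {f.name for f in dataclasses.fields(PipelineParams)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown pipeline parameters: {sorted(unknown)}")
        if "baseline_window" in raw:
            raw["baseline_window"] = tuple(raw["baseline_window"])
        params = PipelineParams(**raw)
        return cls(params=params, design=payload.get("design", {}) or {},
                   simulate=payload.get("simulate", {}) or {},
                   paths=payload.get("paths", {}) or {})

    def experiment_design(self) -> ExperimentDesign:
        d = dict(self.design)
        for key in ("reference_odorants", "test_odorants"):
            if key not in d:
                raise ValidationError(f"design missing {key!r}")
            d[key] = tuple(d[key])
        for key in ("train_concentrations", "test_concentrations"):
            if d.get(key) is not None:
                d[key] = tuple(float(x) for x in d[key])
        return ExperimentDesign(**d)

    def dump_results(self, result: CrossvalResult, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(result.summary(), fh, indent=2)
        result.per_split_table().to_csv(out / "per_split.csv", index=False)
        result.pooled_confusion.as_dataframe().to_csv(
            out / "pooled_confusion.csv")
        result.pooled_confusion.as_percentages().to_csv(
            out / "pooled_confusion_percent.csv")
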