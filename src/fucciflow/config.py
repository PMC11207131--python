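"""Parameter dataclasses for every pipeline stage, plus YAML/JSON loading.

Defaults mirror a 10x, 10-minute-interval epithelial monolayer regime; all
values are configurable per run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class SimConfig:
    """Synthetic FUCCI-movie generator settings.

    ``phase_durations`` are mean frame counts per color state; each cell draws
    its own durations once from a truncated normal with coefficient of
    variation ``phase_duration_cv`` (truncated at 1 frame). ``init_phase``
    is "random" (cells start uniformly distributed through their cycle) or a
    phase name (every initial cell starts at that phase's first frame).
    """

    fov_size_px: int = 512
    n_frames: int = 60
    dt_min: float = 10.0
    n_cells_init: int = 100
    motility_speed: float = 0.5   # px/frame
    persistence: float = 0.7      # in [0, 1]
    drift: tuple[float, float] = (0.0, 0.0)  # px/frame
    repulsion_radius: float = 16.0  # px
    phase_durations: dict = field(default_factory=lambda: {
        "red": 40, "yellow": 6, "green": 30, "colorless": 4})
    phase_duration_cv: float = 0.2
    nucleus_sigma_px: float = 3.0
    peak_intensity: dict = field(default_factory=lambda: {
        "red": 2000.0, "green": 2000.0})
    background: float = 100.0
    noise_sd: float = 5.0
    division_enabled: bool = True
    init_phase: str = "random"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fov_size_px < 64:
            raise ValueError("fov_size_px must be >= 64")
        if self.n_cells_init < 1:
            raise ValueError("n_cells_init must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.motility_speed < 0 or self.noise_sd < 0:
            raise ValueError("motility_speed and noise_sd must be >= 0")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must lie in [0, 1]")
        for k in ("red", "yellow", "green", "colorless"):
            if self.phase_durations.get(k, 0) < 1:
                raise ValueError(f"phase duration '{k}' must be >= 1 frame")
        if self.init_phase not in ("random", "colorless", "red", "yellow", "green"):
            raise ValueError(f"unknown init_phase {self.init_phase!r}")
        # over-packing guard: disks of radius repulsion_radius/2 must fit
        if self.n_cells_init * self.repulsion_radius ** 2 > self.fov_size_px ** 2:
            raise ValueError("config over-packed: n_cells_init * repulsion_radius^2 "
                             "exceeds the FOV area")


@dataclass
class SegmentationParams:
    """Classical nuclear segmentation: smooth, threshold, fill, split, filter."""

    smoothing_sigma_px: float = 1.5
    threshold_method: str = "otsu"   # "otsu" | "fixed"
    fixed_threshold: float = 0.0     # counts, used when method == "fixed"
    min_area_px2: int = 9
    split_touching: bool = True
    watershed_min_distance_px: int = 5

    def __post_init__(self) -> None:
        if self.min_area_px2 < 1:
            raise ValueError("min_area_px2 must be >= 1")
        if self.smoothing_sigma_px < 0:
            raise ValueError("smoothing_sigma_px must be >= 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")


@dataclass
class TrackingParams:
    """Frame-to-frame LAP linking with gap closing."""

    max_link_distance_px: float = 15.0
    max_gap_frames: int = 2
    max_gap_distance_px: float = 15.0
    min_track_length: int = 3

    def __post_init__(self) -> None:
        if self.max_link_distance_px <= 0:
            raise ValueError("max_link_distance_px must be > 0")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")
        if self.min_track_length < 1:
            raise ValueError("min_track_length must be >= 1")


@dataclass
class FusionParams:
    """Red/green track pairing and phase fusion settings.

    ``similarity_threshold`` is the maximum average per-overlapping-frame
    center distance (strict inequality) for a pair to be called the same
    cell — 2 px for 10x imaging. ``grid_n`` is the pre-filter grid subdivision.
    """

    grid_n: int = 10
    similarity_threshold: float = 2.0
    min_overlap_frames: int = 2
    transition_criterion: str = "window_mid"  # window_start | window_mid | window_end

    def __post_init__(self) -> None:
        if self.grid_n < 1:
            raise ValueError("grid_n must be >= 1")
        if self.similarity_threshold <= 0:
            raise ValueError("similarity_threshold must be > 0")
        if self.min_overlap_frames < 1:
            raise ValueError("min_overlap_frames must be >= 1")
        if self.transition_criterion not in ("window_start", "window_mid", "window_end"):
            raise ValueError(f"unknown transition_criterion "
                             f"{self.transition_criterion!r}")


@dataclass
class KinematicsParams:
    """Velocity-field sampling and unit conversions.

    The Eulerian field averages nuclear velocities in square bins of side
    ``bin_side_fraction`` x FOV centered on a triangular lattice whose rows
    are spaced ``grid_row_spacing_fraction`` x FOV apart.
    """

    bin_side_fraction: float = 0.1
    grid_row_spacing_fraction: float = 0.05
    velocity_window_frames: int = 5
    px_per_um: float = 1.5385   # ~0.65 um/px at 10x
    min_per_frame: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.bin_side_fraction <= 1:
            raise ValueError("bin_side_fraction must lie in (0, 1]")
        if self.grid_row_spacing_fraction <= 0:
            raise ValueError("grid_row_spacing_fraction must be > 0")
        if self.velocity_window_frames < 1:
            raise ValueError("velocity_window_frames must be >= 1")


@dataclass
class PipelineConfig:
    """End-to-end run description: input paths, stage parameters, seed."""

    red_stack: str | None = None
    green_stack: str | None = None
    red_masks: str | None = None       # pre-made label TIFFs replace segmentation
    green_masks: str | None = None
    red_tracks: str | None = None      # pre-made track CSVs replace tracking too
    green_tracks: str | None = None
    output_dir: str = "fucciflow_out"
    fov_size_px: int | None = None     # required when starting from track CSVs
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    fusion: FusionParams = field(default_factory=FusionParams)
    kinematics: KinematicsParams = field(default_factory=KinematicsParams)
    sim: SimConfig = field(default_factory=SimConfig)
    log_level: str = "INFO"
    rng_seed: int = 0


_NESTED = {"segmentation": SegmentationParams, "tracking": TrackingParams,
           "fusion": FusionParams, "kinematics": KinematicsParams,
           "sim": SimConfig}


def config_from_dict(data: dict) -> PipelineConfig:
    kwargs = dict(data)
    for key, cls in _NESTED.items():
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = cls(**kwargs[key])
    if "drift" in data.get("sim", {}) and isinstance(kwargs.get("sim"), SimConfig):
        kwargs["sim"].drift = tuple(kwargs["sim"].drift)
    return PipelineConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return config_from_dict(data or {})


def config_to_dict(config: PipelineConfig) -> dict:
    return dataclasses.asdict(config)
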