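"""Run-wide configuration.

A single flat record of the physical and algorithmic constants shared by the
pipeline stages, with JSON round-trip and strict unknown-key rejection so a
run manifest is sufficient to reproduce a run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration.

    Attributes
    ----------
    pixel_size_A:
        Detector pixel size in Angstrom per pixel, used when the STAR file
        carries no optics table. 0.83 A/px corresponds to a K3 detector at
        105,000x magnification.
    mt_outer_diameter_nm:
        Outer wall-to-wall diameter of a microtubule; subtracted from
        center-to-center spacing to obtain the edge gap.
    coherence_threshold:
        Minimum weighted mean resultant length for a filament's consensus
        polarity to be considered confident.
    max_edge_gap_nm, min_overlap_frac:
        Gates for calling two filaments in one micrograph a bundled pair.
    pause_band_nm_s:
        Half-width of the zero-velocity band separating pause from
        growth/shrinkage in dynamics segmentation.
    min_phase_s:
        Shortest phase retained by the segmentation; shorter runs are
        absorbed into their neighbours.
    velocity_window:
        Sliding-window length (samples) for the per-sample velocity estimate
        that seeds the segmentation.
    seed:
        Base seed for any stochastic stage (simulation subcommands).
    out_dir:
        Output directory for CLI runs.
    """

    pixel_size_A: float = 0.83
    mt_outer_diameter_nm: float = 25.0
    coherence_threshold: float = 0.8
    max_edge_gap_nm: float = 50.0
    min_overlap_frac: float = 0.5
    pause_band_nm_s: float = 0.3
    min_phase_s: float = 5.0
    velocity_window: int = 5
    ambiguous_angle_tol_deg: float = 1.0
    near_polar_sin_tilt: float = 0.1
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_A",
            "mt_outer_diameter_nm",
            "coherence_threshold",
            "max_edge_gap_nm",
            "min_overlap_frac",
            "pause_band_nm_s",
            "min_phase_s",
            "velocity_window",
            "ambiguous_angle_tol_deg",
            "near_polar_sin_tilt",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"RunConfig.{name} must be positive")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def replace(self, **kwargs: Any) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


DEFAULT_CONFIG = RunConfig()
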