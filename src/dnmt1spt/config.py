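"""Configuration objects for the SPT pipeline.

All defaults mirror a fast live-cell HiLo acquisition: 10 ms frame interval
(~97 fps effective), 0.16 µm pixels, a 1.35 px Gaussian PSF and a 0.700 µm
axial detection slice. Internal computation is always in physical units
(µm, s); pixels appear only at the image boundary.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any


def _asdict_clean(obj: Any) -> dict:
    d = dataclasses.asdict(obj)

    def clean(v):
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, float) and math.isinf(v):
            return "inf"
        return v

    return clean(d)


@dataclass
class AcquisitionConfig:
    """Camera / optics parameters of the acquisition (real or simulated).

    ``dz`` is the effective axial thickness of the detection slice used both
    by the trajectory simulator (censoring) and by the defocalization
    correction of the kinetic fit. ``psf_sigma`` is in pixels, everything
    else in µm / s / photons.
    """

    frame_interval: float = 0.010
    exposure: float = 0.010
    pixel_size: float = 0.16
    psf_sigma: float = 1.35
    dz: float = 0.700
    fov: tuple[int, int] = (128, 256)  # (ny, nx) pixels
    photon_budget: float = 500.0
    background: float = 100.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.dz <= 0:
            raise ValueError("dz must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def fov_um(self) -> tuple[float, float]:
        return (self.fov[0] * self.pixel_size, self.fov[1] * self.pixel_size)


@dataclass
class DetectionConfig:
    """Spot detection / subpixel refinement parameters.

    ``log_error_threshold`` is the base-10 exponent of the per-pixel false
    positive rate of the matched-filter amplitude test (-5 by default, -6 for
    the sparser visualization setting); ``min_separation`` is the minimum
    distance in pixels between reported maxima.
    """

    log_error_threshold: float = -5.0
    psf_sigma: float = 1.35
    min_separation: float = 2.0
    fit_window_halfwidth: int = 4
    deflation_loops: int = 1

    def __post_init__(self) -> None:
        if self.log_error_threshold >= 0:
            raise ValueError("log_error_threshold must be < 0")


@dataclass
class LinkingConfig:
    """Trajectory linking parameters.

    The gating radius for a link spanning k frames is
    ``sqrt(4 * d_max_expected * k * frame_interval) * safety_factor``;
    up to ``max_gaps`` consecutive missed frames may be bridged.
    """

    d_max_expected: float = 5.0  # µm²/s
    max_gaps: int = 2
    frame_interval: float = 0.010
    safety_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.d_max_expected <= 0:
            raise ValueError("d_max_expected must be > 0")
        if self.max_gaps < 0:
            raise ValueError("max_gaps must be >= 0")

    def r_max(self, k: int) -> float:
        return math.sqrt(4.0 * self.d_max_expected * k * self.frame_interval) * self.safety_factor


# Diffusion-coefficient boxes (µm²/s) for the bounded least-squares fit.
TWO_STATE_BOUNDS = {"D_bound": (0.0001, 0.5), "D_free": (0.5, 10.0)}
THREE_STATE_BOUNDS = {
    "D_bound": (0.0001, 0.05),
    "D_free1": (0.05, 1.0),
    "D_free2": (1.0, 10.0),
}


@dataclass
class FitConfig:
    """Histogram compilation and kinetic-fit parameters.

    Displacement histograms use a 0.01 µm bin width, time gaps of
    1..``n_timepoints`` frames and at most ``jumps_per_trajectory`` jumps per
    trajectory per time gap (guards against over-representation of long
    bound tracks). The localization error sigma is fitted within
    ``sigma_bounds`` unless ``sigma_fixed`` is set.
    """

    n_states: int = 3
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(THREE_STATE_BOUNDS)
    )
    sigma_fixed: float | None = None
    sigma_bounds: tuple[float, float] = (0.01, 0.075)
    dz: float = 0.700
    use_dz_correction: bool = True
    objective: str = "pdf"
    n_restarts: int = 10
    seed: int = 0
    # histogram settings
    frame_interval: float = 0.010
    n_timepoints: int = 7
    bin_width: float = 0.01
    max_jump: float = 1.2
    jumps_per_trajectory: int | None = 4   # None: use all jumps
    min_jumps: int = 500

    def __post_init__(self) -> None:
        if self.n_states not in (2, 3):
            raise ValueError("n_states must be 2 or 3")
        if self.n_states == 2 and "D_free1" in self.bounds:
            self.bounds = dict(TWO_STATE_BOUNDS)
        if self.dz <= 0:
            raise ValueError("dz must be > 0")
        names = (
            ("D_bound", "D_free") if self.n_states == 2 else ("D_bound", "D_free1", "D_free2")
        )
        missing = [n for n in names if n not in self.bounds]
        if missing:
            raise ValueError(f"bounds missing entries for {missing}")
        prev_hi = -math.inf
        for n in names:
            lo, hi = self.bounds[n]
            if not (0 <= lo < hi):
                raise ValueError(f"invalid bound for {n}: {self.bounds[n]}")
            if lo < prev_hi:
                raise ValueError("diffusion bounds must be ordered and non-overlapping")
            prev_hi = hi

    @classmethod
    def two_state(cls, **kw) -> "FitConfig":
        kw.setdefault("bounds", dict(TWO_STATE_BOUNDS))
        return cls(n_states=2, **kw)


@dataclass
class StatsConfig:
    """Per-cell aggregation and group-comparison options."""

    min_trajectories: int = 500
    test_mode: str = "student"  # or "welch"
    holm_adjust: bool = False


@dataclass
class PipelineConfig:
    """Top-level configuration tying all pipeline stages together."""

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    linking: LinkingConfig = field(default_factory=LinkingConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(_asdict_clean(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        raw = json.loads(p.read_text() if p.exists() else str(source))

        def de_inf(d: dict) -> dict:
            return {k: (math.inf if v == "inf" else v) for k, v in d.items()}

        def build(klass, d):
            d = de_inf(d)
            fields = {f.name for f in dataclasses.fields(klass)}
            kw = {k: v for k, v in d.items() if k in fields}
            if "fov" in kw:
                kw["fov"] = tuple(kw["fov"])
            if "bounds" in kw:
                kw["bounds"] = {k: tuple(v) for k, v in kw["bounds"].items()}
            if "sigma_bounds" in kw:
                kw["sigma_bounds"] = tuple(kw["sigma_bounds"])
            return klass(**kw)

        return cls(
            acquisition=build(AcquisitionConfig, raw.get("acquisition", {})),
            detection=build(DetectionConfig, raw.get("detection", {})),
            linking=build(LinkingConfig, raw.get("linking", {})),
            fit=build(FitConfig, raw.get("fit", {})),
            stats=build(StatsConfig, raw.get("stats", {})),
            seed=raw.get("seed", 0),
        )
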