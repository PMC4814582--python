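"""Run configuration: one YAML document driving reproducible runs.

A ``RunConfig`` mirrors each module's parameters in named sections and
carries a single global seed that is expanded deterministically into
per-module streams, so that a persisted config re-runs to identical outputs
in noiseless or seeded modes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import numpy as np
import yaml

from .imaging_sim import CameraModel
from .recon import ReconConfig
from .slm_patterns import AnnulusSpec, SlmGrid
from .wave_optics import GridSpec, OpticalConfig, SlitSpec

__all__ = ["RunConfig", "BeamConfig", "TilingConfig", "PhantomConfig"]


@dataclass(frozen=True)
class BeamConfig:
    """Which excitation beam to synthesize."""

    kind: str = "bessel"  # bessel | gaussian | dammann_array | coherent_array
    na_inner: float = 0.14
    na_outer: float = 0.35
    n_beams: int = 1
    beam_spacing_um: float = 2.0
    dammann_period_px: int = 128
    carrier_offset_um: float = 20.0

    def annulus(self) -> AnnulusSpec:
        # a Gaussian beam is the na_inner = 0 case of the annular family
        inner = 0.0 if self.kind == "gaussian" else self.na_inner
        return AnnulusSpec(inner, self.na_outer)


@dataclass(frozen=True)
class TilingConfig:
    fov_extent_um: float = 30.0
    sheet_length_um: float = 10.0
    spacing_um: float = 10.0


@dataclass(frozen=True)
class PhantomConfig:
    kind: str = "beads"
    n_objects: int = 12
    shape: tuple[int, int, int] = (72, 96, 288)
    voxel_um: tuple[float, float, float] = (0.2, 0.1, 0.1)  # z-stack step 0.2 um
    min_separation_um: float = 2.5


@dataclass(frozen=True)
class RunConfig:
    """Top-level config: sections mirror the pipeline stages."""

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    beam: BeamConfig = field(default_factory=BeamConfig)
    slit: SlitSpec = field(default_factory=SlitSpec)
    tiling: TilingConfig = field(default_factory=TilingConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    camera: CameraModel = field(default_factory=CameraModel)
    recon: ReconConfig = field(default_factory=ReconConfig)
    slm: SlmGrid = field(default_factory=SlmGrid)
    seed: int = 0
    output_dir: str = "tilesheet_out"
    log_level: str = "INFO"

    def module_seed(self, module: str) -> int:
        """Deterministic per-module seed derived from the global seed."""
        import zlib

        ss = np.random.SeedSequence([self.seed, zlib.crc32(module.encode())])
        return int(ss.generate_state(1)[0] % (2**31))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_as_plain(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = {}
        errors = []
        section_types = {f.name: f.type for f in fields(cls)}
        known = {f.name for f in fields(cls)}
        for key in raw:
            if key not in known:
                errors.append(f"unknown section or key: {key!r}")
        for f in fields(cls):
            if f.name not in raw:
                continue
            value = raw[f.name]
            factory = _SECTION_CLASSES.get(f.name)
            if factory is None:
                kwargs[f.name] = value
                continue
            try:
                kwargs[f.name] = _build_section(factory, value, f.name, errors)
            except (TypeError, ValueError) as exc:
                errors.append(f"section {f.name!r}: {exc}")
        if errors:
            raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))
        return cls(**kwargs)


_SECTION_CLASSES = {
    "optics": OpticalConfig,
    "beam": BeamConfig,
    "slit": SlitSpec,
    "tiling": TilingConfig,
    "phantom": PhantomConfig,
    "camera": CameraModel,
    "recon": ReconConfig,
    "slm": SlmGrid,
}


def _build_section(factory, value: dict, name: str, errors: list[str]):
    if not isinstance(value, dict):
        raise ValueError(f"expected a mapping, got {type(value).__name__}")
    valid = {f.name: f for f in fields(factory)}
    kwargs = {}
    for key, v in value.items():
        if key not in valid:
            errors.append(f"section {name!r}: unknown key {key!r}")
            continue
        if isinstance(v, list):
            v = tuple(v)
        kwargs[key] = v
    if name == "optics" and isinstance(kwargs.get("grid"), dict):
        kwargs["grid"] = GridSpec(**kwargs["grid"])
    return factory(**kwargs)


def _as_plain(obj):
    if is_dataclass(obj):
        return {k: _as_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
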