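"""YAML run configuration.

A single schema-validated document describes a whole benchmark run: the
energy landscape (wells or the 12-well default), the two-body phantom, the
imaging conditions (particle count, SNR, seed, orientations, optional CTF)
and the evaluation settings.  Unknown keys are rejected so typos fail
loudly, and configurations round-trip losslessly through YAML.
"""

from __future__ import annotations

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import landscape as _ls
from . import phantom as _ph

__all__ = [
    "WellConfig",
    "LandscapeConfig",
    "PhantomConfig",
    "ImagingConfig",
    "EvaluationConfig",
    "RunConfig",
    "load_config",
    "dump_config",
    "build_landscape",
    "build_phantom",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class WellConfig(_Strict):
    id: int
    center: tuple[float, float]
    depth: float = Field(gt=0)
    width: float = Field(gt=0)


class LandscapeConfig(_Strict):
    wells: list[WellConfig] | None = None  # None -> default 12-well 3x4 grid
    kT: float = 1.0
    domain: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 1.0), (0.0, 1.0))
    background_energy: float = 0.0
    grid_resolution: int = 128


class PhantomConfig(_Strict):
    box_size: int = 64
    voxel_size: float = 3.0
    max_angle1: float = 10.0
    max_angle2: float = 10.0


class ImagingConfig(_Strict):
    n: int = 1000
    snr: float = 1.0
    seed: int = 0
    orientation_mode: str = "uniform"
    ctf: bool = False
    noise_mask: str = "frame"


class EvaluationConfig(_Strict):
    bins: int = 40
    floor_count: int = 1
    std_ddof: int = 0  # 0 = population convention, 1 = sample


class RunConfig(_Strict):
    landscape: LandscapeConfig = LandscapeConfig()
    phantom: PhantomConfig = PhantomConfig()
    imaging: ImagingConfig = ImagingConfig()
    evaluation: EvaluationConfig = EvaluationConfig()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def dump_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(cfg.model_dump(), sort_keys=False)


def build_landscape(cfg: LandscapeConfig) -> _ls.EnergyLandscape:
    if cfg.wells is None:
        base = _ls.default_landscape()
        return _ls.EnergyLandscape(
            wells=base.wells,
            kT=cfg.kT,
            domain=cfg.domain,
            background_energy=cfg.background_energy,
        )
    wells = tuple(
        _ls.Well(id=w.id, center=w.center, depth=w.depth, width=w.width) for w in cfg.wells
    )
    return _ls.EnergyLandscape(
        wells=wells, kT=cfg.kT, domain=cfg.domain, background_energy=cfg.background_energy
    )


def build_phantom(cfg: PhantomConfig) -> _ph.TwoBodyPhantom:
    base = _ph.build_default_phantom(cfg.box_size, cfg.voxel_size)
    return _ph.TwoBodyPhantom(
        lsu=base.lsu,
        ssu=base.ssu,
        pivot=base.pivot,
        axis1=base.axis1,
        axis2=base.axis2,
        max_angle1=cfg.max_angle1,
        max_angle2=cfg.max_angle2,
        box_size=cfg.box_size,
        voxel_size=cfg.voxel_size,
    )
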