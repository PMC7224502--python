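"""Run configuration: schema-validated YAML for the simulation entry points."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from .conductivity import DEFAULT_TISSUES

__all__ = ["RunConfig", "load_config", "PhantomConfig", "ElectrodeConfig", "SolverSection"]


class PhantomConfig(BaseModel):
    kind: Literal["layered_sphere", "mesh_file"] = "layered_sphere"
    radii: list[float] = [90.0, 85.0, 80.0]
    conductivities: list[float] = [0.465, 0.01, 0.33]
    subdivisions: int = 4
    radial_layers: Optional[list[int]] = None
    grading: float = 0.8
    mesh_path: Optional[str] = None

    @field_validator("radii")
    @classmethod
    def _decreasing(cls, v):
        if any(b >= a for a, b in zip(v, v[1:])):
            raise ValueError("radii must be strictly decreasing")
        return v


class ElectrodeConfig(BaseModel):
    name: str
    shape: Literal["rect", "circle", "polygon"] = "circle"
    dims: list = [10.0]
    thickness: float = Field(2.0, ge=1.0)
    position: list[float] | str = "Cz"
    role: Literal["anode", "cathode"] = "anode"


class FiducialConfig(BaseModel):
    nasion: list[float]
    inion: list[float]
    tragus_left: list[float]
    tragus_right: list[float]


class SolverSection(BaseModel):
    inner_tol: float = Field(1e-6, gt=0)
    outer_tol: float = Field(1e-5, gt=0)
    max_outer: int = 200
    correction: Literal["none", "corrected", "limited"] = "corrected"
    alpha: float = Field(1.0, ge=0.0, le=1.0)
    face_interpolation: Literal["arithmetic", "harmonic"] = "arithmetic"
    preconditioner: Literal["auto", "jacobi", "ilu"] = "auto"


class AnisotropySection(BaseModel):
    tensor_file: Optional[str] = None
    wm_label: int = 3
    sigma_wm: float = Field(0.126, gt=0)
    ratio: float = Field(10.0, gt=1)


class RunConfig(BaseModel):
    phantom: PhantomConfig = PhantomConfig()
    electrodes: list[ElectrodeConfig] = [
        ElectrodeConfig(name="anode", position=[0.0, 0.0, 90.0], role="anode"),
        ElectrodeConfig(name="cathode", position=[0.0, 0.0, -90.0], role="cathode"),
    ]
    fiducials: Optional[FiducialConfig] = None
    tissues: dict[str, float] = dict(DEFAULT_TISSUES)
    electrode_sigma: float = Field(29.4, gt=0)
    anode_potential: float = 5.0
    cathode_potential: float = -5.0
    target_current: float = Field(1e-3, gt=0)
    solver: SolverSection = SolverSection()
    anisotropy: Optional[AnisotropySection] = None
    output_dir: str = "tesfv_out"
    seed: int = 0

    def solver_config(self):
        from .solver import SolverConfig

        s = self.solver
        return SolverConfig(
            inner_tol=s.inner_tol, outer_tol=s.outer_tol, max_outer=s.max_outer,
            correction=s.correction, alpha=s.alpha,
            face_interpolation=s.face_interpolation, preconditioner=s.preconditioner,
        )

    def echo(self) -> dict:
        return self.model_dump()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
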