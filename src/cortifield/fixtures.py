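"""Initial-condition generators and run configuration.

All stochastic fixtures derive from a single integer seed; plane-wave
wavevectors are snapped to the nearest lattice-commensurate value on
periodic grids so the initial data is an exact spatial eigenmode of the
discrete operators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import yaml

from cortifield.dynamics import KGParams, QuarticParams, stable_dt
from cortifield.grid_fields import FieldState, GridSpec

__all__ = [
    "make_plane_wave",
    "make_random_state",
    "snap_wavevector",
    "discrete_mode_eigenvalue",
    "RunConfig",
]


def snap_wavevector(grid: GridSpec, k: Tuple[float, float],
                    warn_tol: float = 1e-6) -> Tuple[float, float]:
    """Snap k to the nearest commensurate lattice wavevector 2 pi n / (N d).

    A warning reports the snap when the requested k was not commensurate.
    """
    kx = 2 * np.pi * round(k[0] * grid.nx * grid.dx / (2 * np.pi)) / (grid.nx * grid.dx)
    ky = 2 * np.pi * round(k[1] * grid.ny * grid.dy / (2 * np.pi)) / (grid.ny * grid.dy)
    if abs(kx - k[0]) > warn_tol or abs(ky - k[1]) > warn_tol:
        warnings.warn(
            f"wavevector {k} snapped to commensurate ({kx:.6g}, {ky:.6g})",
            stacklevel=2,
        )
    return kx, ky


def discrete_mode_eigenvalue(grid: GridSpec, k: Tuple[float, float]) -> float:
    """Eigenvalue of -Laplacian (5-point stencil) on the plane-wave mode k."""
    return (4.0 / grid.dx**2 * np.sin(k[0] * grid.dx / 2.0) ** 2
            + 4.0 / grid.dy**2 * np.sin(k[1] * grid.dy / 2.0) ** 2)


def make_plane_wave(grid: GridSpec, phi0: complex, k: Tuple[float, float],
                    params=None, discrete: bool = True) -> FieldState:
    """Plane-wave initial state phi = phi0 e^{i k.r}, phi_dot = i omega phi.

    omega comes from the model's dispersion at the (snapped) k: the discrete
    stencil eigenvalue by default, so the wave is an exact travelling
    eigenmode of the semi-discrete system; ``discrete=False`` uses the
    continuum relation instead.  With no params, omega = 0 (static phase
    pattern).
    """
    if grid.boundary == "periodic":
        k = snap_wavevector(grid, k)
    lam = (discrete_mode_eigenvalue(grid, k) if discrete
           else k[0] ** 2 + k[1] ** 2)
    if params is None:
        omega = 0.0
    elif isinstance(params, KGParams):
        omega = np.sqrt(params.c**2 * lam + params.m**2 * params.c**4)
    elif isinstance(params, QuarticParams):
        omega = np.sqrt(params.c0 + params.a2 * lam + params.a3 * lam**2)
    else:
        raise TypeError("params must be KGParams, QuarticParams or None")
    x, y = grid.coords()
    phi = phi0 * np.exp(1j * (k[0] * x + k[1] * y))
    return FieldState(grid, phi, 1j * omega * phi, t=0.0)


def make_random_state(grid: GridSpec, seed: int, amplitude: float = 1.0,
                      smooth: int = 0) -> FieldState:
    """Seeded complex Gaussian field (optionally smoothed by stencil passes)."""
    rng = np.random.default_rng(seed)
    phi = amplitude * (rng.standard_normal(grid.shape)
                       + 1j * rng.standard_normal(grid.shape))
    phi_dot = amplitude * (rng.standard_normal(grid.shape)
                           + 1j * rng.standard_normal(grid.shape))
    for _ in range(smooth):
        from cortifield.grid_fields import laplacian_array

        phi = phi + 0.2 * grid.dx**2 * laplacian_array(phi, grid)
        phi_dot = phi_dot + 0.2 * grid.dx**2 * laplacian_array(phi_dot, grid)
    return FieldState(grid, phi, phi_dot, t=0.0)


@dataclass
class RunConfig:
    """Schema-validated simulation configuration.

    dt may be the string "auto", meaning stable_dt / 4 for the configured
    model and grid.
    """

    model: str
    grid: GridSpec
    params: dict
    ic: dict
    n_steps: int
    dt: object = "auto"
    stride: int = 1
    seed: int = 0

    _MODELS = ("kg", "quartic", "limitcycle", "multilayer", "tessellated")

    def __post_init__(self):
        if self.model not in self._MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.n_steps < 1 or self.stride < 1:
            raise ValueError("n_steps and stride must be positive")
        if not (self.dt == "auto" or (isinstance(self.dt, (int, float)) and self.dt > 0)):
            raise ValueError("dt must be 'auto' or a positive number")

    def build_params(self):
        from cortifield.dynamics import LimitCycleParams, MultilayerParams

        if self.model == "kg":
            return KGParams(**self.params)
        if self.model == "quartic":
            return QuarticParams(**self.params)
        if self.model == "limitcycle":
            return LimitCycleParams(**self.params)
        if self.model == "multilayer":
            return MultilayerParams(np.asarray(self.params["A1"]),
                                    self.params.get("A2", 1.0))
        raise ValueError(f"no parameter builder for model {self.model!r}")

    def resolve_dt(self) -> float:
        if self.dt == "auto":
            return stable_dt(self.build_params(), self.grid) / 4.0
        return float(self.dt)

    def build_ic(self) -> FieldState:
        kind = self.ic.get("type", "plane_wave")
        if kind == "plane_wave":
            params = self.build_params() if self.model in ("kg", "quartic") else None
            return make_plane_wave(self.grid, complex(self.ic.get("phi0", 1.0)),
                                   tuple(self.ic.get("k", (0.0, 0.0))), params)
        if kind == "random":
            return make_random_state(self.grid, self.ic.get("seed", self.seed),
                                     self.ic.get("amplitude", 1.0),
                                     self.ic.get("smooth", 0))
        if kind == "half_plane":
            from cortifield.fronts import make_half_plane

            return make_half_plane(self.grid, self.ic.get("phi_l", 1.0),
                                   self.ic.get("eps", 1e-3))
        raise ValueError(f"unknown IC type {kind!r}")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "grid": {
                "nx": self.grid.nx, "ny": self.grid.ny,
                "dx": self.grid.dx, "dy": self.grid.dy,
                "boundary": self.grid.boundary,
                "origin": list(self.grid.origin),
            },
            "params": self.params,
            "ic": self.ic,
            "dt": self.dt,
            "n_steps": self.n_steps,
            "stride": self.stride,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        g = dict(d["grid"])
        g["origin"] = tuple(g.get("origin", (0.0, 0.0)))
        return cls(
            model=d["model"],
            grid=GridSpec(**g),
            params=dict(d.get("params", {})),
            ic=dict(d.get("ic", {})),
            dt=d.get("dt", "auto"),
            n_steps=int(d["n_steps"]),
            stride=int(d.get("stride", 1)),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))
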