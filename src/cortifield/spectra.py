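"""Dispersion relations, power spectra, slope/crossover analysis.

Analytic curves:

* Klein-Gordon:  omega^2 = c^2 k^2 + m^2 c^4
* quartic:       omega^2 = c0 + a2 k^2 + a3 k^4
  (higher-order sigmoid contributions enter the same powers of k and are
  folded additively into the coefficients)
* multilayer:    omega_i^2 = A2 k^2 - D_ii per layer branch
* power over frequency:
  P(f) = 1 / (c0 + (a2/c^2) f^2 + (a3/c^4) f^4)

The P(f) curve has a low-band log-log slope of -2 (the f^2 denominator term
dominant), steepening to -4 where the f^4 term takes over; the crossover
sits at f* = c * sqrt(a2/a3).  Model frequency units map to Hz through a
single scale factor (``hz_per_unit``); the shipped configuration uses
1 model unit = 1 Hz with a propagation speed of 10 mm/s, putting the
crossover at 100 Hz.

Empirical dispersion is measured from simulated plane-wave trajectories by
phase regression and cross-checked against the analytic curves in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np

from cortifield.dynamics import KGParams, MultilayerParams, QuarticParams
from cortifield.errors import InsufficientDataError
from cortifield.grid_fields import Trajectory

__all__ = [
    "DispersionCurve",
    "PowerSpectrum",
    "dispersion_kg",
    "dispersion_quartic",
    "dispersion_multilayer",
    "power_spectrum_multilayer",
    "power_spectrum_frequency",
    "loglog_slope",
    "gradient_transition_frequency",
    "measure_dispersion",
    "measure_plane_wave_frequency",
]


@dataclass
class DispersionCurve:
    """omega(k) samples for one or more branches.

    ``omega`` has shape (n_branches, n_k); evanescent entries (omega^2 < 0)
    are stored as NaN and flagged in ``evanescent`` rather than raising.
    """

    k: np.ndarray
    omega: np.ndarray
    branches: List[str] = field(default_factory=lambda: ["principal"])
    evanescent: Optional[np.ndarray] = None

    def __post_init__(self):
        self.k = np.atleast_1d(np.asarray(self.k, dtype=float))
        self.omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        if self.omega.shape[1] != self.k.size:
            raise ValueError("omega and k sample counts differ")

    def branch(self, name: str = "principal") -> np.ndarray:
        return self.omega[self.branches.index(name)]


@dataclass
class PowerSpectrum:
    """Power P at frequencies f (model units unless hz_per_unit applied)."""

    f: np.ndarray
    P: np.ndarray
    provenance: Literal["analytic", "simulated"] = "analytic"

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.f.shape != self.P.shape:
            raise ValueError("f and P shapes differ")
        if np.any(np.diff(self.f) <= 0):
            raise ValueError("f must be strictly increasing")
        if np.any(self.P <= 0):
            raise ValueError("P must be positive")


def dispersion_kg(k, params: KGParams) -> DispersionCurve:
    """Klein-Gordon branch omega = sqrt(c^2 k^2 + m^2 c^4)."""
    k = np.atleast_1d(np.asarray(k, dtype=float))
    if np.any(k < 0):
        raise ValueError("k must be nonnegative")
    omega = np.sqrt(params.c**2 * k**2 + params.m**2 * params.c**4)
    return DispersionCurve(k, omega[None, :])


def dispersion_quartic(k, params: QuarticParams) -> DispersionCurve:
    """Quartic branch omega = sqrt(c0 + a2 k^2 + a3 k^4)."""
    k = np.atleast_1d(np.asarray(k, dtype=float))
    if np.any(k < 0):
        raise ValueError("k must be nonnegative")
    w2 = params.c0 + params.a2 * k**2 + params.a3 * k**4
    if np.any(w2 < 0):
        raise ValueError("omega^2 < 0: parameters violate the a2,a3 >= 0 invariant")
    return DispersionCurve(k, np.sqrt(w2)[None, :])


def dispersion_multilayer(k, params: MultilayerParams,
                          sign: float = -1.0) -> DispersionCurve:
    """Per-layer branches omega_i^2 = A2 k^2 + sign * D_ii.

    The printed relation is omega_i^2 = A2 k^2 - D_ii; the sign convention
    of the eigen-offsets D is not fixed by the formula alone (positive
    eigenvalues of I + A1 would then give imaginary omega at small k), so
    ``sign`` is exposed: the default -1 follows the printed form and
    entries with omega^2 < 0 are flagged evanescent (NaN), not raised.
    """
    k = np.atleast_1d(np.asarray(k, dtype=float))
    if np.any(k < 0):
        raise ValueError("k must be nonnegative")
    _, D = params.diagonalize()
    w2 = params.A2 * k[None, :] ** 2 + sign * D[:, None]
    evan = w2 < 0
    omega = np.where(evan, np.nan, np.sqrt(np.where(evan, 0.0, w2)))
    names = [f"layer_{i}" for i in range(params.n_layers)]
    return DispersionCurve(k, omega, branches=names, evanescent=evan)


def power_spectrum_multilayer(k: float, params: MultilayerParams,
                              sign: float = -1.0) -> float:
    """P(k) = 1 / sum_i (A2 k^2 + sign*D_ii), sign as in dispersion_multilayer."""
    _, D = params.diagonalize()
    denom = float(np.sum(params.A2 * k**2 + sign * D))
    if denom <= 0:
        raise ValueError(f"nonpositive power denominator {denom:g}")
    return 1.0 / denom


def power_spectrum_frequency(f, params: QuarticParams, c: float,
                             hz_per_unit: float = 1.0) -> PowerSpectrum:
    """Analytic power over frequency for the quartic field.

    P(f) = 1 / (c0 + (a2/c^2) f^2 + (a3/c^4) f^4), with f in model units
    scaled by ``hz_per_unit`` on output.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("f must be positive")
    if c <= 0:
        raise ValueError("c must be positive")
    P = 1.0 / (params.c0 + (params.a2 / c**2) * f**2 + (params.a3 / c**4) * f**4)
    return PowerSpectrum(f * hz_per_unit, P, provenance="analytic")


def loglog_slope(spec: PowerSpectrum, f_lo: float, f_hi: float) -> float:
    """Least-squares slope of log P against log f over [f_lo, f_hi]."""
    mask = (spec.f >= f_lo) & (spec.f <= f_hi)
    if mask.sum() < 8:
        raise ValueError(
            f"need >= 8 samples in [{f_lo:g}, {f_hi:g}], found {int(mask.sum())}"
        )
    slope, _ = np.polyfit(np.log(spec.f[mask]), np.log(spec.P[mask]), 1)
    return float(slope)


def gradient_transition_frequency(params: QuarticParams, c: float,
                                  hz_per_unit: float = 1.0) -> float:
    """Frequency where the quartic and quadratic denominator terms are equal.

    (a3/c^4) f*^4 = (a2/c^2) f*^2  =>  f* = c sqrt(a2/a3); this is where the
    -2 band hands over to the -4 band.  Returns +inf when a3 = 0 (no
    transition).
    """
    if params.a2 <= 0:
        raise ValueError("a2 must be positive")
    if params.a3 == 0:
        return np.inf
    return float(c * np.sqrt(params.a2 / params.a3) * hz_per_unit)


# ---------------------------------------------------------------------------
# Empirical dispersion from simulation


def measure_plane_wave_frequency(traj: Trajectory, k: Tuple[float, float]
                                 ) -> Tuple[float, float]:
    """Temporal frequency of a plane-wave trajectory by phase regression.

    Projects each snapshot onto the spatial mode e^{-i k.r}, unwraps the
    phase of the projection coefficient, and fits a line against time.
    Returns (|omega|, rms residual of the fit).  Requires at least two full
    phase revolutions (about 2 periods) in the record.
    """
    grid = traj[0].grid
    x, y = grid.coords()
    mode = np.exp(1j * (k[0] * x + k[1] * y))
    coeffs = np.array([np.mean(s.phi * np.conj(mode)) for s in traj.states])
    amp = np.abs(coeffs)
    if amp.max() == 0 or np.any(amp < 1e-12 * amp.max()):
        raise InsufficientDataError("plane-wave projection vanished")
    phase = np.unwrap(np.angle(coeffs))
    total = abs(phase[-1] - phase[0])
    if total < 2 * (2 * np.pi):
        raise InsufficientDataError(
            f"only {total / (2 * np.pi):.2f} periods recorded; need >= 2"
        )
    times = traj.times
    slope, intercept = np.polyfit(times, phase, 1)
    resid = float(np.sqrt(np.mean((phase - (slope * times + intercept)) ** 2)))
    return float(abs(slope)), resid


def measure_dispersion(trajs: Sequence[Trajectory],
                       ks: Sequence[Tuple[float, float]]) -> DispersionCurve:
    """Empirical dispersion curve from plane-wave trajectories at known k.

    For a static field the regression returns omega = 0.
    """
    kmags, omegas = [], []
    for traj, k in zip(trajs, ks):
        if all(np.allclose(s.phi, traj[0].phi) for s in traj.states[1:]):
            omega = 0.0
        else:
            omega, _ = measure_plane_wave_frequency(traj, k)
        kmags.append(float(np.hypot(*k)))
        omegas.append(omega)
    order = np.argsort(kmags)
    return DispersionCurve(np.asarray(kmags)[order],
                           np.asarray(omegas)[order][None, :])
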