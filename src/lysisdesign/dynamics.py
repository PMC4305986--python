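"""Time-domain simulation of the lysis circuit coupled to logistic growth.

State vector: regulator concentration ``x_reg`` (nM), lysis-protein
concentration ``x_lys`` (nM) and population density ``N`` (O.D. 600).

    dx_reg/dt = P_c1            − (γ_reg + k)·x_reg  [+ ω1]
    dx_lys/dt = P_2(x_reg, I)   − (γ_lys + k)·x_lys  [+ ω2]
    dN/dt     = k·N·(1 − N/Nmax) − γ_N·N·x_lys       [+ ω3]

where P_2 is the repressible or activatable Hill regulation function of the
second-stage component.  Deterministic runs use a fixed-step classical RK4
scheme; stochastic runs use Euler–Maruyama with additive Gaussian process
noise and clipping of the state at zero after every step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .components import PromoterRBSComponent, regulation_activity, regulation_constitutive
from .errors import DesignDomainError, IntegrationError, UsageError

Topology = Literal["repressor", "activator"]

_TOPOLOGY_KIND = {
    "repressor": "repressor_regulated",
    "activator": "activator_regulated",
}


@dataclass(frozen=True)
class CircuitSpec:
    """A concrete two-stage lysis circuit: component pair plus global rates.

    Parameters
    ----------
    topology:
        ``"repressor"`` or ``"activator"`` — which regulation logic the
        second stage uses.
    constitutive:
        First-stage component producing the regulatory protein.
    regulated:
        Second-stage component driving the lysis gene; its kind must match
        the topology.
    gamma_reg, gamma_lys:
        Degradation rates of the regulatory and lysis proteins (min⁻¹).
    k:
        Dilution rate due to cell growth, also the logistic growth rate
        (min⁻¹); one shared symbol.
    Nmax:
        Carrying capacity (O.D. 600).
    gamma_N:
        Lysis rate of the lysis protein (nM⁻¹·min⁻¹).
    """

    topology: Topology
    constitutive: PromoterRBSComponent
    regulated: PromoterRBSComponent
    gamma_reg: float = 0.05
    gamma_lys: float = 0.05
    k: float = 0.02
    Nmax: float = 1.0
    gamma_N: float = 4e-4

    def __post_init__(self) -> None:
        if self.topology not in _TOPOLOGY_KIND:
            raise UsageError(f"unknown topology {self.topology!r}")
        if self.constitutive.kind != "constitutive":
            raise UsageError(
                f"first-stage component {self.constitutive.id} must be constitutive"
            )
        expected = _TOPOLOGY_KIND[self.topology]
        if self.regulated.kind != expected:
            raise UsageError(
                f"second-stage component {self.regulated.id} has kind "
                f"{self.regulated.kind}, topology {self.topology} needs {expected}"
            )
        for name in ("gamma_reg", "gamma_lys", "k", "gamma_N"):
            if getattr(self, name) < 0.0:
                raise DesignDomainError(f"{name} must be >= 0")
        if self.Nmax <= 0.0:
            raise DesignDomainError("Nmax must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise settings.

    ``omega_sd`` are the standard deviations of the process-noise terms
    ω1, ω2, ω3 entering the three dynamic equations (per sqrt-minute);
    ``v_sd`` are the standard deviations of the steady-state noise terms
    v1, v2, v3 added to the closed-form steady states.
    """

    omega_sd: tuple[float, float, float] = (0.01, 0.01, 0.001)
    v_sd: tuple[float, float, float] = (0.01, 0.01, 0.005)
    enabled: bool = False

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.omega_sd) or any(s < 0 for s in self.v_sd):
            raise DesignDomainError("noise standard deviations must be >= 0")


@dataclass
class Trajectory:
    """Time-indexed circuit state produced by :func:`simulate`."""

    times: np.ndarray
    x_reg: np.ndarray
    x_lys: np.ndarray
    N: np.ndarray
    inducer: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.x_reg) == len(self.x_lys) == len(self.N) == n):
            raise DesignDomainError("trajectory series must share one time grid")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "x_reg": self.x_reg, "x_lys": self.x_lys, "N": self.N}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


#: default initial state (x_reg, x_lys, N) — a fresh low-density culture
DEFAULT_INIT: tuple[float, float, float] = (0.0, 0.0, 0.05)
#: default horizon (min); steady-state O.D. readings are taken at 240 min
DEFAULT_HORIZON: float = 240.0


def growth_rhs(N: float, spec: CircuitSpec, x_lys: float) -> float:
    """Density rate k·N·(1 − N/Nmax) − γ_N·N·x_lys.

    With ``x_lys = 0`` this is plain logistic growth; the lysis protein adds
    a first-order kill term proportional to its concentration.
    """
    if N < 0.0:
        raise DesignDomainError("density must be nonnegative")
    return spec.k * N * (1.0 - N / spec.Nmax) - spec.gamma_N * N * x_lys


def _rhs(spec: CircuitSpec, I: float, y: np.ndarray) -> np.ndarray:
    p1 = regulation_constitutive(spec.constitutive)
    p2 = regulation_activity(spec.regulated, max(y[0], 0.0), I)
    return np.array(
        [
            p1 - (spec.gamma_reg + spec.k) * y[0],
            p2 - (spec.gamma_lys + spec.k) * y[1],
            spec.k * y[2] * (1.0 - y[2] / spec.Nmax) - spec.gamma_N * y[2] * y[1],
        ]
    )


def simulate(
    spec: CircuitSpec,
    I: float,
    init: Sequence[float] = DEFAULT_INIT,
    horizon: float = DEFAULT_HORIZON,
    dt: float = 0.1,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
) -> Trajectory:
    """Integrate the circuit ODEs (or SDEs) on a fixed time grid.

    Deterministic runs (``noise`` absent or disabled) use classical RK4;
    with noise enabled an Euler–Maruyama step adds independent Gaussian
    increments ``omega_sd·sqrt(dt)·z`` to each state, and the state is
    clipped at zero after every step so concentrations and density stay
    physical.  Identical ``(spec, I, init, horizon, dt, noise, seed)``
    always reproduce the same trajectory.
    """
    if dt <= 0.0:
        raise DesignDomainError(f"dt must be positive, got {dt}")
    if horizon < dt:
        raise DesignDomainError("horizon must be at least one step")
    if I < 0.0:
        raise DesignDomainError("inducer concentration must be nonnegative")
    y = np.asarray(init, dtype=float).copy()
    if y.shape != (3,) or np.any(y < 0.0):
        raise DesignDomainError("init must be three nonnegative values (x_reg, x_lys, N)")

    n_steps = int(round(horizon / dt))
    times = np.arange(n_steps + 1) * dt
    out = np.empty((n_steps + 1, 3))
    out[0] = y

    stochastic = noise is not None and noise.enabled
    if stochastic:
        rng = np.random.default_rng(seed)
        sd = np.asarray(noise.omega_sd) * np.sqrt(dt)

    for step in range(1, n_steps + 1):
        if stochastic:
            y = y + dt * _rhs(spec, I, y) + sd * rng.standard_normal(3)
        else:
            k1 = _rhs(spec, I, y)
            k2 = _rhs(spec, I, y + 0.5 * dt * k1)
            k3 = _rhs(spec, I, y + 0.5 * dt * k2)
            k4 = _rhs(spec, I, y + dt * k3)
            y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        y = np.maximum(y, 0.0)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(
                f"non-finite state at step {step} (t = {step * dt:.3f} min): {y}"
            )
        out[step] = y

    return Trajectory(times, out[:, 0], out[:, 1], out[:, 2], inducer=I, seed=seed)


def inducer_sweep(
    spec: CircuitSpec,
    inducers: Sequence[float],
    init: Sequence[float] = DEFAULT_INIT,
    horizon: float = DEFAULT_HORIZON,
    dt: float = 0.1,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
) -> list[Trajectory]:
    """One trajectory per inducer level, with independent noise streams.

    Noise streams are decorrelated by deriving a child seed per inducer from
    ``seed``, so a sweep is reproducible as a whole but its members are
    statistically independent.
    """
    if len(inducers) == 0:
        raise UsageError("inducer_sweep needs at least one inducer concentration")
    seeds: list[int | None]
    if seed is None:
        seeds = [None] * len(inducers)
    else:
        ss = np.random.SeedSequence(seed).spawn(len(inducers))
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    return [
        simulate(spec, I, init=init, horizon=horizon, dt=dt, noise=noise, seed=s)
        for I, s in zip(inducers, seeds)
    ]
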