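"""Closed-form steady state of the lysis circuit and parameter fluctuations.

Setting the time derivatives of the dynamic model to zero gives

    x_reg_ss = P_c1 / (γ_reg + k)                    [+ v1]
    x_lys_ss = P_2(x_reg_ss, I) / (γ_lys + k)        [+ v2]
    N_ss     = Nmax · (1 − (γ_N / k) · x_lys_ss)     [+ v3]

The density line is the nontrivial root of the logistic-with-lysis growth
law; the formula can go negative when lysis outpaces growth
(γ_N·x_lys_ss > k), in which case the physical steady state is extinction
and the result is clamped to 0 and flagged.

Kinetic-parameter uncertainty is modelled multiplicatively: each synthesis
strength and rate p is replaced by p·(1 + frac·n), with three shared
standard-normal sources per draw — one for the first expression stage
(constitutive strength and regulator degradation), one for the second stage
(regulated strengths and lysis-protein degradation), and one for the
population parameters (k and γ_N).  Binding constants (K, n, KI) are treated
as structural and left unperturbed.  The default fractional standard
deviation is 0.05 (5% part-to-part variability).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence
import warnings

import numpy as np

from .components import regulation_activity, regulation_constitutive
from .dynamics import CircuitSpec, NoiseSpec
from .errors import DesignDomainError

__all__ = [
    "PerturbationSpec",
    "SteadyStateResult",
    "steady_state",
    "perturbation_multipliers",
    "apply_perturbation",
    "perturb",
    "predicted_density_ensemble",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """Monte-Carlo settings for kinetic-parameter fluctuations.

    ``frac`` is the fractional standard deviation applied to every perturbed
    parameter (0.05 means each strength/rate has SD equal to 5% of its
    nominal value); ``draws`` is the ensemble size.
    """

    frac: float = 0.05
    draws: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac < 0.0:
            raise DesignDomainError("frac must be >= 0")
        if self.draws < 1:
            raise DesignDomainError("draws must be >= 1")
        if self.frac >= 1.0:
            warnings.warn(
                f"frac = {self.frac} >= 1 implies heavy truncation of the "
                "positivity-rejected Gaussian; interpret ensembles with care",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SteadyStateResult:
    """Steady-state concentrations and density for one circuit and inducer."""

    x_reg_ss: float
    x_lys_ss: float
    N_ss: float
    clamped: bool = False


def steady_state(
    spec: CircuitSpec,
    I: float,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
) -> SteadyStateResult:
    """Evaluate the closed-form steady state at inducer concentration ``I``.

    With ``noise`` enabled, Gaussian terms v1, v2, v3 (standard deviations
    ``noise.v_sd``) are added to the regulator, lysis-protein and density
    steady states; concentrations are clipped at 0 and the density is
    clamped to [0, Nmax] with the ``clamped`` flag set when the raw value
    fell outside.
    """
    if spec.k <= 0.0:
        raise DesignDomainError("steady state requires k > 0 (density formula divides by k)")
    if I < 0.0:
        raise DesignDomainError("inducer concentration must be nonnegative")

    v1 = v2 = v3 = 0.0
    if noise is not None and noise.enabled:
        rng = np.random.default_rng(seed)
        v1, v2, v3 = rng.standard_normal(3) * np.asarray(noise.v_sd)

    x_reg = regulation_constitutive(spec.constitutive) / (spec.gamma_reg + spec.k) + v1
    x_reg = max(x_reg, 0.0)
    x_lys = regulation_activity(spec.regulated, x_reg, I) / (spec.gamma_lys + spec.k) + v2
    x_lys = max(x_lys, 0.0)
    raw_N = spec.Nmax * (1.0 - (spec.gamma_N / spec.k) * x_lys) + v3
    N = min(max(raw_N, 0.0), spec.Nmax)
    return SteadyStateResult(x_reg, x_lys, N, clamped=not (0.0 <= raw_N <= spec.Nmax))


def perturbation_multipliers(pert: PerturbationSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the (draws × 3) matrix of shared stage multipliers 1 + frac·n.

    Rows are resampled until all three multipliers are strictly positive, so
    every perturbed rate p·m stays physical for any positive nominal p.  The
    rejection rule depends only on the multipliers, never on the circuit, so
    one matrix can be shared across candidates as common random numbers.
    """
    if rng is None:
        rng = np.random.default_rng(pert.seed)
    m = 1.0 + pert.frac * rng.standard_normal((pert.draws, 3))
    while True:
        bad = m <= 0.0
        if not bad.any():
            return m
        m[bad] = 1.0 + pert.frac * rng.standard_normal(int(bad.sum()))


def apply_perturbation(spec: CircuitSpec, multipliers: Sequence[float]) -> CircuitSpec:
    """Scale one circuit's kinetic parameters by one row of stage multipliers.

    ``multipliers[0]`` scales the first stage (constitutive Pu, γ_reg),
    ``multipliers[1]`` the second stage (regulated Pu and Pl, γ_lys) and
    ``multipliers[2]`` the population parameters (k, γ_N).  Binding
    parameters are untouched.
    """
    m1, m2, m3 = (float(m) for m in multipliers)
    return replace(
        spec,
        constitutive=replace(spec.constitutive, Pu=spec.constitutive.Pu * m1),
        regulated=replace(
            spec.regulated, Pu=spec.regulated.Pu * m2, Pl=spec.regulated.Pl * m2
        ),
        gamma_reg=spec.gamma_reg * m1,
        gamma_lys=spec.gamma_lys * m2,
        k=spec.k * m3,
        gamma_N=spec.gamma_N * m3,
    )


def perturb(spec: CircuitSpec, pert: PerturbationSpec) -> list[CircuitSpec]:
    """Monte-Carlo ensemble of circuits with fluctuating kinetic parameters."""
    mults = perturbation_multipliers(pert)
    return [apply_perturbation(spec, row) for row in mults]


def predicted_density_ensemble(
    spec: CircuitSpec,
    inducers: Sequence[float],
    pert: PerturbationSpec,
    noise: NoiseSpec | None = None,
) -> np.ndarray:
    """Steady-state density matrix (draws × inducers) under perturbation.

    Row d holds N_ss of the d-th perturbed circuit across the inducer grid;
    this is the ensemble the design cost averages over.  With ``noise``
    enabled, independent steady-state noise is added per (draw, inducer)
    cell using a stream derived from ``pert.seed``.
    """
    inducers = np.asarray(inducers, dtype=float)
    if inducers.size == 0:
        raise DesignDomainError("inducer grid must be nonempty")
    specs = perturb(spec, pert)
    out = np.empty((pert.draws, inducers.size))
    if noise is not None and noise.enabled:
        seeds = np.random.SeedSequence(pert.seed).spawn(pert.draws * inducers.size)
        it = iter(seeds)
        for d, s in enumerate(specs):
            for g, I in enumerate(inducers):
                child = int(next(it).generate_state(1)[0] % (2**31))
                out[d, g] = steady_state(s, I, noise=noise, seed=child).N_ss
    else:
        for d, s in enumerate(specs):
            for g, I in enumerate(inducers):
                out[d, g] = steady_state(s, I).N_ss
    return out


def ensemble_to_frame(matrix: np.ndarray, inducers: Sequence[float], Nmax: float):
    """Tidy export of an ensemble: one row per (draw, inducer) pair."""
    import pandas as pd

    draws, grid = matrix.shape
    inducers = np.asarray(inducers, dtype=float)
    return pd.DataFrame(
        {
            "draw": np.repeat(np.arange(draws), grid),
            "inducer": np.tile(inducers, draws),
            "N_ss": matrix.ravel(),
            "clamped": ~((matrix.ravel() > 0.0) & (matrix.ravel() < Nmax)),
        }
    )
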