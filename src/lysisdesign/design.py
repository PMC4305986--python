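"""Tracking cost, fitness, GA component search and inducer recommendation.

The design problem: pick one constitutive and one regulated promoter-RBS
component from their libraries so the circuit's steady-state density
N_ss(I) tracks a prescribed reference response N_ref(I) over a feasible
inducer range.  Quality is measured by the expected integrated squared
tracking error

    J(S) = E ∫ (N_ss(S, I) − N_ref(I))² dI ,   I ∈ [I_min, I_max]

with the expectation over the kinetic-parameter fluctuation ensemble and
the integral taken by the trapezoid rule on a log-spaced inducer grid.  The
genetic algorithm maximizes the fitness F = 1/(J + ε), using
fitness-proportional reproduction, single-index crossover and random-index
mutation on the (constitutive, regulated) index pair; an exhaustive search
over all pairs serves as the brute-force reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


import numpy as np

from .dynamics import CircuitSpec
from .errors import DesignDomainError, TargetRangeError, UsageError
from .library import ComponentLibrary
from .steady_state import (
    PerturbationSpec,
    apply_perturbation,
    perturbation_multipliers,
    steady_state,
)

#: regularization in F = 1/(J + eps); a perfect fit has finite fitness 1e12
FITNESS_EPS = 1e-12

#: default number of log-spaced inducer grid points in the cost integral
DEFAULT_GRID_POINTS = 25


@dataclass(frozen=True)
class ReferenceResponse:
    """Prescribed density-vs-inducer curve N_ref(I) = base + amplitude/(1 + scale·I^exponent).

    The default parameters (base 0.1 O.D., amplitude 0.6 O.D., scale
    2 nM⁻², exponent 2) give the demo target 0.1 + 0.6/(1 + 2·I²): density
    0.7 with no inducer, falling to 0.1 at saturating inducer.
    """

    base: float = 0.1
    amplitude: float = 0.6
    scale: float = 2.0
    exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.base < 0.0 or self.amplitude < 0.0 or self.scale <= 0.0:
            raise DesignDomainError("need base >= 0, amplitude >= 0, scale > 0")
        if self.exponent <= 0.0:
            raise DesignDomainError("exponent must be positive")

    def __call__(self, I: float) -> float:
        if I < 0.0:
            raise DesignDomainError("inducer concentration must be nonnegative")
        if math.isinf(I):
            return self.base
        return self.base + self.amplitude / (1.0 + self.scale * I**self.exponent)

    def invert_unchecked(self, target: float) -> float:
        """Inducer solving N_ref(I) = target, without range validation."""
        return ((self.amplitude / (target - self.base) - 1.0) / self.scale) ** (
            1.0 / self.exponent
        )


@dataclass(frozen=True)
class DesignCandidate:
    """One evaluated component pair: indices, ids and its cost/fitness."""

    S: tuple[int, int]
    constitutive_id: str
    regulated_id: str
    cost: float
    fitness: float


@dataclass(frozen=True)
class GASettings:
    """Genetic-algorithm hyperparameters for the component-pair search."""

    population: int = 20
    generations: int = 100
    crossover: float = 0.7
    mutation: float = 0.1
    elitism: int = 1
    seed: int = 0
    stop_cost: float | None = None

    def __post_init__(self) -> None:
        if self.population < 2:
            raise DesignDomainError("population must be >= 2")
        for name in ("crossover", "mutation"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise DesignDomainError(f"{name} probability must lie in [0, 1]")
        if self.generations < 1:
            raise DesignDomainError("generations must be >= 1")
        if self.elitism < 0:
            raise DesignDomainError("elitism must be >= 0")


def inducer_grid(I_range: tuple[float, float], points: int = DEFAULT_GRID_POINTS) -> np.ndarray:
    """Log-spaced inducer grid over a (positive) feasible range."""
    I_min, I_max = I_range
    if not (0.0 < I_min < I_max):
        raise DesignDomainError(f"need 0 < I_min < I_max, got {I_range}")
    if points < 2:
        raise DesignDomainError("grid needs at least 2 points")
    return np.geomspace(I_min, I_max, points)


def _pair_spec(
    S: tuple[int, int], lib: ComponentLibrary, template: CircuitSpec
) -> CircuitSpec:
    i, j = S
    consts = lib.constitutive
    regs = lib.regulated_for(template.topology)
    if not (0 <= i < len(consts) and 0 <= j < len(regs)):
        raise DesignDomainError(
            f"candidate indices {S} outside library bounds "
            f"({len(consts)} constitutive × {len(regs)} regulated)"
        )
    return CircuitSpec(
        topology=template.topology,
        constitutive=consts[i],
        regulated=regs[j],
        gamma_reg=template.gamma_reg,
        gamma_lys=template.gamma_lys,
        k=template.k,
        Nmax=template.Nmax,
        gamma_N=template.gamma_N,
    )


def cost(
    S: tuple[int, int],
    lib: ComponentLibrary,
    template: CircuitSpec,
    ref: ReferenceResponse,
    I_range: tuple[float, float] = (0.1, 10.0),
    pert: PerturbationSpec | None = None,
    grid_points: int = DEFAULT_GRID_POINTS,
    _multipliers: np.ndarray | None = None,
) -> float:
    """Expected integrated squared tracking error J(S) of one component pair.

    With ``pert`` absent (or frac = 0) the cost is deterministic; otherwise
    it averages the integral over the perturbation ensemble.  A search can
    pass a fixed multiplier matrix so every candidate is scored against the
    same parameter draws (common random numbers).
    """
    grid = inducer_grid(I_range, grid_points)
    target = np.array([ref(I) for I in grid])
    nominal = _pair_spec(S, lib, template)
    if pert is None:
        specs = [nominal]
    else:
        mults = _multipliers if _multipliers is not None else perturbation_multipliers(pert)
        specs = [apply_perturbation(nominal, row) for row in mults]
    integrals = np.empty(len(specs))
    for d, spec in enumerate(specs):
        dens = np.array([steady_state(spec, I).N_ss for I in grid])
        integrals[d] = np.trapezoid((dens - target) ** 2, grid)
    return float(integrals.mean())


def fitness(cost_value: float) -> float:
    """Regularized reciprocal fitness F = 1/(J + ε), strictly decreasing in J."""
    if cost_value < 0.0:
        raise DesignDomainError("cost must be nonnegative")
    return 1.0 / (cost_value + FITNESS_EPS)


class _Evaluator:
    """Memoized candidate scoring with common random numbers."""

    def __init__(self, lib, template, ref, I_range, pert, grid_points):
        self.lib = lib
        self.template = template
        self.ref = ref
        self.I_range = I_range
        self.pert = pert
        self.grid_points = grid_points
        self.mults = perturbation_multipliers(pert) if pert is not None else None
        self.cache: dict[tuple[int, int], float] = {}
        consts = lib.constitutive
        regs = lib.regulated_for(template.topology)
        if not consts or not regs:
            raise UsageError(
                f"library lacks components for topology {template.topology!r}"
            )
        self.shape = (len(consts), len(regs))
        self.const_ids = [c.id for c in consts]
        self.reg_ids = [r.id for r in regs]

    def __call__(self, S: tuple[int, int]) -> float:
        if S not in self.cache:
            self.cache[S] = cost(
                S, self.lib, self.template, self.ref, self.I_range,
                self.pert, self.grid_points, _multipliers=self.mults,
            )
        return self.cache[S]

    def candidate(self, S: tuple[int, int]) -> DesignCandidate:
        J = self(S)
        return DesignCandidate(S, self.const_ids[S[0]], self.reg_ids[S[1]], J, fitness(J))

    def ranked(self, pairs) -> list[DesignCandidate]:
        cands = [self.candidate(S) for S in pairs]
        return sorted(cands, key=lambda c: (c.cost, c.S))


def exhaustive_search(
    lib: ComponentLibrary,
    template: CircuitSpec,
    ref: ReferenceResponse,
    I_range: tuple[float, float] = (0.1, 10.0),
    pert: PerturbationSpec | None = None,
    grid_points: int = DEFAULT_GRID_POINTS,
    max_pairs: int = 100_000,
) -> list[DesignCandidate]:
    """Score every component pair; the brute-force reference for the GA.

    Returns all candidates sorted by ascending cost, ties broken by lowest
    (constitutive, regulated) index.
    """
    ev = _Evaluator(lib, template, ref, I_range, pert, grid_points)
    n_pairs = ev.shape[0] * ev.shape[1]
    if n_pairs > max_pairs:
        raise UsageError(
            f"{n_pairs} pairs exceed the exhaustive-search guard ({max_pairs})"
        )
    return ev.ranked([(i, j) for i in range(ev.shape[0]) for j in range(ev.shape[1])])


def ga_search(
    lib: ComponentLibrary,
    template: CircuitSpec,
    ref: ReferenceResponse,
    I_range: tuple[float, float] = (0.1, 10.0),
    pert: PerturbationSpec | None = None,
    settings: GASettings = GASettings(),
    grid_points: int = DEFAULT_GRID_POINTS,
) -> list[DesignCandidate]:
    """Genetic-algorithm search over (constitutive, regulated) index pairs.

    The genome is the index pair itself.  Each generation applies
    fitness-proportional reproduction, crossover that exchanges one index
    between two parents, and mutation that replaces an index with a uniform
    random valid one; elitism re-inserts the best pairs seen so far.  The
    search stops at the generation cap or once the best cost reaches
    ``settings.stop_cost``.  Returns every distinct pair evaluated, sorted
    by ascending cost — the head of the list is the recommended design.
    """
    ev = _Evaluator(lib, template, ref, I_range, pert, grid_points)
    nC, nR = ev.shape
    rng = np.random.default_rng(settings.seed)
    if nC * nR == 1:
        return ev.ranked([(0, 0)])

    pop = [(int(rng.integers(nC)), int(rng.integers(nR))) for _ in range(settings.population)]
    for _ in range(settings.generations):
        costs = np.array([ev(S) for S in pop])
        best = pop[int(np.argmin(costs))]
        if settings.stop_cost is not None and ev(best) <= settings.stop_cost:
            break
        # reproduction: fitness-proportional copying
        fits = 1.0 / (costs + FITNESS_EPS)
        probs = fits / fits.sum()
        parents = [pop[i] for i in rng.choice(len(pop), size=settings.population, p=probs)]
        # crossover: swap one index between adjacent parent pairs
        offspring = list(parents)
        for a in range(0, settings.population - 1, 2):
            if rng.random() < settings.crossover:
                (i1, j1), (i2, j2) = offspring[a], offspring[a + 1]
                if rng.random() < 0.5:
                    offspring[a], offspring[a + 1] = (i2, j1), (i1, j2)
                else:
                    offspring[a], offspring[a + 1] = (i1, j2), (i2, j1)
        # mutation: replace an index with a uniform random valid index
        for idx in range(settings.population):
            i, j = offspring[idx]
            if rng.random() < settings.mutation:
                i = int(rng.integers(nC))
            if rng.random() < settings.mutation:
                j = int(rng.integers(nR))
            offspring[idx] = (i, j)
        # elitism: keep the best pairs evaluated so far
        if settings.elitism > 0:
            elites = sorted(ev.cache, key=lambda S: (ev.cache[S], S))[: settings.elitism]
            offspring[: len(elites)] = elites
        # diversity preservation: once selection converges, duplicates carry no
        # information — replace them with uniform random immigrants so the
        # population keeps exploring the (small, discrete) pair space
        seen: set[tuple[int, int]] = set()
        for idx, S in enumerate(offspring):
            if S in seen:
                offspring[idx] = (int(rng.integers(nC)), int(rng.integers(nR)))
            seen.add(offspring[idx])
        pop = offspring

    for S in pop:
        ev(S)
    return ev.ranked(list(ev.cache))


def recommend_inducer(
    ref: ReferenceResponse,
    target_density: float,
    I_range: tuple[float, float] = (0.1, 10.0),
) -> float:
    """Invert the reference response: the inducer achieving a target density.

    The reference family is strictly decreasing in I, so on the feasible
    range the attainable densities form the interval
    [N_ref(I_max), N_ref(I_min)]; a target outside it raises
    :class:`TargetRangeError` carrying that interval.
    """
    I_min, I_max = I_range
    if not (0.0 <= I_min < I_max):
        raise DesignDomainError(f"need 0 <= I_min < I_max, got {I_range}")
    lo, hi = ref(I_max), ref(I_min)
    if not (lo <= target_density <= hi):
        raise TargetRangeError(
            f"target density {target_density} unattainable; feasible range "
            f"[{I_min}, {I_max}] nM reaches densities in [{lo:.6g}, {hi:.6g}]",
            attainable=(lo, hi),
        )
    if target_density == hi:
        return I_min
    if target_density == lo:
        return I_max
    return ref.invert_unchecked(target_density)
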