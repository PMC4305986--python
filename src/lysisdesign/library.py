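"""Promoter-RBS component libraries: I/O, synthesis, fitting, calibration.

A library holds three part classes — constitutive, repressor-regulated and
activator-regulated promoter-RBS components — serialized as a plain CSV
table with columns ``id, kind, Pu, Pl, K, n, KI`` (decimal text, empty
cells for the fields a constitutive part does not carry).

Because no public table of characterized parts ships with the package, a
synthetic generator produces libraries whose kinetic strengths span several
decades (log-uniform), the regime real promoter/RBS collections cover, and a
calibration routine plants one (constitutive, activated) pair whose
steady-state density response reproduces a prescribed reference curve — the
ground truth used by the end-to-end design tests.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .components import (
    KINDS,
    PromoterRBSComponent,
    regulation_activity,
)
from .dynamics import CircuitSpec
from .errors import CalibrationError, DesignDomainError, FitError, SchemaError, UsageError
from .steady_state import steady_state

_COLUMNS = ["id", "kind", "Pu", "Pl", "K", "n", "KI"]


@dataclass
class ComponentLibrary:
    """Three lists of promoter-RBS components with library-wide unique ids."""

    constitutive: list[PromoterRBSComponent] = field(default_factory=list)
    repressed: list[PromoterRBSComponent] = field(default_factory=list)
    activated: list[PromoterRBSComponent] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [c.id for c in self.all_components()]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SchemaError(f"duplicate component ids in library: {sorted(dupes)}")
        for name, kind in (
            ("constitutive", "constitutive"),
            ("repressed", "repressor_regulated"),
            ("activated", "activator_regulated"),
        ):
            for c in getattr(self, name):
                if c.kind != kind:
                    raise SchemaError(f"component {c.id} of kind {c.kind} listed under {name}")

    def all_components(self) -> list[PromoterRBSComponent]:
        return [*self.constitutive, *self.repressed, *self.activated]

    def regulated_for(self, topology: str) -> list[PromoterRBSComponent]:
        """Second-stage candidates for a circuit topology."""
        if topology == "repressor":
            return self.repressed
        if topology == "activator":
            return self.activated
        raise UsageError(f"unknown topology {topology!r}")

    def __len__(self) -> int:
        return len(self.constitutive) + len(self.repressed) + len(self.activated)


def _component_from_row(row: pd.Series, rownum: int) -> PromoterRBSComponent:
    kind = row["kind"]
    if kind not in KINDS:
        raise SchemaError(f"row {rownum}: unknown kind {kind!r}")

    def num(col: str, required: bool) -> float | None:
        val = row[col]
        if pd.isna(val):
            if required:
                raise SchemaError(f"row {rownum} ({row['id']}): missing {col} for kind {kind}")
            return None
        return float(val)

    regulated = kind != "constitutive"
    try:
        return PromoterRBSComponent(
            id=str(row["id"]),
            kind=kind,
            Pu=num("Pu", True),
            Pl=num("Pl", regulated) or 0.0,
            K=num("K", regulated),
            n=num("n", regulated),
            KI=num("KI", regulated),
        )
    except DesignDomainError as exc:
        raise SchemaError(f"row {rownum}: {exc}") from exc


def read_library(path: str | Path | io.TextIOBase) -> ComponentLibrary:
    """Read a component library from its CSV schema, validating every row."""
    frame = pd.read_csv(path, dtype={"id": str, "kind": str}, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"library table lacks columns {missing}")
    lib = ComponentLibrary()
    for rownum, (_, row) in enumerate(frame.iterrows(), start=2):  # 1 header line
        comp = _component_from_row(row, rownum)
        {"constitutive": lib.constitutive,
         "repressor_regulated": lib.repressed,
         "activator_regulated": lib.activated}[comp.kind].append(comp)
    return ComponentLibrary(lib.constitutive, lib.repressed, lib.activated,
                            provenance=str(path))


def write_library(lib: ComponentLibrary, path: str | Path | io.TextIOBase) -> None:
    """Write the CSV table; floats use repr so read-back is bit-exact."""
    rows = []
    for c in lib.all_components():
        rows.append(
            {
                "id": c.id,
                "kind": c.kind,
                "Pu": repr(c.Pu),
                "Pl": repr(c.Pl),
                "K": "" if c.K is None else repr(c.K),
                "n": "" if c.n is None else repr(c.n),
                "KI": "" if c.KI is None else repr(c.KI),
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def generate_library(
    C: int,
    R: int,
    A: int,
    strength_decades: tuple[float, float] = (0.05, 50.0),
    seed: int | None = 0,
    K_range: tuple[float, float] = (1.0, 100.0),
    n_range: tuple[float, float] = (1.0, 4.0),
    KI_range: tuple[float, float] = (0.1, 10.0),
) -> ComponentLibrary:
    """Synthesize a random library spanning the given strength decades.

    Maximum strengths Pu are log-uniform over ``strength_decades``
    (nM·min⁻¹); minimum strengths Pl are a uniform 1–10% leaky fraction of
    Pu; binding affinity K is log-uniform, cooperativity n uniform and
    inducer dissociation KI log-uniform over their ranges.  Deterministic
    per seed.
    """
    for count, label in ((C, "C"), (R, "R"), (A, "A")):
        if count < 1:
            raise DesignDomainError(f"library class size {label} must be >= 1")
    lo, hi = strength_decades
    if not (0.0 < lo < hi):
        raise DesignDomainError(f"strength_decades must satisfy 0 < low < high, got {strength_decades}")
    rng = np.random.default_rng(seed)

    def log_uniform(low: float, high: float, size: int) -> np.ndarray:
        return np.exp(rng.uniform(math.log(low), math.log(high), size))

    constitutive = [
        PromoterRBSComponent(id=f"C{i + 1}", kind="constitutive", Pu=float(pu))
        for i, pu in enumerate(log_uniform(lo, hi, C))
    ]

    def regulated(prefix: str, kind: str, count: int) -> list[PromoterRBSComponent]:
        pu = log_uniform(lo, hi, count)
        pl = pu * rng.uniform(0.01, 0.1, count)
        K = log_uniform(*K_range, count)
        n = rng.uniform(*n_range, count)
        KI = log_uniform(*KI_range, count)
        return [
            PromoterRBSComponent(
                id=f"{prefix}{i + 1}", kind=kind, Pu=float(pu[i]), Pl=float(pl[i]),
                K=float(K[i]), n=float(n[i]), KI=float(KI[i]),
            )
            for i in range(count)
        ]

    return ComponentLibrary(
        constitutive=constitutive,
        repressed=regulated("R", "repressor_regulated", R),
        activated=regulated("A", "activator_regulated", A),
        provenance=f"generate_library(C={C}, R={R}, A={A}, seed={seed})",
    )


@dataclass
class CharacterizationCurve:
    """Reporter measurements of one part's activity across conditions.

    Rows are (regulator concentration, inducer concentration, measured
    activity, replicate id); activities come from e.g. a GFP reporter scaled
    to synthesis-rate units.
    """

    x_reg: np.ndarray
    inducer: np.ndarray
    activity: np.ndarray
    replicate: np.ndarray

    def __post_init__(self) -> None:
        self.x_reg = np.asarray(self.x_reg, dtype=float)
        self.inducer = np.asarray(self.inducer, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        self.replicate = np.asarray(self.replicate)
        n = self.x_reg.size
        if not (self.inducer.size == self.activity.size == self.replicate.size == n):
            raise SchemaError("curve columns must have equal length")
        if np.any(self.activity < 0.0):
            raise SchemaError("measured activities must be nonnegative")
        if np.unique(self.inducer).size < 5 and np.unique(self.x_reg).size < 5:
            raise SchemaError("need at least 5 distinct inducer (or regulator) levels to fit")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CharacterizationCurve":
        return cls(frame["x_reg"], frame["inducer"], frame["activity"], frame["replicate"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x_reg": self.x_reg, "inducer": self.inducer,
             "activity": self.activity, "replicate": self.replicate}
        )


@dataclass
class FitResult:
    """A fitted component plus residual diagnostics."""

    component: PromoterRBSComponent
    rmse: float
    relative_rmse: float


def fit_component(
    curve: CharacterizationCurve,
    kind: Literal["repressor_regulated", "activator_regulated"],
    id: str = "fit",
) -> FitResult:
    """Least-squares fit of (Pu, Pl, K, n, KI) to a characterization curve.

    Pu, K and KI are fitted on a log scale (they are positive and span
    decades); n is bounded to [0.5, 6].  A flat curve carries no information
    about the Hill parameters and raises :class:`FitError`.
    """
    if kind not in ("repressor_regulated", "activator_regulated"):
        raise UsageError(f"cannot fit kind {kind!r}")
    act = curve.activity
    spread = act.max() - act.min()
    if spread <= 1e-9 * max(act.max(), 1.0):
        raise FitError("activity curve is flat; Hill parameters are not identifiable")

    def build(theta: np.ndarray) -> PromoterRBSComponent:
        log_pu, pl_frac, log_K, n, log_KI = theta
        pu = math.exp(log_pu)
        return PromoterRBSComponent(
            id=id, kind=kind, Pu=pu, Pl=pu * _sigmoid(pl_frac) * 0.999,
            K=math.exp(log_K), n=n, KI=math.exp(log_KI),
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        comp = build(theta)
        pred = np.array(
            [regulation_activity(comp, x, i) for x, i in zip(curve.x_reg, curve.inducer)]
        )
        return pred - act

    x_scale = np.median(curve.x_reg[curve.x_reg > 0]) if np.any(curve.x_reg > 0) else 1.0
    i_scale = np.median(curve.inducer[curve.inducer > 0]) if np.any(curve.inducer > 0) else 1.0
    theta0 = np.array([math.log(act.max() + 1e-9), -2.0, math.log(x_scale), 2.0, math.log(i_scale)])
    sol = least_squares(
        residuals, theta0,
        bounds=([-30.0, -12.0, -30.0, 0.5, -30.0], [30.0, 12.0, 30.0, 6.0, 30.0]),
        method="trf",
    )
    if not sol.success:
        raise FitError(f"least-squares fit failed: {sol.message}")
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    rel = rmse / max(spread, 1e-12)
    if rel > 0.5:
        raise FitError(f"fit explains almost none of the curve (relative RMSE {rel:.2f})")
    return FitResult(build(sol.x), rmse, rel)


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


@dataclass
class DemoCalibration:
    """Calibrated demo library plus the identity of the planted optimum."""

    library: ComponentLibrary
    constitutive_id: str
    activated_id: str
    max_rel_error: float

    @property
    def planted_pair(self) -> tuple[int, int]:
        """(constitutive index, activated index) of the planted optimum."""
        ci = [c.id for c in self.library.constitutive].index(self.constitutive_id)
        ai = [a.id for a in self.library.activated].index(self.activated_id)
        return ci, ai


def calibrate_demo_library(
    ref,
    template: CircuitSpec,
    seed: int | None = 0,
    C: int = 6,
    R: int = 5,
    A: int = 5,
    I_range: tuple[float, float] = (0.1, 10.0),
    rel_tol: float = 0.02,
) -> DemoCalibration:
    """Build a library containing one pair that tracks a reference response.

    The planted constitutive part keeps the template's first-stage strength;
    the planted activated part's (Pu, Pl, K) are found by least squares so
    the deterministic steady-state density matches ``ref`` over ``I_range``
    (cooperativity fixed at 2, inducer dissociation at 1000 nM so the active
    complex is nearly linear in inducer across the nanomolar range).  The
    remaining C−1 / R / A−1 parts are random decoys.  Raises
    :class:`CalibrationError` if the best fit misses the relative tolerance.
    """
    if template.topology != "activator":
        raise UsageError("demo calibration targets the activator (quorum-sensing) topology")
    grid = np.geomspace(I_range[0], I_range[1], 60)
    target = np.array([ref(I) for I in grid])

    planted_const = PromoterRBSComponent(id="C-cal", kind="constitutive",
                                         Pu=template.constitutive.Pu)
    n_fixed, KI_fixed = 2.0, 1000.0

    def build(theta: np.ndarray) -> PromoterRBSComponent:
        log_pu, pl_frac, log_K = theta
        pu = math.exp(log_pu)
        return PromoterRBSComponent(
            id="A-cal", kind="activator_regulated", Pu=pu,
            Pl=pu * _sigmoid(pl_frac) * 0.999, K=math.exp(log_K), n=n_fixed, KI=KI_fixed,
        )

    def density(comp: PromoterRBSComponent) -> np.ndarray:
        spec = CircuitSpec(
            topology="activator", constitutive=planted_const, regulated=comp,
            gamma_reg=template.gamma_reg, gamma_lys=template.gamma_lys,
            k=template.k, Nmax=template.Nmax, gamma_N=template.gamma_N,
        )
        return np.array([steady_state(spec, I).N_ss for I in grid])

    # analytic initial guess: invert the density line for the needed lysis-protein
    # span, then the linear-complex approximation for K
    denom = (template.gamma_lys + template.k)
    x_hi = (1.0 - ref(math.inf) / template.Nmax) * template.k / template.gamma_N
    x_lo = (1.0 - ref(0.0) / template.Nmax) * template.k / template.gamma_N
    x_lo = max(x_lo, 1e-6 * x_hi)
    x_a1ss = planted_const.Pu / (template.gamma_reg + template.k)
    half_I = ref.invert_unchecked((ref(0.0) + ref(math.inf)) / 2.0)
    K0 = x_a1ss * half_I / (half_I + KI_fixed)
    theta0 = np.array([math.log(x_hi * denom), _logit(x_lo / x_hi), math.log(K0)])

    sol = least_squares(lambda t: density(build(t)) - target, theta0, method="lm")
    planted_act = build(sol.x)
    rel_err = float(np.max(np.abs(density(planted_act) - target) / target))
    if rel_err > rel_tol:
        raise CalibrationError(
            f"calibration reached max relative tracking error {rel_err:.4f} "
            f"(> {rel_tol}); template rates make the reference unreachable"
        )

    # child seed: decoys must not replay the RNG stream that produced any
    # template component, or a decoy could duplicate the planted pair
    decoy_seed = None if seed is None else int(
        np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)
    )
    decoys = generate_library(max(C - 1, 1), R, max(A - 1, 1), seed=decoy_seed)
    lib = ComponentLibrary(
        constitutive=[planted_const, *decoys.constitutive],
        repressed=decoys.repressed,
        activated=[planted_act, *decoys.activated],
        provenance=(
            f"calibrate_demo_library(seed={seed}); planted pair "
            f"C-cal/A-cal tracks the reference within {rel_err:.2%}"
        ),
    )
    return DemoCalibration(lib, "C-cal", "A-cal", rel_err)


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1.0 - 1e-9)
    return math.log(p / (1.0 - p))
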