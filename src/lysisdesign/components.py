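"""Promoter-RBS components and their Hill-type regulation functions.

A promoter-RBS component lumps transcription and translation into a single
kinetic strength (nM·min⁻¹ of protein synthesis).  Three classes exist:

* ``constitutive`` — fixed synthesis rate ``Pu``; drives the first circuit
  stage (the regulatory protein).
* ``repressor_regulated`` — activity falls from ``Pu`` to ``Pl`` as the
  effective repressor concentration rises; the inducer I1 sequesters the
  repressor and de-represses the promoter.
* ``activator_regulated`` — activity rises from ``Pl`` to ``Pu`` as the
  effective activator concentration rises; the inducer I2 (e.g. AHL in a
  LuxR quorum-sensing stage) is required to form the active complex.

Units: concentrations in nM, time in minutes, strengths in nM·min⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .errors import DesignDomainError, UsageError

ComponentKind = Literal["constitutive", "repressor_regulated", "activator_regulated"]

KINDS: tuple[str, ...] = ("constitutive", "repressor_regulated", "activator_regulated")

#: fields that must be present (positive) for a regulated component
_REGULATED_FIELDS = ("K", "n", "KI")


@dataclass(frozen=True)
class PromoterRBSComponent:
    """One library entry: a promoter-RBS part described by lumped kinetics.

    Parameters
    ----------
    id:
        Short unique label, e.g. ``"C3"`` or ``"A-cal"``.
    kind:
        Component class; one of :data:`KINDS`.
    Pu:
        Maximum promoter-RBS strength (nM·min⁻¹).
    Pl:
        Minimum strength (nM·min⁻¹); 0 for constitutive components.
    K:
        Binding affinity between the regulator and the promoter-RBS (nM);
        ``None`` for constitutive components.
    n:
        Hill binding cooperativity (dimensionless, > 0); ``None`` for
        constitutive components.
    KI:
        Dissociation constant between inducer and regulator (nM); ``None``
        for constitutive components.
    """

    id: str
    kind: ComponentKind
    Pu: float
    Pl: float = 0.0
    K: float | None = None
    n: float | None = None
    KI: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise UsageError(f"unknown component kind {self.kind!r}")
        if not self.id:
            raise DesignDomainError("component id must be non-empty")
        if not (math.isfinite(self.Pu) and self.Pu >= 0.0):
            raise DesignDomainError(f"{self.id}: Pu must be finite and >= 0, got {self.Pu}")
        if not (math.isfinite(self.Pl) and self.Pl >= 0.0):
            raise DesignDomainError(f"{self.id}: Pl must be finite and >= 0, got {self.Pl}")
        if self.kind == "constitutive":
            if self.Pl != 0.0:
                raise DesignDomainError(f"{self.id}: constitutive component must have Pl = 0")
            for name in _REGULATED_FIELDS:
                if getattr(self, name) is not None:
                    raise DesignDomainError(
                        f"{self.id}: constitutive component must not carry {name}"
                    )
        else:
            if self.Pu <= self.Pl:
                raise DesignDomainError(
                    f"{self.id}: require Pu > Pl, got Pu={self.Pu}, Pl={self.Pl}"
                )
            for name in _REGULATED_FIELDS:
                value = getattr(self, name)
                if value is None or not math.isfinite(value) or value <= 0.0:
                    raise DesignDomainError(
                        f"{self.id}: regulated component needs {name} > 0, got {value}"
                    )


def effective_repressor(x_r1: float, I1: float, KI1: float) -> float:
    """Inducer-adjusted repressor concentration x_r1* = x_r1 / (1 + I1/KI1).

    The inducer I1 binds the repressor and removes it from the pool able to
    occupy the operator, so the effective repressor decreases monotonically
    in I1, from ``x_r1`` at I1 = 0 towards 0 at saturating inducer.
    """
    if x_r1 < 0.0 or I1 < 0.0:
        raise DesignDomainError("concentrations must be nonnegative")
    if KI1 <= 0.0:
        raise DesignDomainError(f"KI1 must be positive, got {KI1}")
    return x_r1 / (1.0 + I1 / KI1)


def effective_activator(x_a1: float, I2: float, KI2: float) -> float:
    """Inducer-bound activator concentration x_a1* = x_a1 / (1 + KI2/I2).

    Only the activator–inducer complex is active (the quorum-sensing
    LuxR·AHL picture), so x_a1* rises from 0 at I2 = 0 (taken as the
    continuous limit) to ``x_a1`` at saturating inducer.
    """
    if x_a1 < 0.0 or I2 < 0.0:
        raise DesignDomainError("concentrations must be nonnegative")
    if KI2 <= 0.0:
        raise DesignDomainError(f"KI2 must be positive, got {KI2}")
    if I2 == 0.0:
        return 0.0
    return x_a1 / (1.0 + KI2 / I2)


def regulation_constitutive(comp: PromoterRBSComponent) -> float:
    """Activity of a constitutive component: the constant ``Pu``."""
    if comp.kind != "constitutive":
        raise UsageError(f"{comp.id}: regulation_constitutive needs a constitutive component")
    return comp.Pu


def regulation_repressed(comp: PromoterRBSComponent, x_r1: float, I1: float) -> float:
    """Repressible promoter-RBS activity Pl + (Pu−Pl) / (1 + (x_r1*/K)^n).

    Decreasing Hill function of the effective repressor; equals ``Pu`` with
    no repressor and approaches ``Pl`` under full repression.
    """
    if comp.kind != "repressor_regulated":
        raise UsageError(f"{comp.id}: regulation_repressed needs a repressor-regulated component")
    x_star = effective_repressor(x_r1, I1, comp.KI)
    return comp.Pl + (comp.Pu - comp.Pl) / (1.0 + _pow(x_star / comp.K, comp.n))


def regulation_activated(comp: PromoterRBSComponent, x_a1: float, I2: float) -> float:
    """Activatable promoter-RBS activity Pl + (Pu−Pl) / (1 + (K/x_a1*)^n).

    Increasing Hill function of the effective activator; equals ``Pl`` when
    no active complex is present (x_a1* = 0, taken as the limit) and
    saturates at ``Pu``.
    """
    if comp.kind != "activator_regulated":
        raise UsageError(f"{comp.id}: regulation_activated needs an activator-regulated component")
    x_star = effective_activator(x_a1, I2, comp.KI)
    if x_star == 0.0:
        return comp.Pl
    return comp.Pl + (comp.Pu - comp.Pl) / (1.0 + _pow(comp.K / x_star, comp.n))


def _pow(ratio: float, n: float) -> float:
    # ratio**n can exceed float range for extreme regulator levels; the Hill
    # term then saturates, so +inf is the correct limit
    try:
        return ratio**n
    except OverflowError:
        return math.inf


def regulation_activity(comp: PromoterRBSComponent, x_reg: float, I: float) -> float:
    """Dispatch to the regulation function matching ``comp.kind``."""
    if comp.kind == "constitutive":
        return regulation_constitutive(comp)
    if comp.kind == "repressor_regulated":
        return regulation_repressed(comp, x_reg, I)
    return regulation_activated(comp, x_reg, I)
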