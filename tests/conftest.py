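import numpy as np
import pytest

import lysisdesign as ld


@pytest.fixture(scope="session")
def ref():
    """Demo reference response 0.1 + 0.6/(1 + 2 I^2)."""
    return ld.ReferenceResponse()


@pytest.fixture(scope="session")
def template():
    """Activator-topology circuit template with the package default rates."""
    lib = ld.generate_library(1, 1, 1, seed=0)
    return ld.CircuitSpec(
        topology="activator",
        constitutive=ld.PromoterRBSComponent("c0", "constitutive", Pu=5.0),
        regulated=lib.activated[0],
    )


@pytest.fixture(scope="session")
def calibrated(ref, template):
    """Demo library with a planted pair tracking the reference response."""
    return ld.calibrate_demo_library(ref, template, seed=0)


def random_activator_spec(rng, gamma_N_scale=0.5, at_inducer=1.0):
    """A random activator circuit whose lysis kills only part of the population.

    gamma_N is scaled so gamma_N * x_lys_ss = gamma_N_scale * k at the given
    inducer level, keeping the steady-state density strictly positive there.
    """
    const = ld.PromoterRBSComponent("c", "constitutive", Pu=float(rng.uniform(1, 10)))
    act = ld.PromoterRBSComponent(
        "a", "activator_regulated",
        Pu=float(rng.uniform(1, 5)), Pl=float(rng.uniform(0.01, 0.5)),
        K=float(rng.uniform(1, 50)), n=float(rng.uniform(1, 3)),
        KI=float(rng.uniform(0.5, 10)),
    )
    k = float(rng.uniform(0.01, 0.04))
    spec = ld.CircuitSpec(
        "activator", const, act,
        gamma_reg=float(rng.uniform(0.02, 0.2)),
        gamma_lys=float(rng.uniform(0.02, 0.2)),
        k=k, Nmax=1.0, gamma_N=0.0,
    )
    x_lys = ld.steady_state(spec, at_inducer).x_lys_ss
    from dataclasses import replace

    return replace(spec, gamma_N=gamma_N_scale * k / x_lys)


def random_repressor_spec(rng, gamma_N_scale=0.5, at_inducer=10.0):
    const = ld.PromoterRBSComponent("c", "constitutive", Pu=float(rng.uniform(1, 10)))
    rep = ld.PromoterRBSComponent(
        "r", "repressor_regulated",
        Pu=float(rng.uniform(1, 5)), Pl=float(rng.uniform(0.01, 0.5)),
        K=float(rng.uniform(1, 50)), n=float(rng.uniform(1, 3)),
        KI=float(rng.uniform(0.5, 10)),
    )
    k = float(rng.uniform(0.01, 0.04))
    spec = ld.CircuitSpec(
        "repressor", const, rep,
        gamma_reg=float(rng.uniform(0.02, 0.2)),
        gamma_lys=float(rng.uniform(0.02, 0.2)),
        k=k, Nmax=1.0, gamma_N=0.0,
    )
    # lysis expression is strongest at high I1 for the repressible stage
    x_lys = ld.steady_state(spec, at_inducer).x_lys_ss
    from dataclasses import replace

    return replace(spec, gamma_N=gamma_N_scale * k / x_lys)
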