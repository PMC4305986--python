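# Methods

## Model

`lysisdesign` models a two-stage genetic lysis circuit in *E. coli*. A
constitutive promoter-RBS component synthesizes a regulatory protein at a
constant lumped rate; that protein (a repressor, or an activator such as
LuxR that must first complex with its inducer) regulates a second
promoter-RBS component driving a lysis gene; the lysis protein kills cells
at a first-order rate. With x_reg and x_lys the protein concentrations (nM)
and N the population density (O.D. 600):

    dx_reg/dt = P_c1              − (γ_reg + k)·x_reg
    dx_lys/dt = P_2(x_reg, I)     − (γ_lys + k)·x_lys
    dN/dt     = k·N·(1 − N/Nmax)  − γ_N·N·x_lys

P_c1 is the constitutive strength P_u. P_2 is a Hill function of the
*effective* regulator:

* repressible stage:  P_2 = P_l + (P_u − P_l)/(1 + (x*/K)^n), with
  x* = x_reg/(1 + I/K_I) — the inducer sequesters the repressor;
* activatable stage:  P_2 = P_l + (P_u − P_l)/(1 + (K/x*)^n), with
  x* = x_reg/(1 + K_I/I) — only the regulator–inducer complex activates.

At x* = 0 the activatable form is defined by its continuous limit (activity
P_l), including I = 0; `ratio**n` overflow for extreme regulator levels
saturates to the same rail. Transcription and translation are lumped into
one strength per component; there is no mRNA stage, no copy-number noise
model, and no agent-based division — these are deliberate non-goals.

Setting the derivatives to zero gives the closed-form steady state used
everywhere in design:

    x_reg_ss = P_c1/(γ_reg + k)
    x_lys_ss = P_2(x_reg_ss, I)/(γ_lys + k)
    N_ss     = Nmax·(1 − (γ_N/k)·x_lys_ss)

The density line is the nontrivial logistic root; when lysis outpaces
growth (γ_N·x_lys_ss > k) the formula goes negative, the physical steady
state is extinction, and the result is clamped to 0 with a `clamped` flag.
Because N_ss is built from monotone pieces, it is nonincreasing in the
inducer for both topologies (more inducer ⇒ more lysis protein ⇒ lower
density); the suite asserts this over randomized parameter grids.

## Units and default parameters

The model is unit-consistent rather than unit-derived: inducer and protein
concentrations in nM (the AHL working range), time in minutes, strengths in
nM·min⁻¹, density in O.D. 600. Defaults, chosen as typical for engineered
*E. coli* strains growing in batch:

| parameter | meaning | default |
|---|---|---|
| k | growth/dilution rate | 0.02 min⁻¹ (≈35 min doubling) |
| γ_reg, γ_lys | protein degradation | 0.05 min⁻¹ (tagged proteins) |
| Nmax | carrying capacity | 1.0 O.D. |
| γ_N | lysis rate per nM of lysis protein | 4×10⁻⁴ nM⁻¹·min⁻¹ |
| horizon | steady-state read-out | 240 min |

One symbol k serves both as protein dilution and logistic growth rate; the
two are the same physical process in exponential-to-stationary batch growth.

## Integration and noise

Deterministic trajectories use fixed-step classical RK4 (default dt =
0.1 min). Stochastic trajectories use Euler–Maruyama with additive Gaussian
process noise ω·√dt per state and clipping at zero after every step; a
shared fixed grid keeps deterministic and stochastic paths comparable. The
integrator is validated against the closed form: for random circuits with
partial lysis, the terminal state of a long-horizon run matches the
steady-state formulas to 10⁻⁶ relative, and halving dt moves the terminal
density by < 10⁻⁴.

Steady-state observation noise (v₁, v₂, v₃) is additive on the three
steady-state quantities, applied before clamping. A unit-variance
convention for v on an O.D. scale bounded by 1 would swamp the signal, so
the defaults are small (0.01, 0.01, 0.005) and configurable; noise is off
unless explicitly enabled.

## Parameter fluctuations

Kinetic uncertainty is multiplicative: every synthesis strength and rate p
is replaced by p·(1 + frac·n) with frac = 0.05 by default (5% part-to-part
variability). Three standard-normal sources are shared per draw — one for
the first expression stage (constitutive strength, γ_reg), one for the
second stage (regulated strengths, γ_lys), one for the population
parameters (k, γ_N) — reflecting that parameters of one expression stage
fluctuate together; binding constants (K, n, K_I) are treated as structural
and not perturbed. Draws whose multiplier would be non-positive are
resampled; the rejection rule depends only on the multiplier, so one draw
matrix can be reused across design candidates as common random numbers.
Note two structural consequences: within a stage the ordering P_u > P_l is
preserved exactly, and the γ_N/k ratio in the density line is noise-free
because both share the population source.

## Design search

The tracking cost of a candidate pair S = (constitutive i, regulated j) is

    J(S) = E ∫ (N_ss(S, I) − N_ref(I))² dI,  I ∈ [I_min, I_max]

with the expectation over the fluctuation ensemble (default 100 draws,
common random numbers across candidates) and the integral by the trapezoid
rule on a 25-point log-spaced inducer grid (inducer dose–responses live on
a log axis; doubling the grid changes J negligibly). Fitness is
F = 1/(J + ε), ε = 10⁻¹², regularizing the perfect-fit pole.

The genetic algorithm's genome is the index pair itself: fitness-
proportional reproduction, crossover that exchanges one index between two
parents (p = 0.7), per-gene mutation to a uniform random valid index
(p = 0.1), elitism 1, population 20, generations 100. Two implementation
choices matter on small discrete spaces. First, costs are memoized, so the
reported optimum is the best pair ever evaluated. Second, after mutation,
duplicate individuals are replaced by uniform random immigrants: with pure
fitness-proportional selection the population otherwise collapses onto one
genotype, crossover becomes a no-op, and escaping requires a rare double
mutation. The no-duplicate policy keeps exploration alive without touching
the canonical operators, and makes the GA provably (with overwhelming
probability) find the exhaustive optimum on libraries of ≤ 100 pairs — an
identity the suite checks against brute-force enumeration on 20 random
libraries.

`recommend_inducer` inverts the reference family
N_ref(I) = base + amplitude/(1 + scale·I^exponent) in closed form and
validates the target against the attainable interval
[N_ref(I_max), N_ref(I_min)].

## Synthetic libraries and calibration

No public table of characterized promoter-RBS parts ships with the
package, so libraries are synthesized: maximum strengths log-uniform over
several decades (default 0.05–50 nM·min⁻¹, the span a promoter/RBS
collection typically covers), leaky minima at 1–10% of the maximum, K
log-uniform 1–100 nM, n uniform 1–4, K_I log-uniform 0.1–10 nM. The
generator is deterministic per seed. `fit_component` recovers a part's
parameters from reporter-style activity measurements by bounded least
squares (P_u, K, K_I on a log scale, n ∈ [0.5, 6]); flat curves are
rejected as non-identifiable. Synthetic libraries emulate the kinetic
*ranges* of real collections, not any measured part, so green tests
demonstrate correctness of the machinery, not agreement with any specific
laboratory strain.

`calibrate_demo_library` plants a known-optimal pair: holding the template
rates, the first-stage strength, cooperativity n = 2 and K_I = 1000 nM
fixed (a large K_I keeps the active complex nearly linear in inducer over
0.1–10 nM, which is what lets a Hill stage reproduce the
amplitude/(1 + scale·I²) reference shape), it solves for the activated
part's (P_u, P_l, K) by least squares against the reference response on a
log grid, verifies the tracking error (≤ 2% required; ~0.07% achieved for
the default reference), and pads the library with random decoys. The
planted pair is the ground truth for the end-to-end search tests.

## Numerical conventions and limitations

* Ties in candidate ranking break by lowest (i, j); searches are fully
  reproducible per seed, with child seeds spawned via `SeedSequence`.
* Library CSV round-trips exactly: floats are written as `repr` and parsed
  with pandas' round-trip parser.
* Degenerate inputs fail loudly: k = 0 (division in the density line),
  empty inducer grids/sweeps, mismatched component kinds, flat
  characterization curves, unreachable target densities (the error carries
  the attainable interval).
* Oracle tests use horizons of a few thousand minutes — far beyond a real
  240-min experiment — because verifying a 10⁻⁶ fixed-point identity
  requires letting the slow density mode decay; this is a numerical
  verification device, not a biological claim.
* The model says nothing about spatial structure, resource burden,
  mutational escape from the lysis circuit, or the OMPLA lysis mechanism
  itself; it predicts population-average steady states under the stated
  kinetics.
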