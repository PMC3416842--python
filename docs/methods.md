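# Methods

## Model

The network has N binary neurons sigma_i = +/-1 updated **in parallel**
(Little-model dynamics): given local fields h_i = sum_j J_ij sigma_j +
theta_i, every spin is redrawn simultaneously with

    P(sigma_i(t+1) = +1) = exp(beta h_i) / (2 cosh(beta h_i)),   beta = 1/T,

which at T = 0 degenerates to the deterministic map sigma_i <- sign(h_i)
(tie-break sign(0) = +1, fixed for reproducibility; ties have vanishing
probability for generic patterns but occur in toy inputs).  External fields
theta_i default to zero everywhere; they exist in the interface because the
theory treats them as probe fields, not because any protocol uses them.

The couplings mix two Hebbian constructions with a mixture parameter
nu in [0, 1],

    J = nu * Xi_sym + (1 - nu) * Xi_asym,
    Xi_sym[ij]  = (1/N) sum_mu xi[mu,i] xi[mu,j],
    Xi_asym[ij] = (1/N) sum_mu xi~[(mu+1) mod P, i] xi~[mu,j],

with zero self-couplings (standard for Hopfield-class models).  nu = 1 is
the Hopfield model (associative memory, AM: patterns are fixed points);
nu = 0 is the asymmetric sequence network (sequential pattern recognition,
SPR: the P patterns form one cyclic attractor traversed one pattern per
step).  Two variants differ in where the two parts get their patterns:

* **one-set**: xi~ = xi — symmetric and asymmetric parts share one pattern
  set and are therefore correlated;
* **two-set**: xi and xi~ are independent sets, so fixed points and the
  cycle can in principle coexist in one network.

The load parameter is alpha = P/N, held finite (saturated regime).

## Simulation protocols

Dilution: each neuron keeps exactly K randomly chosen incoming connections
(fixed once drawn).  Kept weights are rescaled by N/K so the mean local
field at a stored pattern is unchanged; the effective load of a diluted
run is then P/K.  The rescaling is this package's choice — it keeps the
fully-connected mean-field theory approximately predictive for the diluted
simulations — and is exposed, not hidden.

AM protocol: for each pattern, start from a state with exactly 10% of
spins flipped (an exact count, not per-spin Bernoulli, so the initial
overlap is exactly 0.8), run 35 synchronous steps, record the overlap with
that pattern; report the average over patterns.  SPR protocol: corrupt a
sequence pattern by 10%, run 3P transient steps, align the cycle phase to
the best-matching sequence index, then average the signed overlap with the
sequence advanced one pattern per step over one full period.  Signed
overlaps mean retrieval of the anti-cycle is visible as a mean near -1
rather than being silently counted as success.

Attractor detection stores visited states in a hash table and reports the
exact recurrence period; it is restricted to T = 0, where the dynamics are
a deterministic map on a finite state space and every trajectory is
eventually periodic.

A master seed spawns independent streams for pattern generation, dilution,
corruption, and thermal noise; all outputs record their seeds.

## Stationary mean-field theory

Near saturation, the condensed-pattern ansatz (the state has O(1) overlap
m with one pattern per time step — the same pattern for AM, the cyclically
advancing one for SPR — and O(N^-1/2) overlaps with all others) reduces
each of the four cases (AM/SPR x one-set/two-set) to three coupled scalar
equations for the condensed overlap m, the state correlation C (frozen,
Edwards-Anderson-type order), and the variance r of the non-condensed
overlaps.  With s = nu (AM) or 1 - nu (SPR) and V = alpha r + Gamma:

    m = Int Dz tanh[beta (s m + sqrt(V) z)]
    C = Int Dz tanh^2[beta (s m + sqrt(V) z)]
    r = C * R(nu, chi),        chi = beta (1 - C).

R resums the feedback ladder of the interference noise.  Chains running
through the symmetric couplings of a *static* condensed state add
coherently in time (factor 1/(1 - nu chi)^2, the classical susceptibility
enhancement); chains through sequence couplings visit an independent
pattern at every step and add incoherently (factor 1/(1 - w^2 chi^2)); in
the one-set model both channels share one pattern set and the mixed chain
sum becomes a circulant (Poisson-kernel) integral, evaluated in closed
form.  The derivation reproduces the classical limits exactly: at nu = 1
(AM) the Hopfield/Little equations with zero-temperature capacity
alpha_c = 0.1379 (m_c = 0.967), and at nu = 0 (SPR) the asymmetric
sequence network with alpha_c = 0.2691.

Gamma is specific to the one-set model: there the asymmetric couplings
coherently push a condensed state onto the successor patterns, seeding a
cascade of secondary overlaps.  Treated at linear response, the cascade
contributes a self-induced quasi-noise Gamma proportional to m^2, which is
what frustrates intermediate-nu retrieval when both parts share patterns.
For independent sets Gamma = 0 — the structural reason AM and SPR can
coexist in the two-set model.  The linear-response (Gaussian) treatment of
the cascade is a closure choice; its known consequence is that every
retrieval branch of the one-set AM system terminates discontinuously, so
this theory has no weakly-correlated band in which m decays continuously
to zero (the WC label exists in the classifier and is simply empty here).
A full treatment of frustrated mixture states would require a
condensed-overlap *vector*, outside this package's three-parameter systems.

The trivial solution (0, 0, 0) solves every system exactly.  Spin-glass
solutions (m = 0, C, r > 0) appear below T_SG, obtained by linearizing the
(C, r) sector around zero (chi -> beta), which gives the closed scalar
condition alpha beta^2 R(nu, beta) = 1.  R diverges at the edge of its
convergence domain, so a root — and hence a spin-glass phase — exists for
every alpha > 0 and every nu.  At nu = 1 the condition solves to the
Hopfield line T_SG = 1 + sqrt(alpha).  At T = 0 the spin-glass
susceptibility solves chi = sqrt(2 / (pi alpha R(chi))), which always has
a root: the zero-temperature spin-glass state exists everywhere.

### Numerics

* Gaussian averages: fixed-order Gauss-Hermite (order 96), chosen over
  adaptive quadrature so every quantity is smooth in its parameters — the
  existence bisections need noise-free continuity.  For beta > 50 the tanh
  kink is narrower than the node spacing, so the averages switch to an
  exact T = 0 part (error function) plus a thermal-layer correction
  integrated on a fixed grid in u = beta h, where tanh(u) - sign(u) and
  sech^2(u) decay like e^(-2|u|); truncation at |u| = 40 with spacing 0.05
  is far below solver tolerance.
* Finite-T solving: damped fixed-point iteration (damping 0.5, tolerance
  1e-10 in max norm, cap 10000 iterations).  Retrieval starts from m = 1
  with initial susceptibility chi0 = 0.2 (retries 0.05 and 0.4): the
  retrieval system generically has a stable root and an unstable middle
  root, and too aggressive an initial chi lands in the middle root's
  outflow.  The spin-glass branch starts from the zero-T closed form via
  C0 = 1 - T chi0.  Collapse onto m = 0 (retrieval) or C = 0 (spin glass)
  is reported as "no solution"; iterates leaving the ladder convergence
  domain or turning non-finite are reported as "diverged", a distinct
  outcome.
* beta -> infinity is a separate code path: with C -> 1 and
  chi -> sqrt(2/(pi V)) exp(-x^2), x = s m / sqrt(2 V), the system
  collapses to the scalar family alpha(x); capacity is its maximum over x
  (dense scan plus ternary refinement), the retrieval state is the
  descending-branch root, and "retrieval with m >= theta" boundaries come
  from the same family.  The finite-T integrands degenerate in this limit,
  which is why it is not taken as a large-beta limit of the finite-T path.
* critical_alpha bisects on retrieval existence to 1e-4 in alpha,
  doubling alpha upward from 1e-4 to bracket; absence of retrieval already
  at alpha = 1e-4 raises a bracket error rather than returning a value.

## Phase classification

theta_HC = 0.9 and theta_WC = 0.5 by default (a state with m = 0.5 has
(1 + m)/2 = 75% of its neurons correct, the natural "not useful recall"
line); both are explicit inputs, not constants.  HC means the retrieval
branch exists with |m| >= theta_HC (anti-pattern retrieval counts — the
specular copies are stored too); retrieval in [theta_WC, theta_HC) is an
explicit indeterminate outcome; sub-theta_WC retrieval is the WC label in
the one-set AM system and is otherwise disregarded in favour of the
disordered solutions (a near-critical vestigial branch is not recall); SG
when only spin-glass solutions remain; TS when only the trivial solution
exists.  HC wins over SG where both exist.  Default grids are 101 x 101
over alpha in [0, 0.35], T in [0, 1.5], which bracket every boundary of
interest; tests and examples use coarser grids purely for speed, stated
where used.

## What the synthetic data does and does not emulate

Pattern sets are i.i.d. equiprobable +/-1 matrices — exactly the ensemble
the theory assumes.  The glyph fixture emulates storing digitized
grayscale images (procedurally drawn seven-segment glyphs on a textured
background, 8 bits per pixel, most-significant bit first, bit 1 -> +1) so
that the demonstration pipeline runs on image-like data with no bundled
assets; the texture keeps distinct glyph patterns nearly orthogonal
(pairwise overlaps < 0.23 at the default 16 x 10 x 8 size).  None of this
probes correlated or sparse patterns, asymmetric dilution statistics, or
non-binary neurons: passing tests say nothing about such regimes.

Simulation scales used throughout (N = 2000, K = 500, P = 10 + 10;
capacity cross-checks at N = 4000) are the package's choice of a size
where mean-field predictions are already sharp to a few percent while a
full run stays in seconds; finite-size rounding of transitions — e.g. the
remanent overlap ~0.5 that a T = 0 Hopfield network keeps just above
capacity — is visible and expected at these sizes.

## Known limitations

* The two-set AM and SPR critical lines are *not* exact mirror images
  under nu <-> 1 - nu in this theory: a static condensed state enjoys the
  coherent 1/(1 - nu chi)^2 ladder from its own symmetric couplings,
  whereas a cycling state collects only the incoherent sum — compare the
  pure limits, alpha_c = 0.138 (Hopfield) vs 0.269 (sequence).  The mirror
  is qualitative (same region topology, HC shrinking in the opposing
  weight), and the package reports the measured discrepancy rather than
  hiding it.
* Replica-symmetry-breaking corrections, stability (AT-line) analysis,
  quasi-periodic states, correlated patterns, and partially shared pattern
  sets are all out of scope.
* The one-set cascade closure is linear-response Gaussian (see above); it
  preserves both pure limits and the no-coexistence structure but cannot
  produce weakly-correlated stationary states.
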