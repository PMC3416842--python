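"""Stationary mean-field theory of the mixed-synapse network near saturation.

For load alpha = P/N held finite as N -> infinity, the condensed-pattern
ansatz reduces the parallel (Little) dynamics to three coupled scalar
self-consistency equations per case.  Writing s for the condensed signal
weight (s = nu for AM retrieval, s = 1 - nu for SPR retrieval), the
stationary order parameters (m, C, r) obey

    m = Int Dz tanh[beta (s m + sqrt(V) z)]
    C = Int Dz tanh^2[beta (s m + sqrt(V) z)]
    r = C * R(nu, chi),        chi = beta (1 - C),    V = alpha r + Gamma,

where Int Dz is the standard-Gaussian average, C is the correlation between
two network states (the frozen, Edwards-Anderson-type order), r is the
variance of the non-condensed overlaps, and R is a case-dependent chain
(ladder) resummation of the interference noise:

* two-set AM:   R = nu^2/(1-nu chi)^2 + (1-nu)^2/(1-(1-nu)^2 chi^2)
* two-set SPR:  R = nu^2/(1-nu^2 chi^2) + (1-nu)^2/(1-(1-nu)^2 chi^2)
* one-set AM:   R = (1/2pi) Int dw (a + b cos w) / |(1-nu chi) - (1-nu) chi e^{iw}|^2
* one-set SPR:  R = (1/2pi) Int dw (a + b cos w) / (1 - chi^2 (a + b cos w))

with a = nu^2 + (1-nu)^2, b = 2 nu (1-nu).  The static condensed state is
coherently reinforced by its own symmetric couplings (the (1-nu chi)^-2
ladder), while chains that traverse the sequence couplings visit a fresh
pattern at every step and add incoherently; in the one-set model the two
channels mix, giving the circulant (Fourier) forms.

In the one-set model the sequence couplings additionally feed the condensed
overlap coherently into the successor patterns.  Treating this cascade at
linear response gives a self-induced quasi-noise of variance

    Gamma_AM  = m^2 (1-nu)^2 / [(1-nu chi)^2 - (1-nu)^2 chi^2]
    Gamma_SPR = m^2 nu^2     / [(1-(1-nu) chi)^2 - nu^2 chi^2]

which is what frustrates retrieval at intermediate nu; for the two-set
model the sets are independent and Gamma = 0.

The trivial solution (0, 0, 0) solves every system.  Spin-glass solutions
have m = 0 with C, r > 0; they appear below the temperature T_SG at which
the trivial solution loses stability, the root of alpha beta^2 R(nu, beta) = 1.

At T = 0 the retrieval equations collapse to one scalar relation: with
x = s m / sqrt(2 V), C -> 1 and chi -> chi0 = sqrt(2/(pi V)) exp(-x^2),

    m = erf(x),     V = alpha R(nu, chi0) + Gamma(m, chi0),

and the load alpha(x) admitting a solution at given x traces the family of
curves whose maximum over x is the storage capacity alpha_c.  At nu = 1
(AM) this reproduces the classical Hopfield capacity alpha_c ~ 0.1379 and
at nu = 0 (SPR) the sequence-processing capacity alpha_c ~ 0.269.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf, erfinv

__all__ = [
    "MeanFieldContext",
    "OrderParameters",
    "BranchResult",
    "gauss_expectation",
    "noise_multiplier",
    "cascade_variance",
    "rhs",
    "solve_branch",
    "spin_glass_temperature",
    "zero_t_alpha_of_x",
    "retrieval_zero_temperature",
    "capacity_zero_temperature",
    "alpha_hc_zero_temperature",
    "critical_alpha",
    "sg_chi_zero_temperature",
]

# fixed-order Gauss-Hermite quadrature: smooth in parameters, which the
# existence bisections rely on; order 96 gives ~1e-14 on the tanh averages
_GH_ORDER = 96
_gh_nodes, _gh_weights = np.polynomial.hermite.hermgauss(_GH_ORDER)
_Z = _gh_nodes * math.sqrt(2.0)
_W = _gh_weights / math.sqrt(math.pi)

_EDGE = 1.0 - 1e-12  # chain sums are used on the convergent side of their poles
_RETRIEVAL_CHI0 = 0.2  # initial susceptibility guess for the retrieval branch

log = logging.getLogger("mixnet.meanfield")


def gauss_expectation(f) -> float:
    """Standard-Gaussian average Int f(z) exp(-z^2/2)/sqrt(2 pi) dz."""
    return float(np.dot(_W, f(_Z)))


# at large beta the tanh kink is narrower than the quadrature spacing, so
# the thermal layer is integrated in the field variable u = beta*(s + sqrt(V) z)
_BETA_SWITCH = 50.0
_U = np.linspace(-40.0, 40.0, 1601)
_DU = _U[1] - _U[0]
_TANH_MINUS_SIGN = np.tanh(_U) - np.sign(_U)
_SECH2 = 1.0 / np.cosh(_U) ** 2


def _tanh_moments(beta: float, s: float, V: float) -> tuple[float, float]:
    """(E tanh(beta h), E tanh^2(beta h)) for h ~ Normal(s, V).

    Gauss-Hermite handles moderate beta; for beta above _BETA_SWITCH the
    averages are split into the T=0 part (an error function) plus a thermal
    correction localized within |beta h| < O(10), integrated on a fixed grid
    in u = beta h where tanh(u) - sign(u) and sech^2(u) decay like e^(-2|u|).
    """
    if V <= 0.0:
        t = math.tanh(beta * s)
        return t, t * t
    if beta <= _BETA_SWITCH:
        t = np.tanh(beta * (s + math.sqrt(V) * _Z))
        return float(np.dot(_W, t)), float(np.dot(_W, t * t))
    sd = math.sqrt(V)
    z = (_U / beta - s) / sd
    dens = np.exp(-0.5 * z * z) / (math.sqrt(2.0 * math.pi) * sd * beta)
    m0 = float(erf(s / math.sqrt(2.0 * V)))
    m = m0 + float(np.dot(dens, _TANH_MINUS_SIGN)) * _DU
    one_minus_c = float(np.dot(dens, _SECH2)) * _DU
    return m, 1.0 - one_minus_c


@dataclass(frozen=True)
class MeanFieldContext:
    """Which stationary system applies, and at which (alpha, nu, T)."""

    alpha: float
    nu: float
    temperature: float
    dynamics: str = "AM"       # "AM" | "SPR"
    variant: str = "two_set"   # "one_set" | "two_set"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0.0 <= self.nu <= 1.0:
            raise ValueError("nu must lie in [0, 1]")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.dynamics not in ("AM", "SPR"):
            raise ValueError(f"unknown dynamics {self.dynamics!r}")
        if self.variant not in ("one_set", "two_set"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def beta(self) -> float:
        return math.inf if self.temperature == 0 else 1.0 / self.temperature

    @property
    def signal_weight(self) -> float:
        return self.nu if self.dynamics == "AM" else 1.0 - self.nu


@dataclass(frozen=True)
class OrderParameters:
    """Condensed overlap m, state correlation C, overlap variance r."""

    m: float = 0.0
    C: float = 0.0
    r: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.C, self.r])


@dataclass(frozen=True)
class BranchResult:
    """Solver outcome: 'converged', 'no_solution' (branch collapsed), or 'diverged'."""

    status: str
    op: OrderParameters | None = None
    iterations: int = 0

    @property
    def converged(self) -> bool:
        return self.status == "converged"


# ---------------------------------------------------------------------------
# Interference-noise resummation R(nu, chi) and the one-set cascade Gamma
# ---------------------------------------------------------------------------

def _poisson_integral(a: float, b: float, c: float, d: float) -> float:
    """(1/2pi) Int (a + b cos w)/(c - d cos w) dw for c > |d|."""
    s = math.sqrt(c * c - d * d)
    if abs(d) < 1e-14:
        return a / c + b * d / (2 * c * c)
    return a / s + b * ((c / d) / s - 1.0 / d)


def noise_multiplier(dynamics: str, variant: str, nu: float, chi: float) -> float:
    """Chain resummation R such that r = C * R; NaN outside the convergence domain."""
    if chi < 0:
        return math.nan
    nb = 1.0 - nu
    if variant == "two_set":
        if nu * chi >= _EDGE or nb * chi >= _EDGE:
            return math.nan
        seq = nb ** 2 / (1.0 - nb ** 2 * chi ** 2)
        if dynamics == "AM":
            return nu ** 2 / (1.0 - nu * chi) ** 2 + seq
        return nu ** 2 / (1.0 - nu ** 2 * chi ** 2) + seq
    # one-set: the two channels share patterns, giving circulant chain sums
    if chi >= _EDGE:
        return math.nan
    a = nu ** 2 + nb ** 2
    b = 2.0 * nu * nb
    if dynamics == "AM":
        c = (1.0 - nu * chi) ** 2 + nb ** 2 * chi ** 2
        d = 2.0 * (1.0 - nu * chi) * nb * chi
    else:
        c = 1.0 - chi ** 2 * a
        d = chi ** 2 * b
    if c <= abs(d) or c <= 0:
        return math.nan
    return _poisson_integral(a, b, c, d)


def cascade_variance(dynamics: str, variant: str, nu: float, chi: float,
                     m: float) -> float:
    """Quasi-noise from the coherent one-set cascade; 0 for the two-set model."""
    if variant == "two_set":
        return 0.0
    nb = 1.0 - nu
    if dynamics == "AM":
        den = (1.0 - nu * chi) ** 2 - nb ** 2 * chi ** 2
        num = m * m * nb ** 2
    else:
        den = (1.0 - nb * chi) ** 2 - nu ** 2 * chi ** 2
        num = m * m * nu ** 2
    if den <= 0:
        return math.nan
    return num / den


# ---------------------------------------------------------------------------
# Finite-temperature system
# ---------------------------------------------------------------------------

def rhs(ctx: MeanFieldContext, op: OrderParameters) -> OrderParameters:
    """One evaluation of the self-consistency system; pure in (ctx, op).

    Requires T > 0 (the T = 0 limit is handled by the reduced scalar
    equations below).  Returns NaN components if (ctx, op) leaves the
    convergence domain of the chain resummations.
    """
    if ctx.temperature == 0:
        raise ValueError("rhs is the finite-temperature system; use the zero-T path")
    beta = ctx.beta
    chi = beta * (1.0 - op.C)
    # a vanishing order parameter silences its noise channel exactly, even
    # where the chain resummation itself is outside its convergence domain
    R = 0.0 if op.C == 0.0 else noise_multiplier(ctx.dynamics, ctx.variant, ctx.nu, chi)
    G = 0.0 if op.m == 0.0 else cascade_variance(ctx.dynamics, ctx.variant, ctx.nu, chi, op.m)
    if math.isnan(R) or math.isnan(G):
        bad = math.nan
        return OrderParameters(bad, bad, bad)
    V = ctx.alpha * op.r + G
    m_new, c_new = _tanh_moments(beta, ctx.signal_weight * op.m, max(V, 0.0))
    return OrderParameters(m=m_new, C=c_new, r=op.C * R)


def _initial_op(ctx: MeanFieldContext, branch: str,
                chi0: float | None = None) -> OrderParameters | None:
    beta = ctx.beta
    if branch == "trivial":
        return OrderParameters()
    if branch == "retrieval":
        # start at perfect recall, close to the physical (iteration-stable)
        # root; too small a C0 lands in the unstable middle root's outflow
        C0 = max(0.0, min(1.0, 1.0 - (chi0 or _RETRIEVAL_CHI0) * ctx.temperature))
        m0 = 1.0
    elif branch == "spin_glass":
        if chi0 is not None:
            C0 = max(0.0, min(1.0, 1.0 - chi0 * ctx.temperature))
            R0 = noise_multiplier(ctx.dynamics, ctx.variant, ctx.nu, beta * (1.0 - C0))
            if math.isnan(R0):
                return None
            return OrderParameters(m=0.0, C=C0, r=C0 * R0)
        # anchor C at the zero-temperature spin-glass susceptibility
        try:
            chi0 = sg_chi_zero_temperature(ctx.dynamics, ctx.variant, ctx.nu, ctx.alpha)
        except ValueError:
            chi0 = 0.5
        C0 = max(0.0, min(1.0, 1.0 - ctx.temperature * chi0))
        m0 = 0.0
    else:
        raise ValueError(f"unknown branch {branch!r}")
    R0 = noise_multiplier(ctx.dynamics, ctx.variant, ctx.nu, beta * (1.0 - C0))
    if math.isnan(R0):
        return None
    return OrderParameters(m=m0, C=C0, r=C0 * R0)


def solve_branch(ctx: MeanFieldContext, branch: str = "retrieval",
                 tol: float = 1e-10, max_iter: int = 10000,
                 damping: float = 0.5,
                 m_floor: float = 0.01) -> BranchResult:
    """Damped fixed-point iteration from a branch-specific initialization.

    Returns 'no_solution' when the iteration collapses onto the trivial (or,
    for retrieval, the m = 0) branch, and 'diverged' when an iterate leaves
    the convergence domain of the chain sums or becomes non-finite.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if ctx.temperature == 0:
        raise ValueError("solve_branch is the finite-T solver; use the zero-T path")
    if branch == "trivial":
        return BranchResult("converged", OrderParameters(), 0)
    result = None
    for chi0 in (None, 0.05, 0.4):  # None = branch default initialization
        op = _initial_op(ctx, branch, chi0)
        if op is None:
            continue
        result = _iterate(ctx, branch, op, tol, max_iter, damping, m_floor)
        if result.converged:
            return result
    return result if result is not None else BranchResult("diverged")


def _iterate(ctx: MeanFieldContext, branch: str, op: OrderParameters,
             tol: float, max_iter: int, damping: float,
             m_floor: float) -> BranchResult:
    for it in range(1, max_iter + 1):
        new = rhs(ctx, op)
        vec_new, vec_old = new.as_array(), op.as_array()
        if not np.all(np.isfinite(vec_new)):
            return BranchResult("diverged", iterations=it)
        delta = float(np.max(np.abs(vec_new - vec_old)))
        mixed = (1.0 - damping) * vec_old + damping * vec_new
        op = OrderParameters(*mixed)
        log.debug("%s it=%d m=%.6g C=%.6g r=%.6g residual=%.3g",
                  branch, it, op.m, op.C, op.r, delta)
        if delta < tol:
            break
    else:
        return BranchResult("diverged", op, max_iter)
    log.info("%s/%s %s branch: converged in %d iterations (residual %.3g)",
             ctx.dynamics, ctx.variant, branch, it, delta)
    if branch == "retrieval" and abs(op.m) < m_floor:
        return BranchResult("no_solution", op, it)
    if branch == "spin_glass" and (op.C < 1e-8 or op.r < 1e-12):
        return BranchResult("no_solution", op, it)
    return BranchResult("converged", op, it)


# ---------------------------------------------------------------------------
# Spin-glass transition temperature: instability of the trivial solution
# ---------------------------------------------------------------------------

def _sg_condition(dynamics: str, variant: str, nu: float, alpha: float,
                  beta: float) -> float:
    R = noise_multiplier(dynamics, variant, nu, beta)
    if math.isnan(R):
        return math.inf
    return alpha * beta * beta * R - 1.0


def _chi_domain_edge(dynamics: str, variant: str, nu: float) -> float:
    if variant == "one_set":
        return 1.0
    return 1.0 / max(nu, 1.0 - nu, 1e-300)


def spin_glass_temperature(ctx: MeanFieldContext) -> float:
    """T_SG(alpha, nu): where linearizing (C, r) around zero reaches unit gain.

    Expanding the system to first order in (C, r) at m = 0 (so chi -> beta)
    gives the scalar condition alpha beta^2 R(nu, beta) = 1.  Because R
    diverges at the edge of its convergence domain, a root exists for every
    alpha > 0 and nu, i.e. the spin-glass phase always appears at some
    finite temperature.
    """
    if ctx.alpha <= 0:
        raise ValueError("spin-glass temperature requires alpha > 0")
    edge = _chi_domain_edge(ctx.dynamics, ctx.variant, ctx.nu) * (1.0 - 1e-10)
    f = lambda b: _sg_condition(ctx.dynamics, ctx.variant, ctx.nu, ctx.alpha, b)
    lo = 1e-9
    hi = edge
    # f is -1 at beta -> 0 and +inf at the edge; bisect for the first crossing
    while f(hi) < 0:  # pragma: no cover - edge always diverges
        hi *= 0.999999
    beta_g = brentq(f, lo, hi, xtol=1e-14, rtol=1e-15)
    return 1.0 / beta_g


def sg_chi_zero_temperature(dynamics: str, variant: str, nu: float,
                            alpha: float) -> float:
    """Zero-T spin-glass susceptibility chi0, root of chi = sqrt(2/(pi alpha R(chi))).

    At T = 0 the spin-glass branch has C -> 1 with chi = beta (1 - C) finite;
    with m = 0 the zero-T limit of the C equation gives the closed relation
    above, which always has a root: the zero-T spin-glass state exists for
    every alpha > 0 and nu.
    """
    if alpha <= 0:
        raise ValueError("requires alpha > 0")
    target = math.sqrt(2.0 / (math.pi * alpha))

    def g(chi: float) -> float:
        R = noise_multiplier(dynamics, variant, nu, chi)
        if math.isnan(R):
            return math.inf
        return chi * math.sqrt(R) - target

    edge = _chi_domain_edge(dynamics, variant, nu) * (1.0 - 1e-10)
    return brentq(g, 1e-12, edge, xtol=1e-14)


# ---------------------------------------------------------------------------
# Zero-temperature retrieval: reduced scalar equations and capacities
# ---------------------------------------------------------------------------

def zero_t_alpha_of_x(dynamics: str, variant: str, nu: float,
                      x: np.ndarray) -> np.ndarray:
    """Load alpha(x) at which x = s m / sqrt(2 V) solves the zero-T system.

    This is the family of curves whose largest value over x is the storage
    capacity: for alpha below the maximum a retrieval root exists (the
    descending branch, larger x), above it only the trivial solution
    remains.  NaN marks x values outside the theory's domain.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    s_w = nu if dynamics == "AM" else 1.0 - nu
    out = np.full(x.shape, math.nan)
    if s_w == 0.0:
        return out
    m = erf(x)
    V = (s_w * m) ** 2 / (2.0 * x ** 2)
    chi = np.sqrt(2.0 / (math.pi * V)) * np.exp(-x ** 2)
    for i in range(x.size):
        if not np.isfinite(V[i]) or V[i] <= 0:
            continue
        R = noise_multiplier(dynamics, variant, nu, float(chi[i]))
        G = cascade_variance(dynamics, variant, nu, float(chi[i]), float(m[i]))
        if math.isnan(R) or math.isnan(G) or R <= 0:
            continue
        a = (V[i] - G) / R
        if a > 0:
            out[i] = a
    return out


_X_GRID = np.linspace(0.02, 6.0, 2400)


def capacity_zero_temperature(dynamics: str, variant: str, nu: float,
                              x_grid: np.ndarray = _X_GRID) -> float:
    """Largest load alpha_c for which the zero-T system has a nontrivial root."""
    alphas = zero_t_alpha_of_x(dynamics, variant, nu, x_grid)
    if not np.any(np.isfinite(alphas)):
        return 0.0
    i = int(np.nanargmax(alphas))
    # golden-section refinement of the maximum around the grid winner
    lo = x_grid[max(i - 1, 0)]
    hi = x_grid[min(i + 1, x_grid.size - 1)]
    for _ in range(60):
        ml = lo + (hi - lo) / 3.0
        mr = hi - (hi - lo) / 3.0
        fl = zero_t_alpha_of_x(dynamics, variant, nu, np.array([ml]))[0]
        fr = zero_t_alpha_of_x(dynamics, variant, nu, np.array([mr]))[0]
        if not (np.isfinite(fl) and np.isfinite(fr)):
            break
        if fl < fr:
            lo = ml
        else:
            hi = mr
    best = zero_t_alpha_of_x(dynamics, variant, nu,
                             np.array([(lo + hi) / 2.0]))[0]
    return float(max(alphas[i], best if np.isfinite(best) else 0.0))


def retrieval_zero_temperature(dynamics: str, variant: str, nu: float,
                               alpha: float,
                               x_grid: np.ndarray = _X_GRID):
    """Zero-T retrieval overlap m at load alpha, or None beyond capacity.

    Selects the descending (large-x) branch of the alpha(x) family, which is
    the stable retrieval state.
    """
    alphas = zero_t_alpha_of_x(dynamics, variant, nu, x_grid)
    if not np.any(np.isfinite(alphas)):
        return None
    i_max = int(np.nanargmax(alphas))
    if alpha > alphas[i_max]:
        return None
    if alpha <= 0:
        return 1.0
    # on the descending branch alpha(x) decreases with x: bisect for the root
    tail_x, tail_a = x_grid[i_max:], alphas[i_max:]
    finite = np.isfinite(tail_a)
    tail_x, tail_a = tail_x[finite], tail_a[finite]
    below = np.nonzero(tail_a <= alpha)[0]
    if below.size == 0:
        return float(erf(tail_x[-1]))
    j = below[0]
    if j == 0:
        return float(erf(tail_x[0]))
    lo, hi = tail_x[j - 1], tail_x[j]
    f = lambda xx: zero_t_alpha_of_x(dynamics, variant, nu, np.array([xx]))[0] - alpha
    try:
        x_root = brentq(f, lo, hi, xtol=1e-12)
    except ValueError:
        x_root = 0.5 * (lo + hi)
    return float(erf(x_root))


def alpha_hc_zero_temperature(dynamics: str, variant: str, nu: float,
                              theta_hc: float = 0.9,
                              x_grid: np.ndarray = _X_GRID) -> float:
    """Largest load at which the zero-T retrieval state still has m >= theta_hc."""
    alphas = zero_t_alpha_of_x(dynamics, variant, nu, x_grid)
    if not np.any(np.isfinite(alphas)):
        return 0.0
    i_max = int(np.nanargmax(alphas))
    x_theta = float(erfinv(theta_hc))
    if x_grid[i_max] >= x_theta:
        return capacity_zero_temperature(dynamics, variant, nu, x_grid)
    a_theta = zero_t_alpha_of_x(dynamics, variant, nu, np.array([x_theta]))[0]
    return float(a_theta) if np.isfinite(a_theta) else 0.0


# ---------------------------------------------------------------------------
# Finite-temperature critical load
# ---------------------------------------------------------------------------

def _retrieval_m(ctx: MeanFieldContext, m_threshold: float | None) -> float | None:
    res = solve_branch(ctx, "retrieval")
    if not res.converged:
        return None
    if m_threshold is not None and abs(res.op.m) < m_threshold:
        return None
    return res.op.m


def critical_alpha(dynamics: str, variant: str, nu: float, temperature: float,
                   m_threshold: float | None = None, tol: float = 1e-4,
                   alpha_max: float = 1.0) -> float:
    """Bisection in alpha on the existence of the retrieval branch at fixed (T, nu).

    With ``m_threshold`` set, bisects instead on existence of retrieval with
    |m| >= threshold (used for the highly-correlated region boundaries).
    Raises if no bracket exists (retrieval absent already at alpha -> 0).
    """
    if temperature <= 0:
        raise ValueError("critical_alpha requires finite temperature; "
                         "use capacity_zero_temperature at T = 0")
    exists = lambda a: _retrieval_m(
        MeanFieldContext(a, nu, temperature, dynamics, variant), m_threshold) is not None
    lo = 1e-4
    if not exists(lo):
        raise ValueError(f"bracket failure: no retrieval solution at alpha={lo} "
                         f"(T={temperature}, nu={nu}, {dynamics}/{variant})")
    hi = 2 * lo
    while exists(hi):
        hi *= 2.0
        if hi > alpha_max:
            return alpha_max
    lo = hi / 2.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if exists(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
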