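"""Hebbian synaptic matrices: symmetric, sequence (asymmetric), mixed, diluted.

The coupling matrix interpolates between two outer-product constructions,

    J = nu * Xi_sym + (1 - nu) * Xi_asym,        nu in [0, 1],

where the symmetric part stores each pattern as an independent attractor,

    Xi_sym[i, j]  = (1/N) sum_mu  xi[mu, i] * xi[mu, j],

and the asymmetric part projects every pattern onto its successor in the
sequence (index mu + 1 taken modulo P),

    Xi_asym[i, j] = (1/N) sum_mu  xi[(mu+1) % P, i] * xi[mu, j].

nu = 1 is the classical Hopfield model; nu = 0 the asymmetric (sequence
processing) Hopfield model.  In the one-set variant both parts are built
from the same pattern set; in the two-set variant the asymmetric part uses
an independent second set, which is what allows fixed points and a cycle
to coexist in one network.

All builders zero the self-couplings J_ii.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patterns import PatternSet

__all__ = [
    "SynapticMatrix",
    "build_symmetric",
    "build_asymmetric",
    "mix",
    "mixed_matrix",
    "dilute",
    "export_triplets",
]


@dataclass
class SynapticMatrix:
    """N x N coupling matrix plus the metadata needed to reproduce it."""

    weights: np.ndarray
    nu: float
    variant: str = "one_set"          # "one_set" | "two_set"
    in_degree: int | str = "full"
    mask: np.ndarray | None = None    # boolean in-connection indicator

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]


def build_symmetric(pats: PatternSet) -> np.ndarray:
    """Hopfield outer-product part, (1/N) sum_mu xi^mu_i xi^mu_j, zero diagonal."""
    xi = pats.entries.astype(np.float64)
    n = pats.n_neurons
    w = xi.T @ xi / n
    np.fill_diagonal(w, 0.0)
    return w


def build_asymmetric(pats: PatternSet) -> np.ndarray:
    """Sequence part, (1/N) sum_mu xi^(mu+1 mod P)_i xi^mu_j, zero diagonal."""
    xi = pats.entries.astype(np.float64)
    n = pats.n_neurons
    xi_next = np.roll(xi, -1, axis=0)  # row mu holds pattern mu+1 (mod P)
    w = xi_next.T @ xi / n
    np.fill_diagonal(w, 0.0)
    return w


def mix(sym_part: np.ndarray, asym_part: np.ndarray, nu: float,
        variant: str = "one_set") -> SynapticMatrix:
    """nu-weighted combination nu * sym + (1 - nu) * asym."""
    if not 0.0 <= nu <= 1.0:
        raise ValueError("nu must lie in [0, 1]")
    if sym_part.shape != asym_part.shape:
        raise ValueError("symmetric and asymmetric parts must have equal shapes")
    return SynapticMatrix(weights=nu * sym_part + (1.0 - nu) * asym_part,
                          nu=nu, variant=variant)


def mixed_matrix(am_set: PatternSet, nu: float,
                 spr_set: PatternSet | None = None) -> SynapticMatrix:
    """Build the full mixture in one call.

    With ``spr_set=None`` the asymmetric part reuses ``am_set`` (one-set
    model); otherwise it is built from the independent ``spr_set`` (two-set
    model).
    """
    sym = build_symmetric(am_set)
    if spr_set is None:
        return mix(sym, build_asymmetric(am_set), nu, variant="one_set")
    if spr_set.n_neurons != am_set.n_neurons:
        raise ValueError("both pattern sets must have the same number of neurons")
    return mix(sym, build_asymmetric(spr_set), nu, variant="two_set")


def dilute(J: SynapticMatrix, in_degree: int, seed: int = 0) -> SynapticMatrix:
    """Keep exactly ``in_degree`` random incoming weights per neuron.

    Every neuron receives input from in_degree others chosen uniformly
    (self-input excluded); the remaining weights are zeroed and the kept
    ones rescaled by N / in_degree so the mean local field at a stored
    pattern is preserved.  The connection mask is fixed once drawn.
    """
    n = J.n_neurons
    if not 1 <= in_degree < n:
        raise ValueError(f"in_degree must satisfy 1 <= K < N, got {in_degree} for N={n}")
    rng = np.random.default_rng(seed)
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        choices = rng.choice(n - 1, size=in_degree, replace=False)
        choices[choices >= i] += 1  # skip the diagonal
        mask[i, choices] = True
    weights = np.where(mask, J.weights * (n / in_degree), 0.0)
    return SynapticMatrix(weights=weights, nu=J.nu, variant=J.variant,
                          in_degree=in_degree, mask=mask)


def export_triplets(J: SynapticMatrix, path) -> None:
    """Debug dump: one 'i j w' line per nonzero coupling."""
    ii, jj = np.nonzero(J.weights)
    with open(path, "w") as fh:
        fh.write(f"# N={J.n_neurons} nu={J.nu} variant={J.variant} in_degree={J.in_degree}\n")
        for i, j in zip(ii, jj):
            fh.write(f"{i} {j} {J.weights[i, j]:.12g}\n")
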