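"""Reaction-based models (RBMs) and their mass-action ODE right-hand side.

An RBM is a set of N molecular species and M irreversible reactions

    R_i:  sum_j a_ij S_j  --k_i-->  sum_j b_ij S_j

with non-negative integer stoichiometric coefficients collected in the
M x N matrices ``A`` (reactants) and ``B`` (products), and a positive
kinetic constant ``k_i`` per reaction.  Under mass-action kinetics the
species concentrations ``X`` evolve as

    dX/dt = (B - A)^T (K o X^A)

where ``o`` is the Hadamard product and ``(X^A)_i = prod_j x_j^{A_ij}``
is the vector-matrix exponentiation (the flux monomial of reaction i,
before multiplication by ``k_i``).

The module is unit-agnostic: concentrations may be molar amounts or
molecule counts as long as the kinetic constants are expressed in the
matching units for their reaction order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RBM",
    "mass_action_rhs",
    "mass_action_jacobian",
    "validate_rbm",
]


@dataclass
class RBM:
    """A reaction-based model.

    Parameters
    ----------
    species_names : list of str
        N species identifiers.
    A, B : (M, N) arrays of non-negative integers
        Reactant and product stoichiometric matrices.
    K : (M,) array of positive floats
        Kinetic constants, one per reaction, in units consistent with
        each reaction's mass-action order.
    X0 : (N,) array of non-negative floats
        Initial concentrations.
    metadata : dict
        Free-form provenance (e.g. the generator seed).
    """

    species_names: list[str]
    A: np.ndarray
    B: np.ndarray
    K: np.ndarray
    X0: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.K = np.asarray(self.K, dtype=float).ravel()
        self.X0 = np.asarray(self.X0, dtype=float).ravel()

    @property
    def n_species(self) -> int:
        return self.A.shape[1]

    @property
    def n_reactions(self) -> int:
        return self.A.shape[0]

    @property
    def stoichiometry(self) -> np.ndarray:
        """Net stoichiometric change matrix (B - A), shape (M, N)."""
        return self.B - self.A

    def rhs(self, x: np.ndarray, k: np.ndarray | None = None) -> np.ndarray:
        return mass_action_rhs(self, x, k=k)

    def jacobian(self, x: np.ndarray, k: np.ndarray | None = None) -> np.ndarray:
        return mass_action_jacobian(self, x, k=k)

    def __eq__(self, other) -> bool:  # metadata intentionally ignored
        if not isinstance(other, RBM):
            return NotImplemented
        return (
            self.species_names == other.species_names
            and self.A.shape == other.A.shape
            and np.array_equal(self.A, other.A)
            and np.array_equal(self.B, other.B)
            and np.array_equal(self.K, other.K)
            and np.array_equal(self.X0, other.X0)
        )


def _check_state(rbm: RBM, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size != rbm.n_species:
        raise ValueError(
            f"state vector has length {x.size}, model has {rbm.n_species} species"
        )
    return x


def _fluxes(rbm: RBM, x: np.ndarray, k: np.ndarray) -> np.ndarray:
    # (X^A)_i = prod_j x_j^{A_ij}, with 0^0 := 1 so that species absent
    # from a reaction never affect its flux.  Negative transients coming
    # from a solver are raised as-is (no clamping); fractional powers
    # never occur because stoichiometries are integers.
    with np.errstate(divide="ignore", invalid="ignore"):
        pw = np.where(rbm.A == 0.0, 1.0, x[np.newaxis, :] ** rbm.A)
    return k * np.prod(pw, axis=1)


def mass_action_rhs(
    rbm: RBM, x: np.ndarray, k: np.ndarray | None = None
) -> np.ndarray:
    """Evaluate dX/dt = (B - A)^T (K o X^A) at state ``x``.

    ``k`` overrides the model's kinetic constants (used when a batch
    carries per-simulation parameterizations).
    """
    x = _check_state(rbm, x)
    kk = rbm.K if k is None else np.asarray(k, dtype=float).ravel()
    if kk.size != rbm.n_reactions:
        raise ValueError(
            f"kinetic vector has length {kk.size}, model has {rbm.n_reactions} reactions"
        )
    return rbm.stoichiometry.T @ _fluxes(rbm, x, kk)


def mass_action_jacobian(
    rbm: RBM, x: np.ndarray, k: np.ndarray | None = None
) -> np.ndarray:
    """Analytic Jacobian J[p, q] = d(dX_p/dt)/dx_q of the mass-action RHS.

    For reaction i the flux is ``k_i prod_j x_j^{a_ij}``; its derivative
    w.r.t. ``x_q`` is ``k_i a_iq x_q^{a_iq - 1} prod_{j != q} x_j^{a_ij}``
    (zero where ``a_iq`` is zero).
    """
    x = _check_state(rbm, x)
    kk = rbm.K if k is None else np.asarray(k, dtype=float).ravel()
    if kk.size != rbm.n_reactions:
        raise ValueError(
            f"kinetic vector has length {kk.size}, model has {rbm.n_reactions} reactions"
        )
    A = rbm.A
    with np.errstate(divide="ignore", invalid="ignore"):
        pw = np.where(A == 0.0, 1.0, x[np.newaxis, :] ** A)
        # derivative factor per (i, q): a_iq * x_q^(a_iq - 1)
        dpw = np.where(A == 0.0, 0.0, A * x[np.newaxis, :] ** (A - 1.0))
    # dflux[i, q] = k_i * dpw[i, q] * prod_{j != q} pw[i, j]
    M, N = A.shape
    dflux = np.zeros((M, N))
    for q in range(N):
        rest = np.prod(np.delete(pw, q, axis=1), axis=1)
        dflux[:, q] = kk * dpw[:, q] * rest
    return rbm.stoichiometry.T @ dflux


def validate_rbm(rbm: RBM) -> list[str]:
    """Check every RBM invariant; returns human-readable violations.

    An empty list means the model is simulable.  Validation never raises.
    """
    out: list[str] = []
    A, B = rbm.A, rbm.B
    if A.ndim != 2 or B.ndim != 2:
        out.append("A and B must be 2-dimensional matrices")
        return out
    if A.shape != B.shape:
        out.append(f"A has shape {A.shape} but B has shape {B.shape}")
        return out
    M, N = A.shape
    if len(rbm.species_names) != N:
        out.append(
            f"{len(rbm.species_names)} species names for {N} matrix columns"
        )
    for name, mat in (("A", A), ("B", B)):
        if not np.all(np.isfinite(mat)):
            out.append(f"{name} contains non-finite entries")
            continue
        if np.any(mat < 0):
            bad = np.argwhere(mat < 0)[0]
            out.append(
                f"{name}[{bad[0]}, {bad[1]}] = {mat[tuple(bad)]} is negative"
            )
        if np.any(mat != np.round(mat)):
            bad = np.argwhere(mat != np.round(mat))[0]
            out.append(
                f"{name}[{bad[0]}, {bad[1]}] = {mat[tuple(bad)]} is not an integer"
            )
    empty = np.where((np.abs(A).sum(axis=1) + np.abs(B).sum(axis=1)) == 0)[0]
    for i in empty:
        out.append(f"reaction {i} is empty (no reactants and no products)")
    if rbm.K.size != M:
        out.append(f"K has length {rbm.K.size}, expected {M} reactions")
    else:
        for i in np.where(~(rbm.K > 0) | ~np.isfinite(rbm.K))[0]:
            out.append(f"k of reaction {i} is {rbm.K[i]}, must be finite and > 0")
    if rbm.X0.size != N:
        out.append(f"X0 has length {rbm.X0.size}, expected {N} species")
    else:
        for j in np.where(~(rbm.X0 >= 0) | ~np.isfinite(rbm.X0))[0]:
            out.append(f"X0 of species {j} is {rbm.X0[j]}, must be finite and >= 0")
    return out
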