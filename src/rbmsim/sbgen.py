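"""Synthetic reaction-based model generation.

Models are built to mimic the statistical shape of curated biochemical
networks: initial concentrations log-uniform on [1e-4, 1), kinetic
constants log-uniform on [1e-6, 10] (both span several orders of
magnitude, as measured kinetic data do), reactions restricted to zero,
first and second order on the reactant side (at most two reactant
molecules, of the same or different species) and at most two product
molecules.  The resulting stoichiometric matrices are sparse.

A batch of parameterizations of one model is obtained by perturbing
each kinetic constant log-uniformly within +/-25% of its value:

    k' = exp( ln(0.75 k) + (ln(1.25 k) - ln(0.75 k)) * rnd ),
    rnd ~ Uniform[0, 1)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dispatch import ParameterizationSet
from .model import RBM

__all__ = ["SyntheticSpec", "generate_rbm", "perturb_kinetics", "make_batch"]


@dataclass
class SyntheticSpec:
    """Parameters of the random-model generator.

    ``x0_range`` and ``k_range`` are log-uniform sampling bounds.
    ``include_zero_order`` controls whether pure-source reactions
    (empty reactant side) may be emitted.
    """

    N: int
    M: int
    x0_range: tuple[float, float] = (1e-4, 1.0)
    k_range: tuple[float, float] = (1e-6, 10.0)
    max_reactant_order: int = 2
    max_products: int = 2
    include_zero_order: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.N < 1 or self.M < 1:
            raise ValueError("N and M must be >= 1")
        for name, (lo, hi) in (("x0_range", self.x0_range), ("k_range", self.k_range)):
            if not (0 < lo < hi):
                raise ValueError(f"{name} must satisfy 0 < low < high")
        if self.max_reactant_order < 1 or self.max_products < 1:
            raise ValueError("stoichiometry limits must be >= 1")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def generate_rbm(spec: SyntheticSpec) -> RBM:
    """Draw a random RBM with exactly ``spec.N`` species and ``spec.M`` reactions.

    Deterministic given ``spec.seed``; the seed is recorded in the model
    metadata.  Reactant order is drawn uniformly from the allowed orders
    and species are chosen uniformly with replacement (so 2A and A+B
    both occur); duplicate reactions are permitted -- they are
    mathematically benign under mass action.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    N, M = spec.N, spec.M
    A = np.zeros((M, N), dtype=int)
    B = np.zeros((M, N), dtype=int)
    min_order = 0 if spec.include_zero_order else 1
    orders = np.arange(min_order, spec.max_reactant_order + 1)
    for i in range(M):
        while True:
            r_order = int(rng.choice(orders))
            p_count = int(rng.integers(0, spec.max_products + 1))
            if r_order > 0 or p_count > 0:
                break
        row_a = np.zeros(N, dtype=int)
        for _ in range(r_order):
            row_a[rng.integers(0, N)] += 1
        row_b = np.zeros(N, dtype=int)
        for _ in range(p_count):
            row_b[rng.integers(0, N)] += 1
        A[i], B[i] = row_a, row_b
    K = _log_uniform(rng, *spec.k_range, M)
    X0 = _log_uniform(rng, *spec.x0_range, N)
    names = [f"S{j}" for j in range(N)]
    return RBM(
        species_names=names, A=A, B=B, K=K, X0=X0,
        metadata={"generator": "sbgen", "seed": spec.seed},
    )


def perturb_kinetics(K: np.ndarray, rnd: np.ndarray) -> np.ndarray:
    """Log-uniform +/-25% perturbation of each kinetic constant.

    ``rnd`` must lie in [0, 1); the result is in [0.75 K, 1.25 K)
    component-wise.
    """
    K = np.asarray(K, dtype=float)
    rnd = np.asarray(rnd, dtype=float)
    if np.any(K <= 0) or np.any(~np.isfinite(K)):
        raise ValueError("kinetic constants must be positive and finite")
    if np.any(rnd < 0) or np.any(rnd >= 1):
        raise ValueError("rnd values must lie in [0, 1)")
    lo = np.log(K - 0.25 * K)
    hi = np.log(K + 0.25 * K)
    return np.exp(lo + (hi - lo) * rnd)


def make_batch(rbm: RBM, R: int, seed: int = 0) -> ParameterizationSet:
    """Build R parameterizations of ``rbm`` by kinetic perturbation.

    Every row shares the model's initial state; row r applies
    ``perturb_kinetics`` with its own slice of a seeded uniform stream.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    rnd = rng.random((R, rbm.n_reactions))
    K_batch = perturb_kinetics(rbm.K[np.newaxis, :], rnd)
    X0_batch = np.tile(rbm.X0, (R, 1))
    return ParameterizationSet(X0_batch=X0_batch, K_batch=K_batch)
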