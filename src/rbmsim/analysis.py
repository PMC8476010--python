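"""Analysis workflows on top of the batch simulator.

Three workflows commonly run against reaction-based models:

* **PSA-2D** -- bi-dimensional parameter sweep: two quantities (an
  initial concentration or a masked set of kinetic constants) are varied
  on a Cartesian grid, every grid cell is simulated, and a per-trajectory
  summary (e.g. mean oscillation amplitude) is tabulated.
* **Sobol sensitivity analysis** -- Saltelli's sampling design plus the
  Saltelli-2010 first-order and Jansen total-order estimators with
  percentile-bootstrap confidence intervals.
* **Parameter estimation** -- a relative-distance fitness between a
  target time course and a simulated one, exposed as a plain objective
  for any optimizer, plus a seeded differential-evolution reference
  optimizer for recovery experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import differential_evolution
from scipy.stats import qmc

from .dispatch import ParameterizationSet, run_batch
from .integrators import SolverSettings, Status, Trajectory
from .model import RBM

__all__ = [
    "SweepAxis",
    "SobolResult",
    "psa_2d",
    "oscillation_amplitude",
    "saltelli_sample",
    "sobol_indices",
    "sa_output_statistic",
    "fitness_relative_distance",
    "estimate_parameters",
]


# ---------------------------------------------------------------------------
# PSA-2D


@dataclass
class SweepAxis:
    """One axis of a bi-dimensional parameter sweep.

    ``kind`` is ``"x0"`` (vary the initial concentration of species
    ``target``) or ``"k"`` (assign the axis value to every kinetic
    constant selected by the ``target`` index list / boolean mask --
    mirroring sweeps where one scaling parameter sets thousands of
    constants at once).
    """

    kind: str  # "x0" | "k"
    target: object  # species index, or indices/mask of kinetic constants
    bounds: tuple[float, float]
    n_points: int
    scale: str = "linear"  # "linear" | "log"

    def points(self) -> np.ndarray:
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError("axis bounds must satisfy lo < hi")
        if self.n_points < 2:
            raise ValueError("axis needs at least 2 points")
        if self.scale == "log":
            if lo <= 0:
                raise ValueError("log-scaled axis requires positive bounds")
            return np.geomspace(lo, hi, self.n_points)
        if self.scale != "linear":
            raise ValueError(f"unknown scale {self.scale!r}")
        return np.linspace(lo, hi, self.n_points)

    def indices(self, rbm: RBM) -> np.ndarray:
        if self.kind == "x0":
            j = int(self.target)  # type: ignore[arg-type]
            if not 0 <= j < rbm.n_species:
                raise ValueError(f"species index {j} out of range")
            return np.array([j])
        if self.kind == "k":
            tgt = np.asarray(self.target)
            if tgt.dtype == bool:
                if tgt.size != rbm.n_reactions:
                    raise ValueError("kinetic mask length mismatch")
                idx = np.where(tgt)[0]
            else:
                idx = tgt.astype(int).ravel()
            if idx.size == 0 or np.any(idx < 0) or np.any(idx >= rbm.n_reactions):
                raise ValueError("invalid kinetic-constant selection")
            return idx
        raise ValueError(f"unknown axis kind {self.kind!r}")


def sweep_parameterizations(
    rbm: RBM, axis1: SweepAxis, axis2: SweepAxis
) -> tuple[ParameterizationSet, np.ndarray, np.ndarray]:
    """Enumerate the full Cartesian grid of a PSA-2D campaign.

    Returns the flat parameterization set (row-major: axis1 outer,
    axis2 inner) and the two axis point vectors.
    """
    p1, p2 = axis1.points(), axis2.points()
    i1, i2 = axis1.indices(rbm), axis2.indices(rbm)
    R = p1.size * p2.size
    X0 = np.tile(rbm.X0, (R, 1))
    K = np.tile(rbm.K, (R, 1))
    r = 0
    for v1 in p1:
        for v2 in p2:
            for ax, idx, v in ((axis1, i1, v1), (axis2, i2, v2)):
                if ax.kind == "x0":
                    X0[r, idx] = v
                else:
                    K[r, idx] = v  # assignment semantics: the axis IS the value
            r += 1
    return ParameterizationSet(X0_batch=X0, K_batch=K), p1, p2


def psa_2d(
    rbm: RBM,
    axis1: SweepAxis,
    axis2: SweepAxis,
    settings: SolverSettings,
    summary: Callable[[Trajectory], float],
    batch_size: int = 512,
    n_jobs: int = 1,
) -> np.ndarray:
    """Run the Cartesian sweep and summarize each cell.

    Result shape is ``(axis1.n_points, axis2.n_points)``; entry [i, j]
    is ``summary`` applied to the trajectory simulated at
    (axis1 point i, axis2 point j).  Simulations run in batches of
    ``batch_size`` parameterizations.
    """
    params, p1, p2 = sweep_parameterizations(rbm, axis1, axis2)
    values = np.empty(params.n_rows)
    for start in range(0, params.n_rows, batch_size):
        stop = min(start + batch_size, params.n_rows)
        chunk = ParameterizationSet(
            X0_batch=params.X0_batch[start:stop],
            K_batch=None if params.K_batch is None else params.K_batch[start:stop],
        )
        res = run_batch(rbm, chunk, settings, n_jobs=n_jobs)
        for i, traj in enumerate(res.trajectories):
            values[start + i] = summary(traj)
    return values.reshape(p1.size, p2.size)


def oscillation_amplitude(
    traj: Trajectory, species_index: int, transient_fraction: float = 0.5
) -> float:
    """Mean peak-to-trough amplitude of one species' time course.

    The first ``transient_fraction`` of the output grid is discarded;
    strict local maxima/minima of the remaining series are paired
    (each maximum with the following minimum) and the mean difference is
    returned.  Series with fewer than two peaks, or whose total range is
    below ``1e-6 * max(1, global max)``, score 0 (non-oscillating).
    """
    if traj.status != Status.SUCCESS:
        raise ValueError(f"cannot summarize a failed trajectory ({traj.status.value})")
    if not 0 <= transient_fraction < 1:
        raise ValueError("transient_fraction must be in [0, 1)")
    y = traj.states[:, species_index]
    start = int(math.floor(transient_fraction * y.size))
    y = y[start:]
    if y.size < 3:
        return 0.0
    gmax, gmin = float(np.max(y)), float(np.min(y))
    if gmax - gmin < 1e-6 * max(1.0, gmax):
        return 0.0
    interior = y[1:-1]
    is_max = (interior > y[:-2]) & (interior > y[2:])
    is_min = (interior < y[:-2]) & (interior < y[2:])
    idx_max = np.where(is_max)[0] + 1
    idx_min = np.where(is_min)[0] + 1
    if idx_max.size < 2:
        return 0.0
    drops = []
    for im in idx_max:
        following = idx_min[idx_min > im]
        if following.size:
            drops.append(y[im] - y[following[0]])
    if not drops:
        return 0.0
    return float(np.mean(drops))


# ---------------------------------------------------------------------------
# Sobol sensitivity analysis


@dataclass
class SobolResult:
    """First/total-order Sobol indices with bootstrap CI half-widths."""

    S1: np.ndarray
    S1_conf: np.ndarray
    ST: np.ndarray
    ST_conf: np.ndarray
    S2: Optional[np.ndarray] = None
    n_base: int = 0
    n_boot: int = 0
    degenerate: bool = False
    factor_names: list[str] = field(default_factory=list)


def saltelli_rows(D: int, n_base: int, second_order: bool = True) -> int:
    """Design size of the Saltelli scheme: n_base*(2D+2), or n_base*(D+2)."""
    return n_base * (2 * D + 2) if second_order else n_base * (D + 2)


def saltelli_sample(
    bounds: Sequence[tuple[float, float]],
    n_base: int,
    second_order: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Saltelli's extension of the Sobol sequence.

    Draws ``n_base`` points from a scrambled 2D-dimensional Sobol
    sequence, splits them into base matrices A and B, and emits, per
    base point: the A row, the D rows AB_i (A with column i taken from
    B), optionally the D rows BA_i, and the B row.  Each column is then
    scaled into its bounds.  Row count is ``n_base*(2D+2)`` with second
    order, ``n_base*(D+2)`` without.
    """
    D = len(bounds)
    if D < 1:
        raise ValueError("need at least one factor")
    if n_base < 1:
        raise ValueError("n_base must be >= 1")
    for lo, hi in bounds:
        if not lo < hi:
            raise ValueError("factor bounds must satisfy lo < hi")
    sampler = qmc.Sobol(d=2 * D, scramble=True, seed=seed)
    base = sampler.random(n_base)
    A, B = base[:, :D], base[:, D:]
    blocks = []
    for j in range(n_base):
        rows = [A[j]]
        for i in range(D):
            ab = A[j].copy()
            ab[i] = B[j, i]
            rows.append(ab)
        if second_order:
            for i in range(D):
                ba = B[j].copy()
                ba[i] = A[j, i]
                rows.append(ba)
        rows.append(B[j])
        blocks.append(rows)
    unit = np.vstack([r for rows in blocks for r in rows])
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return lo + unit * (hi - lo)


def _unpack_design(Y: np.ndarray, D: int, second_order: bool):
    per = 2 * D + 2 if second_order else D + 2
    n_base = Y.size // per
    Yb = Y.reshape(n_base, per)
    fA = Yb[:, 0]
    fAB = Yb[:, 1 : D + 1]
    fBA = Yb[:, D + 1 : 2 * D + 1] if second_order else None
    fB = Yb[:, -1]
    return fA, fAB, fBA, fB, n_base


def _indices_from(fA, fAB, fBA, fB, second_order: bool):
    V = np.var(np.concatenate([fA, fB]), ddof=0)
    if V == 0:
        D = fAB.shape[1]
        return np.zeros(D), np.zeros(D), None, True
    # Saltelli (2010) first-order, Jansen total-order estimators
    S1 = np.mean(fB[:, None] * (fAB - fA[:, None]), axis=0) / V
    ST = 0.5 * np.mean((fA[:, None] - fAB) ** 2, axis=0) / V
    S2 = None
    if second_order and fBA is not None:
        D = fAB.shape[1]
        S2 = np.full((D, D), np.nan)
        for i in range(D):
            for j in range(i + 1, D):
                Vij = np.mean(fBA[:, i] * fAB[:, j] - fA * fB) / V
                S2[i, j] = S2[j, i] = Vij - S1[i] - S1[j]
    return S1, ST, S2, False


def sobol_indices(
    Y: np.ndarray,
    D: int,
    n_base: int,
    second_order: bool = True,
    n_boot: int = 1000,
    conf_level: float = 0.95,
    seed: int = 0,
    factor_names: Optional[Sequence[str]] = None,
) -> SobolResult:
    """Estimate Sobol indices from outputs ordered as the Saltelli design.

    Confidence half-widths come from a percentile bootstrap over the
    base sample (``n_boot`` resamples, default 95% level).  A
    zero-variance output yields all-zero indices with the ``degenerate``
    flag set.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    per = 2 * D + 2 if second_order else D + 2
    if Y.size != n_base * per:
        raise ValueError(
            f"got {Y.size} outputs, expected n_base*({per}) = {n_base * per}"
        )
    if not np.all(np.isfinite(Y)):
        raise ValueError("model outputs must be finite")
    fA, fAB, fBA, fB, n_base = _unpack_design(Y, D, second_order)
    S1, ST, S2, degenerate = _indices_from(fA, fAB, fBA, fB, second_order)
    if degenerate or n_boot < 2:
        conf = np.zeros(D)
        return SobolResult(
            S1=S1, S1_conf=conf, ST=ST, ST_conf=conf.copy(), S2=S2,
            n_base=n_base, n_boot=0, degenerate=degenerate,
            factor_names=list(factor_names or []),
        )
    rng = np.random.default_rng(seed)
    s1_bs = np.empty((n_boot, D))
    st_bs = np.empty((n_boot, D))
    for b in range(n_boot):
        idx = rng.integers(0, n_base, n_base)
        s1, st, _, deg = _indices_from(
            fA[idx], fAB[idx], None, fB[idx], False
        )
        s1_bs[b] = s1
        st_bs[b] = st
    alpha = (1.0 - conf_level) / 2.0
    q = np.quantile(s1_bs, [alpha, 1 - alpha], axis=0)
    S1_conf = (q[1] - q[0]) / 2.0
    q = np.quantile(st_bs, [alpha, 1 - alpha], axis=0)
    ST_conf = (q[1] - q[0]) / 2.0
    return SobolResult(
        S1=S1, S1_conf=S1_conf, ST=ST, ST_conf=ST_conf, S2=S2,
        n_base=n_base, n_boot=n_boot, degenerate=False,
        factor_names=list(factor_names or []),
    )


def sa_output_statistic(
    traj: Trajectory, species_index: int, reference_value: float
) -> float:
    """Difference between a species' final concentration and a reference."""
    if traj.status != Status.SUCCESS:
        raise ValueError(f"cannot summarize a failed trajectory ({traj.status.value})")
    return float(traj.states[-1, species_index] - reference_value)


# ---------------------------------------------------------------------------
# Parameter estimation


def fitness_relative_distance(
    sim: Trajectory,
    target_times: np.ndarray,
    target_values: np.ndarray,
    species_indices: Optional[Sequence[int]] = None,
    delta: float = 1e-12,
) -> float:
    """Mean relative distance between simulated and target dynamics.

    ``target_values`` has one row per target time and one column per
    target species.  The score is

        mean over points of |sim - target| / max(|target|, delta)

    which is 0 iff the simulation matches the target exactly on the
    grid, and invariant to the ordering of the species.  A failed
    trajectory scores +inf so minimizers penalize it.
    """
    if sim.status != Status.SUCCESS:
        return math.inf
    target_times = np.asarray(target_times, dtype=float).ravel()
    target_values = np.atleast_2d(np.asarray(target_values, dtype=float))
    if target_values.shape[0] != target_times.size:
        raise ValueError("target_values must have one row per target time")
    if not np.all(np.isfinite(target_values)):
        raise ValueError("target values must be finite")
    pos = np.searchsorted(sim.times, target_times)
    pos = np.clip(pos, 0, sim.times.size - 1)
    if not np.allclose(sim.times[pos], target_times, rtol=1e-9, atol=1e-12):
        raise ValueError("target times must be a subset of the simulated times")
    cols = (
        np.arange(target_values.shape[1])
        if species_indices is None
        else np.asarray(species_indices, dtype=int)
    )
    simvals = sim.states[np.ix_(pos, cols)]
    rel = np.abs(simvals - target_values) / np.maximum(np.abs(target_values), delta)
    return float(np.mean(rel))


def rank_kinetic_sensitivity(
    rbm: RBM,
    settings: SolverSettings,
    factor: float = 2.0,
) -> np.ndarray:
    """Rank kinetic constants by their influence on the dynamics.

    Each constant is scaled by ``factor`` in turn and the relative
    distance of the perturbed trajectory from the unperturbed one is
    measured; returns reaction indices sorted from least to most
    influential.  Constants with zero score are structurally or
    practically non-identifiable from this trajectory, so estimation
    experiments should pick their free constants from the top of this
    ranking.
    """
    base = run_batch(
        rbm, ParameterizationSet(X0_batch=rbm.X0[np.newaxis, :]), settings
    ).trajectories[0]
    scores = np.empty(rbm.n_reactions)
    for i in range(rbm.n_reactions):
        k = rbm.K.copy()
        k[i] *= factor
        res = run_batch(
            rbm,
            ParameterizationSet(
                X0_batch=rbm.X0[np.newaxis, :], K_batch=k[np.newaxis, :]
            ),
            settings,
        )
        scores[i] = fitness_relative_distance(
            res.trajectories[0], base.times, base.states
        )
    return np.argsort(scores)


def estimate_parameters(
    rbm: RBM,
    free_indices: Sequence[int],
    bounds: Sequence[tuple[float, float]],
    target_times: np.ndarray,
    target_values: np.ndarray,
    settings: SolverSettings,
    species_indices: Optional[Sequence[int]] = None,
    seed: int = 0,
    maxiter: int = 40,
    popsize: int = 12,
) -> tuple[np.ndarray, float]:
    """Recover selected kinetic constants by minimizing the fitness.

    A seeded differential-evolution search in log10 space over the
    given bounds; returns (estimated constants for the free indices,
    best fitness).  This is a reference optimizer for recovery
    experiments, not a tuned estimation framework.
    """
    free_indices = list(free_indices)
    log_bounds = [(math.log10(lo), math.log10(hi)) for lo, hi in bounds]

    def objective(logk: np.ndarray) -> float:
        k = rbm.K.copy()
        k[free_indices] = 10.0 ** np.asarray(logk)
        params = ParameterizationSet(
            X0_batch=rbm.X0[np.newaxis, :], K_batch=k[np.newaxis, :]
        )
        res = run_batch(rbm, params, settings)
        return fitness_relative_distance(
            res.trajectories[0], target_times, target_values, species_indices
        )

    out = differential_evolution(
        objective,
        log_bounds,
        seed=seed,
        maxiter=maxiter,
        popsize=popsize,
        tol=1e-8,
        polish=True,
    )
    return 10.0**out.x, float(out.fun)
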