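"""Plain-text model-folder I/O (BioSimWare-style dialect) and dynamics output.

The normative on-disk dialect of this package is a folder of
whitespace-separated numeric text files, compatible in naming with the
cupSODA family of simulators:

    left_side    M rows x N columns: reactant stoichiometric matrix A
    right_side   M rows x N columns: product stoichiometric matrix B
    c_vector     M lines, one kinetic constant per line
    M_0          one row of N initial concentrations
    MX_0         optional, R rows of N initial concentrations (a batch)
    c_matrix     optional, R rows of M per-simulation kinetic constants
    t_vector     optional, one output time per line, strictly increasing
    cs_vector    optional, 0-based indices of the species to save,
                 one per line (absent -> all species saved)
    alphabet     optional, one line of whitespace-separated species names

Files are UTF-8, '.' decimal point, scientific notation accepted, blank
lines ignored.  ``left_side``, ``right_side``, ``c_vector`` and ``M_0``
are mandatory.  All indices are 0-based, on disk and in memory.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .dispatch import BatchResult, ParameterizationSet
from .model import RBM, validate_rbm

__all__ = [
    "ModelFolder",
    "read_biosimware",
    "write_biosimware",
    "write_dynamics",
    "ModelIOError",
]

MANDATORY = ("left_side", "right_side", "c_vector", "M_0")
OPTIONAL = ("MX_0", "c_matrix", "t_vector", "cs_vector", "alphabet")


class ModelIOError(RuntimeError):
    """Raised on missing files or dimension-inconsistent model folders."""


@dataclass
class ModelFolder:
    """Parsed contents of a model folder."""

    path: Path
    rbm: RBM
    params: ParameterizationSet
    t_out: Optional[np.ndarray]
    species_to_save: Optional[np.ndarray]


def _read_matrix(path: Path) -> np.ndarray:
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            rows.append([float(tok) for tok in line.split()])
        except ValueError as exc:
            raise ModelIOError(f"{path.name}, line {ln}: {exc}") from None
    if not rows:
        raise ModelIOError(f"{path.name} is empty")
    width = len(rows[0])
    for ln, row in enumerate(rows, start=1):
        if len(row) != width:
            raise ModelIOError(
                f"{path.name}, line {ln}: expected {width} values, got {len(row)}"
            )
    return np.array(rows)


def read_biosimware(folder: os.PathLike | str):
    """Read a model folder.

    Returns ``(rbm, params, t_out, species_to_save)``; ``t_out`` and
    ``species_to_save`` are None when the optional files are absent.
    The batch defaults to the single parameterization given by ``M_0``
    (and per-row kinetics from ``c_matrix`` when present).
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise ModelIOError(f"model folder not found: {folder}")
    for name in MANDATORY:
        if not (folder / name).is_file():
            raise ModelIOError(f"mandatory file missing from {folder}: {name}")

    A = _read_matrix(folder / "left_side")
    B = _read_matrix(folder / "right_side")
    K = _read_matrix(folder / "c_vector").ravel()
    X0 = _read_matrix(folder / "M_0").ravel()
    if A.shape != B.shape:
        raise ModelIOError(
            f"left_side is {A.shape[0]}x{A.shape[1]} but right_side is "
            f"{B.shape[0]}x{B.shape[1]}"
        )
    M, N = A.shape
    if K.size != M:
        raise ModelIOError(f"c_vector has {K.size} entries, expected {M} reactions")
    if X0.size != N:
        raise ModelIOError(f"M_0 has {X0.size} entries, expected {N} species")

    names = [f"S{j}" for j in range(N)]
    if (folder / "alphabet").is_file():
        toks = (folder / "alphabet").read_text().split()
        if len(toks) != N:
            raise ModelIOError(f"alphabet has {len(toks)} names, expected {N}")
        names = toks

    rbm = RBM(species_names=names, A=A, B=B, K=K, X0=X0,
              metadata={"source": str(folder)})
    problems = validate_rbm(rbm)
    if problems:
        raise ModelIOError(f"{folder}: " + "; ".join(problems))

    X0_batch = X0[np.newaxis, :]
    if (folder / "MX_0").is_file():
        X0_batch = np.atleast_2d(_read_matrix(folder / "MX_0"))
        if X0_batch.shape[1] != N:
            raise ModelIOError(
                f"MX_0 has {X0_batch.shape[1]} columns, expected {N}"
            )
    K_batch = None
    if (folder / "c_matrix").is_file():
        K_batch = np.atleast_2d(_read_matrix(folder / "c_matrix"))
        if K_batch.shape[1] != M:
            raise ModelIOError(
                f"c_matrix has {K_batch.shape[1]} columns, expected {M}"
            )
        if K_batch.shape[0] != X0_batch.shape[0]:
            if X0_batch.shape[0] == 1:
                X0_batch = np.tile(X0, (K_batch.shape[0], 1))
            else:
                raise ModelIOError(
                    f"c_matrix has {K_batch.shape[0]} rows but MX_0 has "
                    f"{X0_batch.shape[0]}"
                )
    params = ParameterizationSet(X0_batch=X0_batch, K_batch=K_batch)

    t_out = None
    if (folder / "t_vector").is_file():
        t_out = _read_matrix(folder / "t_vector").ravel()
        if t_out.size > 1 and not np.all(np.diff(t_out) > 0):
            raise ModelIOError("t_vector must be strictly increasing")
    species_to_save = None
    if (folder / "cs_vector").is_file():
        species_to_save = _read_matrix(folder / "cs_vector").ravel().astype(int)
        if np.any(species_to_save < 0) or np.any(species_to_save >= N):
            raise ModelIOError("cs_vector index out of range")
    return rbm, params, t_out, species_to_save


def _fmt(v: float) -> str:
    return f"{v:.17g}"


def write_biosimware(
    rbm: RBM,
    params: Optional[ParameterizationSet],
    folder: os.PathLike | str,
    t_out: Optional[np.ndarray] = None,
    species_to_save: Optional[Sequence[int]] = None,
) -> None:
    """Write a model (and optional batch) in the folder dialect above."""
    problems = validate_rbm(rbm)
    if problems:
        raise ValueError("refusing to write invalid model: " + "; ".join(problems))
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)

    def _write_mat(name: str, mat: np.ndarray, as_int: bool = False) -> None:
        lines = []
        for row in np.atleast_2d(mat):
            if as_int:
                lines.append("\t".join(str(int(v)) for v in row))
            else:
                lines.append("\t".join(_fmt(v) for v in row))
        (folder / name).write_text("\n".join(lines) + "\n")

    _write_mat("left_side", rbm.A, as_int=True)
    _write_mat("right_side", rbm.B, as_int=True)
    (folder / "c_vector").write_text("\n".join(_fmt(k) for k in rbm.K) + "\n")
    _write_mat("M_0", rbm.X0[np.newaxis, :])
    (folder / "alphabet").write_text(" ".join(rbm.species_names) + "\n")
    if params is not None:
        if params.n_rows > 1 or not np.array_equal(params.X0_batch[0], rbm.X0):
            _write_mat("MX_0", params.X0_batch)
        if params.K_batch is not None:
            _write_mat("c_matrix", params.K_batch)
    if t_out is not None:
        (folder / "t_vector").write_text(
            "\n".join(_fmt(t) for t in np.asarray(t_out).ravel()) + "\n"
        )
    if species_to_save is not None:
        (folder / "cs_vector").write_text(
            "\n".join(str(int(i)) for i in species_to_save) + "\n"
        )


def write_dynamics(
    result: BatchResult,
    species_names: Sequence[str],
    folder: os.PathLike | str,
    species_to_save: Optional[Sequence[int]] = None,
) -> None:
    """Write one dynamics TSV per simulation plus a batch summary.

    Each ``simulation_<r>.tsv`` has a ``time`` column followed by one
    column per saved species (header = species names).  An empty or
    absent ``species_to_save`` saves every species.  ``summary.tsv``
    records per-row status, solver and dominant-eigenvalue estimate.
    """
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    idx = (
        [int(j) for j in species_to_save]
        if species_to_save is not None and len(species_to_save) > 0
        else list(range(len(species_names)))
    )
    header = "time\t" + "\t".join(species_names[j] for j in idx)
    for r, traj in enumerate(result.trajectories):
        lines = [header]
        for i, t in enumerate(traj.times):
            vals = "\t".join(_fmt(traj.states[i, j]) for j in idx)
            lines.append(f"{_fmt(t)}\t{vals}")
        (folder / f"simulation_{r}.tsv").write_text("\n".join(lines) + "\n")
    lines = ["row\tstatus\tsolver\tclassification\tfallback\trho"]
    for r, traj in enumerate(result.trajectories):
        lines.append(
            f"{r}\t{traj.status.value}\t{traj.solver_used}\t"
            f"{result.classification[r]}\t{int(result.fallback_mask[r])}\t"
            f"{_fmt(result.rho[r]) if np.isfinite(result.rho[r]) else 'nan'}"
        )
    (folder / "summary.tsv").write_text("\n".join(lines) + "\n")


def read_dynamics(path: os.PathLike | str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read back one dynamics TSV: (times, states, species_names)."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split("\t")
    data = np.array([[float(v) for v in ln.split("\t")] for ln in lines[1:]])
    return data[:, 0], data[:, 1:], header[1:]
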