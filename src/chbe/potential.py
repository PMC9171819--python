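"""Pairwise 12-6 and 12-6-4 Lennard-Jones + Coulomb nonbonded potentials.

The 12-6 form is

    U(r) = A_ij/r^12 - B_ij/r^6 + k_e q_i q_j / r

and the 12-6-4 form adds an attractive ion-induced-dipole term,

    U(r) = A_ij/r^12 - B_ij/r^6 - C_ij/r^4 + k_e q_i q_j / r,

where the pairwise ``C_ij`` coefficient (kcal mol^-1 A^4) is the quantity
the chelator-based parameterization in :mod:`chbe.cijfit` solves for.  This
module is a plain analytic evaluator: energies, forces, minimum location,
Lorentz-Berthelot combination from per-atom-type parameters, and CSV /
plain-text round-tripping of parameter tables.  No cutoffs or switching
functions are applied here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import COULOMB_KCAL

__all__ = [
    "PairPotentialParams",
    "AtomTypeParams",
    "energy_12_6",
    "energy_12_6_4",
    "force_12_6_4",
    "minimum_location",
    "pair_from_atom_types",
    "read_atom_types_csv",
    "write_atom_types_csv",
    "read_c4_table_csv",
    "format_c4_block",
]


@dataclass(frozen=True)
class PairPotentialParams:
    """Nonbonded parameters for one atom-type pair.

    Attributes
    ----------
    a_ij : float
        Repulsion coefficient, kcal mol^-1 A^12.
    b_ij : float
        Dispersion coefficient, kcal mol^-1 A^6.
    c_ij : float
        Ion-induced-dipole coefficient, kcal mol^-1 A^4.  Must be
        non-negative: a negative C_ij has no physical interpretation.
    q_i, q_j : float
        Partial charges, elementary-charge units.
    coulomb_constant : float
        e^2 conversion factor, kcal mol^-1 A e^-2.
    """

    a_ij: float
    b_ij: float
    c_ij: float = 0.0
    q_i: float = 0.0
    q_j: float = 0.0
    coulomb_constant: float = COULOMB_KCAL

    def __post_init__(self) -> None:
        if self.a_ij < 0 or self.b_ij < 0 or self.c_ij < 0:
            raise ValueError(
                "a_ij, b_ij and c_ij must be non-negative "
                f"(got a={self.a_ij}, b={self.b_ij}, c={self.c_ij})"
            )


@dataclass(frozen=True)
class AtomTypeParams:
    """Per-atom-type Lennard-Jones parameters in the r_min/epsilon convention.

    ``c4_overrides`` maps a partner atom-type label to a pairwise C_ij
    (kcal mol^-1 A^4); pairs absent from the table get C_ij = 0.  C_ij is
    never combined from per-atom values -- pair specificity is the point.
    """

    name: str
    r_min_half: float
    epsilon: float
    charge: float = 0.0
    c4_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0 (got {self.epsilon})")
        if self.r_min_half <= 0:
            raise ValueError(f"r_min_half must be > 0 (got {self.r_min_half})")


def _check_r(r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance r must be positive")
    return r


def energy_12_6(r, p: PairPotentialParams):
    """12-6 Lennard-Jones + Coulomb energy at separation ``r`` (A), kcal/mol."""
    r = _check_r(r)
    out = (
        p.a_ij / r**12
        - p.b_ij / r**6
        + p.coulomb_constant * p.q_i * p.q_j / r
    )
    return float(out) if out.ndim == 0 else out


def energy_12_6_4(r, p: PairPotentialParams):
    """12-6-4 Lennard-Jones + Coulomb energy at separation ``r`` (A), kcal/mol.

    Identical to :func:`energy_12_6` minus ``c_ij / r**4``; with
    ``c_ij == 0`` the two agree bitwise.
    """
    r = _check_r(r)
    out = energy_12_6(r, p) - p.c_ij / r**4
    return float(out) if np.ndim(out) == 0 else out


def force_12_6_4(r, p: PairPotentialParams):
    """Radial force -dU/dr of the 12-6-4 potential, kcal mol^-1 A^-1.

    Positive values push the pair apart.
    """
    r = _check_r(r)
    out = (
        12 * p.a_ij / r**13
        - 6 * p.b_ij / r**7
        - 4 * p.c_ij / r**5
        + p.coulomb_constant * p.q_i * p.q_j / r**2
    )
    return float(out) if out.ndim == 0 else out


def minimum_location(p: PairPotentialParams, r_lo: float = 0.05, r_hi: float = 50.0) -> float:
    """Location (A) of the interior minimum of the 12-6-4 energy.

    Solves ``force = 0`` by bracketed root finding.  For a purely repulsive
    or monotone potential no interior minimum exists and a ``ValueError``
    is raised.
    """
    grid = np.geomspace(r_lo, r_hi, 4096)
    f = force_12_6_4(grid, p)
    # minimum = force crossing from + (repulsive core) to - (attractive tail)
    sign_change = np.nonzero((f[:-1] > 0) & (f[1:] <= 0))[0]
    if sign_change.size == 0:
        raise ValueError("potential has no interior minimum in the search range")
    i = sign_change[0]
    return float(brentq(lambda r: force_12_6_4(r, p), grid[i], grid[i + 1]))


def pair_from_atom_types(i: AtomTypeParams, j: AtomTypeParams) -> PairPotentialParams:
    """Combine two atom types into pair parameters (Lorentz-Berthelot).

    eps_ij is the geometric mean of the epsilons and R_min,ij the sum of
    the r_min_half values; then A = eps*R^12, B = 2*eps*R^6.  The pairwise
    C_ij is looked up in either atom type's override table (0 if absent).
    """
    eps = math.sqrt(i.epsilon * j.epsilon)
    r_min = i.r_min_half + j.r_min_half
    c4 = i.c4_overrides.get(j.name, j.c4_overrides.get(i.name, 0.0))
    return PairPotentialParams(
        a_ij=eps * r_min**12,
        b_ij=2 * eps * r_min**6,
        c_ij=c4,
        q_i=i.charge,
        q_j=j.charge,
    )


# ---------------------------------------------------------------------------
# parameter-table I/O


def read_atom_types_csv(path: str | Path) -> dict[str, AtomTypeParams]:
    """Read an atom-type table with columns atom_type, r_min_half, epsilon, charge."""
    df = pd.read_csv(path)
    required = {"atom_type", "r_min_half", "epsilon", "charge"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"atom-type table missing columns: {sorted(missing)}")
    return {
        str(row.atom_type): AtomTypeParams(
            name=str(row.atom_type),
            r_min_half=float(row.r_min_half),
            epsilon=float(row.epsilon),
            charge=float(row.charge),
        )
        for row in df.itertuples()
    }


def write_atom_types_csv(types: Iterable[AtomTypeParams], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "atom_type": t.name,
                "r_min_half": t.r_min_half,
                "epsilon": t.epsilon,
                "charge": t.charge,
            }
            for t in types
        ]
    ).to_csv(path, index=False)


def read_c4_table_csv(path: str | Path) -> dict[tuple[str, str], float]:
    """Read pairwise C_ij values from a CSV with columns ion, atom_type, c_ij."""
    df = pd.read_csv(path)
    required = {"ion", "atom_type", "c_ij"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"C4 table missing columns: {sorted(missing)}")
    return {
        (str(row.ion), str(row.atom_type)): float(row.c_ij) for row in df.itertuples()
    }


def format_c4_block(c4_table: Mapping[tuple[str, str], float]) -> str:
    """Format ion/atom-type C_ij triples as a plain-text block.

    One ``ion atom_type c_ij`` triple per line, suitable for pasting into
    MD-engine C4-amendment workflows.
    """
    lines = [
        f"{ion} {atom_type} {c4:.4f}"
        for (ion, atom_type), c4 in sorted(c4_table.items())
    ]
    return "\n".join(lines) + "\n"
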