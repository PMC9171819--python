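"""Chelator-based fitting of pairwise C_ij coefficients.

The method: simulated chelator-metal binding free energies respond linearly
to the ligating-atom C_ij coefficients of the 12-6-4 potential, so for a
reference chelator (EDTA) with ligating-oxygen and tertiary-nitrogen
gradients m(O), m(N),

    dG_sim(C_O, C_N) = dG'(0,0) + m(O)*C_O + m(N)*C_N.

Directly simulated zero-C_ij binding energies are unreliable for some
metal/chelator pairs, so the zero-C_ij reference dG'(0,0) is instead
back-extrapolated from the binding energy at the default C_ij values.  A
second chelator (NTA) is brought in not through its own (sometimes
unphysical) gradients but by (a) scaling the reference dG'(0,0) by the
ratio of the experimental binding energies and (b) scaling the reference
gradients by denticity ratios -- the ratio of ligating oxygens (3/4) and
nitrogens (1/2) the second chelator offers relative to the first.  Setting
both predicted binding energies equal to experiment gives a 2x2 linear
system whose solution is the pair (C_O, C_N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TIObservation",
    "GradientSet",
    "DenticityRatios",
    "ChBESolution",
    "DegenerateDesignError",
    "MixedDesignError",
    "SingularSystemError",
    "fit_gradient",
    "build_gradient_set",
    "back_extrapolate_zero",
    "scale_reference_zero",
    "predict_dg",
    "solve_cij",
    "solve_cij_direct",
    "solve_cij_lstsq",
    "contour_line",
    "read_observations",
    "load_ti_summary",
    "load_cij_reference",
    "reference_gradient_set",
    "solve_reference",
    "solutions_to_frame",
    "METALS",
    "DEFAULT_RATIOS",
]

#: Metals covered by the packaged chelator TI summary.
METALS = ("Ca2+", "Mg2+", "Y3+", "La3+")

#: Determinant magnitude below which the 2x2 system is treated as singular.
SINGULAR_DET = 1e-10


class DegenerateDesignError(ValueError):
    """All observations share the same value of the varied coordinate."""


class MixedDesignError(ValueError):
    """Both C_ij coordinates vary across the observations."""


class SingularSystemError(ValueError):
    """The two-chelator system has (near-)proportional rows."""


@dataclass(frozen=True)
class TIObservation:
    """One simulated binding free energy at a given (C_O, C_N) setting."""

    chelator: str
    metal: str
    c_o: float
    c_n: float
    dg_sim: float

    def __post_init__(self) -> None:
        if self.c_o < 0 or self.c_n < 0:
            raise ValueError("C_ij values must be non-negative")


@dataclass(frozen=True)
class GradientSet:
    """Linear model of dG_sim vs (C_O, C_N) for one chelator-metal pair.

    ``dg_zero`` is the model's zero-C_ij intercept; when built by
    back-extrapolation it satisfies
    ``dg_zero == dg_default - m_o*c_o_default - m_n*c_n_default``.
    """

    chelator: str
    metal: str
    m_o: float
    m_n: float
    dg_default: float
    c_o_default: float
    c_n_default: float
    dg_zero: float

    @classmethod
    def from_back_extrapolation(
        cls,
        chelator: str,
        metal: str,
        m_o: float,
        m_n: float,
        dg_default: float,
        c_o_default: float,
        c_n_default: float,
    ) -> "GradientSet":
        dg_zero = dg_default - m_o * c_o_default - m_n * c_n_default
        return cls(chelator, metal, m_o, m_n, dg_default, c_o_default, c_n_default, dg_zero)


@dataclass(frozen=True)
class DenticityRatios:
    """Ligating-atom count ratios of the second chelator to the reference.

    Defaults (3/4 for oxygen, 1/2 for nitrogen) are the NTA:EDTA ratios of
    maximum ligating oxygens and tertiary nitrogens.
    """

    rho_o: float = 0.75
    rho_n: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.rho_o <= 1 and 0 < self.rho_n <= 1):
            raise ValueError("denticity ratios must lie in (0, 1]")


DEFAULT_RATIOS = DenticityRatios()


@dataclass(frozen=True)
class ChBESolution:
    """Solved chelator-based (C_O, C_N) pair with diagnostics."""

    metal: str
    c_o: float
    c_n: float
    physical: bool
    residuals: tuple[float, ...]
    condition_diag: float


# ---------------------------------------------------------------------------
# gradient fitting


def fit_gradient(
    observations: Sequence[TIObservation],
    anchor: tuple[float, float] | None = None,
) -> float:
    """Least-squares slope of dG_sim against the single varied C_ij.

    Exactly one of the two C_ij coordinates must vary across the
    observations; the other is expected to sit at its default.  The fit has
    a free intercept unless ``anchor=(c_value, dg_value)`` is given, in
    which case the line is constrained through that point.
    """
    if len(observations) < 2:
        raise ValueError("need at least two observations to fit a gradient")
    c_o = np.array([o.c_o for o in observations])
    c_n = np.array([o.c_n for o in observations])
    y = np.array([o.dg_sim for o in observations])
    o_varies = np.unique(c_o).size > 1
    n_varies = np.unique(c_n).size > 1
    if o_varies and n_varies:
        raise MixedDesignError("both C_ij(O) and C_ij(N) vary across observations")
    if not (o_varies or n_varies):
        raise DegenerateDesignError("varied C_ij coordinate is constant")
    x = c_o if o_varies else c_n
    if anchor is not None:
        x0, y0 = anchor
        dx = x - x0
        return float(np.dot(dx, y - y0) / np.dot(dx, dx))
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def build_gradient_set(
    observations: Sequence[TIObservation],
    c_o_default: float,
    c_n_default: float,
) -> GradientSet:
    """Fit m(O) and m(N) from a two-scan design and back-extrapolate.

    The design must contain an oxygen scan (C_N held at default) and a
    nitrogen scan (C_O held at default); the binding energy at the default
    point is the mean over observations sitting at the defaults.
    """
    if not observations:
        raise ValueError("no observations")
    chelators = {o.chelator for o in observations}
    metals = {o.metal for o in observations}
    if len(chelators) != 1 or len(metals) != 1:
        raise ValueError("observations must come from a single chelator-metal pair")
    o_scan = [o for o in observations if o.c_n == c_n_default]
    n_scan = [o for o in observations if o.c_o == c_o_default]
    m_o = fit_gradient(o_scan)
    m_n = fit_gradient(n_scan)
    at_default = [o.dg_sim for o in observations
                  if o.c_o == c_o_default and o.c_n == c_n_default]
    if not at_default:
        raise ValueError("design contains no observation at the default C_ij point")
    return GradientSet.from_back_extrapolation(
        chelator=chelators.pop(),
        metal=metals.pop(),
        m_o=m_o,
        m_n=m_n,
        dg_default=float(np.mean(at_default)),
        c_o_default=c_o_default,
        c_n_default=c_n_default,
    )


# ---------------------------------------------------------------------------
# the extrapolate / scale / solve pipeline


def back_extrapolate_zero(g: GradientSet) -> float:
    """Zero-C_ij binding energy extrapolated down the fitted gradients.

    Returns ``dg_default - m_o*c_o_default - m_n*c_n_default`` (kJ/mol).
    """
    return g.dg_default - g.m_o * g.c_o_default - g.m_n * g.c_n_default


def scale_reference_zero(
    dg_zero_ref: float, dg_exp_ref: float, dg_exp_other: float
) -> float:
    """Transfer the reference zero-C_ij energy to another chelator.

    Scales by the ratio of the experimental binding energies so that the
    zero-C_ij references follow the experimental affinity trend.
    """
    if dg_exp_ref == 0:
        raise ZeroDivisionError("reference experimental dG must be nonzero")
    return dg_zero_ref * (dg_exp_other / dg_exp_ref)


def predict_dg(g: GradientSet, c_o: float, c_n: float) -> float:
    """Linear-model binding energy at (c_o, c_n), kJ/mol."""
    return g.dg_zero + g.m_o * c_o + g.m_n * c_n


def _solve_2x2(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
    if abs(det) < SINGULAR_DET:
        raise SingularSystemError(
            f"system determinant {det:.3e} below {SINGULAR_DET:.0e}; "
            "gradient rows are (near-)proportional"
        )
    return np.linalg.solve(a, b), abs(det)


def solve_cij(
    g_ref: GradientSet,
    dg_exp_ref: float,
    dg_exp_other: float,
    ratios: DenticityRatios = DEFAULT_RATIOS,
) -> ChBESolution:
    """Solve the denticity-scaled two-chelator system for (C_O, C_N).

    The reference chelator's equation uses its own gradients and
    back-extrapolated zero reference (carried at full precision); the
    second chelator's equation uses the experimentally scaled zero
    reference and the denticity-scaled gradients:

        dg_exp_ref   = z + m_o*C_O + m_n*C_N
        dg_exp_other = z*(dg_exp_other/dg_exp_ref)
                       + rho_o*m_o*C_O + rho_n*m_n*C_N

    A solution with a negative coefficient is returned flagged
    ``physical=False`` rather than raised: negative C_ij is not physically
    realistic and signals that the inputs (often a second chelator's own
    gradients) cannot support the linear model.
    """
    z = back_extrapolate_zero(g_ref)
    z_other = scale_reference_zero(z, dg_exp_ref, dg_exp_other)
    a = np.array(
        [
            [g_ref.m_o, g_ref.m_n],
            [ratios.rho_o * g_ref.m_o, ratios.rho_n * g_ref.m_n],
        ]
    )
    b = np.array([dg_exp_ref - z, dg_exp_other - z_other])
    x, det = _solve_2x2(a, b)
    resid = tuple(float(r) for r in (a @ x - b))
    return ChBESolution(
        metal=g_ref.metal,
        c_o=float(x[0]),
        c_n=float(x[1]),
        physical=bool(x[0] >= 0 and x[1] >= 0),
        residuals=resid,
        condition_diag=det,
    )


def solve_cij_direct(
    g_a: GradientSet,
    g_b: GradientSet,
    dg_exp_a: float,
    dg_exp_b: float,
) -> ChBESolution:
    """Solve using two chelators' own gradients and zero references.

    This is the naive route the ratio-based scheme replaces: each chelator
    contributes its own equation ``dg_exp = dg_zero + m_o*C_O + m_n*C_N``.
    With unreliable second-chelator zero references or positive m(N) values
    it typically yields a non-physical (negative) coefficient, which is
    returned flagged.
    """
    if g_a.metal != g_b.metal:
        raise ValueError("chelators must target the same metal")
    a = np.array([[g_a.m_o, g_a.m_n], [g_b.m_o, g_b.m_n]])
    b = np.array([dg_exp_a - g_a.dg_zero, dg_exp_b - g_b.dg_zero])
    x, det = _solve_2x2(a, b)
    resid = tuple(float(r) for r in (a @ x - b))
    return ChBESolution(
        metal=g_a.metal,
        c_o=float(x[0]),
        c_n=float(x[1]),
        physical=bool(x[0] >= 0 and x[1] >= 0),
        residuals=resid,
        condition_diag=det,
    )


def solve_cij_lstsq(
    g_ref: GradientSet,
    dg_exp_ref: float,
    others: Sequence[tuple[float, DenticityRatios]],
) -> ChBESolution:
    """Over-determined (>= 3 chelator) least-squares extension.

    Each entry of ``others`` is ``(dg_exp, ratios)`` for one additional
    chelator sharing the reference gradients through its denticity ratios.
    This generalizes the exactly determined two-chelator scheme and is an
    extrapolation beyond it: residuals are generally nonzero.
    """
    if not others:
        raise ValueError("need at least one non-reference chelator")
    z = back_extrapolate_zero(g_ref)
    rows = [[g_ref.m_o, g_ref.m_n]]
    rhs = [dg_exp_ref - z]
    for dg_exp, ratios in others:
        rows.append([ratios.rho_o * g_ref.m_o, ratios.rho_n * g_ref.m_n])
        rhs.append(dg_exp - scale_reference_zero(z, dg_exp_ref, dg_exp))
    a = np.array(rows)
    b = np.array(rhs)
    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    resid = tuple(float(r) for r in (a @ x - b))
    gram_det = float(abs(np.linalg.det(a.T @ a)))
    return ChBESolution(
        metal=g_ref.metal,
        c_o=float(x[0]),
        c_n=float(x[1]),
        physical=bool(x[0] >= 0 and x[1] >= 0),
        residuals=resid,
        condition_diag=gram_det,
    )


def contour_line(
    g: GradientSet, dg_target: float, c_o_grid: Sequence[float]
) -> list[tuple[float, float]]:
    """Iso-binding-energy contour of the linear model in the (C_O, C_N) plane.

    For each grid C_O returns the C_N for which ``predict_dg`` equals
    ``dg_target``.
    """
    if g.m_n == 0:
        raise ValueError("m(N) = 0: contour is degenerate (vertical lines)")
    return [
        (float(c_o), float((dg_target - g.dg_zero - g.m_o * c_o) / g.m_n))
        for c_o in c_o_grid
    ]


# ---------------------------------------------------------------------------
# tabular I/O and packaged reference data


def read_observations(path: str | Path) -> list[TIObservation]:
    """Read TI observations from CSV/JSON (columns chelator, metal, c_o, c_n, dg_sim)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.read_json(path)
    else:
        df = pd.read_csv(path)
    required = {"chelator", "metal", "c_o", "c_n", "dg_sim"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    return [
        TIObservation(
            chelator=str(r.chelator),
            metal=str(r.metal),
            c_o=float(r.c_o),
            c_n=float(r.c_n),
            dg_sim=float(r.dg_sim),
        )
        for r in df.itertuples()
    ]


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("chbe.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_ti_summary() -> pd.DataFrame:
    """Published chelator TI summary: experimental and simulated binding
    energies (kJ/mol) and fitted gradients for EDTA and NTA across the four
    metals."""
    return _load_packaged("chelator_ti_summary.csv")


def load_cij_reference() -> pd.DataFrame:
    """Published default and chelator-derived C_ij coefficients
    (kcal mol^-1 A^4) for ligating oxygen and nitrogen."""
    return _load_packaged("cij_reference.csv")


def reference_gradient_set(metal: str, chelator: str = "EDTA") -> GradientSet:
    """GradientSet for one metal from the packaged summary tables.

    For the reference chelator (EDTA) ``dg_zero`` is back-extrapolated; the
    directly simulated zero-C_ij value is used for other chelators, whose
    back-extrapolation the method deliberately avoids.
    """
    summary = load_ti_summary()
    cij = load_cij_reference()
    row = summary[(summary.metal == metal) & (summary.chelator == chelator)]
    crow = cij[cij.metal == metal]
    if row.empty or crow.empty:
        raise KeyError(f"no packaged data for metal {metal!r} / chelator {chelator!r}")
    row = row.iloc[0]
    crow = crow.iloc[0]
    if chelator == "EDTA":
        return GradientSet.from_back_extrapolation(
            chelator=chelator,
            metal=metal,
            m_o=float(row.m_o),
            m_n=float(row.m_n),
            dg_default=float(row.dg_sim_default),
            c_o_default=float(crow.c_o_default),
            c_n_default=float(crow.c_n_default),
        )
    return GradientSet(
        chelator=chelator,
        metal=metal,
        m_o=float(row.m_o),
        m_n=float(row.m_n),
        dg_default=float(row.dg_sim_default),
        c_o_default=float(crow.c_o_default),
        c_n_default=float(crow.c_n_default),
        dg_zero=float(row.dg_sim_zero),
    )


def solve_reference(
    metal: str, ratios: DenticityRatios = DEFAULT_RATIOS
) -> ChBESolution:
    """Run the full pipeline on the packaged EDTA/NTA summary for one metal."""
    summary = load_ti_summary()
    g = reference_gradient_set(metal, "EDTA")
    exp = summary.set_index(["metal", "chelator"]).dg_exp
    return solve_cij(g, float(exp[metal, "EDTA"]), float(exp[metal, "NTA"]), ratios)


def solutions_to_frame(solutions: Sequence[ChBESolution]) -> pd.DataFrame:
    """Tabulate solutions for CSV export."""
    return pd.DataFrame(
        [
            {
                "metal": s.metal,
                "c_o": s.c_o,
                "c_n": s.c_n,
                "physical": s.physical,
                "residual_ref": s.residuals[0],
                "residual_other": s.residuals[-1],
                "abs_det": s.condition_diag,
            }
            for s in solutions
        ]
    )
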