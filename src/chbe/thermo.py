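"""Binding thermodynamics: affinity constants <-> free energies, TI cycles.

Experimental chelator and protein affinities arrive either as stability
constants K1 (larger = tighter) or dissociation constants Kd (smaller =
tighter).  Both convert to a binding free energy via dG = -RT ln K1 =
+RT ln Kd, reported in kJ/mol with the convention that more negative means
stronger binding.

Simulated binding energies come from a thermodynamic cycle whose
electrostatic + polarization leg is run in replicates while the
van-der-Waals leg is either computed once or held at a fixed preset
(-dG_VdW = 9 kJ/mol), mirroring common practice for families of closely
related complexes where the VdW contribution is small and nearly constant.
"""

from __future__ import annotations

import enum
import math
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .constants import R_KJ, T_REF

__all__ = [
    "ConstantKind",
    "CycleSign",
    "ExperimentalAffinity",
    "TICycleResult",
    "dg_from_affinity",
    "affinity_from_dg",
    "combine_cycle",
    "read_affinities_csv",
    "FIXED_MINUS_DG_VDW_KJ",
]

#: Fixed -dG_VdW preset (kJ/mol) usable when the van-der-Waals leg is not
#: recomputed per system.
FIXED_MINUS_DG_VDW_KJ = 9.0


class ConstantKind(str, enum.Enum):
    STABILITY = "stability"      # K1: dG = -RT ln K1
    DISSOCIATION = "dissociation"  # Kd: dG = +RT ln Kd


class CycleSign(str, enum.Enum):
    """Orientation of the decoupling cycle.

    ``COMPLEX_MINUS_VDW`` subtracts the VdW leg from the mean ele+pol leg
    (equivalently adds the -dG_VdW preset); ``COMPLEX_PLUS_VDW`` adds it.
    The default orientation keeps 'more negative = stronger binding'.
    """

    COMPLEX_MINUS_VDW = "complex_minus_vdw"
    COMPLEX_PLUS_VDW = "complex_plus_vdw"


@dataclass(frozen=True)
class ExperimentalAffinity:
    species: str
    metal: str
    constant_kind: ConstantKind
    log10_value: float
    temperature: float = T_REF

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not math.isfinite(self.log10_value):
            raise ValueError("log10_value must be finite")


@dataclass(frozen=True)
class TICycleResult:
    dg_vdw: float
    dg_ele_pol_replicates: tuple[float, ...]
    dg_binding: float
    dg_sd: float


def dg_from_affinity(a: ExperimentalAffinity) -> float:
    """Binding free energy (kJ/mol) from an experimental affinity constant."""
    kind = ConstantKind(a.constant_kind)
    rt_ln10 = R_KJ * a.temperature * math.log(10.0)
    if kind is ConstantKind.STABILITY:
        return -rt_ln10 * a.log10_value
    return rt_ln10 * a.log10_value


def affinity_from_dg(
    dg: float,
    kind: ConstantKind = ConstantKind.STABILITY,
    temperature: float = T_REF,
) -> float:
    """Inverse of :func:`dg_from_affinity`: log10 of the constant."""
    rt_ln10 = R_KJ * temperature * math.log(10.0)
    sign = -1.0 if ConstantKind(kind) is ConstantKind.STABILITY else 1.0
    return sign * dg / rt_ln10


def combine_cycle(
    dg_vdw: float,
    dg_ele_pol_replicates: Sequence[float],
    sign: CycleSign = CycleSign.COMPLEX_MINUS_VDW,
) -> TICycleResult:
    """Combine cycle legs into a binding free energy with replicate spread.

    ``dg_vdw`` is the -dG_VdW contribution in kJ/mol (pass
    :data:`FIXED_MINUS_DG_VDW_KJ` for the fixed 9 kJ/mol preset).  The
    replicate standard deviation is the sample (n-1) estimate, 0 for a
    single replicate; the VdW leg carries no error term.
    """
    reps = tuple(float(x) for x in dg_ele_pol_replicates)
    if not reps:
        raise ValueError("at least one ele+pol replicate is required")
    mean = statistics.fmean(reps)
    sd = statistics.stdev(reps) if len(reps) > 1 else 0.0
    if CycleSign(sign) is CycleSign.COMPLEX_MINUS_VDW:
        total = mean - dg_vdw
    else:
        total = mean + dg_vdw
    return TICycleResult(
        dg_vdw=dg_vdw,
        dg_ele_pol_replicates=reps,
        dg_binding=total,
        dg_sd=sd,
    )


def read_affinities_csv(path: str | Path) -> list[ExperimentalAffinity]:
    """Read affinities from a CSV with columns species, metal, kind, log10K, T.

    ``T`` is optional and defaults to 298 K.
    """
    df = pd.read_csv(path)
    required = {"species", "metal", "kind", "log10K"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"affinity table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples():
        out.append(
            ExperimentalAffinity(
                species=str(row.species),
                metal=str(row.metal),
                constant_kind=ConstantKind(str(row.kind)),
                log10_value=float(row.log10K),
                temperature=float(getattr(row, "T", T_REF)),
            )
        )
    return out
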