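"""Seedable Metropolis Monte-Carlo sampler for an ion in a solvent-site bath.

A desk-scale stand-in for explicit-solvent trajectories: one ion plus
``n_sites`` identical solvent sites in a cubic periodic box, interacting
through the 12-6-4 (ion-site) and 12-6 (site-site) pair potentials under
the minimum-image convention with no cutoff beyond the image truncation.
Single-particle displacement moves with standard Metropolis acceptance at
the system temperature give correct equilibrium ensembles, which is all the
downstream RDF analysis needs; no dynamics are implied.

Also provides an analytic shell-geometry fixture generator whose
ground-truth ion-oxygen distance and coordination number are known by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import KB_KCAL
from .potential import AtomTypeParams, PairPotentialParams, pair_from_atom_types
from .rdf import FrameSet

__all__ = [
    "ToySystem",
    "McTrace",
    "run_mc",
    "make_shell_fixture",
    "tip3p_like_site",
]

#: Pair energy (kcal/mol) above which an initial placement counts as an overlap.
OVERLAP_ENERGY = 1e4

#: Attempts to place each site before giving up.
PLACEMENT_RETRIES = 2000


def tip3p_like_site(charge: float = -0.834) -> AtomTypeParams:
    """A water-oxygen-like solvent site (fixture convention, not physics)."""
    return AtomTypeParams(name="OW", r_min_half=1.768, epsilon=0.152, charge=charge)


@dataclass(frozen=True)
class ToySystem:
    """Ion + identical solvent sites in a cubic periodic box.

    The ion-site C_ij coefficient comes from the ion's ``c4_overrides``
    entry for the site's atom-type name (0 if absent).  Site-site pairs
    interact through the plain 12-6 + Coulomb potential.
    """

    ion: AtomTypeParams
    site: AtomTypeParams
    n_sites: int
    box_length: float
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        min_box = 4 * (self.ion.r_min_half + self.site.r_min_half)
        if self.box_length <= min_box:
            raise ValueError(
                f"box_length must exceed {min_box:.2f} A for these atom types"
            )
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def ion_site_pair(self) -> PairPotentialParams:
        return pair_from_atom_types(self.ion, self.site)

    @property
    def site_site_pair(self) -> PairPotentialParams:
        return pair_from_atom_types(self.site, self.site)


@dataclass(frozen=True)
class McTrace:
    frames: FrameSet
    energies: np.ndarray
    acceptance_rate: float
    n_steps: int
    save_interval: int


def _pair_energy_array(r: np.ndarray, p: PairPotentialParams) -> np.ndarray:
    r2 = r * r
    r6 = r2 * r2 * r2
    return (
        p.a_ij / (r6 * r6)
        - p.b_ij / r6
        - p.c_ij / (r2 * r2)
        + p.coulomb_constant * p.q_i * p.q_j / r
    )


def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def _particle_energy(
    idx: int, pos: np.ndarray, sys: ToySystem
) -> float:
    """Interaction energy of particle ``idx`` with all others (index 0 = ion)."""
    if idx == 0:
        d = _min_image(pos[1:] - pos[0], sys.box_length)
        r = np.linalg.norm(d, axis=1)
        return float(_pair_energy_array(r, sys.ion_site_pair).sum())
    # one ion pair + the remaining site-site pairs
    d_ion = _min_image(pos[0] - pos[idx], sys.box_length)
    r_ion = float(np.linalg.norm(d_ion))
    r_sites = np.linalg.norm(
        _min_image(np.delete(pos, (0, idx), axis=0) - pos[idx], sys.box_length), axis=1
    )
    e = float(_pair_energy_array(np.array([r_ion]), sys.ion_site_pair).sum())
    if r_sites.size:
        e += float(_pair_energy_array(r_sites, sys.site_site_pair).sum())
    return e


def _total_energy(pos: np.ndarray, sys: ToySystem) -> float:
    e = 0.0
    for i in range(len(pos)):
        e += _particle_energy(i, pos, sys)
    return e / 2


def _initial_positions(sys: ToySystem, rng: np.random.Generator) -> np.ndarray:
    """Ion at the box center, sites placed by rejection of overlaps."""
    pos = np.empty((sys.n_sites + 1, 3))
    pos[0] = sys.box_length / 2
    for i in range(1, sys.n_sites + 1):
        for _ in range(PLACEMENT_RETRIES):
            trial = rng.random(3) * sys.box_length
            pos[i] = trial
            if _particle_energy(i, pos[: i + 1], sys) < OVERLAP_ENERGY:
                break
        else:
            raise RuntimeError(
                f"could not place site {i} without overlap after "
                f"{PLACEMENT_RETRIES} attempts; box too crowded"
            )
    return pos


def run_mc(
    sys: ToySystem,
    n_steps: int,
    step_size: float,
    save_interval: int,
    seed: int,
    move_ion: bool = True,
) -> McTrace:
    """Metropolis sampling of the toy system.

    One step displaces one uniformly chosen particle by a uniform
    perturbation in ``[-step_size, step_size]^3`` and accepts with
    probability ``min(1, exp(-dE/kT))``; zero-energy moves are always
    accepted.  Frames (wrapped into the box) and total energies are saved
    every ``save_interval`` steps.  Identical seeds give identical traces.
    """
    if n_steps < save_interval:
        raise ValueError("n_steps must be at least save_interval")
    rng = np.random.default_rng(seed)
    pos = _initial_positions(sys, rng)
    beta = 1.0 / (KB_KCAL * sys.temperature)
    energy = _total_energy(pos, sys)

    movable_lo = 0 if move_ion else 1
    n_particles = len(pos)
    accepted = 0
    ions, frames, energies = [], [], []

    for step in range(1, n_steps + 1):
        idx = int(rng.integers(movable_lo, n_particles))
        old = pos[idx].copy()
        e_old = _particle_energy(idx, pos, sys)
        pos[idx] = old + (rng.random(3) * 2 - 1) * step_size
        e_new = _particle_energy(idx, pos, sys)
        de = e_new - e_old
        if de <= 0 or rng.random() < math.exp(-beta * de):
            accepted += 1
            energy += de
        else:
            pos[idx] = old
        if step % save_interval == 0:
            wrapped = np.mod(pos, sys.box_length)
            ions.append(wrapped[0].copy())
            frames.append(wrapped[1:].copy())
            energies.append(energy)

    return McTrace(
        frames=FrameSet(
            ion=np.array(ions), sites=np.array(frames), box_length=sys.box_length
        ),
        energies=np.array(energies),
        acceptance_rate=accepted / n_steps,
        n_steps=n_steps,
        save_interval=save_interval,
    )


def make_shell_fixture(
    n_shell: int,
    radius: float,
    jitter: float,
    n_frames: int,
    rng_seed: int,
) -> FrameSet:
    """Frames with ``n_shell`` sites on a sphere around the ion.

    Sites are drawn uniformly on the sphere with Gaussian radial jitter, so
    the ground-truth ion-oxygen distance is ``radius`` and the ground-truth
    coordination number is ``n_shell``.  Open boundary (no box).
    """
    if n_shell < 1:
        raise ValueError("n_shell must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    rng = np.random.default_rng(rng_seed)
    directions = rng.normal(size=(n_frames, n_shell, 3))
    directions /= np.linalg.norm(directions, axis=2, keepdims=True)
    radii = radius + jitter * rng.normal(size=(n_frames, n_shell, 1))
    sites = directions * np.abs(radii)
    return FrameSet(ion=np.zeros((n_frames, 3)), sites=sites, box_length=None)
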