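"""Ion-site radial distribution functions, first-shell distances and
coordination numbers.

An ion-oxygen distance (IOD) is extracted as the vertex of a quadratic
fitted to the RDF within +/-0.1 A of its raw first peak, and the
coordination number (CN) as the integral of ``4 pi rho r^2 g(r)`` from 0 to
the first minimum after that peak.  When the curve has no unambiguous first
minimum the result is flagged and a CN range over candidate minima is
reported instead of a single value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrameSet",
    "RDFCurve",
    "CoordinationResult",
    "NoPeakError",
    "compute_rdf",
    "iod_from_rdf",
    "cn_from_rdf",
    "read_xyz",
    "write_xyz",
    "rdf_report_frame",
]

#: Default RDF bin width, A.
DEFAULT_DR = 0.01

#: Smoothed g(r) must exceed this to count as a first peak; midway between
#: the bulk level (1) and the ~2+ heights of genuine first solvation peaks,
#: so counting noise on a structureless curve does not register as a peak.
PEAK_THRESHOLD = 1.5

#: Half-width (bins on each side) of the local-extremum window.
EXTREMUM_HALF_WINDOW = 2

#: Half-width (A) of the quadratic-fit window around the raw peak.
PEAK_FIT_HALF_WIDTH = 0.1

#: Peak search starts here (A): no ion-ligand pair approaches closer, and
#: the tiny shell volumes below it make single counts explode g(r).
MIN_PEAK_R = 0.5


class NoPeakError(ValueError):
    """The RDF has no detectable first peak (e.g. an ideal-gas curve)."""


@dataclass(frozen=True)
class FrameSet:
    """Ion + solvent-site coordinates over a set of snapshots.

    ``ion`` has shape (n_frames, 3) and ``sites`` (n_frames, n_sites, 3),
    both in A.  ``box_length`` is the edge of a cubic periodic box, or
    ``None`` for open boundaries.
    """

    ion: np.ndarray
    sites: np.ndarray
    box_length: float | None = None

    def __post_init__(self) -> None:
        ion = np.asarray(self.ion, dtype=float)
        sites = np.asarray(self.sites, dtype=float)
        object.__setattr__(self, "ion", ion)
        object.__setattr__(self, "sites", sites)
        if ion.ndim != 2 or ion.shape[1] != 3:
            raise ValueError("ion coordinates must have shape (n_frames, 3)")
        if sites.ndim != 3 or sites.shape[2] != 3:
            raise ValueError("site coordinates must have shape (n_frames, n_sites, 3)")
        if sites.shape[0] != ion.shape[0]:
            raise ValueError("ion and site frame counts differ")
        if not (np.isfinite(ion).all() and np.isfinite(sites).all()):
            raise ValueError("coordinates must be finite")
        if self.box_length is not None and self.box_length <= 0:
            raise ValueError("box_length must be positive")

    @property
    def n_frames(self) -> int:
        return self.ion.shape[0]

    @property
    def site_count(self) -> int:
        return self.sites.shape[1]

    def distances(self) -> np.ndarray:
        """Ion-site distances per frame, minimum image if periodic."""
        d = self.sites - self.ion[:, None, :]
        if self.box_length is not None:
            d -= self.box_length * np.round(d / self.box_length)
        return np.linalg.norm(d, axis=2)


@dataclass(frozen=True)
class RDFCurve:
    """Binned g(r) with the density used to normalize it.

    Bins are half-open ``[r, r+dr)`` with values reported at bin centers.
    """

    bin_centers: np.ndarray
    g: np.ndarray
    bulk_density: float
    n_frames: int

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.g) < 0):
            raise ValueError("g(r) must be non-negative")

    @property
    def dr(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    @property
    def shell_volumes(self) -> np.ndarray:
        lo = self.bin_centers - self.dr / 2
        hi = self.bin_centers + self.dr / 2
        return 4.0 / 3.0 * np.pi * (hi**3 - np.clip(lo, 0, None) ** 3)

    def running_coordination(self) -> np.ndarray:
        """n(r): cumulative 4*pi*rho*r^2*g integral up to each bin edge."""
        return np.cumsum(self.bulk_density * self.shell_volumes * self.g)


@dataclass(frozen=True)
class CoordinationResult:
    iod: float
    cn: float
    first_min_r: float
    minimum_clear: bool
    cn_range: tuple[float, float] | None = None


def compute_rdf(
    fs: FrameSet, r_max: float, dr: float = DEFAULT_DR
) -> RDFCurve:
    """Ion-site radial distribution function at resolution ``dr``.

    Normalization uses exact spherical-shell volumes (which agree with
    ``4 pi r^2 dr`` to second order in ``dr/r``), the bulk site density and
    the frame count.  For periodic frames ``r_max`` may not exceed half the
    box edge; the bulk density is the total site count over the box volume.
    For open boundaries the density is estimated from the outer 10% of the
    ``r_max`` sphere, falling back to the mean density inside the whole
    sphere when that outer shell is empty.
    """
    if fs.n_frames < 1:
        raise ValueError("need at least one frame")
    if fs.box_length is not None and r_max > fs.box_length / 2 + 1e-12:
        raise ValueError(
            f"r_max={r_max} exceeds half the box edge ({fs.box_length / 2})"
        )
    d = fs.distances()
    edges = np.arange(0.0, r_max + dr / 2, dr)
    counts, _ = np.histogram(d, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2

    if fs.box_length is not None:
        rho = fs.site_count / fs.box_length**3
    else:
        outer = (d >= 0.9 * r_max) & (d < r_max)
        outer_vol = 4.0 / 3.0 * np.pi * (r_max**3 - (0.9 * r_max) ** 3)
        rho = outer.sum() / (fs.n_frames * outer_vol)
        if rho == 0:
            inside = (d < r_max).sum()
            rho = inside / (fs.n_frames * 4.0 / 3.0 * np.pi * r_max**3)
        if rho == 0:
            raise ValueError("no sites within r_max; cannot estimate density")

    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (fs.n_frames * rho * shell_vol)
    return RDFCurve(bin_centers=centers, g=g, bulk_density=float(rho), n_frames=fs.n_frames)


def _smooth(g: np.ndarray, half_window: int = EXTREMUM_HALF_WINDOW) -> np.ndarray:
    kernel = np.ones(2 * half_window + 1)
    padded = np.pad(g, half_window, mode="edge")
    return np.convolve(padded, kernel / kernel.size, mode="valid")


def _first_peak_index(c: RDFCurve, threshold: float = PEAK_THRESHOLD) -> int:
    """Index of the first local maximum of smoothed g exceeding ``threshold``.

    Extremum detection runs on the 5-bin smoothed curve so single-bin
    counting noise does not register; a local maximum is a bin whose
    smoothed g is >= all bins in a 5-bin window centred on it (the window
    shrinks at the curve's ends).
    """
    gs = _smooth(np.asarray(c.g))
    w = EXTREMUM_HALF_WINDOW
    for i in range(len(gs)):
        if c.bin_centers[i] < MIN_PEAK_R or gs[i] <= threshold:
            continue
        lo, hi = max(0, i - w), min(len(gs), i + w + 1)
        if gs[i] >= gs[lo:hi].max():
            return i
    raise NoPeakError("no first peak found above threshold")


def iod_from_rdf(c: RDFCurve) -> float:
    """First-peak position (A) refined by a local quadratic fit.

    A parabola is least-squares fitted to the bins within
    +/-0.1 A of the raw first-peak bin and its vertex abscissa returned;
    if the fitted parabola opens upward the raw bin center is returned.
    """
    i_peak = _first_peak_index(c)
    r0 = c.bin_centers[i_peak]
    mask = np.abs(c.bin_centers - r0) <= PEAK_FIT_HALF_WIDTH + 1e-12
    r = c.bin_centers[mask]
    g = np.asarray(c.g)[mask]
    if r.size < 3:
        return float(r0)
    a, b, _ = np.polyfit(r - r0, g, 2)
    if a >= 0:
        return float(r0)
    return float(r0 - b / (2 * a))


def cn_from_rdf(c: RDFCurve) -> CoordinationResult:
    """First-shell coordination number by integration to the first minimum.

    Minimum detection runs on a 5-bin smoothed copy of g; the integration
    itself uses the raw curve.  A minimum is 'clear' when its smoothed g
    falls below half the peak height; otherwise the result is flagged and
    ``cn_range`` spans the CN values at all candidate minima.
    """
    i_peak = _first_peak_index(c)
    g = np.asarray(c.g)
    gs = _smooth(g)
    w = EXTREMUM_HALF_WINDOW
    half_height = gs[i_peak] / 2

    candidates = []
    # the last window is the curve boundary, not a detected minimum
    for i in range(i_peak + 1, len(gs) - w - 1):
        lo, hi = max(0, i - w), min(len(gs), i + w + 1)
        if gs[i] <= gs[lo:hi].min() and gs[i] < gs[i - 1]:
            candidates.append(i)

    n_running = c.running_coordination()
    iod = iod_from_rdf(c)

    clear = [i for i in candidates if gs[i] < half_height]
    if clear:
        i_min = clear[0]
        return CoordinationResult(
            iod=iod,
            cn=float(n_running[i_min]),
            first_min_r=float(c.bin_centers[i_min]),
            minimum_clear=True,
        )
    if candidates:
        cns = [float(n_running[i]) for i in candidates]
        return CoordinationResult(
            iod=iod,
            cn=cns[0],
            first_min_r=float(c.bin_centers[candidates[0]]),
            minimum_clear=False,
            cn_range=(min(cns), max(cns)),
        )
    # monotone tail: integrate to the end of the curve and flag
    return CoordinationResult(
        iod=iod,
        cn=float(n_running[-1]),
        first_min_r=float(c.bin_centers[-1]),
        minimum_clear=False,
        cn_range=None,
    )


# ---------------------------------------------------------------------------
# XYZ trajectory I/O

_ION_DEFAULT = "M"
_SITE_DEFAULT = "O"


def write_xyz(
    fs: FrameSet,
    path: str | Path,
    ion_element: str = _ION_DEFAULT,
    site_element: str = _SITE_DEFAULT,
) -> None:
    """Write a FrameSet as a multi-frame XYZ file.

    The comment line carries ``box_length=<L>`` for periodic frames so the
    trajectory round-trips through :func:`read_xyz`.
    """
    with open(path, "w") as fh:
        for k in range(fs.n_frames):
            fh.write(f"{1 + fs.site_count}\n")
            comment = f"frame {k}"
            if fs.box_length is not None:
                comment += f" box_length={fs.box_length:.6f}"
            fh.write(comment + "\n")
            x, y, z = fs.ion[k]
            fh.write(f"{ion_element} {x:.6f} {y:.6f} {z:.6f}\n")
            for sx, sy, sz in fs.sites[k]:
                fh.write(f"{site_element} {sx:.6f} {sy:.6f} {sz:.6f}\n")


def read_xyz(path: str | Path, ion_element: str = _ION_DEFAULT) -> FrameSet:
    """Read a multi-frame XYZ trajectory into a FrameSet.

    Exactly one atom per frame must carry ``ion_element`` as its element
    label; all other atoms are treated as solvent sites.  Malformed input
    raises ``ValueError`` naming the offending line number.
    """
    lines = Path(path).read_text().splitlines()
    ions, frames, box = [], [], None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"line {i + 1}: expected atom count, got {lines[i]!r}")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        for token in comment.split():
            if token.startswith("box_length="):
                box = float(token.split("=", 1)[1])
        ion_xyz, site_xyz = None, []
        for j in range(n_atoms):
            ln = i + 2 + j
            if ln >= len(lines):
                raise ValueError(f"line {ln + 1}: truncated frame (expected {n_atoms} atoms)")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ValueError(f"line {ln + 1}: expected 'element x y z', got {lines[ln]!r}")
            el, coords = parts[0], parts[1:4]
            try:
                xyz = [float(v) for v in coords]
            except ValueError:
                raise ValueError(f"line {ln + 1}: non-numeric coordinate in {lines[ln]!r}")
            if el == ion_element:
                if ion_xyz is not None:
                    raise ValueError(f"line {ln + 1}: multiple ion atoms in one frame")
                ion_xyz = xyz
            else:
                site_xyz.append(xyz)
        if ion_xyz is None:
            raise ValueError(f"frame starting at line {i + 1} has no ion atom {ion_element!r}")
        ions.append(ion_xyz)
        frames.append(site_xyz)
        i += 2 + n_atoms
    if not frames:
        raise ValueError("no frames found in XYZ file")
    return FrameSet(ion=np.array(ions), sites=np.array(frames), box_length=box)


def rdf_report_frame(c: RDFCurve) -> pd.DataFrame:
    """Tabulate r, g(r) and the running coordination number for export."""
    return pd.DataFrame(
        {
            "r_A": c.bin_centers,
            "g": c.g,
            "n_running": c.running_coordination(),
        }
    )
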