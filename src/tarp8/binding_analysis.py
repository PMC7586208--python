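"""Geometric trajectory analytics for ligand engagement of a two-helix pocket.

The pocket of interest is framed by two marker residues (in TARP gamma-8,
Val-176 on M3 and Gly-209 on M4); its width is the Cα–Cα distance of that
pair and its centre is their midpoint.  A ligand's engagement is the
distance between its centre of mass and that midpoint.  Hydrogen bonds are
scored by a plain distance criterion, either hydrogen-to-acceptor
(< 0.25 nm for at least a weak bond) or heavy-atom donor-to-acceptor
(< 0.36 nm) when the bonding hydrogen is not the measured atom.  No angular
term is applied.

All lengths are nm except superposition RMSD, which is reported in Å as is
conventional for structure comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import AnalysisError, SelectionError
from .mol_io import AtomSelector, Frame, Trajectory, select_atoms

__all__ = [
    "DistanceSeries",
    "HBondMode",
    "HBondSpec",
    "BoundIntervals",
    "atom_distance",
    "pocket_width_series",
    "site_center",
    "ligand_com",
    "engagement_series",
    "classify_bound",
    "hbond_series",
    "hbond_occupancy",
    "select_max_width_frame",
    "superpose_rmsd",
    "DEFAULT_BOUND_CUTOFF_NM",
    "DEFAULT_MIN_DWELL_NS",
]

# A centre-of-mass distance above ~0.8 nm marks a broken pocket contact;
# dwell shorter than 5 ns is treated as a transient touch, not binding.
DEFAULT_BOUND_CUTOFF_NM = 0.8
DEFAULT_MIN_DWELL_NS = 5.0

#: Distance criteria for at least a weak hydrogen bond.
HBOND_CUTOFF_H_ACCEPTOR_NM = 0.25
HBOND_CUTOFF_HEAVY_HEAVY_NM = 0.36


@dataclass
class DistanceSeries:
    """A labelled per-frame distance time series (times ns, values nm)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if len(self.times) == 0:
            raise ValueError("series must be non-empty")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")


class HBondMode(str, Enum):
    H_TO_ACCEPTOR = "h_to_acceptor"
    HEAVY_TO_HEAVY = "heavy_to_heavy"


@dataclass
class HBondSpec:
    """Distance criterion for one hydrogen bond.

    ``H_TO_ACCEPTOR`` measures the bonding hydrogen to the acceptor heavy
    atom (default cutoff 0.25 nm); ``HEAVY_TO_HEAVY`` measures donor heavy
    atom to acceptor heavy atom (default cutoff 0.36 nm), the appropriate
    criterion when only heavy-atom positions are compared.
    """

    donor: AtomSelector
    acceptor: AtomSelector
    hydrogen: AtomSelector | None = None
    mode: HBondMode = HBondMode.H_TO_ACCEPTOR
    cutoff: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.mode = HBondMode(self.mode)
        if self.mode is HBondMode.H_TO_ACCEPTOR and self.hydrogen is None:
            raise ValueError("H_TO_ACCEPTOR mode requires a hydrogen selector")
        if self.cutoff is None:
            self.cutoff = (
                HBOND_CUTOFF_H_ACCEPTOR_NM
                if self.mode is HBondMode.H_TO_ACCEPTOR
                else HBOND_CUTOFF_HEAVY_HEAVY_NM
            )
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")


@dataclass
class BoundIntervals:
    """Disjoint bound-state time intervals with the rule that produced them."""

    intervals: list[tuple[float, float]]
    cutoff: float
    min_dwell: float

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end in self.intervals:
            if not end > start:
                raise ValueError(f"interval ({start}, {end}) must have end > start")
            if start < prev_end:
                raise ValueError("intervals must be disjoint and ordered")
            prev_end = end

    @property
    def total_dwell(self) -> float:
        return float(sum(e - s for s, e in self.intervals))

    def bound_fraction(self, t_start: float, t_end: float) -> float:
        """Fraction of [t_start, t_end] covered by bound intervals."""
        if not t_end > t_start:
            raise ValueError("t_end must exceed t_start")
        return self.total_dwell / (t_end - t_start)


def _resolve_one(traj: Trajectory, sel: AtomSelector, what: str) -> int:
    idx = select_atoms(traj, sel)
    if len(idx) != 1:
        raise SelectionError(
            f"{what} selector resolved to {len(idx)} atoms (need exactly 1): {sel}"
        )
    return idx[0]


def atom_distance(frame: Frame, a: int, b: int) -> float:
    """Euclidean distance (nm) between two atoms of one frame."""
    n = frame.coords.shape[0]
    if not (0 <= a < n and 0 <= b < n):
        raise IndexError(f"atom index out of range (n_atoms={n})")
    return float(np.linalg.norm(frame.coords[a] - frame.coords[b]))


def pocket_width_series(
    traj: Trajectory, res_a: AtomSelector, res_b: AtomSelector
) -> DistanceSeries:
    """Per-frame distance between two single-atom selections (pocket width)."""
    ia = _resolve_one(traj, res_a, "pocket residue A")
    ib = _resolve_one(traj, res_b, "pocket residue B")
    values = [atom_distance(f, ia, ib) for f in traj.frames]
    return DistanceSeries(times=traj.times, values=np.array(values), label="pocket_width")


def site_center(frame: Frame, idx_a: int, idx_b: int) -> np.ndarray:
    """Arithmetic midpoint (nm) of two atoms — the binding-site centre."""
    n = frame.coords.shape[0]
    if not (0 <= idx_a < n and 0 <= idx_b < n):
        raise IndexError(f"atom index out of range (n_atoms={n})")
    return (frame.coords[idx_a] + frame.coords[idx_b]) / 2.0


def ligand_com(frame: Frame, ligand: list[int], masses: np.ndarray) -> np.ndarray:
    """Mass-weighted mean position (nm) of the selected ligand atoms."""
    if len(ligand) == 0:
        raise SelectionError("ligand selection is empty")
    m = np.asarray(masses, dtype=float)[ligand]
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    pos = frame.coords[ligand]
    return (m[:, None] * pos).sum(axis=0) / m.sum()


def engagement_series(
    traj: Trajectory,
    ligand: AtomSelector,
    res_a: AtomSelector,
    res_b: AtomSelector,
    heavy_only: bool = True,
) -> DistanceSeries:
    """Distance between ligand centre of mass and the pocket centre, per frame.

    By default hydrogens are excluded from the centre-of-mass atom set
    (configurable with ``heavy_only``).
    """
    lig_idx = select_atoms(traj, ligand)
    if heavy_only:
        lig_idx = [i for i in lig_idx if traj.atoms[i].element != "H"]
    if not lig_idx:
        raise SelectionError(f"ligand selector matched no atoms: {ligand}")
    ia = _resolve_one(traj, res_a, "pocket residue A")
    ib = _resolve_one(traj, res_b, "pocket residue B")
    masses = traj.masses
    values = [
        float(np.linalg.norm(ligand_com(f, lig_idx, masses) - site_center(f, ia, ib)))
        for f in traj.frames
    ]
    return DistanceSeries(times=traj.times, values=np.array(values), label="engagement")


def classify_bound(
    series: DistanceSeries,
    cutoff: float = DEFAULT_BOUND_CUTOFF_NM,
    min_dwell: float = DEFAULT_MIN_DWELL_NS,
) -> BoundIntervals:
    """Maximal sub-cutoff runs of a distance series as bound intervals.

    A run of consecutive samples with value < ``cutoff`` becomes the
    interval from the first to the last sample time of the run.  Runs whose
    span is shorter than ``min_dwell`` (ns) are dropped; a single-frame
    contact has zero measurable dwell and is always dropped.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    if min_dwell < 0:
        raise ValueError("min_dwell must be non-negative")
    below = series.values < cutoff
    intervals: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(below):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((series.times[start], series.times[i - 1]))
            start = None
    if start is not None:
        intervals.append((series.times[start], series.times[len(below) - 1]))
    kept = [(s, e) for s, e in intervals if e > s and (e - s) >= min_dwell]
    return BoundIntervals(intervals=kept, cutoff=cutoff, min_dwell=min_dwell)


def hbond_series(traj: Trajectory, spec: HBondSpec) -> DistanceSeries:
    """Per-frame distance of the atom pair named by the H-bond criterion."""
    _resolve_one(traj, spec.donor, "donor")  # donor must resolve in either mode
    if spec.mode is HBondMode.H_TO_ACCEPTOR:
        ia = _resolve_one(traj, spec.hydrogen, "hydrogen")
    else:
        ia = _resolve_one(traj, spec.donor, "donor")
    ib = _resolve_one(traj, spec.acceptor, "acceptor")
    values = [atom_distance(f, ia, ib) for f in traj.frames]
    return DistanceSeries(
        times=traj.times, values=np.array(values), label=spec.label or "hbond"
    )


def hbond_occupancy(series: DistanceSeries, spec: HBondSpec | float) -> float:
    """Time-weighted fraction of the trajectory satisfying the bond criterion.

    Each sample is weighted by half the interval to each neighbour (the two
    ends get half-intervals only), making the estimate robust to uneven
    snapshot spacing.  ``spec`` may be an :class:`HBondSpec` or a bare
    cutoff in nm.
    """
    cutoff = spec.cutoff if isinstance(spec, HBondSpec) else float(spec)
    t, v = series.times, series.values
    if len(t) == 1:
        return float(v[0] < cutoff)
    w = np.empty_like(t)
    w[0] = (t[1] - t[0]) / 2.0
    w[-1] = (t[-1] - t[-2]) / 2.0
    if len(t) > 2:
        w[1:-1] = (t[2:] - t[:-2]) / 2.0
    return float(w[v < cutoff].sum() / w.sum())


def select_max_width_frame(
    traj: Trajectory, res_a: AtomSelector, res_b: AtomSelector
) -> int:
    """Index of the frame with maximal pocket width (earliest frame on ties).

    This is the snapshot-selection rule used to pick dilated-pocket
    conformations as docking substrates.
    """
    series = pocket_width_series(traj, res_a, res_b)
    return int(np.argmax(series.values))  # argmax returns first maximum


def superpose_rmsd(ref: np.ndarray, mob: np.ndarray) -> float:
    """RMSD (Å) after optimal rigid superposition of ``mob`` onto ``ref``.

    Inputs are (n, 3) coordinate sets in nm.  A least-squares rotation +
    translation (Kabsch, proper rotation enforced) is applied over all
    supplied atom pairs, with no outlier rejection, then the RMSD is
    reported in Å.
    """
    ref = np.asarray(ref, dtype=float)
    mob = np.asarray(mob, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != 3 or mob.shape != ref.shape:
        raise ValueError(f"need matching (n, 3) coordinate sets, got {ref.shape} vs {mob.shape}")
    if ref.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    _, rssd = Rotation.align_vectors(ref_c, mob_c)
    rmsd_nm = rssd / np.sqrt(ref.shape[0])
    return float(rmsd_nm * 10.0)
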