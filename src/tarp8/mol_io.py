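"""Structure, trajectory and electrophysiology-sweep I/O.

Coordinate data are held in a lightweight :class:`Trajectory` container whose
canonical length unit is the nanometre (MD convention).  Conversion from the
ångström-based PDB format happens only at the file boundary (exact x0.1).

Supported on-disk formats (all plain text):

* PDB ``ATOM``/``HETATM``/``MODEL``/``ENDMDL`` records, wwPDB fixed columns;
  one frame per ``MODEL`` block.
* A trajectory table (TSV) with columns ``time_ns, serial, x_nm, y_nm, z_nm``
  and optional atom-metadata columns; every time must list the same atoms.
* Current sweeps as TSV (``time_s, current_pA`` and optional ``sweep_id``)
  plus a JSON sidecar carrying the agonist-application window and labels.

Binary acquisition/MD formats (ABF, XTC, DCD) are deliberately out of scope;
external adapters can construct :class:`Trajectory` / :class:`SweepTrace`
objects directly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, ParseError

__all__ = [
    "Atom",
    "Frame",
    "Trajectory",
    "AtomSelector",
    "SweepTrace",
    "read_pdb",
    "write_pdb",
    "read_traj_table",
    "write_traj_table",
    "select_atoms",
    "read_sweeps",
    "write_sweeps",
    "ANGSTROM_PER_NM",
]

ANGSTROM_PER_NM = 10.0

# Standard atomic weights (Da) for the elements that occur in protein /
# small-molecule work; "X" is the placeholder for metadata-free tables.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845, "MN": 54.938, "CU": 63.546, "SE": 78.971, "X": 1.0,
}

# Two-letter element symbols that can appear in PDB atom names.
_TWO_LETTER = {"CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CU", "SE"}


def infer_element(atom_name: str, res_name: str = "") -> str:
    """Infer an element symbol from a PDB atom name.

    Digits are stripped; a leading two-letter symbol is preferred only when
    it cannot be a protein atom-position code (e.g. ``CA`` in an amino acid
    is an alpha-carbon, not calcium).
    """
    stripped = "".join(ch for ch in atom_name if ch.isalpha()).upper()
    if not stripped:
        raise ParseError(f"cannot infer element from atom name {atom_name!r}")
    two = stripped[:2]
    if two in _TWO_LETTER and not (two == "CA" and res_name):
        return two
    if two == "CA" and res_name.upper() == "CA":  # calcium ion residue
        return "CA"
    return stripped[0]


def mass_of(element: str) -> float:
    """Standard atomic weight in Da (1.0 for the unknown element ``X``)."""
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise ParseError(f"no standard mass for element {element!r}") from None


@dataclass(frozen=True)
class Atom:
    """Topology entry for a single atom."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    mass: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not self.mass > 0:
            raise ValueError(f"atom mass must be positive, got {self.mass}")


@dataclass
class Frame:
    """One trajectory frame: a time stamp (ns) and per-atom coordinates (nm)."""

    time: float
    coords: np.ndarray  # (n_atoms, 3), nm

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")


@dataclass
class Trajectory:
    """An ordered list of frames over a fixed atom topology."""

    atoms: list[Atom]
    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        n = len(self.atoms)
        for f in self.frames:
            if f.coords.shape[0] != n:
                raise ValueError(
                    f"frame at t={f.time} has {f.coords.shape[0]} atoms, topology has {n}"
                )
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        """Frame times in ns."""
        return np.array([f.time for f in self.frames])

    @property
    def masses(self) -> np.ndarray:
        """Per-atom masses in Da, topology order."""
        return np.array([a.mass for a in self.atoms])

    def coords(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_atoms, 3), nm."""
        return np.stack([f.coords for f in self.frames])


@dataclass(frozen=True)
class AtomSelector:
    """Conjunction of optional atom-attribute filters.

    At least one field must be set; an atom matches when every set field
    equals the corresponding attribute.
    """

    chain_id: str | None = None
    res_seq: int | None = None
    res_name: str | None = None
    atom_name: str | None = None

    def __post_init__(self) -> None:
        if all(
            v is None
            for v in (self.chain_id, self.res_seq, self.res_name, self.atom_name)
        ):
            raise ValueError("selector must set at least one field")

    def matches(self, atom: Atom) -> bool:
        if self.chain_id is not None and atom.chain_id != self.chain_id:
            return False
        if self.res_seq is not None and atom.res_seq != self.res_seq:
            return False
        if self.res_name is not None and atom.res_name != self.res_name:
            return False
        if self.atom_name is not None and atom.name != self.atom_name:
            return False
        return True


def select_atoms(traj: Trajectory, sel: AtomSelector) -> list[int]:
    """Indices of topology atoms matching all set selector fields.

    Returned in topology order; an empty result is valid (downstream
    operations reject empty selections where they must).
    """
    return [i for i, a in enumerate(traj.atoms) if sel.matches(a)]


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> Trajectory:
    """Read a single- or multi-model PDB file into a :class:`Trajectory`.

    One frame per ``MODEL`` block (a single frame if no ``MODEL`` records).
    Coordinates are converted from Å to nm.  Only the first alternate
    location (altLoc blank or "A") of each atom is kept; others are skipped
    with a warning.  The element column is used when present, otherwise the
    element is inferred from the atom name.  PDB carries no time axis, so
    frames are stamped 0, 1, 2, ... ns.
    """
    path = Path(path)
    atoms: list[Atom] = []
    frames: list[np.ndarray] = []
    current: list[list[float]] | None = None
    first_model_done = False

    def _close_model(lineno: int) -> None:
        nonlocal current, first_model_done
        if current is None:
            return
        if first_model_done and len(current) != len(atoms):
            raise FormatError(
                f"{path}: MODEL ending before line {lineno} has {len(current)} atoms, "
                f"expected {len(atoms)}"
            )
        frames.append(np.array(current, dtype=float))
        first_model_done = True
        current = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                _close_model(lineno)
                current = []
            elif rec == "ENDMDL":
                _close_model(lineno)
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = []
                alt_loc = line[16:17].strip()
                if alt_loc not in ("", "A"):
                    warnings.warn(
                        f"{path}:{lineno}: skipping altLoc {alt_loc!r} "
                        "(only blank/'A' kept)",
                        stacklevel=2,
                    )
                    continue
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    res_name = line[17:20].strip()
                    chain_id = line[21:22].strip()
                    res_seq = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}: malformed record at line {lineno}: {exc}") from exc
                element = line[76:78].strip().upper() if len(line) >= 78 else ""
                if not element:
                    element = infer_element(name, res_name)
                if not first_model_done:
                    atoms.append(
                        Atom(
                            serial=serial,
                            name=name,
                            element=element,
                            res_name=res_name,
                            res_seq=res_seq,
                            chain_id=chain_id,
                            mass=mass_of(element),
                        )
                    )
                current.append([x / ANGSTROM_PER_NM, y / ANGSTROM_PER_NM, z / ANGSTROM_PER_NM])

    _close_model(lineno if "lineno" in locals() else 0)
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return Trajectory(
        atoms=atoms,
        frames=[Frame(time=float(i), coords=c) for i, c in enumerate(frames)],
    )


def write_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a (multi-)model PDB file, nm -> Å."""
    path = Path(path)
    multi = traj.n_frames > 1
    with open(path, "w") as fh:
        for imodel, frame in enumerate(traj.frames, start=1):
            if multi:
                fh.write(f"MODEL     {imodel:4d}\n")
            for atom, xyz in zip(traj.atoms, frame.coords):
                x, y, z = (v * ANGSTROM_PER_NM for v in xyz)
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                fh.write(
                    f"ATOM  {atom.serial:5d} {name:<4s} {atom.res_name:<3s} "
                    f"{atom.chain_id:1s}{atom.res_seq:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{atom.element:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Trajectory table (TSV)
# ---------------------------------------------------------------------------

_TRAJ_REQUIRED = ["time_ns", "serial", "x_nm", "y_nm", "z_nm"]
_TRAJ_META = ["name", "element", "res_name", "res_seq", "chain_id"]


def read_traj_table(path: str | Path) -> Trajectory:
    """Read a per-frame coordinate table (TSV).

    Required columns: ``time_ns, serial, x_nm, y_nm, z_nm``.  Optional
    metadata columns (``name, element, res_name, res_seq, chain_id``) are
    used when present; otherwise placeholder topology metadata is filled in
    (element "X", mass 1 Da).  Every time must list the same serial set.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TRAJ_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise FormatError(f"{path}: empty trajectory table")

    times = np.sort(df["time_ns"].unique())
    if len(times) != df["time_ns"].nunique():
        raise FormatError(f"{path}: duplicate times")

    groups = dict(tuple(df.groupby("time_ns", sort=True)))
    ref = groups[times[0]].sort_values("serial")
    ref_serials = ref["serial"].to_numpy()
    if len(np.unique(ref_serials)) != len(ref_serials):
        raise FormatError(f"{path}: duplicate serial within one time")

    has_meta = all(c in df.columns for c in _TRAJ_META)
    atoms = []
    for _, row in ref.iterrows():
        if has_meta:
            element = str(row["element"]).upper()
            atoms.append(
                Atom(
                    serial=int(row["serial"]),
                    name=str(row["name"]),
                    element=element,
                    res_name=str(row["res_name"]),
                    res_seq=int(row["res_seq"]),
                    chain_id=str(row["chain_id"]),
                    mass=mass_of(element),
                )
            )
        else:
            atoms.append(
                Atom(
                    serial=int(row["serial"]),
                    name=f"X{int(row['serial'])}",
                    element="X",
                    res_name="UNK",
                    res_seq=1,
                    chain_id="",
                    mass=1.0,
                )
            )

    frames = []
    for t in times:
        g = groups[t].sort_values("serial")
        serials = g["serial"].to_numpy()
        if len(serials) != len(ref_serials) or not np.array_equal(serials, ref_serials):
            raise FormatError(
                f"{path}: atom set at time {t} ns differs from the first frame"
            )
        frames.append(
            Frame(time=float(t), coords=g[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float))
        )
    return Trajectory(atoms=atoms, frames=frames)


def write_traj_table(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as TSV with full metadata columns (round-trippable)."""
    rows = []
    for frame in traj.frames:
        for atom, xyz in zip(traj.atoms, frame.coords):
            rows.append(
                {
                    "time_ns": frame.time,
                    "serial": atom.serial,
                    "x_nm": xyz[0],
                    "y_nm": xyz[1],
                    "z_nm": xyz[2],
                    "name": atom.name,
                    "element": atom.element,
                    "res_name": atom.res_name,
                    "res_seq": atom.res_seq,
                    "chain_id": atom.chain_id,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Electrophysiology sweeps (TSV + JSON sidecar)
# ---------------------------------------------------------------------------

@dataclass
class SweepTrace:
    """One fast-application current sweep.

    ``current`` is in pA with inward current negative (physiological sign
    convention); ``app_on``/``app_off`` bound the agonist-application window
    in seconds on the same clock as ``times``.
    """

    times: np.ndarray  # s
    current: np.ndarray  # pA, inward negative
    rate: float  # Hz
    app_on: float  # s
    app_off: float  # s
    cell_id: str = ""
    condition: str = ""
    sweep_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.times.shape != self.current.shape or self.times.ndim != 1:
            raise ValueError("times and current must be equal-length 1-D arrays")
        if len(self.times) < 2:
            raise ValueError("sweep needs at least two samples")
        period = 1.0 / self.rate
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise FormatError("sweep times must be strictly increasing")
        if np.max(np.abs(dt - period)) > period:  # within one sample period
            raise FormatError("sampling is non-uniform beyond one sample-period tolerance")
        if not self.app_on < self.app_off:
            raise ValueError("app_on must precede app_off")
        if self.app_off > self.times[-1] + period:
            raise ValueError("application window extends past the trace")

    @property
    def period(self) -> float:
        return 1.0 / self.rate

    def with_current(self, current: np.ndarray) -> "SweepTrace":
        return replace(self, current=np.asarray(current, dtype=float))


def read_sweeps(path: str | Path, meta: str | Path) -> list[SweepTrace]:
    """Read current sweeps from TSV plus a JSON metadata sidecar.

    The TSV needs ``time_s`` and ``current_pA`` columns; an optional
    ``sweep_id`` column separates concatenated sweeps.  The sidecar must
    provide ``app_on_s`` and ``app_off_s`` and may provide ``cell_id`` and
    ``condition``.  The sampling rate is inferred from the median interval.
    """
    path = Path(path)
    with open(meta) as fh:
        side = json.load(fh)
    for key in ("app_on_s", "app_off_s"):
        if key not in side:
            raise ConfigError(f"{meta}: sidecar missing required key {key!r}")

    df = pd.read_csv(path, sep="\t")
    for col in ("time_s", "current_pA"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")

    if "sweep_id" in df.columns:
        blocks = [(str(k), g) for k, g in df.groupby("sweep_id", sort=True)]
    else:
        blocks = [("", df)]

    traces = []
    for sweep_id, g in blocks:
        t = g["time_s"].to_numpy(dtype=float)
        i = g["current_pA"].to_numpy(dtype=float)
        if len(t) < 2:
            raise FormatError(f"{path}: sweep {sweep_id!r} has fewer than 2 samples")
        rate = 1.0 / float(np.median(np.diff(t)))
        traces.append(
            SweepTrace(
                times=t,
                current=i,
                rate=rate,
                app_on=float(side["app_on_s"]),
                app_off=float(side["app_off_s"]),
                cell_id=str(side.get("cell_id", "")),
                condition=str(side.get("condition", "")),
                sweep_id=sweep_id,
            )
        )
    return traces


def write_sweeps(
    traces: Sequence[SweepTrace], path: str | Path, meta: str | Path | None = None
) -> None:
    """Write sweeps as TSV (+ optional JSON sidecar from the first trace)."""
    rows = []
    multi = len(traces) > 1
    for k, tr in enumerate(traces):
        block = pd.DataFrame({"time_s": tr.times, "current_pA": tr.current})
        if multi or tr.sweep_id:
            block.insert(0, "sweep_id", tr.sweep_id or f"sweep{k:03d}")
        rows.append(block)
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.10g")
    if meta is not None:
        first = traces[0]
        with open(meta, "w") as fh:
            json.dump(
                {
                    "app_on_s": first.app_on,
                    "app_off_s": first.app_off,
                    "cell_id": first.cell_id,
                    "condition": first.condition,
                },
                fh,
                indent=1,
            )
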