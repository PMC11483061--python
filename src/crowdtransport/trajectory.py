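"""Particle-trajectory container, readers, unwrapping and equilibration cut.

The in-memory model is deliberately minimal: frames of coordinates in a
cubic periodic box, plus per-particle labels (molecule id, residue index,
atom class, mass).  Standard MD formats (PDB topology + DCD/XTC
coordinates) are read through MDAnalysis; a self-describing plain-text
fixture format is provided for synthetic data and tests.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Trajectory", "LabelRules", "TrajectoryError",
    "load_trajectory", "read_fixture", "write_fixture",
    "discard_equilibration",
]

#: Atom-class vocabulary.  "calpha" is implicitly heavy; "other" covers
#: hydrogens and anything excluded from contact analysis.
ATOM_CLASSES = ("calpha", "heavy", "solvent", "other")

_TIME_RTOL = 1e-6


class TrajectoryError(ValueError):
    """Malformed or inconsistent trajectory input."""


@dataclass
class Trajectory:
    """Frames of labeled particle coordinates in a cubic periodic box.

    Attributes
    ----------
    times : ndarray, shape (n_frames,)
        Frame times in ns, strictly increasing and uniformly spaced.
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Coordinates in Å.
    box : ndarray, shape (n_frames,)
        Cubic box edge L per frame, Å.
    mol_ids, residue_ids : int ndarrays, shape (n_atoms,)
    atom_class : str ndarray, shape (n_atoms,)
        One of ``"calpha" | "heavy" | "solvent" | "other"``.
    masses : ndarray, shape (n_atoms,)
    wrapped : bool
        True if coordinates are folded into the primary box.
    """

    times: np.ndarray
    coords: np.ndarray
    box: np.ndarray
    mol_ids: np.ndarray
    residue_ids: np.ndarray
    atom_class: np.ndarray
    masses: np.ndarray | None = None
    wrapped: bool = True
    ground_truth: "object | None" = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.mol_ids = np.asarray(self.mol_ids, dtype=int)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.atom_class = np.asarray(self.atom_class, dtype="U8")
        if self.masses is None:
            self.masses = np.ones(self.n_atoms)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError("coords must have shape (n_frames, n_atoms, 3)")
        if self.times.shape != (self.n_frames,):
            raise TrajectoryError("times length does not match frame count")
        if self.box.shape != (self.n_frames,):
            raise TrajectoryError("box length does not match frame count")
        for arr, name in ((self.mol_ids, "mol_ids"),
                          (self.residue_ids, "residue_ids"),
                          (self.atom_class, "atom_class"),
                          (self.masses, "masses")):
            if arr.shape != (self.n_atoms,):
                raise TrajectoryError(f"{name} length does not match atom count")
        bad = set(np.unique(self.atom_class)) - set(ATOM_CLASSES)
        if bad:
            raise TrajectoryError(f"unknown atom classes: {sorted(bad)}")
        if self.n_frames > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise TrajectoryError("times must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=_TIME_RTOL, atol=0):
                raise TrajectoryError("frame spacing is not uniform")
        if np.any(self.box <= 0):
            raise TrajectoryError("box edge must be positive")

    # -- basic properties -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def dt(self) -> float:
        """Frame spacing in ns."""
        if self.n_frames < 2:
            raise TrajectoryError("need >= 2 frames for a frame spacing")
        return float(self.times[1] - self.times[0])

    @property
    def molecules(self) -> np.ndarray:
        return np.unique(self.mol_ids)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.isin(self.atom_class, ("heavy", "calpha"))

    @property
    def calpha_mask(self) -> np.ndarray:
        return self.atom_class == "calpha"

    def mean_box(self) -> float:
        """Mean-L reduction of per-frame box edges (NPT fluctuations)."""
        return float(self.box.mean())

    # -- selections -------------------------------------------------------
    def atoms_of(self, mol_id: int, heavy_only: bool = False) -> np.ndarray:
        mask = self.mol_ids == mol_id
        if heavy_only:
            mask &= self.heavy_mask
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise TrajectoryError(f"molecule {mol_id} selects no atoms")
        return idx

    def center_of_mass(self, mol_id: int) -> np.ndarray:
        """Mass-weighted center of a molecule, shape (n_frames, 3).

        Requires unwrapped coordinates to be meaningful across the box
        boundary; callers computing MSDs must unwrap first.
        """
        idx = self.atoms_of(mol_id)
        m = self.masses[idx]
        return np.einsum("fij,i->fj", self.coords[:, idx, :], m) / m.sum()

    def time_slice(self, mask: np.ndarray) -> "Trajectory":
        return replace(self, times=self.times[mask],
                       coords=self.coords[mask], box=self.box[mask])

    # -- periodic wrapping ------------------------------------------------
    def wrap(self) -> "Trajectory":
        """Fold coordinates into [0, L) per frame."""
        L = self.box[:, None, None]
        return replace(self, coords=np.mod(self.coords, L), wrapped=True)

    def unwrap(self) -> "Trajectory":
        return unwrap(self)


def unwrap(traj: Trajectory) -> Trajectory:
    """Undo periodic wrapping by minimum-image continuation.

    Assumes sampling is dense enough that no true per-frame displacement
    reaches L/2; an apparent corrected jump at (or numerically
    indistinguishable from) L/2 is reported as an error naming the
    particle and frame.
    """
    if not traj.wrapped:
        raise TrajectoryError("trajectory is already unwrapped")
    if traj.n_frames < 2:
        return replace(traj, wrapped=False)
    disp = np.diff(traj.coords, axis=0)
    L = traj.box[1:, None, None]
    disp = disp - L * np.round(disp / L)
    bad = np.abs(disp) >= 0.499 * L
    if np.any(bad):
        f, p, _ = np.argwhere(bad)[0]
        raise TrajectoryError(
            f"apparent jump >= L/2 for particle {p} between frames "
            f"{f} and {f + 1}; sampling too sparse to unwrap")
    coords = np.concatenate(
        [traj.coords[:1], traj.coords[0] + np.cumsum(disp, axis=0)], axis=0)
    return replace(traj, coords=coords, wrapped=False)


def discard_equilibration(obj, t_cut: float):
    """Drop all samples with time < ``t_cut`` (ns).

    Works for any container exposing ``times`` and ``time_slice``
    (Trajectory, PressureSeries).  An empty result is an error.
    """
    if t_cut < 0:
        raise ValueError("t_cut must be >= 0")
    times = np.asarray(obj.times)
    mask = times >= t_cut
    if not mask.any():
        raise ValueError(
            f"t_cut={t_cut} ns is beyond the final sample at {times[-1]} ns")
    return obj.time_slice(mask)


# ---------------------------------------------------------------------------
# Label rules for standard-format topologies
# ---------------------------------------------------------------------------

@dataclass
class LabelRules:
    """How topology atoms map to molecules and atom classes.

    Molecule grouping is supplied, never inferred from geometry: the
    default groups by MDAnalysis fragment (bonded unit) when bonds are
    available and by segment otherwise.  ``merge`` joins named groups
    into one diffusing unit (e.g. a homo-dimer counted as one crowder).
    """

    group_by: str = "auto"          # "auto" | "fragment" | "segment" | "residue"
    merge: Sequence[Sequence[int]] = ()
    solvent_resnames: Sequence[str] = ("HOH", "WAT", "TIP3", "SOL", "SPC")
    calpha_names: Sequence[str] = ("CA",)

    def molecule_ids(self, universe) -> np.ndarray:
        mode = self.group_by
        if mode == "auto":
            try:
                universe.atoms.fragments
                mode = "fragment"
            except Exception:
                mode = "segment"
        if mode == "fragment":
            raw = universe.atoms.fragindices
        elif mode == "segment":
            raw = universe.atoms.segindices
        elif mode == "residue":
            raw = universe.atoms.resindices
        else:
            raise ValueError(f"unknown group_by mode {mode!r}")
        ids = np.asarray(raw, dtype=int).copy()
        for group in self.merge:
            group = sorted(group)
            ids[np.isin(ids, group)] = group[0]
        return ids


def _classify_atoms(universe, rules: LabelRules) -> np.ndarray:
    names = universe.atoms.names
    resnames = universe.atoms.resnames
    try:
        masses = universe.atoms.masses
        is_h = masses < 1.5
    except Exception:
        is_h = np.char.startswith(np.char.upper(names), "H")
    classes = np.full(len(names), "heavy", dtype="U8")
    classes[is_h] = "other"
    classes[np.isin(names, tuple(rules.calpha_names)) & ~is_h] = "calpha"
    classes[np.isin(resnames, tuple(rules.solvent_resnames))] = "solvent"
    return classes


def load_trajectory(topology_path, coordinate_paths,
                    label_rules: LabelRules | None = None) -> Trajectory:
    """Read a PDB topology plus DCD/XTC coordinates into a Trajectory.

    The box must be cubic in every frame (all the finite-size
    corrections assume a single edge length L).
    """
    import MDAnalysis as mda

    rules = label_rules or LabelRules()
    if isinstance(coordinate_paths, (str, Path)):
        coordinate_paths = [coordinate_paths]
    coordinate_paths = [str(p) for p in coordinate_paths]
    for p in [str(topology_path)] + coordinate_paths:
        if not Path(p).exists():
            raise TrajectoryError(f"file not found: {p}")
    try:
        universe = mda.Universe(str(topology_path), *coordinate_paths)
    except Exception as exc:
        raise TrajectoryError(f"unreadable trajectory input: {exc}") from exc

    mol_ids = rules.molecule_ids(universe)
    residue_ids = np.asarray(universe.atoms.resindices, dtype=int)
    classes = _classify_atoms(universe, rules)
    try:
        masses = np.asarray(universe.atoms.masses, dtype=float)
    except Exception:
        masses = np.ones(len(universe.atoms))

    times, coords, box = [], [], []
    try:
        for i, ts in enumerate(universe.trajectory):
            dims = ts.dimensions
            if dims is None or np.any(dims[:3] <= 0):
                raise TrajectoryError(f"frame {i}: missing box dimensions")
            a, b, c, al, be, ga = dims
            if not (np.allclose([al, be, ga], 90.0, atol=1e-3)
                    and np.allclose([a, b], c, rtol=1e-6)):
                raise TrajectoryError(
                    f"frame {i}: non-cubic box {dims[:3]} rejected")
            times.append(ts.time / 1000.0)   # MDAnalysis uses ps
            coords.append(ts.positions.astype(float).copy())
            box.append(float(a))
    except TrajectoryError:
        raise
    except Exception as exc:
        raise TrajectoryError(
            f"error reading coordinate frame {len(times)}: {exc}") from exc

    return Trajectory(np.asarray(times), np.asarray(coords), np.asarray(box),
                      mol_ids, residue_ids, classes, masses, wrapped=True)


# ---------------------------------------------------------------------------
# Plain-text fixture format
# ---------------------------------------------------------------------------

_FIXTURE_MAGIC = "# crowdtransport-trajectory v1"


def write_fixture(traj: Trajectory, path) -> None:
    """Write the self-describing columnar text fixture format."""
    buf = io.StringIO()
    buf.write(_FIXTURE_MAGIC + "\n")
    buf.write(f"# wrapped: {str(traj.wrapped).lower()}\n")
    buf.write(f"# n_atoms: {traj.n_atoms}\n")
    buf.write("# atoms: mol res class mass\n")
    for m, r, c, w in zip(traj.mol_ids, traj.residue_ids,
                          traj.atom_class, traj.masses):
        buf.write(f"{m} {r} {c} {w:.10g}\n")
    for f in range(traj.n_frames):
        buf.write(f"# frame: t={traj.times[f]:.10g} L={traj.box[f]:.10g}\n")
        np.savetxt(buf, traj.coords[f], fmt="%.10g")
    Path(path).write_text(buf.getvalue())


def read_fixture(path) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != _FIXTURE_MAGIC:
        raise TrajectoryError(f"{path}: not a trajectory fixture file")
    wrapped = lines[1].split(":")[1].strip() == "true"
    n_atoms = int(lines[2].split(":")[1])
    i = 4
    mol_ids, residue_ids, classes, masses = [], [], [], []
    for _ in range(n_atoms):
        m, r, c, w = lines[i].split()
        mol_ids.append(int(m)); residue_ids.append(int(r))
        classes.append(c); masses.append(float(w))
        i += 1
    times, boxes, frames = [], [], []
    while i < len(lines):
        header = lines[i]
        if not header.startswith("# frame:"):
            raise TrajectoryError(f"{path}: malformed frame header at line {i + 1}")
        fields = dict(tok.split("=") for tok in header.split()[2:])
        times.append(float(fields["t"])); boxes.append(float(fields["L"]))
        i += 1
        rows = []
        for _ in range(n_atoms):
            if i >= len(lines) or lines[i].startswith("#"):
                raise TrajectoryError(
                    f"{path}: truncated frame {len(frames)} "
                    f"(expected {n_atoms} atoms, got {len(rows)})")
            rows.append([float(x) for x in lines[i].split()])
            i += 1
        frames.append(rows)
    return Trajectory(np.asarray(times), np.asarray(frames, dtype=float),
                      np.asarray(boxes), np.asarray(mol_ids),
                      np.asarray(residue_ids), np.asarray(classes, dtype="U8"),
                      np.asarray(masses), wrapped=wrapped)
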