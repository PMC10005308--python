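"""Core trajectory container shared by all analysis modules.

A :class:`Trajectory` holds per-frame positions (nm), box vectors (nm) and
times (ns) together with a static :class:`Topology` mapping each atom to a
species, a molecule, an atom name, a mass (amu) and a leaflet label.
The membrane normal is an axis index (default z).
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass

import numpy as np

from .exceptions import SelectionError

LEAFLET_LABELS = ("upper", "lower", "solvent")


@dataclass
class Topology:
    """Static per-atom annotation."""

    species: np.ndarray      # str, (n_atoms,)
    molecule_id: np.ndarray  # int, (n_atoms,)
    atom_name: np.ndarray    # str, (n_atoms,)
    mass: np.ndarray         # amu, (n_atoms,)
    leaflet: np.ndarray      # {"upper","lower","solvent"}, (n_atoms,)

    def __post_init__(self) -> None:
        self.species = np.asarray(self.species, dtype=object)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.mass = np.asarray(self.mass, dtype=float)
        self.leaflet = np.asarray(self.leaflet, dtype=object)
        n = len(self.species)
        for arr in (self.molecule_id, self.atom_name, self.mass, self.leaflet):
            if len(arr) != n:
                raise ValueError("topology arrays must have equal length")
        bad = set(self.leaflet) - set(LEAFLET_LABELS)
        if bad:
            raise ValueError(f"unknown leaflet labels: {sorted(bad)}")

    @property
    def n_atoms(self) -> int:
        return len(self.species)


@dataclass
class Trajectory:
    """Frames of positions/box/time plus a topology.

    Attributes
    ----------
    positions : ndarray, shape (n_frames, n_atoms, 3), nm
    box : ndarray, shape (n_frames, 3), nm (orthorhombic)
    time : ndarray, shape (n_frames,), ns
    topology : Topology
    normal_axis : int
        Index of the membrane normal axis (default 2, i.e. z).
    """

    positions: np.ndarray
    box: np.ndarray
    time: np.ndarray
    topology: Topology
    normal_axis: int = 2

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        if self.positions.shape[1] != self.topology.n_atoms:
            raise ValueError("positions second axis must match topology size")
        if self.box.shape != (self.n_frames, 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if self.time.shape != (self.n_frames,):
            raise ValueError("time must have shape (n_frames,)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if np.any(self.box <= 0):
            raise ValueError("box components must be positive")

    # ------------------------------------------------------------------ info
    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.n_frames else 0.0

    # ------------------------------------------------------------- selection
    def select(
        self,
        species: str | None = None,
        name: str | None = None,
        leaflet: str | None = None,
    ) -> np.ndarray:
        """Return atom indices matching the given criteria.

        ``name`` accepts fnmatch-style patterns (e.g. ``"C*"``).
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        top = self.topology
        if species is not None:
            mask &= np.array([s == species for s in top.species])
        if name is not None:
            mask &= np.array(
                [fnmatch.fnmatchcase(str(a), name) for a in top.atom_name]
            )
        if leaflet is not None:
            mask &= np.array([l == leaflet for l in top.leaflet])
        return np.flatnonzero(mask)

    def require(self, err: str = "selection is empty", **kwargs) -> np.ndarray:
        idx = self.select(**kwargs)
        if idx.size == 0:
            raise SelectionError(err)
        return idx

    def discard_before(self, t0: float) -> "Trajectory":
        """Keep frames with time >= t0 (half-open interval [t0, end])."""
        keep = self.time >= t0
        return Trajectory(
            self.positions[keep], self.box[keep], self.time[keep],
            self.topology, self.normal_axis,
        )

    # --------------------------------------------------------------- helpers
    def molecule_atom_indices(self, atom_indices: np.ndarray) -> dict[int, np.ndarray]:
        """Group a flat atom-index array by molecule id (insertion order)."""
        out: dict[int, list[int]] = {}
        mids = self.topology.molecule_id
        for i in atom_indices:
            out.setdefault(int(mids[i]), []).append(int(i))
        return {m: np.array(v) for m, v in out.items()}

    def molecule_com(self, atom_indices: np.ndarray) -> np.ndarray:
        """Mass-weighted COM of the given atoms for every frame, (n_frames, 3)."""
        m = self.topology.mass[atom_indices]
        w = m / m.sum()
        return np.einsum("fad,a->fd", self.positions[:, atom_indices, :], w)

    def bilayer_com(self) -> np.ndarray:
        """Membrane (non-solvent) COM per frame, (n_frames, 3)."""
        idx = np.flatnonzero(
            np.array([l != "solvent" for l in self.topology.leaflet])
        )
        if idx.size == 0:
            raise SelectionError("no non-solvent atoms to define the bilayer COM")
        return self.molecule_com(idx)


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement(s) d for an
    orthorhombic box (broadcasts over leading axes)."""
    return d - box * np.round(d / box)
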