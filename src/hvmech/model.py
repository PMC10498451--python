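"""Core data model: bead topologies, frames, trajectories and column tables.

The substrate of every analysis in the package is a coarse-grained bead
description of a flat bilayer whose normal is the z axis.  A
:class:`BeadTopology` carries the time-independent description (names,
molecule membership, masses, profile weights, bonds); a :class:`BeadFrame`
carries one snapshot (coordinates in nm plus the orthorhombic box); a
:class:`Trajectory` is an ordered frame sequence.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np


class MoleculeKind(enum.Enum):
    LIPID = "lipid"
    POLYMER = "polymer"
    WATER = "water"
    PEPTIDE = "peptide"
    OTHER = "other"

    @property
    def is_membrane(self) -> bool:
        return self in (MoleculeKind.LIPID, MoleculeKind.POLYMER)


@dataclass
class BeadTopology:
    """Per-bead static description of a coarse-grained system.

    Parameters
    ----------
    bead_names : array of str, one per bead.
    molecule_ids : integer molecule index per bead.
    molecule_kinds : :class:`MoleculeKind` per bead.
    masses : atomic-mass units per bead.  Coarse-grained beads default to
        72 amu (four heavy atoms per bead at the standard 4:1 mapping).
    weights : non-negative per-bead weighting used by density profiles
        (mass by default; an electron count may be substituted).
    bonds : (n_bonds, 2) integer array of bead-id pairs.
    """

    bead_names: np.ndarray
    molecule_ids: np.ndarray
    molecule_kinds: np.ndarray  # object array of MoleculeKind
    masses: np.ndarray
    weights: np.ndarray
    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    def __post_init__(self) -> None:
        n = len(self.bead_names)
        self.bead_names = np.asarray(self.bead_names, dtype=object)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        self.molecule_kinds = np.asarray(self.molecule_kinds, dtype=object)
        self.masses = np.asarray(self.masses, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        for arr, name in (
            (self.molecule_ids, "molecule_ids"),
            (self.molecule_kinds, "molecule_kinds"),
            (self.masses, "masses"),
            (self.weights, "weights"),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != bead count {n}")
        if np.any(self.weights < 0):
            raise ValueError("bead weights must be non-negative")
        if self.bonds.size and (self.bonds.min() < 0 or self.bonds.max() >= n):
            raise ValueError("bond references a bead id outside [0, n_beads)")

    @property
    def n_beads(self) -> int:
        return len(self.bead_names)

    def kind_mask(self, *kinds: MoleculeKind) -> np.ndarray:
        return np.array([k in kinds for k in self.molecule_kinds], dtype=bool)

    @property
    def membrane_mask(self) -> np.ndarray:
        return np.array([k.is_membrane for k in self.molecule_kinds], dtype=bool)


@dataclass
class BeadFrame:
    """One snapshot: (n, 3) coordinates in nm, orthorhombic box lengths, time in ps."""

    coordinates: np.ndarray
    box: np.ndarray  # (Lx, Ly, Lz) in nm
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if np.any(self.box <= 0):
            raise ValueError(f"box lengths must be positive, got {self.box}")

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[0]

    @property
    def area_xy(self) -> float:
        return float(self.box[0] * self.box[1])

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def copy(self) -> "BeadFrame":
        return BeadFrame(self.coordinates.copy(), self.box.copy(), self.time)


@dataclass
class Trajectory:
    """Ordered sequence of frames with a constant bead count."""

    frames: list[BeadFrame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n = self.frames[0].n_beads
        times = [f.time for f in self.frames]
        for f in self.frames:
            if f.n_beads != n:
                raise ValueError("bead count varies across frames")
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[BeadFrame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> BeadFrame:
        return self.frames[i]

    @property
    def n_beads(self) -> int:
        return self.frames[0].n_beads

    @property
    def timestep(self) -> float:
        if len(self.frames) < 2:
            return 0.0
        return self.frames[1].time - self.frames[0].time

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def coordinate_stack(self) -> np.ndarray:
        """(n_frames, n_beads, 3) array of coordinates."""
        return np.stack([f.coordinates for f in self.frames])

    @classmethod
    def from_coordinates(
        cls,
        coords: np.ndarray,
        box: Sequence[float],
        timestep: float = 1.0,
        t0: float = 0.0,
    ) -> "Trajectory":
        coords = np.asarray(coords, dtype=float)
        frames = [
            BeadFrame(c, np.asarray(box, dtype=float), t0 + i * timestep)
            for i, c in enumerate(coords)
        ]
        return cls(frames)


@dataclass
class ColumnTable:
    """Rectangular numeric table with named, unit-annotated columns."""

    column_names: list[str]
    data: np.ndarray
    units: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.size == 0:
            self.data = self.data.reshape(0, len(self.column_names))
        if self.data.ndim != 2 or self.data.shape[1] != len(self.column_names):
            raise ValueError("table data must be rectangular, one column per name")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("table contains non-finite values")
        if self.units is not None and len(self.units) != len(self.column_names):
            raise ValueError("one unit string per column required")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.data[:, self.column_names.index(name)]
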