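"""Reading and writing coordinate and table formats.

GRO coordinate files are parsed and written through MDAnalysis; this module
adds the structural validation (line-numbered errors for malformed files),
the nm unit convention, and the mapping from residue names to
:class:`~hvmech.model.MoleculeKind`.  XVG-style whitespace tables ('#'/'@'
comments) are read with :func:`numpy.loadtxt`.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import BeadFrame, BeadTopology, ColumnTable, MoleculeKind

__all__ = [
    "ParseError",
    "read_gro",
    "write_gro",
    "read_xvg_table",
    "write_xvg_table",
    "table_to_csv",
]

ANGSTROM_PER_NM = 10.0

#: Default residue-name -> molecule-kind mapping.  Martini water is "W";
#: the hybrid-membrane components are POPC (lipid) and PBD-b-PEO (polymer).
DEFAULT_KIND_MAP: dict[str, MoleculeKind] = {
    "W": MoleculeKind.WATER,
    "WN": MoleculeKind.WATER,
    "SOL": MoleculeKind.WATER,
    "HOH": MoleculeKind.WATER,
    "POPC": MoleculeKind.LIPID,
    "DOPC": MoleculeKind.LIPID,
    "DPPC": MoleculeKind.LIPID,
    "LIP": MoleculeKind.LIPID,
    "PBD": MoleculeKind.POLYMER,
    "PEO": MoleculeKind.POLYMER,
    "PBDP": MoleculeKind.POLYMER,
    "POLY": MoleculeKind.POLYMER,
    "WALP": MoleculeKind.PEPTIDE,
}

#: Standard Martini coarse-grained bead mass, amu (4 heavy atoms per bead).
DEFAULT_BEAD_MASS = 72.0


class ParseError(ValueError):
    """A coordinate or table file violated its format."""


def _validate_gro_structure(path: Path) -> int:
    """Cheap structural check producing line-numbered errors; returns atom count."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: GRO file needs title, atom count and box lines")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError:
        raise ParseError(f"{path}, line 2: atom count {lines[1]!r} is not an integer")
    if n_atoms < 0:
        raise ParseError(f"{path}, line 2: negative atom count {n_atoms}")
    if len(lines) < n_atoms + 3:
        raise ParseError(
            f"{path}, line {len(lines) + 1}: declared {n_atoms} atoms but file "
            f"ends after {max(len(lines) - 3, 0)} atom records"
        )
    box_line = lines[n_atoms + 2].split()
    if len(box_line) < 3:
        raise ParseError(f"{path}, line {n_atoms + 3}: box line needs >= 3 fields")
    if len(box_line) > 3:
        # GRO triclinic boxes carry 9 fields; off-diagonal terms must vanish.
        off_diag = [float(v) for v in box_line[3:]]
        if any(abs(v) > 1e-9 for v in off_diag):
            raise ParseError(
                f"{path}, line {n_atoms + 3}: triclinic box not supported "
                "(only orthorhombic boxes are handled)"
            )
    return n_atoms


def read_gro(
    path: str | Path,
    kind_map: Mapping[str, MoleculeKind] | None = None,
    bead_mass: float = DEFAULT_BEAD_MASS,
) -> tuple[BeadTopology, BeadFrame]:
    """Read a GRO coordinate file.

    Coordinates are returned in nm.  Residue names are mapped to molecule
    kinds through ``kind_map`` (unknown names become ``OTHER``); every bead
    receives ``bead_mass`` since GRO carries no masses, and profile weights
    default to the masses.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_gro_structure(path)
    kind_map = dict(DEFAULT_KIND_MAP if kind_map is None else kind_map)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            universe = mda.Universe(str(path), to_guess=())
        except Exception as exc:  # surface MDAnalysis failures as parse errors
            raise ParseError(f"{path}: {exc}") from exc

    atoms = universe.atoms
    coords = atoms.positions.astype(float) / ANGSTROM_PER_NM
    dims = universe.dimensions
    if dims is None or np.all(dims[:3] == 0):
        raise ParseError(f"{path}: missing or zero box")
    if not np.allclose(dims[3:], 90.0):
        raise ParseError(f"{path}: triclinic box not supported")
    box = dims[:3].astype(float) / ANGSTROM_PER_NM

    resnames = atoms.resnames
    kinds = np.array(
        [kind_map.get(rn.strip().upper(), MoleculeKind.OTHER) for rn in resnames],
        dtype=object,
    )
    masses = np.full(len(atoms), float(bead_mass))
    topology = BeadTopology(
        bead_names=np.array([n.strip() for n in atoms.names], dtype=object),
        molecule_ids=atoms.resindices.astype(int),
        molecule_kinds=kinds,
        masses=masses,
        weights=masses.copy(),
    )
    frame = BeadFrame(coordinates=coords, box=box, time=0.0)
    return topology, frame


def write_gro(
    path: str | Path,
    topology: BeadTopology,
    frame: BeadFrame,
    resnames: Sequence[str] | None = None,
    title: str = "hvmech frame",
) -> None:
    """Write a frame as a GRO file (fixed columns, nm, 3 decimals)."""
    import MDAnalysis as mda

    if frame.n_beads != topology.n_beads:
        raise ValueError("frame and topology bead counts differ")
    if resnames is None:
        kind_names = {
            MoleculeKind.LIPID: "POPC",
            MoleculeKind.POLYMER: "PBDP",
            MoleculeKind.WATER: "W",
            MoleculeKind.PEPTIDE: "WALP",
            MoleculeKind.OTHER: "UNK",
        }
        resnames = [kind_names[k] for k in topology.molecule_kinds]

    mol_ids = topology.molecule_ids
    unique_ids, res_index = np.unique(mol_ids, return_inverse=True)
    n_res = len(unique_ids)
    first_bead = np.searchsorted(mol_ids, unique_ids)
    per_res_names = [resnames[i] for i in first_bead]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe.empty(
            topology.n_beads,
            n_residues=n_res,
            atom_resindex=res_index,
            residue_segindex=np.zeros(n_res, dtype=int),
            trajectory=True,
        )
        universe.add_TopologyAttr("names", list(topology.bead_names))
        universe.add_TopologyAttr("resnames", per_res_names)
        universe.add_TopologyAttr("resids", (unique_ids + 1).tolist())
        universe.atoms.positions = frame.coordinates * ANGSTROM_PER_NM
        universe.dimensions = np.array(
            [*(frame.box * ANGSTROM_PER_NM), 90.0, 90.0, 90.0]
        )
        universe.atoms.write(str(path))


def read_xvg_table(
    path: str | Path,
    column_names: Sequence[str] | None = None,
) -> ColumnTable:
    """Read a whitespace-delimited numeric table, ignoring '#'/'@' comment lines.

    Column names default to legends parsed from ``@ sN legend "..."`` lines
    when present, else ``col0, col1, ...``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    legends: dict[int, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                continue
            if line.startswith("@"):
                parts = line.split('"')
                tokens = line.split()
                if len(tokens) >= 3 and tokens[1].startswith("s") and tokens[2] == "legend":
                    try:
                        legends[int(tokens[1][1:])] = parts[1]
                    except (ValueError, IndexError):
                        pass
                continue
            values = []
            for token in line.split():
                try:
                    value = float(token)
                except ValueError:
                    raise ParseError(
                        f"{path}, line {lineno}: non-numeric token {token!r}"
                    )
                if not np.isfinite(value):
                    raise ParseError(
                        f"{path}, line {lineno}: non-finite value {token!r}"
                    )
                values.append(value)
            if rows and len(values) != len(rows[0]):
                raise ParseError(
                    f"{path}, line {lineno}: expected {len(rows[0])} columns, "
                    f"got {len(values)}"
                )
            rows.append(values)

    if not rows:
        names = list(column_names) if column_names else []
        return ColumnTable(column_names=names, data=np.empty((0, len(names))))

    data = np.array(rows, dtype=float)
    n_cols = data.shape[1]
    if column_names is not None:
        if len(column_names) != n_cols:
            raise ParseError(
                f"{path}: {len(column_names)} names given for {n_cols} columns"
            )
        names = list(column_names)
    else:
        names = ["col0"] + [legends.get(i, f"col{i + 1}") for i in range(n_cols - 1)]
    return ColumnTable(column_names=names, data=data)


def write_xvg_table(path: str | Path, table: ColumnTable, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# " + "  ".join(table.column_names) + "\n")
        np.savetxt(fh, table.data, fmt="%.8g")


def table_to_csv(path: str | Path, table: ColumnTable) -> None:
    pd.DataFrame(table.data, columns=table.column_names).to_csv(path, index=False)
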