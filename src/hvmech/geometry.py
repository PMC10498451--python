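"""Periodic-boundary utilities and leaflet assignment.

The membrane normal is the z axis by convention; boxes are orthorhombic.
"""
from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np

from .model import BeadFrame, BeadTopology, MoleculeKind, Trajectory

__all__ = ["unwrap_pbc", "wrap_to_box", "assign_leaflets", "membrane_midplane"]


def unwrap_pbc(trajectory: Trajectory, warn_fraction: float = 0.45) -> Trajectory:
    """Remove periodic jumps so coordinates are continuous in time.

    Each inter-frame displacement is replaced by its minimum image; this is
    correct as long as no bead moves further than half a box length between
    stored frames.  Steps longer than ``warn_fraction`` of the box trigger a
    warning naming the beads, since they suggest undersampled output.  The
    first frame is returned unchanged.
    """
    frames = trajectory.frames
    out = [frames[0].copy()]
    suspicious: set[int] = set()
    for prev_raw, cur in zip(frames[:-1], frames[1:]):
        box = cur.box
        step = cur.coordinates - prev_raw.coordinates
        step -= box * np.round(step / box)
        bad = np.any(np.abs(step) > warn_fraction * box, axis=1)
        suspicious.update(np.nonzero(bad)[0].tolist())
        out.append(BeadFrame(out[-1].coordinates + step, cur.box.copy(), cur.time))
    if suspicious:
        warnings.warn(
            "unwrap_pbc: displacement exceeded "
            f"{warn_fraction:.0%} of the box for beads {sorted(suspicious)[:10]}"
            f"{'...' if len(suspicious) > 10 else ''}; trajectory may be "
            "stored too infrequently for reliable unwrapping"
        )
    return Trajectory(out)


def wrap_to_box(frame: BeadFrame) -> BeadFrame:
    """Fold all coordinates into [0, L) in each dimension."""
    coords = np.mod(frame.coordinates, frame.box)
    return BeadFrame(coords, frame.box.copy(), frame.time)


def membrane_midplane(frame: BeadFrame, topology: BeadTopology) -> float:
    """z of the mass-weighted center of all membrane (lipid + polymer) beads."""
    mask = topology.membrane_mask
    if not mask.any():
        raise ValueError("no membrane beads (lipid or polymer) in topology")
    m = topology.masses[mask]
    z = frame.coordinates[mask, 2]
    return float(np.sum(m * z) / np.sum(m))


def assign_leaflets(
    frame: BeadFrame,
    topology: BeadTopology,
    head_bead_name: str | Sequence[str],
) -> dict[int, str]:
    """Label each membrane molecule ``"upper"`` or ``"lower"``.

    A molecule's leaflet is the sign of its head bead's z relative to the
    bilayer midplane (mass-weighted center of all membrane beads).  Molecules
    lacking the named head bead raise; an empty leaflet (monolayer input)
    warns.
    """
    if isinstance(head_bead_name, str):
        head_names = {head_bead_name}
    else:
        head_names = set(head_bead_name)
    midplane = membrane_midplane(frame, topology)

    labels: dict[int, str] = {}
    missing: list[int] = []
    mask = topology.membrane_mask
    mol_ids = topology.molecule_ids
    for mol in np.unique(mol_ids[mask]):
        sel = (mol_ids == mol) & mask
        head = sel & np.isin(topology.bead_names.astype(str), list(head_names))
        if not head.any():
            missing.append(int(mol))
            continue
        z_head = float(np.mean(frame.coordinates[head, 2]))
        labels[int(mol)] = "upper" if z_head >= midplane else "lower"
    if missing:
        raise ValueError(
            f"molecules without head bead {sorted(head_names)}: {missing[:20]}"
        )
    counts = {"upper": 0, "lower": 0}
    for v in labels.values():
        counts[v] += 1
    if counts["upper"] == 0 or counts["lower"] == 0:
        warnings.warn(
            f"one leaflet is empty (upper={counts['upper']}, "
            f"lower={counts['lower']}); input looks like a monolayer"
        )
    return labels


def leaflet_masks(
    topology: BeadTopology, labels: Mapping[int, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bead boolean masks (upper, lower) from per-molecule labels."""
    upper_mols = {m for m, lab in labels.items() if lab == "upper"}
    lower_mols = {m for m, lab in labels.items() if lab == "lower"}
    upper = np.array([m in upper_mols for m in topology.molecule_ids])
    lower = np.array([m in lower_mols for m in topology.molecule_ids])
    return upper, lower
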