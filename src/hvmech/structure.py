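"""Structural estimators: thickness, lateral area, density profiles,
order parameters, and 2D membrane maps with thin/thick classification.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .geometry import assign_leaflets, leaflet_masks
from .model import BeadFrame, BeadTopology, MoleculeKind, Trajectory

__all__ = [
    "ThicknessResult",
    "DensityProfile",
    "OrderParameterResult",
    "MembraneMap",
    "membrane_thickness",
    "area_per_molecule",
    "density_profile",
    "peak_to_peak",
    "order_parameter",
    "thickness_map",
    "map_smooth_fill",
    "thin_fraction",
]

#: Volume of one coarse-grained water bead (four waters), nm^3.
DEFAULT_WATER_BEAD_VOLUME = 0.12


@dataclass
class ThicknessResult:
    """Volume-based membrane thickness h = (V_box - V_water) / A_xy, nm."""

    h: float
    v_box: float
    v_water: float
    a_xy: float


@dataclass
class DensityProfile:
    """Depth profile of a per-bead weight, membrane center at z = 0.

    values are weight per nm^3 averaged over frames; the profile conserves
    the total frame weight: sum(values) * slab_volume == total weight.
    """

    z_centers: np.ndarray
    values: np.ndarray
    n_slices: int
    weight_kind: str
    slab_volume: float

    @property
    def total_weight(self) -> float:
        return float(np.sum(self.values) * self.slab_volume)


@dataclass
class OrderParameterResult:
    """Second-rank bond order parameter S_cd = 0.5 <3 cos^2(theta) - 1>.

    theta is measured between each bond vector and the membrane normal
    (z axis); S = 1 for bonds along z, -0.5 for in-plane bonds, 0 for an
    isotropic orientation distribution.
    """

    per_bond_s: np.ndarray
    mean_s: float
    theta_samples: np.ndarray


@dataclass
class MembraneMap:
    """Lateral 2D grid of a local membrane property (default 0.5 nm cells)."""

    values: np.ndarray  # (nx, ny); NaN marks empty cells
    grid_edge: float
    kind: str  # "thickness" | "density" | "scd" | ...
    fill_mask: np.ndarray | None = None  # True where a cell was fill-estimated

    @property
    def n_cells(self) -> int:
        return self.values.size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.values.shape
        x = (np.arange(nx) + 0.5) * self.grid_edge
        y = (np.arange(ny) + 0.5) * self.grid_edge
        return x, y


def membrane_thickness(
    frame: BeadFrame,
    topology: BeadTopology,
    water_bead_volume: float = DEFAULT_WATER_BEAD_VOLUME,
) -> ThicknessResult:
    """Average bilayer thickness by volume bookkeeping.

    The volume occupied by water (bead count times the per-bead volume) is
    subtracted from the box volume and the remainder divided by the lateral
    box area: h = (V_box - V_water) / A_xy.
    """
    if water_bead_volume <= 0:
        raise ValueError("water_bead_volume must be positive")
    n_water = int(np.sum(topology.kind_mask(MoleculeKind.WATER)))
    v_water = n_water * water_bead_volume
    v_box = frame.volume
    if v_water >= v_box:
        raise ValueError(
            f"water volume {v_water:.3f} nm^3 >= box volume {v_box:.3f} nm^3; "
            "membrane volume would be non-positive"
        )
    return ThicknessResult(
        h=(v_box - v_water) / frame.area_xy,
        v_box=v_box,
        v_water=v_water,
        a_xy=frame.area_xy,
    )


def area_per_molecule(frame: BeadFrame, n_per_leaflet: int) -> float:
    """Lateral box area divided by the number of molecules per leaflet (nm^2)."""
    if n_per_leaflet < 1:
        raise ValueError("n_per_leaflet must be >= 1")
    return frame.area_xy / n_per_leaflet


def _selection_mask(
    topology: BeadTopology,
    component_filter: np.ndarray | Callable[[BeadTopology], np.ndarray] | Sequence[MoleculeKind] | None,
) -> np.ndarray:
    if component_filter is None:
        return np.ones(topology.n_beads, dtype=bool)
    if callable(component_filter):
        mask = np.asarray(component_filter(topology), dtype=bool)
    elif len(component_filter) and isinstance(next(iter(component_filter)), MoleculeKind):
        mask = topology.kind_mask(*component_filter)
    else:
        mask = np.asarray(component_filter, dtype=bool)
    if mask.shape != (topology.n_beads,):
        raise ValueError("component filter must yield one boolean per bead")
    return mask


def density_profile(
    trajectory: Trajectory,
    topology: BeadTopology,
    weight_kind: str = "mass",
    n_slices: int = 200,
    component_filter=None,
) -> DensityProfile:
    """Depth density profile, averaged over frames.

    Every frame is recentered so the membrane center of mass sits at the
    middle of the box before slicing the box into ``n_slices`` z slabs.
    ``weight_kind`` selects the per-bead weight: "mass" (amu), "electron"
    (the topology's weight column), or "bead-count" (unity).  A component
    filter restricts the binned beads (per-component profiles) while the
    recentering always uses the full membrane.
    """
    if n_slices < 2:
        raise ValueError("need at least 2 slices")
    weights_all = {
        "mass": topology.masses,
        "electron": topology.weights,
        "bead-count": np.ones(topology.n_beads),
    }.get(weight_kind)
    if weights_all is None:
        raise ValueError(f"unknown weight_kind {weight_kind!r}")
    mask = _selection_mask(topology, component_filter)
    if not mask.any():
        raise ValueError("component filter selects no beads")

    box = trajectory[0].box
    for f in trajectory:
        if not np.allclose(f.box, box):
            raise ValueError("density_profile requires a constant box across frames")
    l_z = box[2]
    edges = np.linspace(0.0, l_z, n_slices + 1)
    mem = topology.membrane_mask
    if not mem.any():
        raise ValueError("no membrane beads to recenter on")
    m_mem = topology.masses[mem]

    acc = np.zeros(n_slices)
    for frame in trajectory:
        z = frame.coordinates[:, 2]
        com = np.sum(m_mem * z[mem]) / np.sum(m_mem)
        z_shifted = np.mod(z - com + l_z / 2.0, l_z)
        hist, _ = np.histogram(
            z_shifted[mask], bins=edges, weights=weights_all[mask]
        )
        acc += hist
    slab_volume = frame.area_xy * (l_z / n_slices)
    values = acc / (len(trajectory) * slab_volume)
    centers = 0.5 * (edges[:-1] + edges[1:]) - l_z / 2.0
    return DensityProfile(centers, values, n_slices, weight_kind, slab_volume)


def peak_to_peak(profile: DensityProfile, smooth: bool = True) -> float:
    """Distance between the two head-group density maxima (nm).

    Finds strict local maxima (after optional 3-point smoothing), takes the
    highest on each side of z = 0 (ties broken toward larger |z|), and
    returns their separation.  A unimodal profile raises, since there are
    no flanking head-group peaks.
    """
    v = profile.values.astype(float)
    if smooth and len(v) >= 3:
        v = np.convolve(v, np.ones(3) / 3.0, mode="same")
    z = profile.z_centers
    interior = np.arange(1, len(v) - 1)
    is_max = (v[interior] > v[interior - 1]) & (v[interior] >= v[interior + 1])
    peaks = interior[is_max]
    left = [p for p in peaks if z[p] < 0]
    right = [p for p in peaks if z[p] >= 0]
    if not left or not right:
        raise ValueError(
            "profile lacks local maxima on both sides of z=0 (unimodal?); "
            "peak-to-peak distance undefined"
        )

    def best(cands):
        vmax = max(v[p] for p in cands)
        ties = [p for p in cands if v[p] >= vmax * (1 - 1e-12)]
        return max(ties, key=lambda p: abs(z[p]))

    p_left, p_right = best(left), best(right)
    if min(v[p_left], v[p_right]) <= np.min(v[p_left : p_right + 1]):
        pass  # central trough exists by construction of two strict maxima
    return float(z[p_right] - z[p_left])


def order_parameter(
    trajectory: Trajectory,
    bond_list: np.ndarray | Sequence[tuple[int, int]],
) -> OrderParameterResult:
    """Bond order parameter against the membrane normal.

    Bond vectors use the minimum image in the frame's box; zero-length
    bonds are excluded with a warning.  The per-bond S is averaged over
    frames, and the mean over bonds and frames is reported.
    """
    bonds = np.asarray(bond_list, dtype=int).reshape(-1, 2)
    if bonds.size == 0:
        raise ValueError("empty bond list")
    n = trajectory.n_beads
    if bonds.min() < 0 or bonds.max() >= n:
        raise ValueError("bond references a bead outside the trajectory")

    s_sum = np.zeros(len(bonds))
    s_count = np.zeros(len(bonds))
    thetas = []
    dropped = 0
    for frame in trajectory:
        vec = frame.coordinates[bonds[:, 1]] - frame.coordinates[bonds[:, 0]]
        vec -= frame.box * np.round(vec / frame.box)
        norm = np.linalg.norm(vec, axis=1)
        ok = norm > 1e-12
        dropped += int(np.sum(~ok))
        cos_t = np.zeros(len(bonds))
        cos_t[ok] = vec[ok, 2] / norm[ok]
        s = 0.5 * (3.0 * cos_t**2 - 1.0)
        s_sum[ok] += s[ok]
        s_count[ok] += 1
        thetas.append(np.arccos(np.clip(np.abs(cos_t[ok]), -1, 1)))
    if dropped:
        warnings.warn(f"excluded {dropped} zero-length bond vectors")
    if not np.any(s_count > 0):
        raise ValueError("no valid bond vectors in any frame")
    valid = s_count > 0
    per_bond = np.full(len(bonds), np.nan)
    per_bond[valid] = s_sum[valid] / s_count[valid]
    mean_s = float(np.sum(s_sum) / np.sum(s_count))
    return OrderParameterResult(per_bond, mean_s, np.concatenate(thetas))


def thickness_map(
    frame: BeadFrame,
    topology: BeadTopology,
    head_bead_name: str | Sequence[str],
    grid_edge: float = 0.5,
    fill_bandwidth: float | None = None,
) -> MembraneMap:
    """Lateral map of the leaflet-to-leaflet head separation.

    The box cross-section is discretized into square cells of edge
    ``grid_edge`` (0.5 nm by default); each cell's thickness is the mean z
    of its upper-leaflet head beads minus the mean z of its lower-leaflet
    head beads.  Cells missing either leaflet are filled by non-local
    Gaussian weighted averaging (:func:`map_smooth_fill`) so the returned
    map has no empty cells; filled cells are flagged.
    """
    labels = assign_leaflets(frame, topology, head_bead_name)
    upper, lower = leaflet_masks(topology, labels)
    if not upper.any() or not lower.any():
        raise ValueError("both leaflets must be populated for a thickness map")
    if isinstance(head_bead_name, str):
        head_names = [head_bead_name]
    else:
        head_names = list(head_bead_name)
    head = np.isin(topology.bead_names.astype(str), head_names)

    lx, ly = frame.box[0], frame.box[1]
    nx = max(int(np.ceil(lx / grid_edge - 1e-9)), 1)
    ny = max(int(np.ceil(ly / grid_edge - 1e-9)), 1)
    xy = np.mod(frame.coordinates[:, :2], frame.box[:2])
    ix = np.minimum((xy[:, 0] / grid_edge).astype(int), nx - 1)
    iy = np.minimum((xy[:, 1] / grid_edge).astype(int), ny - 1)
    z = frame.coordinates[:, 2]

    sums = np.zeros((2, nx, ny))
    counts = np.zeros((2, nx, ny))
    for layer, mask in enumerate((upper & head, lower & head)):
        np.add.at(sums[layer], (ix[mask], iy[mask]), z[mask])
        np.add.at(counts[layer], (ix[mask], iy[mask]), 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_up = sums[0] / counts[0]
        mean_lo = sums[1] / counts[1]
    values = mean_up - mean_lo
    values[(counts[0] == 0) | (counts[1] == 0)] = np.nan
    raw = MembraneMap(values=values, grid_edge=grid_edge, kind="thickness")
    return map_smooth_fill(raw, bandwidth=fill_bandwidth or grid_edge)


def map_smooth_fill(mmap: MembraneMap, bandwidth: float | None = None) -> MembraneMap:
    """Fill empty map cells by non-local Gaussian-kernel weighted averaging.

    Every empty (NaN) cell receives the average of all non-empty cells
    weighted by exp(-d^2 / 2 bandwidth^2) of the center-to-center distance;
    non-empty cells are untouched.  Bandwidth defaults to one grid edge —
    the minimal smoothing consistent with leaving no empty cells.
    """
    if bandwidth is None:
        bandwidth = mmap.grid_edge
    values = mmap.values.copy()
    empty = np.isnan(values)
    if empty.all():
        raise ValueError("all map cells are empty; nothing to average from")
    if not empty.any():
        return MembraneMap(values, mmap.grid_edge, mmap.kind, np.zeros_like(empty))

    xc, yc = mmap.cell_centers()
    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    filled_pts = np.column_stack([gx[~empty], gy[~empty]])
    filled_vals = values[~empty]
    empty_pts = np.column_stack([gx[empty], gy[empty]])
    d2 = (
        (empty_pts[:, None, 0] - filled_pts[None, :, 0]) ** 2
        + (empty_pts[:, None, 1] - filled_pts[None, :, 1]) ** 2
    )
    w = np.exp(-d2 / (2.0 * bandwidth**2))
    # guard against total underflow for very distant cells
    wsum = w.sum(axis=1)
    nearest = np.argmin(d2, axis=1)
    est = np.where(
        wsum > 0, w @ filled_vals / np.where(wsum > 0, wsum, 1.0), filled_vals[nearest]
    )
    values[empty] = est
    return MembraneMap(values, mmap.grid_edge, mmap.kind, empty)


def thin_fraction(mmap: MembraneMap, threshold: float = 5.0) -> float:
    """Area fraction of the map with thickness at or below ``threshold`` (nm).

    The 5 nm (50 Angstrom) default separates lipid-like "thin" patches
    (collapsed polymer) from polymer-like "thick" ones in hybrid membranes.
    """
    if mmap.kind != "thickness":
        raise ValueError(f"thin_fraction needs a thickness map, got {mmap.kind!r}")
    if np.isnan(mmap.values).any():
        raise ValueError("map has empty cells; run map_smooth_fill first")
    return float(np.mean(mmap.values <= threshold))
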