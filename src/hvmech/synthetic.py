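"""Synthetic ensembles with the exact statistical structure each estimator
assumes, so every analysis is verifiable by closed-loop parameter recovery
without molecular dynamics.

Each generator is deterministic under a fixed seed and returns its ground
truth alongside the data:

* Gaussian lateral-area series with the variance implied by a target k_A;
* binned stress profiles with prescribed zeroth/first/second moments;
* lattice-built bilayer frames with exact per-cell thickness, bond-tilt
  and leaflet ground truth;
* umbrella-window samples drawn exactly (grid inverse-CDF) from the biased
  Boltzmann density of a prescribed PMF;
* independent 2D Brownian walks at a prescribed diffusion coefficient;
* buckled-membrane force observations from the exact elastica law;
* 4PL leakage curves with homoscedastic Gaussian noise.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import units
from .elastica import elastica_reference
from .leakage import LeakageDataset, four_pl
from .mechanics import AreaSeries, BucklingObservation, StressProfile
from .model import BeadFrame, BeadTopology, MoleculeKind, Trajectory
from .pmf import UmbrellaWindowSet

__all__ = [
    "gen_area_series",
    "gen_stress_profile",
    "stress_profile_from_polynomial",
    "gen_bilayer_frame",
    "BilayerGroundTruth",
    "gen_umbrella_samples",
    "gen_brownian_xy",
    "gen_buckling_observations",
    "gen_leakage_curve",
]

MARTINI_BOND_LENGTH = 0.47  # nm, standard CG bond
LIPID_TAIL_BEADS = 3
POLYMER_CHAIN_BEADS = 5


def gen_area_series(
    mean_area: float,
    k_a: float,
    temperature: float,
    n: int,
    seed: int,
) -> tuple[AreaSeries, float]:
    """I.i.d. Gaussian lateral-area series with a prescribed k_A target.

    Inverts the fluctuation relation: var(A) = k_B T <A> / k_A, with k_A
    given in J m^-2.  Returns the series and the target variance (nm^4).
    """
    if k_a <= 0 or mean_area <= 0:
        raise ValueError("k_A and mean_area must be positive")
    if n < 2:
        raise ValueError("need n >= 2")
    ka_internal = units.ka_from_si(k_a)
    variance = units.KB * temperature * mean_area / ka_internal
    rng = np.random.default_rng(seed)
    areas = rng.normal(mean_area, np.sqrt(variance), size=n)
    return AreaSeries(areas=areas, temperature=temperature), variance


def _polynomial_for_moments(
    m0: float, m1: float, m2: float, z0: float
) -> tuple[float, float, float]:
    """Coefficients (a, b, c) of tau(z) = a + b z + c z^2 on [-z0, z0]
    with prescribed trapezoid-limit moments."""
    # M0 = 2 a z0 + (2/3) c z0^3 ; M2 = (2/3) a z0^3 + (2/5) c z0^5
    mat = np.array(
        [[2.0 * z0, (2.0 / 3.0) * z0**3], [(2.0 / 3.0) * z0**3, (2.0 / 5.0) * z0**5]]
    )
    a, c = np.linalg.solve(mat, np.array([m0, m2]))
    b = m1 / ((2.0 / 3.0) * z0**3)
    return float(a), float(b), float(c)


def gen_stress_profile(
    z_half_width: float,
    m0: float = 0.0,
    m1: float = 0.0,
    m2: float = 0.0,
    n_bins: int = 2001,
) -> StressProfile:
    """Polynomial stress profile whose moments match the spec exactly.

    Builds tau(z) = a + b z + c z^2 on [-z0, z0] solving for the requested
    zeroth (tension), first and second moments; a symmetric profile results
    whenever the first-moment target is zero.  The grid has ``n_bins``
    uniformly spaced nodes including the endpoints, so trapezoid moments
    match to quadrature accuracy.
    """
    if z_half_width <= 0:
        raise ValueError("z_half_width must be positive")
    if n_bins < 16:
        raise ValueError("need at least 16 bins")
    if m0 == 0.0 and m1 == 0.0 and m2 != 0.0 and z_half_width == 0.0:
        raise ValueError("inconsistent moment specification")
    a, b, c = _polynomial_for_moments(m0, m1, m2, z_half_width)
    z = np.linspace(-z_half_width, z_half_width, n_bins)
    return StressProfile(z=z, tau=a + b * z + c * z**2)


def stress_profile_from_polynomial(
    amplitude: float, z0: float, n_bins: int = 2001
) -> StressProfile:
    """The reference family tau(z) = A (3 z^2 - z0^2) on [-z0, z0].

    Zeroth and first moments vanish identically; the second moment is
    8 A z0^5 / 15.  Negative A gives the cohesive-interface (negative
    kappa_G, vesicle-favoring) sign.
    """
    z = np.linspace(-z0, z0, n_bins)
    return StressProfile(z=z, tau=amplitude * (3.0 * z**2 - z0**2))


@dataclass
class BilayerGroundTruth:
    """Constructed truth for a generated bilayer frame."""

    thickness_cells: np.ndarray  # (nx, ny) head separation per cell, NaN unfilled
    leaflet_of_molecule: dict[int, str]
    bond_cos_theta: np.ndarray  # per chain bond, |cos| of tilt from z
    n_water: int
    expected_mean_thickness: float  # area-weighted, nm
    head_bead_names: tuple[str, str]  # (lipid, polymer)
    n_lipids: int
    n_polymers: int


def _sample_tilt(rng: np.random.Generator, spec, size: int) -> np.ndarray:
    """Tilt angles (radians from z) per chain from an angular spec."""
    if spec is None:
        spec = {"kind": "delta", "theta": 0.0}
    kind = spec.get("kind", "delta")
    if kind == "delta":
        return np.full(size, float(spec.get("theta", 0.0)))
    if kind == "uniform":
        return rng.uniform(spec.get("low", 0.0), spec.get("high", np.pi / 4), size)
    raise ValueError(f"unknown tilt distribution {kind!r}")


def gen_bilayer_frame(
    n_per_leaflet: int,
    area_per_molecule: float,
    head_separation: float | np.ndarray,
    chain_tilt_distribution: dict | None = None,
    polymer_fraction: float = 0.0,
    seed: int = 0,
    water_bead_volume: float = 0.12,
    jitter_fraction: float = 0.2,
    water_margin: float = 2.0,
) -> tuple[BeadTopology, BeadFrame, BilayerGroundTruth]:
    """Build a flat bilayer on a jittered lateral lattice with exact truth.

    Molecules occupy cells of a near-square nx-by-ny lattice of edge
    sqrt(area_per_molecule); head beads sit at +-h/2 about the box
    midplane, where h is ``head_separation`` — a scalar or an (nx, ny)
    array for laterally structured (thin/thick) layouts.  Chains of bonded
    beads extend inward with tilt angles drawn from the angular spec
    (default: straight along z).  Water beads fill the non-membrane volume
    so the volume-bookkeeping thickness recovers the constructed mean.
    """
    if not 0.0 <= polymer_fraction <= 1.0:
        raise ValueError("polymer_fraction must lie in [0, 1]")
    edge = float(np.sqrt(area_per_molecule))
    if edge < 0.3:
        raise ValueError(
            f"area per molecule {area_per_molecule} nm^2 too small to place beads"
        )
    rng = np.random.default_rng(seed)
    nx = int(np.ceil(np.sqrt(n_per_leaflet)))
    ny = int(np.ceil(n_per_leaflet / nx))
    n_cells = nx * ny

    h = np.asarray(head_separation, dtype=float)
    if h.ndim == 0:
        h_cells = np.full((nx, ny), float(h))
    elif h.shape == (nx, ny):
        h_cells = h.copy()
    else:
        raise ValueError(
            f"head_separation map must have shape ({nx}, {ny}) for "
            f"n_per_leaflet={n_per_leaflet}, got {h.shape}"
        )
    if np.any(h_cells <= 0):
        raise ValueError("head separations must be positive")

    h_max = float(h_cells.max())
    chain_len_max = MARTINI_BOND_LENGTH * max(LIPID_TAIL_BEADS, POLYMER_CHAIN_BEADS)
    l_z = h_max + 2.0 * water_margin + 2.0
    box = np.array([nx * edge, ny * edge, l_z])
    z_mid = l_z / 2.0

    n_polymers = int(round(polymer_fraction * n_per_leaflet))
    names_all: list[str] = []
    kinds_all: list[MoleculeKind] = []
    mol_ids: list[int] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    leaflet_of_molecule: dict[int, str] = {}
    bond_cos: list[float] = []
    truth_cells = np.full((nx, ny), np.nan)

    cell_order = np.arange(n_cells)[:n_per_leaflet]
    mol_id = 0
    bead_id = 0
    for leaflet, sign in (("upper", +1.0), ("lower", -1.0)):
        is_polymer = np.zeros(n_per_leaflet, dtype=bool)
        is_polymer[rng.permutation(n_per_leaflet)[:n_polymers]] = True
        tilts = _sample_tilt(rng, chain_tilt_distribution, n_per_leaflet)
        for slot, cell in enumerate(cell_order):
            ix, iy = divmod(int(cell), ny)
            h_cell = h_cells[ix, iy]
            truth_cells[ix, iy] = h_cell
            jitter = rng.uniform(-jitter_fraction, jitter_fraction, 2) * edge
            x = (ix + 0.5) * edge + jitter[0]
            y = (iy + 0.5) * edge + jitter[1]
            z_head = z_mid + sign * h_cell / 2.0

            polymer = bool(is_polymer[slot])
            head_name = "EO1" if polymer else "PO4"
            n_chain = POLYMER_CHAIN_BEADS if polymer else LIPID_TAIL_BEADS
            chain_prefix = "B" if polymer else "C"
            kind = MoleculeKind.POLYMER if polymer else MoleculeKind.LIPID

            theta = tilts[slot]
            phi = rng.uniform(0.0, 2.0 * np.pi)
            direction = np.array(
                [
                    np.sin(theta) * np.cos(phi),
                    np.sin(theta) * np.sin(phi),
                    -sign * np.cos(theta),  # chains point toward the midplane
                ]
            )
            head_pos = np.array([x, y, z_head])
            prev = bead_id
            names_all.append(head_name)
            kinds_all.append(kind)
            mol_ids.append(mol_id)
            coords.append(head_pos)
            bead_id += 1
            for j in range(1, n_chain + 1):
                names_all.append(f"{chain_prefix}{j}")
                kinds_all.append(kind)
                mol_ids.append(mol_id)
                coords.append(head_pos + j * MARTINI_BOND_LENGTH * direction)
                bonds.append((prev, bead_id))
                bond_cos.append(abs(np.cos(theta)))
                prev = bead_id
                bead_id += 1
            leaflet_of_molecule[mol_id] = leaflet
            mol_id += 1

    # water fills the non-membrane volume; positions are placed outside the
    # thickest slab so they never sit inside the membrane core, and the
    # upper positions mirror the lower ones so the constructed frame is
    # exactly symmetric in z (count rounded to even)
    cell_area = edge * edge
    v_membrane = float(np.nansum(truth_cells) * cell_area)
    v_box = float(np.prod(box))
    n_water = int(round(max(v_box - v_membrane, 0.0) / water_bead_volume))
    n_water -= n_water % 2
    half_slab = h_max / 2.0
    z_water_lo = rng.uniform(0.0, z_mid - half_slab, n_water // 2)
    z_water = np.concatenate([z_water_lo, l_z - z_water_lo])
    xy_water = rng.uniform(0.0, 1.0, (n_water, 2)) * box[:2]
    for zw, (xw, yw) in zip(z_water, xy_water):
        names_all.append("W")
        kinds_all.append(MoleculeKind.WATER)
        mol_ids.append(mol_id)
        coords.append(np.array([xw, yw, zw]))
        mol_id += 1

    n_beads = len(names_all)
    masses = np.full(n_beads, 72.0)
    topology = BeadTopology(
        bead_names=np.array(names_all, dtype=object),
        molecule_ids=np.array(mol_ids),
        molecule_kinds=np.array(kinds_all, dtype=object),
        masses=masses,
        weights=masses.copy(),
        bonds=np.array(bonds, dtype=int).reshape(-1, 2),
    )
    frame = BeadFrame(coordinates=np.array(coords), box=box, time=0.0)
    filled = ~np.isnan(truth_cells)
    expected_h = float(np.nansum(truth_cells) / truth_cells.size)
    truth = BilayerGroundTruth(
        thickness_cells=truth_cells,
        leaflet_of_molecule=leaflet_of_molecule,
        bond_cos_theta=np.array(bond_cos),
        n_water=n_water,
        expected_mean_thickness=expected_h,
        head_bead_names=("PO4", "EO1"),
        n_lipids=2 * (n_per_leaflet - n_polymers),
        n_polymers=2 * n_polymers,
    )
    return topology, frame, truth


def gen_umbrella_samples(
    pmf: Callable[[np.ndarray], np.ndarray] | tuple[np.ndarray, np.ndarray],
    window_centers: Sequence[float],
    k_restraint: float = 1000.0,
    n_per_window: int = 10_000,
    temperature: float = 300.0,
    seed: int = 0,
    grid_resolution: float = 1e-3,
    span_sigmas: float = 6.0,
) -> UmbrellaWindowSet:
    """Exact biased Boltzmann samples for each umbrella window.

    For window i the density is proportional to
    exp(-[G(z) + k/2 (z - z_i)^2] / k_B T); samples are drawn by inverse
    transform on a fine z grid (default 1e-3 nm), which is exact to grid
    resolution and free of autocorrelation — WHAM correctness is thereby
    isolated from sampler quality.  ``pmf`` is either a callable G(z) in
    kJ mol^-1 or a (z_grid, G) pair, which must cover the window span.
    """
    centers = np.sort(np.asarray(window_centers, dtype=float))
    if k_restraint <= 0:
        raise ValueError("force constant must be positive")
    kbt = units.KB * temperature
    sigma_w = np.sqrt(kbt / k_restraint)
    lo = centers.min() - span_sigmas * sigma_w
    hi = centers.max() + span_sigmas * sigma_w

    if callable(pmf):
        g_of_z = pmf
    else:
        z_grid, g_grid = (np.asarray(a, dtype=float) for a in pmf)
        if z_grid.min() > lo or z_grid.max() < hi:
            raise ValueError(
                f"PMF grid [{z_grid.min():.3f}, {z_grid.max():.3f}] does not "
                f"cover the window span [{lo:.3f}, {hi:.3f}] nm"
            )
        g_of_z = lambda z: np.interp(z, z_grid, g_grid)

    z = np.arange(lo, hi + grid_resolution, grid_resolution)
    g = np.asarray(g_of_z(z), dtype=float)
    rng = np.random.default_rng(seed)
    samples = []
    for center in centers:
        energy = g + 0.5 * k_restraint * (z - center) ** 2
        log_w = -(energy - energy.min()) / kbt
        w = np.exp(log_w)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]))])
        cdf /= cdf[-1]
        u = rng.random(n_per_window)
        samples.append(np.interp(u, cdf, z))
    return UmbrellaWindowSet(
        centers=centers,
        k_restraint=k_restraint,
        samples=samples,
        temperature=temperature,
    )


def gen_brownian_xy(
    d: float,
    dt: float,
    n_steps: int,
    n_particles: int,
    seed: int = 0,
    z_plane: float = 0.0,
) -> Trajectory:
    """Independent 2D Brownian walks at diffusion coefficient ``d``.

    Gaussian increments with variance 2 D dt per lateral dimension; z is
    fixed (lateral diffusion in a flat membrane).  Coordinates are
    continuous (already unwrapped); the box is sized to contain the walks.
    """
    if d < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    if dt <= 0:
        raise ValueError("timestep must be positive")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2.0 * d * dt), size=(n_steps, n_particles, 2))
    xy = np.concatenate(
        [np.zeros((1, n_particles, 2)), np.cumsum(steps, axis=0)], axis=0
    )
    span = max(float(np.abs(xy).max()) * 4.0, 1.0)
    coords = np.zeros((n_steps + 1, n_particles, 3))
    coords[:, :, :2] = xy + span / 2.0
    coords[:, :, 2] = z_plane + span / 2.0
    return Trajectory.from_coordinates(coords, box=(span, span, span), timestep=dt)


def gen_buckling_observations(
    k_c: float,
    strains: Sequence[float],
    l0: float = 32.0,
    l_y: float = 8.0,
    l_z: float = 20.0,
    temperature: float = 300.0,
    force_noise: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> list[BucklingObservation]:
    """Buckled-membrane observations from the exact elastica force law.

    For each strain lam the noise-free restoring force is
    F_x = 4 pi^2 k_C L_y f_hat(lam) / L0^2 (k_C in kJ mol^-1, box in nm,
    default geometry 32 x 8 x 20 nm^3); multiplicative Gaussian noise of
    relative width ``force_noise`` is applied per replicate, and the
    corresponding P_xx = F_x / (L_y L_z) is stored with the compressed
    box dimension L_x = L0 (1 - lam).
    """
    if k_c <= 0:
        raise ValueError("k_C must be positive")
    rng = np.random.default_rng(seed)
    observations = []
    for lam in strains:
        f_exact = 4.0 * np.pi**2 * k_c * l_y * elastica_reference(float(lam)) / l0**2
        for _ in range(n_replicates):
            noise = rng.normal(0.0, force_noise) if force_noise > 0 else 0.0
            f_x = f_exact * (1.0 + noise)
            observations.append(
                BucklingObservation(
                    lam=float(lam),
                    p_xx=f_x / (l_y * l_z),
                    l_x=l0 * (1.0 - float(lam)),
                    l_y=l_y,
                    l_z=l_z,
                    temperature=temperature,
                    force_std=(
                        f_exact * force_noise if force_noise > 0 else None
                    ),
                )
            )
    return observations


def gen_leakage_curve(
    b: float,
    c: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    composition: str = "synthetic",
    temperature: float = 298.0,
) -> LeakageDataset:
    """4PL leakage curve with homoscedastic Gaussian noise, clipped to [0, 1.05]."""
    if c <= 0:
        raise ValueError("inflection concentration must be positive")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    f = four_pl(conc, b, c)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    f = np.clip(f, 0.0, 1.05)
    return LeakageDataset(
        concentrations=conc,
        fluorescence=f,
        composition=composition,
        temperature=temperature,
    )
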