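# Methods

## Scope and conventions

The package analyzes flat coarse-grained bilayers whose normal is the z
axis, in orthorhombic boxes (triclinic input is rejected).  Internal
units are nm, ps, K and kJ mol⁻¹ with k_B = 0.0083145 kJ mol⁻¹ K⁻¹;
conversions (1 kJ mol⁻¹ nm⁻² = 1.6606×10⁻³ J m⁻², 1 nm² ps⁻¹ =
10⁻² cm² s⁻¹) happen only at reporting boundaries, and a unit-audit test
confirms the internal and direct-SI routes agree to 10⁻¹² relative.

Coordinates are read/written as GRO files through MDAnalysis (with a
structural pre-check that produces line-numbered parse errors); tabular
data as XVG-style whitespace tables with `#`/`@` comments.  Trajectories
are in-memory frame sequences — the targets are desk-scale.

## Structural estimators

**Thickness.**  h = (V_box − V_water)/A_xy with V_water = (water bead
count) × v_w.  The per-bead water volume v_w is a required, documented
parameter (default 0.12 nm³ for a standard 4:1 coarse-grained water
bead); the estimator raises if water would fill the box.

**Leaflet assignment.**  The bilayer midplane is the mass-weighted center
of all membrane (lipid + polymer) beads; a molecule's leaflet is the sign
of its head bead's z relative to the midplane.  This choice (over, e.g.,
median head z) is arbitrary but is invariant under rigid z translation
and reproduces constructed leaflet imbalances exactly.

**Density profiles.**  Each frame is recentered so the membrane center of
mass sits at the box middle, then binned into n_slices z slabs (default
200) with per-bead weights: masses, a user-supplied electron column, or
unit counts.  At coarse-grained resolution there is no canonical electron
assignment per bead, so electron-density profiles default to mass weights
unless an electron table is supplied.  The profile conserves total weight
exactly (Σ ρ_s · V_slab = Σ w), which is tested to floating tolerance.

**Peak-to-peak distance.**  Strict local maxima after optional 3-point
smoothing; the highest maximum on each side of z = 0 (ties broken toward
larger |z|, since head-group peaks flank the hydrophobic core) defines
the separation.  Unimodal profiles raise rather than returning a
meaningless number.

**Order parameter.**  S_cd = ½⟨3cos²θ − 1⟩ with θ between the bond
vector (minimum image) and the z axis.  Measuring against the normal —
not the bilayer plane — is the convention that yields the standard
bounds S ∈ [−0.5, 1] with S = 1 fully ordered chains; zero-length bonds
are excluded with a warning.

**Membrane maps.**  Lateral 0.5 nm grid cells (edge configurable);
per-cell thickness is the mean upper-leaflet head z minus the mean
lower-leaflet head z.  Cells missing either leaflet are filled by
non-local weighted averaging over all filled cells with a Gaussian
kernel; the bandwidth defaults to one grid edge, the minimal smoothing
consistent with leaving no empty cells, and filled cells are flagged in
the result.  On a linear field with isolated gaps the fill is unbiased
(kernel regression with symmetric neighborhoods); near map boundaries or
in large contiguous holes it shrinks toward the local mean, which is the
price of guaranteeing full coverage.  The thin fraction is the area
fraction of cells at or below 5 nm (50 Å), the conventional boundary
between lipid-like (thin, collapsed polymer) and polymer-like (thick,
extended polymer) patches in hybrid membranes.

## Mechanical moduli

**Area compressibility.**  k_A = k_B T ⟨A⟩ / var(A) from the lateral
box-area time series.  The fluctuation bracket is read as the variance
about the time mean — the only self-consistent reading, since a bracket
of instantaneous-minus-instantaneous area would vanish identically.
Standard errors come from re-estimating k_A on 5 contiguous blocks;
fewer than 100 samples warns.

**Gaussian curvature modulus.**  κ_G equals the second moment
∫ z² τ₀(z) dz of the lateral-minus-normal stress profile, computed by the
trapezoid rule on the profile's uniform grid.  The relation only holds
for a tensionless membrane, so the zeroth moment (the tension) is
checked first: the default tolerance is 1% of max|τ₀| times the profile
span, overridable.  Sign convention: κ_G is the second moment of the
input τ₀ = τ_L − τ_N as given, with no extra flip — cohesive-interface
profiles then give κ_G < 0, the sign that favors closed vesicular
topologies.  Conventions vary in the literature, hence this prominent
note.

**Bending modulus by buckling.**  A membrane strip of arc length L₀
compressed to L_x = L₀(1 − λ) behaves as a periodic planar Euler
elastica.  From the pendulum first integral, with elliptic modulus m:

    λ = 2(1 − E(m)/K(m)),      f̂(λ) ≡ F_x L₀² / (4π² k_C L_y) = (2K(m)/π)²

The estimator inverts this force law per observation:
k_C = F_x L₀² / (4π² L_y f̂(λ)) with F_x = P_xx L_y L_z.  Two
implementations of f̂ are provided and cross-checked: the **exact
elliptic oracle** (bracketed root-solve of λ(m), valid for 0 < λ < 0.5)
and the **order-10 Taylor series** Σ bᵢλⁱ whose coefficients were derived
exactly by series reversion of the elliptic relations (b₀..b₅ = 1, 1/2,
9/32, 21/128, 795/8192, 945/16384 — matching the published values for
the buckling method); the two agree to ~10⁻⁸ for λ ≤ 0.3.  Observations
at λ > 0.3 warn (series validity).  Multiple observations are combined
by inverse-variance weighting when force uncertainties are supplied,
otherwise by the unweighted mean.

The thermal-undulation force σF = −1.5 k_B T Σ dᵢλⁱ / L_x can be
subtracted when the dᵢ coefficients are supplied by the user; they
derive from fluctuations around the buckled state and are not
re-derivable from the elastica alone, so no default values are shipped
and enabling the correction without them raises (except at T = 0, where
the term vanishes identically).

**Toy stress binner.**  For validation only, an Irving–Kirkwood binner
attributes each pair's configurational virial to z slabs in proportion
to the straight minimum-image segment length per slab, for analytic
central pair potentials.  It reproduces the hand-computed single-pair
attribution and a flat profile for a homogeneous toy fluid; it is not a
force-field local-stress tool.

## Lateral diffusion

MSD uses the FFT autocorrelation form of the time-origin average over
the x, y coordinates of selected beads; wrapped input (inter-frame jump
beyond half a box) is rejected.  D = slope/4.  The fit runs over lags in
[10%, 50%] of the maximum lag and weights each point by
n_origins/lag³ — the inverse of the leading-order variance of a
time-origin-averaged MSD, whose error amplitude grows with lag while
long lags average fewer independent origins.  By default the line is
anchored at the origin (the exact Einstein form MSD = 4Dτ); this
substantially reduces estimator variance because correlated MSD errors
cancel in levels but not in differences.  `fit_intercept=True` is
available for real data with short-time artifacts.  At the reference
problem size (100 walkers × 10⁴ steps) the recovery error is ~2% RMS
across seeds.

## Umbrella sampling and WHAM

Windows carry centers, harmonic force constants and per-window samples.
WHAM iterates the self-consistent binned equations in log space
(logsumexp) until the largest change in window free energies falls below
10⁻⁴ kJ mol⁻¹ (default; max 10⁵ iterations, non-convergence flagged).
The default bin width, 0.02 nm, undersamples the ~0.05 nm Gaussian
window width implied by k = 1000 kJ mol⁻¹ nm⁻² at 300 K.  Adjacent
windows with strictly zero histogram overlap abort with an error naming
the gap; the overlap diagnostic reports histogram-intersection fractions
(Σ min(pᵢ, pⱼ)) and flags adjacent pairs below 0.05.  At 0.1 nm spacing
with k = 1000 at 300 K the analytic overlap of neighboring windows is
2Φ(−1) ≈ 0.317, so measured overlaps sit just above 0.3.  No
autocorrelation correction is applied — the synthetic samples are
i.i.d. by construction; a decorrelation stride should be applied
upstream for real correlated data.  Referencing shifts the profile so
its mean over a declared bulk-water interval is zero; classification
labels the global minimum by region (core → transmembrane, head-group
→ interfacial, water → solvated), with boundary ties resolved toward
the membrane center and flat profiles labeled solvated with a warning.

## Leakage fits

The 4PL response with floor 0 and ceiling 1 fixed leaves (b, c);
c is fitted on a log scale for conditioning, the zero-concentration
anchor is handled by the exact limit F(0) = 0 rather than a log
transform, and standard errors come from the Gauss–Newton covariance
(delta method for c).  Data not bracketing the half response warn.
Comparative statements across vesicle compositions are surfaced as
parameter tables, not hypothesis tests.

## Synthetic generators: what they emulate, and what they do not

Each generator inverts the statistical model its estimator assumes:
Gaussian i.i.d. areas with var = k_B T ⟨A⟩ / k_A; quadratic stress
profiles solved for prescribed moments; lattice-built bilayers (jittered
square lattice, exact per-cell head separations, chains with prescribed
tilt, mirrored water filling the non-membrane volume so both the volume
bookkeeping and z symmetry are exact by construction); umbrella samples
drawn by inverse-CDF on a 10⁻³ nm grid (exact, autocorrelation-free —
WHAM correctness is isolated from sampler quality); ideal 2D Brownian
walks; buckling forces from the exact elastica law with optional
multiplicative Gaussian noise; 4PL curves with homoscedastic Gaussian
noise clipped to [0, 1.05].

These fixtures deliberately lack the correlations of real simulations:
no area-fluctuation autocorrelation, no undulation spectrum coupling
thickness to position, no water penetration at the interface, no
correlated umbrella samples, no hydrodynamic (finite-box) diffusion
corrections.  Passing the closed-loop suites therefore demonstrates that
the estimators are correct implementations of their defining relations
— not that those relations capture every feature of microsecond-scale
membrane trajectories, whose equilibration and sampling adequacy must
be judged separately.

Default generator conditions follow the production setup the estimators
are built for: restraints of 1000 kJ mol⁻¹ nm⁻² at 0.1 nm spacing and
300 K for umbrella windows; buckling geometry 32 × 8 × 20 nm³ with
strains around λ = 0.2; diffusion at 10⁻⁷ cm² s⁻¹ (within the
experimental lipid range); closed-loop problem sizes of 10⁵ area
samples, 10⁴ samples per window, and 100 walkers × 10⁴ steps, at which
the stochastic recovery tolerances (3% for k_A, 5% for noisy k_C and D,
0.5 kJ mol⁻¹ WHAM RMS) hold with margin.

## Known limitations

* Binary trajectory formats (XTC/TRR/DCD) are not read; convert to GRO
  frame sequences or construct `Trajectory` objects directly.
* The buckling thermal correction requires user-supplied dᵢ.
* The map fill guarantees coverage, not unbiasedness, in large holes.
* WHAM assumes decorrelated samples; no MBAR estimator is provided.
* No SAXS/cryo-EM form-factor processing; experimental comparisons are
  inputs, not computations.
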