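# Methods

## Nanoscale geometry and cluster scoring

The simulation volume is a water cube, 100 nm on a side by default, centered
at the origin. Sampling volumes are Z-aligned cylinders of 2.3 nm diameter
and 3.4 nm length — the size and shape of a 10-base-pair DNA segment, where
clustered lesions such as double-strand breaks form. The packing is
deterministic: layers stacked along Z at a pitch equal to the cylinder
length, rows along Y at a pitch equal to the diameter, columns along X at
the same pitch, and alternate rows offset along X by one radius (1.15 nm).

Column, row and layer counts are fixed by the *unshifted* registration
(first center one radius off each wall) and applied uniformly to every row.
For the reference cube this gives 43 × 43 × 29 = 53 621 cylinders at 75.7%
fill. The row shift makes the final cylinder of each shifted row overhang
the wall by `row_shift − (free_span mod pitch)` — 0.05 nm here, about 2% of
a radius. We accept this overhang rather than dropping one cylinder per
shifted row (which would give alternating 43/42 columns and 53 012
cylinders): the uniform-count lattice is the configuration whose published
packing the rest of the pipeline assumes, and a 0.05 nm protrusion is far
below every length scale the scorer resolves. The containment invariant is
therefore enforced with exactly that tolerance, and the placement oracle in
the test suite enumerates the same candidate grid independently while
re-checking pairwise non-overlap (minimum in-layer center distance equals
the diameter; shifted-row neighbours are strictly farther apart).

Cylinder containment is closed (radial distance ≤ r, axial offset ≤ L/2).
Within a layer the packing leaves gaps between rows, so shared radial
boundaries cannot occur; axially, stacked cylinders touch faces, and a point
exactly on a shared face (a measure-zero event for continuous positions) is
assigned to the lower cylinder index, identically in the spatial-hash
locator and the linear-scan reference.

The particle source is a 34 nm diameter vacuum sphere at the cube center —
ten times the largest sampling-volume dimension. Primaries start uniformly
inside it with isotropic directions; sampling volumes overlapping the sphere
are removed with a conservative solid-distance test. Track length is scored
only inside the cube and outside the source sphere; the mean path from a
uniform interior point of the sphere to its surface along an isotropic
direction is 3R/4 = 12.75 nm at R = 17 nm (used as a geometry self-check,
closed form plus Monte Carlo).

Transport bookkeeping mirrors how database and macroscale simulations must
share secondaries without double counting: secondaries *below* the
condensed-history production threshold for their type (0.054 MeV for
electrons, 1.56 MeV for protons — default water cuts) are transported and
their ionizations scored with the parent history, since the macroscale code
would absorb them locally; secondaries at or above the threshold are
terminated because their ionizations are carried by their own database
class. Secondaries heavier than protons are always terminated. Primaries are
killed once their cumulative energy loss exceeds 1% of the gap down to the
next lower database energy (0.05 MeV for a 15 MeV primary above a 10 MeV
grid point), keeping each record nearly monoenergetic. Periodic boundary
re-entry (exit point reflected through the cube center, energy and direction
kept) is implemented for escaping secondaries but off by default: for
histories contained in the volume it is exactly neutral, which the tests
verify by construction.

Uncertainties: histories are split into 10 equal batches; se(f(ν)) and
se(F_k) are standard errors over batches. A convergence helper runs
histories until se(F_k)/F_k ≤ 1% for k ∈ {5, 6, 7}.

## Toy track generator

The generator is *not* physics; its job is known ground truth. A primary ray
carries a Poisson ionization process of density λ_p per nm (default
λ_p(E) ∝ 1/E to mimic the LET rise at low energy); secondaries branch at
Poisson points, each depositing a geometric number of ionizations uniformly
along an exponential-range straight path; all positions can be blurred by an
isotropic Gaussian. Closed forms exist in the secondary-free axial
configuration: a primary along a contiguous cylinder stack yields
F₁ = (1 − e^{−λL})/L clusters per nm, the oracle the scorer is tested
against. What the generator does not emulate: energy-loss straggling,
realistic delta-ray angular/energy spectra, elastic scattering, chemistry.
Passing tests therefore demonstrate correct *scoring and bookkeeping*, not
agreement with track-structure codes.

## Database and adaptive energy binning

A particle class is (species, energy) — energy in MeV for electrons and
protons, MeV per nucleon for ions (He through Ar), over the clinically
motivated ranges hard-coded in `ENERGY_RANGES` (e.g. protons 0.1–230 MeV,
carbon 0.5–425 MeV/u). Records hold f(ν); F_k = Σ_{ν≥k} f(ν) is derived,
non-increasing in k by construction.

Grid energies are laid out marching up from E_min: the next energy is the
largest E at which max_{k∈{5,6,7}} |F_k(E) − F_k(E_prev)|/F_k(E_prev) ≤ 5%,
found by bisection to 10⁻⁶ relative tolerance, with E_max always appended.
Open choices resolved here: the denominator of the relative change is the
previous (lower-energy) grid value, and the criterion is the maximum over
k = 5, 6, 7 jointly. Interpolation between records is linear in energy (not
log-energy — at 5% spacing the difference is ≲ 0.1%), clamped to the
boundary record outside the tabulated range. On grids built this way from
smooth monotone curves the measured interpolation error at random
intermediate energies is ~0.07%, well below the 1% design bound.

Isotopes: the database stores one record set per atomic number (the stable
ion); any (Z, A) query resolves to it, with no energy rescaling since keys
are per nucleon. The helper `isotope_relative_difference` computes the
signed percentage 100(F_k^iso − F_k^stable)/F_k^stable used to audit this
approximation.

Persistence is a diffable UTF-8 CSV (`species,Z,A,energy,unit,nu,f_per_nm,
se_per_nm`) with a YAML header block; round trips are value-identical
(pandas is asked for round-trip float parsing).

## Substep macroscale scoring

For a step from E_pre to E_post over geometric length T, the substep
boundaries are all midpoints of adjacent database energies that fall
strictly inside (E_post, E_pre) — including midpoints formed with the grid
neighbours just outside the step when those land inside. Interior substeps
each enclose exactly one database energy and use its stored value without
interpolation; the first and last substeps interpolate at their own midpoint
energies (E_pre + E_a′)/2 and (E_z′ + E_post)/2. Track lengths are energy
fractions of T under the constant-stopping-power assumption. This single
rule yields both the five-substep case (exterior midpoints inside the step)
and the three-substep case (outside) for a step spanning three database
energies. Degenerate zero-loss steps use E_pre with the full T; a step
bracketing no boundary becomes one substep interpolated at the step's energy
midpoint.

The substep lengths are made to sum to T *bit-exactly*: the last entry is
set by subtraction, and when round-to-even ties make the target float sum
unattainable that way, one earlier entry is dithered by up to two ulps —
a perturbation ~10⁻¹⁶ relative, far below any physical scale.

Voxel-averaged I_p is Σ t·I_p / Σ t with track lengths scaled by ρ/ρ₀
(ρ₀ = 1 g cm⁻³, the database medium). Fluence uses the track-length
estimator φ = Σ t / V_voxel — the standard estimator, adopted here as the
operational definition — so cluster dose g = φ·I_p/ρ₀ equals
Σ(t·I_p)/(V·ρ₀), converted to pg⁻¹. Particles below the grid minimum
contribute with the clamped boundary I_p, not zero. The legacy prestep mode
(single lookup at E_pre for the whole step) is retained for differencing;
with a decreasing I_p(E) the substep mode is strictly larger, and on the
fixture spread-out Bragg peak its cluster dose exceeds the prestep mode's
everywhere distal to the peak — the sign of the effect, which is all the
fixture can establish (magnitudes require real transport physics).

## 1D phantom fixture

Depth-only transport with the Bragg–Kleeman range–energy relation
R = αE^p (protons in water: α = 0.022 mm, p = 1.77, per-nucleon analogues
for ions), steps capped at 1 mm and at voxel boundaries, residual energy
deposited in place below the cut. This is the simplest model that produces
realistic step *structure* — many database intervals per step near end of
range — which is where the substep scorer matters. Primary-only, no
straggling, no nuclear processes, no lateral spread.

The synthetic I_p curves used to populate databases are
F_k(E) = A·L·exp(−(k−1)/m(L)) with L = Z^1.7 E^−0.8 and m = 1 + 1.5√L
(A = 0.02 nm⁻¹): positive, smooth, decreasing in E and k, increasing with
Z, with a cluster spectrum that hardens at low energy. The k–E coupling
through m(L) is deliberate: it makes F_k ratios vary across particle
classes, so the preferred-I_p selection problem is well posed.

## Survival association

For each candidate F_k, the cluster dose of every survival point is placed
on that definition's axis and a single common curve ln S = −αg − βg² is
fitted by linear least squares jointly across beams (β constrained ≥ 0;
α free, so hypersensitivity-free fits are possible; optional
inverse-variance weights, unweighted by default). The preferred I_p is the
k minimizing the mean residual; since the norm is an open choice, both RMS
and mean-absolute ln-survival residuals are reported and RMS drives the
selection, with ties reported rather than broken. The synthetic survival
generator draws (species, energy, fluence) points, computes g_k = φ·F_k(E)
normalized so the true definition's dose equals the fluence factor, and
applies lognormal noise; at noise σ = 0.03 the true definition is recovered
in ≥ 95 of 100 seeded datasets.

## Problem sizes and numerical choices

Default analysis sizes — 10⁴-point locator cross-checks, 10⁵ random substep
decompositions, 10⁶ Monte Carlo source-path samples, 10⁴ interpolation
probes per species, 100 survival datasets, and a 200-history fixture SOBP —
were chosen so each check is statistically decisive while the whole suite
runs in well under a minute of compute per module. Random streams are
`numpy.random.default_rng` generators seeded explicitly everywhere; the
batch count for uncertainties is fixed at 10.

## Known limitations

- No track-structure or condensed-history physics: cross sections,
  scattering, chemistry, straggling and fragmentation are out of scope; all
  inputs beyond the geometry are synthetic and labelled as such.
- Absolute database values, isotope percentage differences and SOBP
  cluster-dose magnitudes cannot be reproduced without an external engine;
  the package establishes structure, invariants and signs instead.
- The lattice locator assumes the full (un-excluded) lattice for hashing and
  falls back to the linear scan otherwise.
- The 1D phantom is primary-only, so its fluence omits secondary buildup.
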