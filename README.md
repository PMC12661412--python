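# idkit — ionization-detail nanodosimetry toolkit

`idkit` implements the ionization-detail (ID) methodology used to bring
nanodosimetric quantities into ion-radiotherapy treatment planning: it scores
ionization clusters in a lattice of DNA-segment-sized sampling volumes,
builds lookup databases of ionization parameters on adaptively spaced energy
grids, converts condensed-history step logs into voxel-averaged ionization
parameters and cluster dose via a substep decomposition, and selects the
ionization-parameter definition most closely associated with cell survival.

It is aimed at computational radiobiology work where the nanoscale inputs
would normally come from track-structure Monte Carlo engines; here, fully
controllable synthetic generators (a toy track model and a 1D phantom)
stand in for those engines so every quantity has a known ground truth.

## The quantities

- **Ionization cluster size** ν: the number of ionizations a single primary
  history deposits in one cylindrical sampling volume (2.3 nm diameter ×
  3.4 nm length, the size of a 10-base-pair DNA segment). Accumulated over
  histories and divided by the summed primary track length this gives the
  frequency ionization cluster size distribution *f(ν)* in nm⁻¹.
- **Ionization parameter** I_p = G_p[f(ν)]; the family used here is
  F_k = Σ_{ν≥k} f(ν), the number of clusters of k or more ionizations per
  unit track length.
- **Voxel-averaged I_p**: I_p^φ = Σ_c t_c I_p^c / Σ_c t_c over the particle
  classes c (species, energy) crossing a voxel, with t_c their track length.
- **Cluster dose** g = φ · I_p^φ / ρ₀ — clusters of ≥k ionizations per unit
  mass (pg⁻¹), the fluence-scaling macroscopic quantity.
- **Preferred I_p**: the F_k whose cluster dose makes survival curves from
  different beams collapse onto one linear-quadratic curve
  ln S = −αg − βg², judged by the lowest RMS ln-survival residual of a
  common fit.

Key numerical machinery:

- deterministic maximal cylinder packing (53 621 volumes at 76% fill in the
  100 nm reference cube) with a spatial-hash point locator;
- adaptive energy binning: grid steps chosen so F₅–F₇ change ≤ 5% between
  adjacent database energies, which keeps linear-interpolation errors at
  intermediate energies below 1%;
- substep decomposition of condensed-history steps at the midpoints of
  database energies inside the step, so interior substeps read the database
  exactly and only the edge substeps interpolate.

## Worked example

```python
import numpy as np
from idkit import *
from idkit.phantom import synthetic_ip_curves, DEFAULT_STOPPING, BeamSpec, transport_1d

lat = build_cylinder_lattice(100, 2.3, 3.4, 1.15)
print(f"lattice: {lat.count} cylinders, fill fraction {100*lat.fill_fraction:.1f}%")
print(f"mean source path (R=17 nm): {mean_source_path(17.0):.2f} nm")

db = IDDatabase.from_curves(synthetic_ip_curves(("proton", "C", "O")))
beam = BeamSpec("proton", ((60.0, 1/3), (65.0, 1/3), (70.0, 1/3)), histories=200, seed=7)
steps = transport_1d(beam, DEFAULT_STOPPING["proton"], n_voxels=60)
sub = VoxelScorer(db, k_values=(5,)).score_steps(steps, mode="substep")
pre = VoxelScorer(db, k_values=(5,)).score_steps(steps, mode="prestep")
gs = sub.cluster_dose().set_index("iz")["g_F5_per_pg"]
gp = pre.cluster_dose().set_index("iz")["g_F5_per_pg"]
peak = int(gp.idxmax())
print(f"peak voxel: {peak}; substep/prestep cluster-dose ratio at peak+4: "
      f"{gs.loc[peak+4]/gp.loc[peak+4]:.3f}")

sel = select_preferred_ip(
    synthetic_survival_dataset(db, np.random.default_rng(1), true_k=5, noise_sigma=0.03)
)
print(sel.fits[sel.k_star].summary())
```

prints

```
lattice: 53621 cylinders, fill fraction 75.7%
mean source path (R=17 nm): 12.75 nm
peak voxel: 30; substep/prestep cluster-dose ratio at peak+4: 1.292
LQ survival fit (ln S = -alpha*g - beta*g^2)
  n points          : 54
  alpha [pg]        : +1.19586 (se 0.00926)
  beta  [pg^2]      : +0.151855 (se 0.00481)
  RMS residual      : 0.027481
  mean |residual|   : 0.021458
```

The lattice count and mean source path are the geometry constants of the
reference configuration. The cluster-dose ratio > 1 distal to the Bragg peak
shows the substep scorer capturing the I_p rise along each step that the
legacy prestep lookup misses. The LQ fit recovers the generating parameters
(α = 1.2, β = 0.15) of the synthetic survival data and selects F₅ — the
definition the data were generated from — as preferred.

A `click` CLI mirrors the library: `idkit pack`, `idkit gen-tracks`,
`idkit score-nano`, `idkit build-grid`, `idkit db validate|fk`,
`idkit phantom`, `idkit score-macro`, `idkit fit-survival`.

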