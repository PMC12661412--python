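"""1D water-phantom fixture: toy condensed-history step logs.

A deliberately simple depth-only transport model that produces step logs
with realistic *structure* (short steps, energies sweeping down a database
grid, a terminal Bragg-like peak) so the macroscale scorer can be exercised
end to end without an external Monte Carlo engine.  Energy-range follows
the Bragg-Kleeman power law R(E) = alpha * E^p, which concentrates energy
loss near the end of range -- exactly where the substep decomposition
matters most.  No straggling, scattering or nuclear processes.

Also provides smooth parametric F_k(E) curve sets ("synthetic I_p curves")
with the qualitative features of scored cluster-size data: F_k positive,
decreasing with energy, increasing with atomic number, and with a cluster
spectrum that hardens (slower decay in k) at low energy / high LET.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .database import ENERGY_RANGES, _species_za
from .macro import StepRecord

__all__ = [
    "BeamSpec",
    "StoppingModel",
    "transport_1d",
    "synthetic_ip_curves",
    "DEFAULT_STOPPING",
]


@dataclass(frozen=True)
class BeamSpec:
    """Beam definition: species plus an (energy, weight) spectrum.

    A single pristine peak is a one-line spectrum; an SOBP superposes
    several energies with weights summing to one.  Energies are in the
    database unit of the species (MeV or MeV/u).
    """

    species: str
    spectrum: tuple[tuple[float, float], ...]
    histories: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        ws = np.array([w for _, w in self.spectrum], dtype=float)
        if len(ws) == 0 or np.any(ws < 0) or not np.isclose(ws.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")
        lo, hi = ENERGY_RANGES[self.species]
        for e, _ in self.spectrum:
            if not lo <= e <= hi:
                raise ValueError(f"beam energy {e} outside database range for {self.species}")


@dataclass(frozen=True)
class StoppingModel:
    """Bragg-Kleeman range-energy relation R(E) = alpha * E^p (mm)."""

    alpha: float = 0.022
    p: float = 1.77
    max_step: float = 1.0  # mm
    energy_cut: float = 0.1  # MeV(/u); residual deposited in place below this

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.p <= 1:
            raise ValueError("require alpha > 0 and p > 1")
        if self.max_step <= 0 or self.energy_cut < 0:
            raise ValueError("max_step must be positive, energy_cut non-negative")

    def range_mm(self, energy: float) -> float:
        return self.alpha * energy**self.p

    def energy_at_residual_range(self, r: float) -> float:
        return (r / self.alpha) ** (1.0 / self.p) if r > 0 else 0.0


# per-species defaults; proton values approximate water, ions reuse the same
# power law per nucleon with a shorter range scale
DEFAULT_STOPPING: dict[str, StoppingModel] = {
    "proton": StoppingModel(alpha=0.022, p=1.77, max_step=1.0, energy_cut=0.1),
    "He": StoppingModel(alpha=0.022, p=1.77, max_step=1.0, energy_cut=0.5),
    "C": StoppingModel(alpha=0.0085, p=1.75, max_step=1.0, energy_cut=0.5),
    "O": StoppingModel(alpha=0.0065, p=1.74, max_step=1.0, energy_cut=0.5),
}


def transport_1d(
    beam: BeamSpec,
    model: StoppingModel,
    n_voxels: int,
    voxel_size: float = 1.0,
    density: float = 1.0,
) -> list[StepRecord]:
    """March each history down the depth axis, logging one step per segment.

    Steps are capped at ``model.max_step`` and at voxel boundaries; the
    poststep energy follows from the residual range.  Histories stop below
    ``model.energy_cut`` (residual energy deposited in place) or on leaving
    the phantom.  Deterministic for a given beam seed.
    """
    rng = np.random.default_rng(beam.seed)
    energies = np.array([e for e, _ in beam.spectrum])
    weights = np.array([w for _, w in beam.spectrum])
    Z, A = _species_za(beam.species)
    depth_max = n_voxels * voxel_size
    eps = 1e-12

    steps: list[StepRecord] = []
    picks = rng.choice(len(energies), size=beam.histories, p=weights)
    for pick in picks:
        E = float(energies[pick])
        if model.range_mm(E) <= 0:
            raise ValueError("beam energy outside the stopping model's domain")
        z = 0.0
        while E > model.energy_cut and z < depth_max - eps:
            r = model.range_mm(E)
            iz = min(int(z / voxel_size + eps), n_voxels - 1)
            to_boundary = (iz + 1) * voxel_size - z
            dz = min(model.max_step, to_boundary, r)
            if dz <= eps:
                break
            E_post = model.energy_at_residual_range(r - dz)
            if E_post < model.energy_cut:
                E_post = 0.0  # stops here; residual deposited in place
            steps.append(
                StepRecord(
                    species=beam.species, Z=Z, A=A, E_pre=E, E_post=E_post,
                    step_length=dz, voxel=(0, 0, iz), density=density,
                )
            )
            z += dz
            E = E_post
    return steps


def synthetic_ip_curves(
    species=("proton", "C", "O"), k_max: int = 10, amplitude: float = 0.02
):
    """Smooth parametric F_k(E) curve sets, one callable per species.

    F_k(E) = amplitude * L * exp(-(k-1)/m(L)), with the LET-like scale
    L = Z^1.7 * E^-0.8 and cluster-spectrum hardness m = 1 + 1.5*sqrt(L).
    The curves are positive and infinitely differentiable, decrease with
    energy, increase with Z at equal E/u, and their decay in k slows at low
    energy -- the qualitative shape of scored cluster-size data.  They are
    synthetic stand-ins: no physics beyond these constraints.
    """
    curves = {}
    for sp in species:
        Z, _ = _species_za(sp)
        zf = float(abs(Z)) ** 1.7

        def curve(E, zf=zf):
            if np.any(np.asarray(E) <= 0):
                raise ValueError("energy must be positive")
            L = zf * np.asarray(E, dtype=float) ** -0.8
            m = 1.0 + 1.5 * np.sqrt(L)
            k = np.arange(1, k_max + 1)
            return amplitude * L * np.exp(-(k - 1) / m)

        curves[sp] = curve
    return curves
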