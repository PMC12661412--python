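"""Macroscale scoring: condensed-history steps -> voxel I_p and cluster dose.

A condensed-history step carries a particle from prestep energy ``E_pre`` to
poststep energy ``E_post`` over a geometric length ``T``.  The step may span
several database energy intervals, so assigning a single I_p (the legacy
"prestep" mode) misses the rise of I_p toward the end of range.  The substep
decomposition instead cuts the step at the midpoints of adjacent database
energies falling inside (E_post, E_pre): each interior substep is centered
on a database energy and uses its stored value without interpolation, while
the first and last substeps interpolate at their own midpoint energies.
Track lengths are apportioned by energy fraction under the assumption of
constant energy loss per unit track length across the step.

Voxel-averaged I_p is the track-length-weighted mean of the looked-up
values (Sigma t*I_p / Sigma t); cluster dose is fluence times the
mass-normalized voxel-averaged I_p, g_j = phi_j * I_p / rho_0, reported in
pg^-1.  Fluence uses the track-length estimator phi_j = Sigma t / V_voxel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .database import IDDatabase, resolve_isotope

__all__ = [
    "StepRecord",
    "Substep",
    "SubstepPlan",
    "VoxelScorer",
    "substep_decompose",
    "steps_spanned_histogram",
    "depth_profile",
    "NM_PER_MM",
    "PG_PER_G",
]

NM_PER_MM = 1.0e6
PG_PER_G = 1.0e12


@dataclass(frozen=True)
class StepRecord:
    """One condensed-history step.

    Energies in the database key unit of the species (MeV or MeV/u);
    ``step_length`` in mm; ``density`` in g cm^-3.
    """

    species: str
    Z: int
    A: int
    E_pre: float
    E_post: float
    step_length: float
    voxel: tuple[int, int, int]
    density: float = 1.0

    def __post_init__(self) -> None:
        if not self.E_pre >= self.E_post >= 0:
            raise ValueError("require E_pre >= E_post >= 0")
        if self.step_length <= 0:
            raise ValueError("step length must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")


@dataclass(frozen=True)
class Substep:
    lookup_energy: float
    interpolated: bool
    t: float  # mm


@dataclass(frozen=True)
class SubstepPlan:
    substeps: tuple[Substep, ...]

    @property
    def N(self) -> int:
        return len(self.substeps)

    @property
    def total_length(self) -> float:
        return sum(s.t for s in self.substeps)


def substep_decompose(
    E_pre: float, E_post: float, grid_energies: np.ndarray, T: float
) -> SubstepPlan:
    """Divide a step at the midpoints of adjacent database energies.

    Boundaries are every midpoint of consecutive grid energies that falls
    strictly inside (E_post, E_pre) -- including midpoints formed with the
    grid neighbours just outside the step, when those land inside.  The
    first and last substeps interpolate I_p at their own midpoints
    ((E_pre + E_a')/2 and (E_z' + E_post)/2); each interior substep encloses
    exactly one database energy and uses its value directly.  Track lengths
    are the energy fractions of T; the last entry absorbs rounding so the
    lengths sum to T exactly.
    """
    if not E_pre >= E_post >= 0:
        raise ValueError("require E_pre >= E_post >= 0")
    if T <= 0:
        raise ValueError("T must be positive")
    grid = np.asarray(grid_energies, dtype=float)
    if len(grid) == 0:
        raise ValueError("empty energy grid")

    if E_pre == E_post:
        return SubstepPlan((Substep(E_pre, True, T),))

    mids = 0.5 * (grid[1:] + grid[:-1])
    inside = mids[(mids > E_post) & (mids < E_pre)]
    if len(inside) == 0:
        return SubstepPlan((Substep(0.5 * (E_pre + E_post), True, T),))

    bounds = np.sort(inside)[::-1]  # descending: E_a' ... E_z'
    dE = E_pre - E_post
    subs: list[Substep] = []
    # first substep: (E_a', E_pre]
    subs.append(
        Substep(0.5 * (E_pre + bounds[0]), True, (E_pre - bounds[0]) / dE * T)
    )
    # interior substeps each enclose one grid energy
    for hi, lo in zip(bounds[:-1], bounds[1:]):
        enclosed = grid[(grid > lo) & (grid < hi)]
        # consecutive midpoints bracket exactly one grid energy
        subs.append(Substep(float(enclosed[0]), False, (hi - lo) / dE * T))
    # last substep: [E_post, E_z')
    subs.append(
        Substep(0.5 * (bounds[-1] + E_post), True, (bounds[-1] - E_post) / dE * T)
    )
    # exactness of the track-length sum: solve the rounding fixpoint so the
    # left-to-right float sum equals T bit-for-bit
    ts = _exact_partition([float(s.t) for s in subs], float(T))
    subs = [Substep(s.lookup_energy, s.interpolated, t) for s, t in zip(subs, ts)]
    return SubstepPlan(tuple(subs))


def _nudge(x: float, k: int) -> float:
    to = math.inf if k > 0 else -math.inf
    for _ in range(abs(k)):
        x = math.nextafter(x, to)
    return x


def _exact_partition(ts: list[float], T: float) -> list[float]:
    """Adjust the partition so its left-to-right float sum equals T exactly.

    The last entry is set by subtraction; when round-to-even ties make T
    unattainable that way, the first entry is dithered by one ulp to shift
    the rounding lattice.  Perturbations are <= 2 ulp, far below any
    physical scale here.
    """
    if len(ts) == 1:
        return [T]
    n_head = len(ts) - 1
    for idx in range(n_head):
        for k in (0, 1, -1, 2, -2, 3, -3):
            if idx > 0 and k == 0:
                continue
            head = ts[:-1]
            head[idx] = _nudge(head[idx], k)
            s_prev = sum(head)
            cand = T - s_prev
            for _ in range(7):
                if s_prev + cand == T:
                    return head + [cand]
                cand = math.nextafter(
                    cand, math.inf if s_prev + cand < T else -math.inf
                )
    return ts[:-1] + [T - sum(ts[:-1])]


@dataclass
class VoxelScorer:
    """Accumulates Sigma t, Sigma t*I_p and fluence per voxel.

    ``k_values`` selects which F_k definitions are tracked; ``rho0`` is the
    density (g cm^-3) of the medium the database was computed in.  Track
    lengths are scaled by rho/rho0 so denser voxels see proportionally more
    ionization detail per geometric length.
    """

    db: IDDatabase
    voxel_volume: float = 1.0  # mm^3
    rho0: float = 1.0  # g cm^-3
    k_values: tuple[int, ...] = tuple(range(1, 11))
    sum_t: dict = field(default_factory=dict)  # voxel -> mm (density-scaled)
    sum_t_ip: dict = field(default_factory=dict)  # voxel -> array per k

    def _species_key(self, step: StepRecord) -> str:
        if step.species in self.db.species:
            return step.species
        return resolve_isotope(step.Z, step.A).species

    def score_step(self, step: StepRecord, mode: str = "substep") -> None:
        """Add one step's contribution in ``substep`` or legacy ``prestep`` mode."""
        if mode not in ("substep", "prestep"):
            raise ValueError(f"unknown mode {mode!r}")
        species = self._species_key(step)
        scale = step.density / self.rho0
        ks = np.asarray(self.k_values)
        if mode == "prestep":
            ip = self.db.interpolate_ip(species, step.E_pre)[ks - 1]
            contrib = step.step_length * scale * ip
            t_add = step.step_length * scale
        else:
            plan = substep_decompose(
                step.E_pre, step.E_post, self.db.energies(species), step.step_length
            )
            contrib = np.zeros(len(ks))
            for sub in plan.substeps:
                if sub.t == 0.0:
                    continue
                ip = self.db.interpolate_ip(species, sub.lookup_energy)[ks - 1]
                contrib += sub.t * scale * ip
            t_add = step.step_length * scale
        self.sum_t[step.voxel] = self.sum_t.get(step.voxel, 0.0) + t_add
        self.sum_t_ip[step.voxel] = self.sum_t_ip.get(
            step.voxel, np.zeros(len(ks))
        ) + contrib

    def score_steps(self, steps, mode: str = "substep") -> "VoxelScorer":
        for step in steps:
            self.score_step(step, mode=mode)
        return self

    def voxel_average(self) -> pd.DataFrame:
        """Per-voxel I_p = Sigma t*I_p / Sigma t (nm^-1); empty voxels omitted."""
        rows = []
        for voxel, st in sorted(self.sum_t.items()):
            if st <= 0:
                continue
            ip = self.sum_t_ip[voxel] / st
            rows.append((*voxel, st, *ip))
        cols = ["ix", "iy", "iz", "sum_t_mm"] + [f"ip_F{k}_per_nm" for k in self.k_values]
        return pd.DataFrame(rows, columns=cols)

    def fluence(self, voxel) -> float:
        """Track-length fluence estimator Sigma t / V (mm^-2)."""
        return self.sum_t.get(voxel, 0.0) / self.voxel_volume

    def cluster_dose(self) -> pd.DataFrame:
        """Cluster dose g = phi * I_p / rho0 per voxel and k, in pg^-1.

        Equals Sigma(t * I_p) / (V * rho0) with the track-length fluence
        estimator; voxels with zero fluence report g = 0.
        """
        # mm * nm^-1 -> clusters; mm^3 * g/cm^3 -> pg
        mass_pg = self.voxel_volume * self.rho0 * 1e-3 * PG_PER_G
        rows = []
        for voxel, st in sorted(self.sum_t.items()):
            phi = st / self.voxel_volume
            g = self.sum_t_ip[voxel] * NM_PER_MM / mass_pg
            rows.append((*voxel, phi, *g))
        cols = ["ix", "iy", "iz", "phi_per_mm2"] + [f"g_F{k}_per_pg" for k in self.k_values]
        return pd.DataFrame(rows, columns=cols)


def steps_spanned_histogram(steps, grid_energies: np.ndarray) -> np.ndarray:
    """Histogram of database energies spanned per step (diagnostic).

    Entry n is the number of steps with exactly n grid energies strictly
    inside (E_post, E_pre); steps near end of range span more intervals.
    """
    grid = np.sort(np.asarray(grid_energies, dtype=float))
    counts = [
        int(np.searchsorted(grid, s.E_pre, "left") - np.searchsorted(grid, s.E_post, "right"))
        for s in steps
    ]
    return np.bincount(counts) if counts else np.zeros(1, dtype=np.int64)


def depth_profile(
    df: pd.DataFrame,
    column: str,
    axis: str = "iz",
    voxel_size: float = 1.0,
    normalization_depth: float | None = None,
) -> pd.DataFrame:
    """1D profile of a voxel table column vs depth (mm).

    Depth is the voxel-center coordinate along ``axis``.  If
    ``normalization_depth`` is given the profile is divided by its value at
    the nearest voxel center; an empty normalization voxel is an error.
    """
    prof = df.groupby(axis)[column].mean().reset_index()
    prof["depth_mm"] = (prof[axis] + 0.5) * voxel_size
    if normalization_depth is not None:
        i = (prof["depth_mm"] - normalization_depth).abs().idxmin()
        ref = prof.loc[i, column]
        if not math.isfinite(ref) or ref == 0:
            raise ValueError("normalization voxel is empty")
        prof[column] = prof[column] / ref
    return prof[["depth_mm", column]]
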