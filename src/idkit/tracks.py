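"""Synthetic ionization-event histories with analytically tractable structure.

This generator is explicitly NOT track-structure physics.  Its single job is
to provide ground-truth input for the nanoscale scorer: a primary ray with
Poisson-distributed ionizations, optional secondary branches carrying
geometric ionization counts over exponential ranges, and Gaussian position
jitter.  Every rate is a free parameter, so closed-form expectations exist
for the quantities the scorer reports.

The default energy dependence of the primary ionization density follows
lambda_p(E) ~ 1/E, mimicking the rise of LET (and hence of large-cluster
frequencies) toward low energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import CylinderLattice, SourceSphere

__all__ = ["ToyTrackModel", "generate_history", "generate_histories", "closed_form_f1"]


class UnsupportedConfigurationError(ValueError):
    """Raised when a closed form is requested outside its tractable regime."""


@dataclass(frozen=True)
class ToyTrackModel:
    """Parameters of the toy history generator.

    primary_ionization_density
        lambda_p, expected primary ionizations per nm of track.
    secondary_yield
        expected secondary branch points per nm of primary track.
    secondary_range
        exponential scale (nm) of the secondary path length.
    secondary_ionizations
        mean of the geometric (support >= 1) ionization count per secondary.
    jitter_sigma
        isotropic Gaussian blur (nm) applied to every ionization position.
    """

    primary_ionization_density: float = 0.2
    secondary_yield: float = 0.0
    secondary_range: float = 5.0
    secondary_ionizations: float = 2.0
    jitter_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.primary_ionization_density,
            self.secondary_yield,
            self.secondary_range,
            self.jitter_sigma,
        ) < 0:
            raise ValueError("rates and scales must be non-negative")
        if self.secondary_ionizations < 1:
            raise ValueError("secondary_ionizations is a geometric mean, >= 1")

    @staticmethod
    def density_for_energy(energy: float, scale: float = 1.0) -> float:
        """Default lambda_p(E) = scale / E: low energy -> dense ionization."""
        if energy <= 0:
            raise ValueError("energy must be positive")
        return scale / energy


def _isotropic(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    u = rng.normal(size=(n, 3))
    return u / np.linalg.norm(u, axis=1)[:, None]


def _ray_cube_exit(p: np.ndarray, u: np.ndarray, half: float) -> float:
    """Distance along +u from interior point p to the cube surface."""
    with np.errstate(divide="ignore"):
        t = np.where(u > 0, (half - p) / u, np.where(u < 0, (-half - p) / u, np.inf))
    return float(t.min())


def _sphere_exit(p: np.ndarray, u: np.ndarray, radius: float) -> float:
    """Distance along +u from interior point p to the sphere surface."""
    b = float(p @ u)
    disc = radius**2 - float(p @ p) + b * b
    return -b + math.sqrt(max(disc, 0.0))


def sample_source_point(source: SourceSphere, rng: np.random.Generator) -> np.ndarray:
    """Uniform point inside the source sphere (the primary start law)."""
    p = rng.normal(size=3)
    p *= source.radius * rng.random() ** (1.0 / 3.0) / np.linalg.norm(p)
    return p + np.asarray(source.center, dtype=float)


def generate_history(
    model: ToyTrackModel,
    source: SourceSphere,
    cube_side: float,
    rng: np.random.Generator,
    start: np.ndarray | None = None,
    direction: np.ndarray | None = None,
):
    """One primary history: (event_positions (n,3) nm, track_length nm).

    The primary starts uniformly in the source sphere with an isotropic
    direction (both overridable for controlled fixtures) and travels in a
    straight line to the cube surface.  Primary ionizations are a Poisson
    process on the ray inside the cube but outside the (vacuum) sphere, and
    the returned track length covers exactly that segment.  Secondaries
    branch at Poisson points and deposit a geometric number of ionizations
    uniformly along an exponential-range straight path.
    """
    half = cube_side / 2.0
    if start is None:
        p = sample_source_point(source, rng)
    else:
        p = np.asarray(start, dtype=float)
    if direction is None:
        u = _isotropic(rng)[0]
    else:
        u = np.asarray(direction, dtype=float)
        u = u / np.linalg.norm(u)

    rel = p - np.asarray(source.center, dtype=float)
    t_sphere = _sphere_exit(rel, u, source.radius) if source.radius > 0 else 0.0
    t_cube = _ray_cube_exit(p, u, half)
    track_length = max(t_cube - t_sphere, 0.0)
    if track_length <= 0:
        return np.empty((0, 3)), 0.0

    events = []
    lam = model.primary_ionization_density
    if lam > 0:
        n_prim = rng.poisson(lam * track_length)
        s = t_sphere + track_length * rng.random(n_prim)
        events.append(p[None, :] + s[:, None] * u[None, :])

    if model.secondary_yield > 0:
        n_sec = rng.poisson(model.secondary_yield * track_length)
        for _ in range(n_sec):
            s0 = t_sphere + track_length * rng.random()
            origin = p + s0 * u
            v = _isotropic(rng)[0]
            rng_len = rng.exponential(model.secondary_range)
            # geometric with mean m on support {1, 2, ...}
            n_ion = rng.geometric(1.0 / model.secondary_ionizations)
            d = rng_len * rng.random(n_ion)
            events.append(origin[None, :] + d[:, None] * v[None, :])

    if events:
        ev = np.concatenate(events, axis=0)
    else:
        ev = np.empty((0, 3))
    if model.jitter_sigma > 0 and len(ev):
        ev = ev + rng.normal(scale=model.jitter_sigma, size=ev.shape)
    return ev, track_length


def generate_histories(
    model: ToyTrackModel,
    source: SourceSphere,
    cube_side: float,
    n: int,
    seed: int | None = None,
    **kwargs,
):
    """List of ``n`` histories from a fresh seeded generator (deterministic)."""
    rng = np.random.default_rng(model.seed if seed is None else seed)
    return [generate_history(model, source, cube_side, rng, **kwargs) for _ in range(n)]


def closed_form_f1(model: ToyTrackModel, cyl_length: float) -> float:
    """Expected F_1 (clusters of >= 1 ionization per nm) on a cylinder axis.

    Valid only for a secondary-free, jitter-free model with the primary
    running along the axis of a contiguous stack of cylinders at pitch equal
    to their length: each cylinder independently holds Poisson(lambda * L)
    primary ionizations, so clusters per nm = (1 - exp(-lambda L)) / L.
    """
    if model.secondary_yield != 0 or model.jitter_sigma != 0:
        raise UnsupportedConfigurationError(
            "closed form requires secondaries and jitter disabled"
        )
    if cyl_length <= 0:
        raise ValueError("cyl_length must be positive")
    lam = model.primary_ionization_density
    return -math.expm1(-lam * cyl_length) / cyl_length
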