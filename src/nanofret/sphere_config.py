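"""Random molecular configurations on a spherical nanoparticle surface.

A nanoparticle of radius ``R`` (surface ``S = 4*pi*R**2``) carries ``N``
donor and ``M`` acceptor fluorophores at fixed, independently uniform
random positions on the surface.  A :class:`Configuration` stores the
ordered position list; by convention indices ``0 .. N-1`` are donors and
``N .. N+M-1`` are acceptors.

Distances that enter the dipole-dipole transfer rates are *chord* (straight
through-space) distances, not geodesic arcs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SphereSpec",
    "Configuration",
    "sample_configuration",
    "chord_distance",
    "pairwise_chord_distances",
]

#: Two sampled points closer than this fraction of ``R`` are treated as
#: coincident and the later point is redrawn: the r**-6 transfer rate
#: diverges and the model assumes distinct binding sites.
COINCIDENCE_FRACTION = 1e-6


@dataclass(frozen=True)
class SphereSpec:
    """Geometry and composition of one labelled nanoparticle.

    Parameters
    ----------
    radius
        Nanoparticle radius ``R`` in nm.
    n_donors
        Number of donor fluorophores ``N`` (at least one, so that there is
        something to excite).
    n_acceptors
        Number of acceptor traps ``M`` (may be zero).
    """

    radius: float
    n_donors: int
    n_acceptors: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.radius) and self.radius > 0):
            raise ValueError(f"radius must be a positive finite length, got {self.radius!r}")
        if int(self.n_donors) != self.n_donors or self.n_donors < 1:
            raise ValueError(f"n_donors must be an integer >= 1, got {self.n_donors!r}")
        if int(self.n_acceptors) != self.n_acceptors or self.n_acceptors < 0:
            raise ValueError(f"n_acceptors must be an integer >= 0, got {self.n_acceptors!r}")

    @property
    def n_total(self) -> int:
        return int(self.n_donors) + int(self.n_acceptors)

    @property
    def surface_area(self) -> float:
        """Surface area ``S = 4*pi*R**2`` in nm^2."""
        return 4.0 * np.pi * self.radius**2


@dataclass
class Configuration:
    """Positions and species labels of all fluorophores on one nanoparticle.

    ``positions`` is an ``(N+M, 3)`` array of Cartesian coordinates in nm;
    rows ``0 .. N-1`` are donors, the rest acceptors.  Every position must
    lie on the sphere to within ``1e-9 * R``.
    """

    positions: np.ndarray
    spec: SphereSpec
    seed: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (self.spec.n_total, 3):
            raise ValueError(
                f"positions must have shape {(self.spec.n_total, 3)}, got {self.positions.shape}"
            )
        radii = np.linalg.norm(self.positions, axis=1)
        if np.any(np.abs(radii - self.spec.radius) > 1e-9 * self.spec.radius):
            raise ValueError("all positions must lie on the sphere surface")

    @property
    def is_acceptor(self) -> np.ndarray:
        """Boolean mask, True for acceptor rows."""
        mask = np.zeros(self.spec.n_total, dtype=bool)
        mask[self.spec.n_donors:] = True
        return mask

    @property
    def species(self) -> np.ndarray:
        """Array of 'D' / 'A' labels, donors first."""
        return np.where(self.is_acceptor, "A", "D")

    @property
    def donor_positions(self) -> np.ndarray:
        return self.positions[: self.spec.n_donors]

    @property
    def acceptor_positions(self) -> np.ndarray:
        return self.positions[self.spec.n_donors:]

    # -- serialization ------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(self.spec.n_total),
                "species": self.species,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """One row per molecule: index, species tag, x, y, z (nm)."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, seed: int | None = None) -> "Configuration":
        frame = pd.read_csv(path)
        positions = frame[["x", "y", "z"]].to_numpy(dtype=float)
        species = frame["species"].to_numpy()
        n_donors = int(np.sum(species == "D"))
        n_acceptors = int(np.sum(species == "A"))
        radius = float(np.linalg.norm(positions, axis=1).mean())
        spec = SphereSpec(radius=radius, n_donors=n_donors, n_acceptors=n_acceptors)
        return cls(positions=positions, spec=spec, seed=seed)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "radius": self.spec.radius,
            "n_donors": self.spec.n_donors,
            "n_acceptors": self.spec.n_acceptors,
            "seed": self.seed,
            "positions": self.positions.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "Configuration":
        payload = json.loads(Path(path).read_text())
        spec = SphereSpec(
            radius=payload["radius"],
            n_donors=payload["n_donors"],
            n_acceptors=payload["n_acceptors"],
        )
        return cls(positions=np.array(payload["positions"]), spec=spec, seed=payload.get("seed"))


def sample_configuration(
    spec: SphereSpec,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> Configuration:
    """Draw ``N + M`` positions i.i.d. uniform on the sphere of radius ``R``.

    Sampling normalizes independent standard Gaussian triples, which is
    rejection-free and exactly uniform.  If two points land closer than
    ``COINCIDENCE_FRACTION * R`` (chord distance) the later point of the
    offending pair is redrawn, because the dipole-dipole rate diverges for
    coincident sites.

    The draw is reproducible: the same ``spec`` and integer ``seed`` always
    return the same configuration.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_total
    positions = _unit_vectors(rng, n) * spec.radius

    tol = COINCIDENCE_FRACTION * spec.radius
    while True:
        dist = squareform(pdist(positions))
        np.fill_diagonal(dist, np.inf)
        bad_i, bad_j = np.where(dist < tol)
        if bad_i.size == 0:
            break
        redraw = np.unique(np.maximum(bad_i, bad_j))  # resample the later point of each pair
        positions[redraw] = _unit_vectors(rng, redraw.size) * spec.radius

    stored_seed = seed if isinstance(seed, (int, np.integer)) else None
    return Configuration(positions=positions, spec=spec, seed=stored_seed)


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    """``n`` i.i.d. uniform unit vectors via normalized Gaussian triples."""
    vecs = rng.standard_normal((n, 3))
    norms = np.linalg.norm(vecs, axis=1)
    # a numerically zero Gaussian triple is essentially impossible, but guard anyway
    while np.any(norms < 1e-12):
        bad = norms < 1e-12
        vecs[bad] = rng.standard_normal((int(bad.sum()), 3))
        norms = np.linalg.norm(vecs, axis=1)
    return vecs / norms[:, None]


def chord_distance(a: np.ndarray, b: np.ndarray) -> float | np.ndarray:
    """Straight-line (through-space) Euclidean distance between two points.

    For two points on a sphere of radius ``R`` the result lies in
    ``[0, 2R]``; antipodal points are separated by the diameter ``2R`` and
    orthogonal radius vectors by ``sqrt(2)*R``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.linalg.norm(a - b, axis=-1)


def pairwise_chord_distances(positions: np.ndarray) -> np.ndarray:
    """Dense symmetric matrix of chord distances, zeros on the diagonal."""
    return squareform(pdist(np.asarray(positions, dtype=float)))
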