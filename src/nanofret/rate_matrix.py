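"""Förster transfer rates and the master-equation generator.

The pairwise excitation-transfer rate follows the point-dipole Förster law

    w(r) = (1/tau0) * (R0 / r)**6,

with the orientational average absorbed into the Förster radius ``R0`` (one
scalar per pair class: donor-donor ``R0_DD``, donor-acceptor ``R0_DA`` and,
optionally, acceptor-acceptor ``R0_AA``).

:func:`build_transition_matrix` assembles the generator ``W`` of the
single-excitation master equation ``dP/dt = W P``.  Entry ``(j, k)`` with
``j != k`` is the rate of the ``k -> j`` transfer; diagonal entries collect
the total outflow of each column (all outgoing transfers plus the
deactivation rate ``1/tau0``).  Donor-to-acceptor transfer is irreversible:
the donor-row / acceptor-column block is identically zero, so each column
sums to ``-1/tau0_d`` (donor columns) or ``-1/tau0_a`` (acceptor columns) —
probability leaks only through deactivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sphere_config import Configuration, pairwise_chord_distances

__all__ = [
    "PhotophysicsParams",
    "TransitionMatrix",
    "forster_rate",
    "build_transition_matrix",
]


@dataclass(frozen=True)
class PhotophysicsParams:
    """Photophysical parameters of the donor/acceptor pair classes.

    Parameters
    ----------
    r0_dd, r0_da, r0_aa
        Förster radii (nm) for donor-donor migration, donor-acceptor
        trapping and acceptor-acceptor migration.  ``r0_aa`` defaults to 0,
        i.e. acceptors act purely as traps.
    tau0_d
        Unquenched donor lifetime.  The radiative and non-radiative
        deactivation channels are absorbed into this single time constant.
        Defaults to 1, the reduced time unit of the whole package.
    tau0_a
        Acceptor lifetime; defaults to ``tau0_d``.
    """

    r0_dd: float
    r0_da: float
    r0_aa: float = 0.0
    tau0_d: float = 1.0
    tau0_a: float | None = None

    def __post_init__(self) -> None:
        if self.tau0_a is None:
            object.__setattr__(self, "tau0_a", self.tau0_d)
        if not (self.tau0_d > 0 and self.tau0_a > 0):
            raise ValueError("lifetimes tau0_d and tau0_a must be positive")
        for name in ("r0_dd", "r0_da", "r0_aa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class TransitionMatrix:
    """Dense master-equation generator for one configuration.

    ``matrix`` is ``(N+M, N+M)`` with units of inverse time; see the module
    docstring for the sign and block conventions.
    """

    matrix: np.ndarray
    n_donors: int
    n_acceptors: int

    @property
    def n_total(self) -> int:
        return self.n_donors + self.n_acceptors

    def column_sums(self) -> np.ndarray:
        """Total column outflow; equals -1/tau0 of the column's species."""
        return self.matrix.sum(axis=0)


def forster_rate(r, r0: float, tau0: float = 1.0):
    """Point-dipole transfer rate ``w = (1/tau0) * (r0/r)**6``.

    At ``r == r0`` the transfer rate equals the deactivation rate
    ``1/tau0``; ``r0 == 0`` switches the channel off.  ``r`` may be a
    scalar or an array; non-positive separations are rejected because the
    rate diverges.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr[np.isfinite(r_arr)] <= 0):
        raise ValueError("separation r must be positive (rate diverges at r = 0)")
    if tau0 <= 0:
        raise ValueError("tau0 must be positive")
    if r0 == 0:
        out = np.zeros_like(r_arr)
    else:
        out = (r0 / r_arr) ** 6 / tau0
    return out if out.ndim else float(out)


def build_transition_matrix(config: Configuration, params: PhotophysicsParams) -> TransitionMatrix:
    """Assemble the generator ``W`` for one molecular configuration.

    Raises a domain error (propagated from :func:`forster_rate`) if any two
    molecules coincide.
    """
    n_d = config.spec.n_donors
    n_a = config.spec.n_acceptors
    size = n_d + n_a

    dist = pairwise_chord_distances(config.positions)
    if np.any(dist[~np.eye(size, dtype=bool)] == 0):
        raise ValueError("coincident molecules: transfer rate diverges")
    np.fill_diagonal(dist, np.inf)  # suppresses self-transfer terms

    w = np.zeros((size, size))
    w[:n_d, :n_d] = forster_rate(dist[:n_d, :n_d], params.r0_dd, params.tau0_d)
    # acceptor rows <- donor columns: irreversible trapping
    w[n_d:, :n_d] = forster_rate(dist[n_d:, :n_d], params.r0_da, params.tau0_d)
    if n_a and params.r0_aa > 0:
        w[n_d:, n_d:] = forster_rate(dist[n_d:, n_d:], params.r0_aa, params.tau0_a)
    # donor rows <- acceptor columns stay zero: no back transfer

    decay = np.concatenate(
        [np.full(n_d, 1.0 / params.tau0_d), np.full(n_a, 1.0 / params.tau0_a)]
    )
    idx = np.arange(size)
    w[idx, idx] = -(w.sum(axis=0) + decay)
    return TransitionMatrix(matrix=w, n_donors=n_d, n_acceptors=n_a)
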