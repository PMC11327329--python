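"""Kinetic Monte Carlo (Gillespie) simulation of excitation hopping.

Each trajectory realizes the continuous-time Markov jump process generated
by the master equation: from a donor, the excitation either deactivates
(rate ``1/tau0_d``), hops to another donor (Förster rate ``w_DD``), or is
transferred to an acceptor (``w_DA``), where it deactivates at rate
``1/tau0_a`` (optionally after acceptor-acceptor hops when ``r0_aa > 0``).
Trapping is irreversible, so for donor observables the walk effectively
ends at the first donor-to-acceptor transfer.

Event selection is rejection-free: per-site cumulative rate tables are
precomputed once per configuration (O(n^2) setup) and each hop costs one
binary search.  Donor pairs whose mutual hopping rate exceeds
``MERGE_RATE_FACTOR / tau0_d`` — sub-nanometre contacts on a typical
nanoparticle, where the r**-6 rate makes the pair exchange the excitation
millions of times per lifetime — are collapsed into a single effective
site with the member-averaged outgoing rates.  Internal equilibration of
such a cluster is orders of magnitude faster than every other process, so
the collapse changes observables only at the relative level of the rate
ratio (~1e-4) while removing an unbounded amount of bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .master_solver import DecayCurve
from .rate_matrix import PhotophysicsParams, forster_rate
from .sphere_config import Configuration, SphereSpec, pairwise_chord_distances, sample_configuration

__all__ = [
    "TrajectoryOutcome",
    "MsdEstimate",
    "simulate_trajectory",
    "run_trajectories",
    "mc_donor_decay",
    "mc_donor_decay_for_config",
    "mc_relative_msd",
    "MERGE_RATE_FACTOR",
]

#: Donor-donor rates above this multiple of the donor deactivation rate are
#: treated as instantaneous exchange and the pair is merged into one site.
MERGE_RATE_FACTOR = 1e4


@dataclass
class TrajectoryOutcome:
    """One excitation history.

    ``terminal_time`` is the deactivation instant (including the acceptor
    residence when trapped); ``donor_exit_time`` is when the excitation left
    the donor subsystem, by donor deactivation or by trapping.
    """

    terminal_type: str  # 'donor_deactivation' | 'acceptor_trap_then_deactivation'
    terminal_time: float
    initial_position: np.ndarray
    terminal_position: np.ndarray
    n_hops: int
    trapped: bool
    donor_exit_time: float


@dataclass(frozen=True)
class MsdEstimate:
    """Relative RMS excitation displacement ``sqrt(<r^2>) / r0_da``."""

    value: float
    stderr: float
    n_traj: int


@dataclass
class _SimTables:
    """Precomputed per-configuration rate tables on the (possibly merged) site set."""

    cum_rates: np.ndarray  # (S, S) row-wise cumulative outgoing transfer rates
    total_rates: np.ndarray  # (S,) total outgoing transfer rate per site
    decay_rates: np.ndarray  # (S,) deactivation rate per site
    is_acceptor: np.ndarray  # (S,) bool
    site_positions: np.ndarray  # (S, 3) cluster centroids / molecule positions
    donor_site_sizes: np.ndarray  # (n_donor_sites,) cluster multiplicities
    n_donor_sites: int


def _build_tables(
    config: Configuration,
    params: PhotophysicsParams,
    merge_rate_factor: float = MERGE_RATE_FACTOR,
) -> _SimTables:
    n_d = config.spec.n_donors
    n_a = config.spec.n_acceptors
    size = n_d + n_a

    dist = pairwise_chord_distances(config.positions)
    np.fill_diagonal(dist, np.inf)

    w_dd = forster_rate(dist[:n_d, :n_d], params.r0_dd, params.tau0_d)
    w_da = forster_rate(dist[:n_d, n_d:], params.r0_da, params.tau0_d)  # donor -> acceptor

    # collapse donor clusters linked by effectively instantaneous exchange
    threshold = merge_rate_factor / params.tau0_d
    adjacency = csr_matrix(w_dd > threshold)
    n_sites_d, labels = connected_components(adjacency, directed=False)
    membership = np.zeros((n_sites_d, n_d))
    membership[labels, np.arange(n_d)] = 1.0
    sizes = membership.sum(axis=1)

    rate_dd = (membership @ w_dd @ membership.T) / sizes[:, None]
    np.fill_diagonal(rate_dd, 0.0)
    rate_da = (membership @ w_da) / sizes[:, None]

    n_sites = n_sites_d + n_a
    rates = np.zeros((n_sites, n_sites))
    rates[:n_sites_d, :n_sites_d] = rate_dd
    rates[:n_sites_d, n_sites_d:] = rate_da
    if n_a and params.r0_aa > 0:
        rates[n_sites_d:, n_sites_d:] = forster_rate(dist[n_d:, n_d:], params.r0_aa, params.tau0_a)

    cum = np.cumsum(rates, axis=1)
    total = cum[:, -1].copy() if n_sites else np.zeros(0)
    decay = np.concatenate(
        [np.full(n_sites_d, 1.0 / params.tau0_d), np.full(n_a, 1.0 / params.tau0_a)]
    )
    is_acc = np.zeros(n_sites, dtype=bool)
    is_acc[n_sites_d:] = True
    positions = np.vstack(
        [
            (membership @ config.positions[:n_d]) / sizes[:, None],
            config.positions[n_d:],
        ]
    )
    return _SimTables(
        cum_rates=cum,
        total_rates=total,
        decay_rates=decay,
        is_acceptor=is_acc,
        site_positions=positions,
        donor_site_sizes=sizes,
        n_donor_sites=n_sites_d,
    )


@njit
def _run_kernel(cum_rates, total_rates, decay_rates, is_acceptor, init_sites, rng):
    n = init_sites.size
    term_site = np.empty(n, np.int64)
    exit_time = np.empty(n)
    term_time = np.empty(n)
    trapped = np.zeros(n, np.bool_)
    n_hops = np.zeros(n, np.int64)
    for idx in range(n):
        site = init_sites[idx]
        t = 0.0
        hops = 0
        is_trapped = False
        t_exit = -1.0
        while True:
            rate_sum = total_rates[site] + decay_rates[site]
            t += rng.standard_exponential() / rate_sum
            u = rng.random() * rate_sum
            if u < decay_rates[site]:
                if not is_trapped:
                    t_exit = t
                break
            target = np.searchsorted(cum_rates[site], u - decay_rates[site], side="right")
            hops += 1
            if (not is_acceptor[site]) and is_acceptor[target]:
                is_trapped = True
                t_exit = t
            site = target
        term_site[idx] = site
        exit_time[idx] = t_exit
        term_time[idx] = t
        trapped[idx] = is_trapped
        n_hops[idx] = hops
    return term_site, exit_time, term_time, trapped, n_hops


def run_trajectories(
    config: Configuration,
    params: PhotophysicsParams,
    n_traj: int,
    rng: np.random.Generator | int | None = None,
    tables: _SimTables | None = None,
):
    """Run ``n_traj`` excitation trajectories on one configuration.

    Returns ``(initial_sites, terminal_sites, donor_exit_times,
    terminal_times, trapped, n_hops, tables)`` as flat arrays; the tables
    are returned so callers can map site indices to positions.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if tables is None:
        tables = _build_tables(config, params)
    probs = tables.donor_site_sizes / tables.donor_site_sizes.sum()
    init = rng.choice(tables.n_donor_sites, size=n_traj, p=probs).astype(np.int64)
    term, exit_t, term_t, trapped, hops = _run_kernel(
        tables.cum_rates,
        tables.total_rates,
        tables.decay_rates,
        tables.is_acceptor,
        init,
        rng,
    )
    return init, term, exit_t, term_t, trapped, hops, tables


def simulate_trajectory(
    config: Configuration,
    params: PhotophysicsParams,
    rng: np.random.Generator | int | None = None,
) -> TrajectoryOutcome:
    """Simulate a single excitation history, starting on a uniform random donor."""
    init, term, exit_t, term_t, trapped, hops, tables = run_trajectories(config, params, 1, rng)
    was_trapped = bool(trapped[0])
    return TrajectoryOutcome(
        terminal_type="acceptor_trap_then_deactivation" if was_trapped else "donor_deactivation",
        terminal_time=float(term_t[0]),
        initial_position=tables.site_positions[init[0]].copy(),
        terminal_position=tables.site_positions[term[0]].copy(),
        n_hops=int(hops[0]),
        trapped=was_trapped,
        donor_exit_time=float(exit_t[0]),
    )


def _survival_fractions(exit_times: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Fraction of trajectories still on a donor at each grid time (exact, unbinned)."""
    sorted_exit = np.sort(exit_times)
    return 1.0 - np.searchsorted(sorted_exit, times, side="right") / sorted_exit.size


def mc_donor_decay_for_config(
    config: Configuration,
    params: PhotophysicsParams,
    times: np.ndarray,
    n_traj: int,
    seed: int | np.random.Generator | None = None,
) -> DecayCurve:
    """Monte Carlo donor survival curve for one fixed configuration.

    ``stderr`` is binomial.  Survival is evaluated exactly at the grid
    points from the event times, without binning.
    """
    times = np.asarray(times, dtype=float)
    _, _, exit_t, _, _, _, _ = run_trajectories(config, params, n_traj, seed)
    values = _survival_fractions(exit_t, times)
    stderr = np.sqrt(values * (1.0 - values) / n_traj)
    return DecayCurve(
        times=times,
        values=values,
        stderr=stderr,
        includes_natural_decay=True,
        meta={"method": "kmc_single_config", "n_traj": n_traj},
    )


def mc_donor_decay(
    spec: SphereSpec,
    params: PhotophysicsParams,
    times: np.ndarray,
    n_traj: int = 1000,
    n_configs: int = 20,
    seed: int | None = None,
) -> DecayCurve:
    """Configuration-averaged Monte Carlo donor decay.

    ``n_traj`` trajectories are run on each of ``n_configs`` independent
    random configurations.  ``stderr`` is the between-configuration
    standard error when ``n_configs > 1`` (which includes the trajectory
    shot noise), else binomial.
    """
    times = np.asarray(times, dtype=float)
    root = np.random.SeedSequence(seed)
    per_config = np.empty((n_configs, times.size))
    for i, child in enumerate(root.spawn(n_configs)):
        config_ss, traj_ss = child.spawn(2)
        config = sample_configuration(spec, config_ss)
        _, _, exit_t, _, _, _, _ = run_trajectories(
            config, params, n_traj, np.random.default_rng(traj_ss)
        )
        per_config[i] = _survival_fractions(exit_t, times)
    values = per_config.mean(axis=0)
    if n_configs > 1:
        stderr = per_config.std(axis=0, ddof=1) / np.sqrt(n_configs)
    else:
        stderr = np.sqrt(values * (1.0 - values) / n_traj)
    meta = {
        "method": "kmc_ensemble",
        "spec": {"radius": spec.radius, "n_donors": spec.n_donors, "n_acceptors": spec.n_acceptors},
        "n_traj": n_traj,
        "n_configs": n_configs,
        "seed": seed,
    }
    return DecayCurve(times=times, values=values, stderr=stderr, includes_natural_decay=True, meta=meta)


def mc_relative_msd(
    spec: SphereSpec,
    params: PhotophysicsParams,
    n_traj: int = 5000,
    n_configs: int = 20,
    seed: int | None = None,
) -> MsdEstimate:
    """Relative RMS excitation displacement ``sqrt(<r^2>) / r0_da``.

    The displacement of one trajectory is the chord distance between the
    initially excited donor and the site occupied at deactivation — the
    trapping acceptor when a donor-to-acceptor transfer occurred, else the
    last donor visited.  The standard error combines the
    between-configuration spread with the trajectory shot noise via the
    delta method.
    """
    if params.r0_da <= 0:
        raise ValueError("r0_da must be positive to normalize the displacement")
    root = np.random.SeedSequence(seed)
    per_config_d2 = np.empty(n_configs)
    for i, child in enumerate(root.spawn(n_configs)):
        config_ss, traj_ss = child.spawn(2)
        config = sample_configuration(spec, config_ss)
        init, term, _, _, _, _, tables = run_trajectories(
            config, params, n_traj, np.random.default_rng(traj_ss)
        )
        disp = tables.site_positions[term] - tables.site_positions[init]
        per_config_d2[i] = float(np.mean(np.sum(disp**2, axis=1)))
    mean_d2 = per_config_d2.mean()
    if n_configs > 1:
        se_d2 = per_config_d2.std(ddof=1) / np.sqrt(n_configs)
    else:
        se_d2 = 0.0
    value = float(np.sqrt(mean_d2) / params.r0_da)
    stderr = float(se_d2 / (2.0 * np.sqrt(mean_d2)) / params.r0_da) if mean_d2 > 0 else 0.0
    return MsdEstimate(value=value, stderr=stderr, n_traj=n_traj * n_configs)
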