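# Methods

## Model

A spherical nanoparticle of radius `R` carries `N` donor and `M` acceptor
fluorophores at fixed positions, drawn independently and uniformly on the
surface `S = 4πR²`. A single electronic excitation moves through the system
as a continuous-time Markov jump process with pairwise Förster rates

    w_XY(r) = (1/τ₀) (R₀^XY / r)⁶,

where `r` is the chord (through-space) distance, `R₀^DD` and `R₀^DA` the
Förster radii for donor–donor migration and donor–acceptor trapping, and
`τ₀` the lifetime of the departing species. Orientational averaging is
absorbed into the scalar `R₀` of each pair class. Trapping is irreversible
(no acceptor→donor back transfer); acceptor–acceptor migration is part of
the generator but defaults off (`R₀^AA = 0`), since donor observables are
provably independent of it. Only one excitation exists at a time — no
annihilation, no re-excitation.

Assembled over one configuration, these rates form the master-equation
generator `W̃`: entry `(j, k)`, `j ≠ k`, is the `k → j` transfer rate;
diagonals collect all outgoing transfers plus deactivation; the
donor-row/acceptor-column block is identically zero. Consequently every
column sums to `−1/τ₀` of its species — probability leaks only through
deactivation — which the test suite asserts at 1e−12 relative tolerance.

Everything runs in reduced units: `τ₀ᴰ = 1` internally, with physical
curves recovered by scaling times and, for the analytic route, multiplying
the reduced decay by `e^{−t}`.

## Exact route (master_solver)

Per configuration, `P(t) = exp(tW̃) P(0)` with the initial excitation
uniform over donors — by linearity, that single propagation *is* the exact
average over the `N` single-donor initial conditions, so no sampling of the
initial site is ever needed. Systems up to 200 sites use scaling-and-squaring
`expm` stepped along the (sorted) time grid; larger systems fall back to
stiff BDF integration with a constant analytic Jacobian (rtol 1e−8,
atol 1e−12). The Laplace-domain components come from LU-factorized solves
of `(εI − W̃) x = e_j`, one right-hand side per initial donor, split into
the self-return part `Ĝ^SD`, the other-donor part `Ĝ^DD` and the acceptor
part `Ĝ^DA` (zero spatial frequency). Probability conservation gives the
exact sum rule `ε_D(Ĝ^SD + Ĝ^DD) + ε_A Ĝ^DA = 1`, which serves as the
numerical health check of the whole resolvent pipeline (asserted at 1e−10;
observed residuals are near machine precision).

Note on the resolvent convention: the Green components are written against
the full generator including the diagonal outflow terms, i.e.
`(εI − W̃)⁻¹`, so that they are literally the Laplace transforms of
`exp(tW̃)` matrix elements. The sum rule above and an explicit
time-domain/Laplace-domain consistency test (numerical quadrature of
`e^{−εt}` times the propagated survival) pin this convention down.

## Stochastic route (kmc_sim)

Rejection-free (direct) Gillespie simulation. Per configuration an
`O(n²)` setup precomputes per-site cumulative outgoing-rate tables; each
hop then costs one exponential waiting-time draw, one uniform draw and one
binary search. The compiled (numba) kernel runs ~10⁵ trajectories of the
largest study systems (600 sites) in about a second.

**Fast-exchange cluster collapse.** Uniform placement imposes no minimum
contact distance, so sub-nanometre donor–donor pairs occur with
appreciable probability on a 600-fluorophore particle, and the `r⁻⁶` rate
then makes the pair exchange the excitation up to ~10¹⁰ times per lifetime
— physically an instantaneously equilibrated dimer, computationally an
unbounded loop. Donor pairs whose mutual rate exceeds
`MERGE_RATE_FACTOR/τ₀ᴰ = 10⁴/τ₀ᴰ` are therefore collapsed (via connected
components of the fast-edge graph) into one effective site whose outgoing
rates are the member average — the quasi-stationary distribution inside a
symmetric-rate cluster is uniform — and whose position is the member
centroid. The approximation error scales like the ratio of external to
internal rates (≲10⁻⁴) and the position blur is far below `R₀^DA`; a
dedicated test plants a 0.67 nm donor pair (mutual rate ≈ 10⁵) and checks
the collapsed simulation against the exact matrix exponential.

**Displacement convention.** The excitation's displacement is the chord
distance between the initially excited donor and the site occupied at
deactivation — the trapping acceptor when a donor→acceptor transfer
occurred, the last donor otherwise. This convention makes single-donor
transfer events contribute to the spread (an emission-only convention
would pin them at zero, contradicting the observed growth of the spread
with acceptor number in the Förster regime). The reported statistic is
`√⟨r²⟩ / R₀^DA` with the mean over all trajectories; its standard error
combines the between-configuration spread with shot noise via the delta
method.

Survival curves are evaluated exactly at the grid points from event times
(no binning). The reported uncertainty is the between-configuration
standard error when several configurations are averaged, else binomial.
For the `M = 0` comparisons in the tests the pooled binomial error is used
as a floor, because a spread estimated from a handful of configurations is
itself noisy while at `M = 0` every trajectory is exactly i.i.d.

## Analytic route (pade_decay)

In reduced variables `ξ_A = R₀^DA/R`, `ξ_D = R₀^DD/R`, the density
expansion of the donor-decay transform is resummed into the rational form

    Ĝᴰ(ε) = (1/ε) / [1 + M f₂(ε) + (M f₂(ε))² + (N−1)M f₃(ε) + M(M−1) g₃(ε)].

* `f₂` (one donor, one acceptor): closed form in
  `a = (ξ_A²/4) ε^{−1/3}`, valid for `a < 1`; its small-`a` limit is the
  power law `(√3π/18) ξ_A² ε^{−1/3}`. The two forms agree within 1% for
  `a ≤ 0.05`, and the closed form matches an independent surface-integral
  quadrature `(1/S)∫ w/(ε+w) dA` to 1e−8. The model uses the power-law
  form by default (the version that enters the final analytic result);
  the closed form is available via `f2_form="exact"`.
* `f₃` (two donors, one acceptor, positive — migration-assisted trapping):
  `ε^{−2/3} ξ_A² ξ_D² 𝒥₃ / (64π²)` with
  `𝒥₃(α) = 1/(a₃ + b₃α²)`, `a₃ = 0.02712`, `b₃ = 0.04649`,
  `α = ξ_A/ξ_D`. The constants are taken as given; the exact integral
  behind `𝒥₃` is not re-derived here.
* `g₃` (one donor, two acceptors, negative — competing traps):
  `ε^{−2/3} ξ_A⁴ 𝒦₃ / 16`, `𝒦₃ = −0.82764`.

Because `f₂² > |g₃|/M²`-wise (`(√3π/18)² > 0.82764/16` for every `ξ_A`),
the guarded denominator is provably positive for real `ε > 0`; the guard
raising a validity error is retained defensively. A separate *validity
warning* (`PadeValidityWarning`) fires when `M·f₂(ε*) > 1` at the
reference point `ε* = 1` — the acceptor load where the resummation is
known to start underestimating the decay (it does so at, e.g., `N = 500`,
`M = 400` in the study geometry). Computation proceeds; the warning is the
documented breakdown signal. The choice `ε* = 1` (one reduced lifetime) is
this package's convention for "where validity is assessed", since the
transform has no single natural scale.

**Inverse Laplace transform.** The transform has a branch point at the
origin (`ε^{−1/3}`), ruling out rational-approximation methods. The
primary inverter is a vectorized fixed-Talbot rule (48 nodes; the contour
`s = rθ(cot θ + i)`, `r = 2n/(5t)`, wraps the negative real axis without
crossing it, keeping the principal cube-root branch single-valued). It is
cross-checked by an independently implemented de Hoog quotient-difference
accelerated Fourier series (period `2t`, 40 terms, tol 1e−12). Both
recover the known pairs `1/ε → 1` and `1/(ε+1) → e^{−t}` to better than
1e−6, and agree with each other to 1e−6 relative on every model the tests
ship, including the breakdown regime. A term-by-term series oracle
(`L⁻¹[f₂/ε] ∝ t^{1/3}/Γ(4/3)`) independently validates the low-density
limit.

## Synthetic configurations

The generator *is* the study's input model: positions i.i.d. uniform on
the sphere (normalized Gaussian triples), donors first, acceptors after,
one root seed per run with all downstream randomness drawn from spawned
child streams (configuration sampling and trajectory simulation are
independently reproducible). The only regularization is a coincidence
guard: points closer than `10⁻⁶·R` are redrawn, since the rate law
diverges and the model assumes distinct binding sites.

What it deliberately does **not** emulate: finite dye size / minimum
contact distance, patchy or correlated coverage, shell-volume (rather than
surface) distributions, orientation dynamics, spectral disorder, or
multi-excitation effects. Passing tests therefore validate the stochastic
model and its analytic approximants, not the chemistry of any specific
dye–particle system.

## Default parameters and problem sizes

| Parameter | Default | Meaning |
|---|---|---|
| `R` | 50 nm | nanoparticle radius of the study regime |
| `R₀^DD` | 4.6 nm | donor–donor Förster radius |
| `R₀^DA` | 5.0 nm | donor–acceptor Förster radius |
| `R₀^AA` | 0 | acceptor migration off (pure traps) |
| `τ₀ᴰ`, `τ₀ᴬ` | 1 | reduced time unit |
| time grid | log, 0.01–10 `τ₀ᴰ`, 60 pts | decay-curve sampling |
| `MERGE_RATE_FACTOR` | 10⁴ | fast-exchange collapse threshold |
| Talbot nodes / de Hoog terms | 48 / 40 | inversion accuracy ≈ 1e−8 |

Validation problem sizes: the displacement statistic uses 20
configurations × 5000 trajectories at `N = 500`, `M = 100`; the
Monte-Carlo-vs-Padé comparison uses 10⁴ trajectories at `N = 100`;
small-system equivalence checks use `N + M ≤ 8` with 4000–6000
trajectories; ordering checks at `N = 500` use 30 configurations × 4000
trajectories per point. These sizes give standard errors a factor of
several below every tolerance asserted.

## Known limitations

* The three-body approximant degrades at very high acceptor loads
  (signalled by the validity warning) and at long times; the Monte Carlo
  route is the reference there.
* Only the zero-spatial-frequency Green components are produced; spatial
  spread is measured by Monte Carlo rather than through finite-`k`
  transforms.
* Acceptor-side observables (e.g. sensitized emission kinetics) are
  limited: with `R₀^AA > 0` acceptor–acceptor hops are simulated but
  acceptor clusters are not collapsed, so pathological sub-nanometre
  acceptor pairs could slow the kernel in that non-default mode.
* `expm`-based propagation above ~10⁵-fold rate spread relies on the BDF /
  scaling-and-squaring machinery's conditioning; the merged-pair KMC test
  and the sum rule bound the practical error, but extreme artificial
  geometries (chords ≪ 10⁻³ nm) are outside the validated envelope.
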