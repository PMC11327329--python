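# nanofret

Excitation energy migration and trapping among fluorophores attached to the
surface of a spherical nanoparticle.

`N` donor dyes (D) and `M` acceptor traps (A) sit at random positions on a
sphere of radius `R`. After a donor is excited, the excitation hops between
donors and is irreversibly transferred to acceptors through Förster
(point-dipole) coupling, `w(r) = (1/τ₀)(R₀/r)⁶`, with `r` the through-space
chord distance. Because the system is finite and curved, classic
infinite-volume energy-transfer kinetics do not apply: the donor decay and
the spatial range of the excitation walk depend jointly on `N`, `M`, `R`
and the Förster radii `R₀ᴰᴰ`, `R₀ᴰᴬ`. This package is for photophysicists
and nanomaterials modellers who need quantitative donor-decay and
excitation-transport predictions for labelled nanoparticles.

## What it computes

Three mutually cross-validating routes:

1. **Exact master equation** (`nanofret.master_solver`). For each random
   configuration the occupation probabilities obey `dP/dt = W̃ P`, where
   `W̃` collects all pair rates plus deactivation (`1/τ₀ᴰ`, `1/τ₀ᴬ`);
   the solution `P(t) = exp(tW̃) P(0)` is averaged over configurations.
   The Laplace-domain Green components `Ĝ^SD`, `Ĝ^DD`, `Ĝ^DA` from the
   resolvent `(εI − W̃)⁻¹` satisfy the sum rule
   `ε_D(Ĝ^SD + Ĝ^DD) + ε_A Ĝ^DA = 1`, checked to 1e−10.
2. **Kinetic Monte Carlo** (`nanofret.kmc_sim`). Rejection-free Gillespie
   trajectories of the same jump process; donor survival curves and the
   relative RMS excitation displacement `√⟨r²⟩ / R₀ᴰᴬ`.
3. **Padé approximants** (`nanofret.pade_decay`). In reduced units
   (time in `τ₀ᴰ`, natural decay factored out) the donor-decay transform is
   resummed as

   ```
   Ĝᴰ(ε) = (1/ε) / [1 + M f₂ + (M f₂)² + (N−1)M f₃ + M(M−1) g₃]
   ```

   with `f₂(ε) ≈ (√3π/18) ξ_A² ε^(−1/3)` (exact closed form also
   available), `f₃(ε) = ε^(−2/3) ξ_A² ξ_D² 𝒥₃/(64π²)`,
   `𝒥₃ = 1/(a + bα²)` (`a = 0.02712`, `b = 0.04649`, `α = ξ_A/ξ_D`), and
   `g₃(ε) = ε^(−2/3) ξ_A⁴ 𝒦₃/16` (`𝒦₃ = −0.82764`), where
   `ξ_A = R₀ᴰᴬ/R`, `ξ_D = R₀ᴰᴰ/R`. Dropping `f₃`/`g₃` gives the two-body
   approximant. Time-domain curves come from fixed-Talbot inversion,
   cross-checked against a de Hoog accelerated-series inverter.

## Worked example

```python
import numpy as np
from nanofret import (SphereSpec, PhotophysicsParams, ReducedVariables,
                      LaplaceDecayModel, invert_to_decay, mc_donor_decay,
                      mc_relative_msd)

spec = SphereSpec(radius=50.0, n_donors=100, n_acceptors=100)   # nm
params = PhotophysicsParams(r0_dd=4.6, r0_da=5.0)               # nm
times = np.array([0.1, 0.5, 1.0, 2.0, 5.0])                     # units of tau0_D

mc = mc_donor_decay(spec, params, times, n_traj=500, n_configs=20, seed=1)
model = LaplaceDecayModel(100, 100, ReducedVariables.from_radii(50.0, 5.0, 4.6))
pade = invert_to_decay(model, times, include_natural_decay=True)
for t, i_mc, se, i_p in zip(times, mc.values, mc.stderr, pade.values):
    print(f"t={t:4.1f}  I_mc={i_mc:.4f} +- {se:.4f}   I_pade3={i_p:.4f}")

est = mc_relative_msd(SphereSpec(50.0, 500, 100), params,
                      n_traj=5000, n_configs=20, seed=1)
print(f"relative RMS displacement (N=500, M=100): {est.value:.3f} +- {est.stderr:.3f}")
```

Output:

```
t= 0.1  I_mc=0.7764 +- 0.0087   I_pade3=0.7707
t= 0.5  I_mc=0.4650 +- 0.0099   I_pade3=0.4597
t= 1.0  I_mc=0.2558 +- 0.0071   I_pade3=0.2590
t= 2.0  I_mc=0.0852 +- 0.0038   I_pade3=0.0868
t= 5.0  I_mc=0.0043 +- 0.0008   I_pade3=0.0037
relative RMS displacement (N=500, M=100): 1.025 +- 0.007
```

With 100 donors and 100 acceptors on a 50 nm particle the donor emission
decays several times faster than the bare exponential (`e^{-1} ≈ 0.368` at
`t = 1`) and is markedly non-exponential; the analytic three-body curve
tracks the simulation to better than 0.01 everywhere. The displacement
figure means the excitation typically ends its life about one
donor–acceptor Förster radius (≈ 5 nm) away from where it was created —
migration is not a local process on this particle.

A command-line interface mirrors the library:

```
nanofret compare --n-donors 100 --n-acceptors 100 --n-traj 500 --out run1
nanofret msd --sweep "1:100,100:100,500:100" --out msd1
nanofret pade --n-donors 300 --n-acceptors 200 --out pade1
```

Each run writes a CSV table and a JSON summary embedding the full run
configuration and package version.

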