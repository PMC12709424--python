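"""Staged accelerated sampling of a double well with cumulant reweighting.

Runs the three-stage boost protocol (unbiased statistics collection,
equilibration with periodic parameter updates, production with frozen
parameters) on a 2.5 kcal/mol double well at 300 K, then recovers the
unbiased free-energy profile from the boosted samples via the
second-order cumulant correction.  The printed table compares the
reweighted profile against exact numerical quadrature of the potential:
agreement within ~0.2 kcal/mol on well-sampled bins shows the boost both
accelerated barrier crossing and remained reweightable.
"""

import numpy as np

from loopdyn import gamd
from loopdyn.potentials import DoubleWell, LandscapeSpec
from loopdyn.synthetic import simulate_langevin

kT = 0.596  # kcal/mol at 300 K
dw = DoubleWell(barrier=2.5, kappa_y=2.0)
spec = LandscapeSpec(wells=[((-1, 0), 1, 1)], kT=kT, dt=0.002, seed=11)

run = gamd.run_staged_gamd(
    spec, stage_lengths=(5000, 20_000, 200_000), sigma0=0.6, potential=dw,
    x0=(-1.0, 0.0),
)
p = run.params["total"]
print(f"boost parameters: E={p.E:.2f} kcal/mol, k0={p.k0:.3f}, "
      f"k={p.k:.4f} (kcal/mol)^-1")
print(f"boost magnitude:  <dV>={run.deltaV.mean():.2f}, "
      f"sigma(dV)={run.deltaV.std():.2f} kcal/mol (cap sigma0=0.6)")

unbiased = simulate_langevin(spec, 200_000, potential=dw, x0=(-1.0, 0.0))
n_unb = gamd.count_well_transitions(unbiased[:, 0])
n_boost = gamd.count_well_transitions(run.positions[:, 0])
print(f"barrier crossings in equal production time: "
      f"unbiased {n_unb}, boosted {n_boost}")

edges = np.linspace(-1.6, 1.6, 17)
prof = gamd.reweight_pmf(run, kT=kT, bins=edges, min_samples=100)
centers = 0.5 * (edges[:-1] + edges[1:])
ref = dw.energy(np.column_stack([centers, np.zeros(16)]))
ref -= ref.min()
print(f"\n{'x':>6s} {'F reweighted':>13s} {'U(x, 0)':>9s}   (kcal/mol)")
for c, f, r in zip(centers, prof.F, ref):
    if np.isfinite(f):
        print(f"{c:6.2f} {f:13.2f} {r:9.2f}")
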