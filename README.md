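# loopdyn

Markov state model and accelerated-sampling analysis toolkit for kinase
activation-loop conformational dynamics.

## The problem

Ser/Thr kinases of the casein kinase 1 family phosphorylate their circadian
substrates with a selectivity that is encoded conformationally: the
activation loop toggles between a "loop up" and a "loop down" arrangement
that reshape the substrate cleft, and mutations near the anion-binding
sites (such as the period-shortening *tau* mutant) invert both the
equilibrium preference and the exchange kinetics of this switch.  Resolving
that equilibrium from molecular-dynamics simulation requires integrating
many microseconds of trajectories into a single kinetic model — the Markov
state model (MSM) workflow:

1. **Featurize** trajectories into informative internal coordinates
   (pairwise distances, backbone dihedrals with circular embedding).
2. **tICA** — project features onto the slowest linear collective variables
   by solving the generalized eigenproblem `C_tau v = lambda C_0 v` over
   instantaneous and time-lagged covariances.
3. **Discretize** the slow subspace into microstates by k-means.
4. **Estimate** the reversible maximum-likelihood transition matrix
   `T(tau)` from transition counts (detailed-balance-constrained MLE) and
   validate it via implied-timescale flatness and the Chapman–Kolmogorov
   test.
5. **Coarse-grain** with PCCA+ into metastable macrostates; report
   equilibrium populations `Pi_A = sum_{i in A} pi_i` and mean first
   passage times from the first-step system
   `m_i = tau + sum_j T_ij m_j` (`m_i = 0` on the target).
6. **Present** MSM-weighted free-energy surfaces
   `F = -kT ln(p / p_max)`, distance-interaction histograms, and voxel
   occupancy maps.

The package also implements desk-scale Gaussian accelerated dynamics
(GaMD): the harmonic boost `dV = k/2 (E - V)^2` below a threshold
`E = Vmax` with `k0 = min(1, (sigma0/sigma_V) (Vmax-Vmin)/(Vmax-Vavg))`,
the three-stage protocol (statistics collection, adaptive equilibration,
frozen-parameter production), and second-order cumulant reweighting
`ln p = ln p* + beta <dV> + beta^2/2 var(dV)` back to the unbiased surface.

Because production MD datasets are tens of gigabytes, everything here is
exercised on synthetic data with retained ground truth: hidden-Markov
feature emitters mimicking the wild-type-like and tau-like study
conditions, circular-angle emitters for dihedral-only models, overdamped
Langevin dynamics on known 2-D landscapes, and toy coordinate trajectories
for featurization.  Every estimator is tested for *recovery* of the known
generating parameters.

## Worked example

```bash
python examples/run_conformational_pipeline.py
```

runs the full chain on both synthetic study conditions and prints:

```
=== scenario: wt ===
         state  pop (true)  pop (est)
            up       0.150      0.135
  intermediate       0.100      0.105
          down       0.750      0.760
MFPT up->down:  true    33.3 ns, est    31.7 ns
MFPT down->up:  true   166.7 ns, est   176.5 ns

=== scenario: tau ===
         state  pop (true)  pop (est)
            up       0.700      0.706
  intermediate       0.120      0.122
          down       0.180      0.172
MFPT up->down:  true    13.4 ns, est    13.8 ns
MFPT down->up:  true     4.3 ns, est     4.2 ns
```

Each block compares metastable-state populations and mean first passage
times recovered by the pipeline (tICA at lag 10 frames, 100 microstates,
reversible MSM at lag 2 frames, PCCA+ with 3 macrostates) against the
hidden kinetics that generated the data.  The wild-type-like condition is
loop-down dominant with slow exchange; the tau-like condition inverts the
preference to loop-up and exchanges several-fold faster — the designed
contrast the estimators must (and do) resolve.

Other examples: `dihedral_switch_msm.py` (MSM from a single backbone
angle), `gamd_double_well.py` (staged boost + reweighting),
`featurize_toy_protein.py` (distances, RMSF, PDB round trip, occupancy
map), `sampling_budget.py` (MD campaign arithmetic).

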