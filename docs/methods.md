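# Methods

This note records the models implemented in `loopdyn`, the defaults that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Synthetic study conditions

`synthetic.make_ck1_like_dataset` emits 5-dimensional "pairwise distance"
feature trajectories from a hidden 3-state Markov chain with Gaussian
emissions.  The two scenarios encode the qualitative physics of an
activation-loop switch and its fast mutant:

- **wt**: states (up, intermediate, down), stationary distribution
  (0.15, 0.10, 0.75), exchange only through the intermediate (the
  loop-EF-unfolded state); per-frame transition probabilities 0.004
  (up→int), 0.006/0.030 (int→up / int→down), 0.004 (down→int).
- **tau**: preference inverted to (0.70, 0.12, 0.18) with an additional
  *direct* up↔down channel; all exchange at least twice as fast as wt.
  Analytically, the up→down MFPT contrast is 2.48x and down→up is 38.9x
  (`DESIGNED_KINETICS_FACTOR = 2.0` is the guaranteed floor).

Neither scenario's numbers are measurements; they are design choices that
reproduce the qualitative pattern (dominant-state inversion, >= 2x
kinetics acceleration, an intermediate present only on the slow pathway).
Emission means are separated by ~3–5 Angstrom at 0.7 Angstrom isotropic
spread, so microstates are nearly pure; the fifth feature is identical
across states, standing in for the uninformative coordinates every real
feature set carries.  Frame interval is fixed at 0.1 ns so recovered
MFPTs carry physical units.  Each trajectory uses an independent RNG
stream (`seed + trajectory_index`), making per-trajectory regeneration
stable.

What the generator does **not** emulate: state-dependent emission
anisotropy, slow within-state diffusion (emissions are i.i.d. given the
state, so discretization error is much smaller than for real MD),
non-Markovian memory from projecting out fast degrees of freedom, and
trajectory-length heterogeneity.  Passing recovery tests therefore
demonstrates estimator correctness, not robustness to real-data
pathologies.

## tICA

Symmetrized (reversible) estimator: per-trajectory accumulation of
`C0` and `C_tau` about the joint instantaneous+lagged mean, no pairs
across trajectory boundaries, `C_tau <- (C_tau + C_tau^T)/2`, generalized
eigenproblem solved against `C0 + ridge I`.  Defaults: lag 10 frames,
ridge `1e-6 trace(C0)/dim`, 2 components retained for landscapes, no
kinetic-map scaling.  Constant columns are dropped with a warning.  Sign
convention: each component's largest-magnitude loading is positive.  The
ridge breaks exact scale equivariance at the ~1e-5 relative level (the
ridge scales with the trace); tests assert equivariance at 1e-4.

## Microstates

k-means (k-means++ init, one seeded run) in TIC space, default k = 100.
Assignment is nearest-center with ties to the lowest index.  Clustering
happens after tICA, never on raw features.

## Markov state models

Sliding-window transition counts by default (strided available), largest
strongly connected component retained, then the detailed-balance-
constrained MLE via the self-consistent fixed point on symmetric
auxiliary counts.  Convergence is declared on the maximum entrywise
change of `T` (default 1e-12) rather than on the log-likelihood, which is
quadratically flat near the optimum and stalls several orders of
magnitude before the matrix converges.  The spectrum comes from the
`diag(pi)^1/2 T diag(pi)^-1/2` symmetrization, guaranteeing real
eigenvalues; eigenvalues below 1e-12 are reported as undefined
timescales.

**Default MSM lag: 2 frames (0.2 ns).**  Lag selection follows the
standard rule — the shortest lag at which implied timescales are flat.
The synthetic hidden process is Markovian at the frame level and the
emission separation makes discretization nearly exact, so timescales are
converged already at 1–2 frames, and a short lag minimizes the O(tau)
discretization bias of MFPTs (at lag 10 the fast tau-scenario passages
would be overestimated by ~30% purely from lag resolution).  For real
data this default must be revisited with the `its_scan` diagnostic.

Validation: `its_scan` (implied timescales vs lag) and `ck_test`
(set-survival probabilities at multiples of the lag, predicted
`sum_{i in A} pi_i [T^k]_{iA} / sum_{i in A} pi_i` vs observed stay
frequencies with a 100-resample whole-trajectory bootstrap band).  Both
diagnostics are exercised positively (exactly Markovian data passes) and
negatively (a deliberate lumping of kinetically distinct states fails
both).

## Metastable decomposition

PCCA+ via the Deuflhard–Weber inner-simplex vertex search on the first m
right eigenvectors, followed by clipping slightly negative barycentric
coordinates and row renormalization; no subsequent membership
optimization.  For the well-separated metastable structure this package
targets, the crisp partition matches the exhaustive
metastability-maximizing partition (verified by brute force for k <= 8).
Populations are reported over crisp (maximal-membership) sets by default;
the membership-weighted variant `chi^T pi` is available.  The coarse
transition matrix is the pi-weighted projection
`(chi^T D chi)^{-1} chi^T D T chi`.

MFPT between macrostates: first-step linear solve on the *microstate*
matrix with the source average weighted by the stationary distribution
restricted to the source set.  MFPT of a set to itself is 0 by
convention.  `choose_macrostate_count` recommends the m in 2..max_m
maximizing the spectral-gap ratio `lambda_m / lambda_{m+1}` over positive
eigenvalue pairs, ties toward smaller m.

Macrostate naming is by nearest reference signature: the mean raw-feature
vector over each macrostate's frames is matched to per-state reference
vectors (for synthetic data, the generator's emission means), replacing
manual labeling with a reproducible rule.

## Landscapes, histograms, occupancy

Free-energy surfaces weight each frame by `pi_s / n_frames(s)` for its
microstate s, bin in the first two TICs (default 100x100 over the data
range padded 5%), and report `F = -ln(p/p_max)` in kT with empty bins NaN
(never zero).  Interaction histograms normalize to unit mass and report
the fraction strictly below a cutoff (defaults: 4.5 Angstrom hydrophobic,
4.0 Angstrom salt bridge — conventional values, not fitted).  Occupancy
grids use half-open 1.0 Angstrom voxels with floor binning and require
the caller to superpose frames first; a frame mask allows state-restricted
maps.  Exports: CSV tables and an OpenDX-style volumetric map.

## Langevin sampler and toy landscapes

Overdamped Euler–Maruyama,
`x <- x - (grad U/gamma) dt + sqrt(2 kT dt/gamma) xi`.  `LandscapeSpec`
wells are inverted Gaussian basins plus a weak harmonic confinement
(default 0.05 energy/length^2) so the Boltzmann measure is normalizable
and the quadrature oracle converges; `Harmonic` and `DoubleWell`
(`a (x^2-1)^2 + kappa_y/2 y^2`) are provided for closed-form checks.
Divergence (|x| > 1e3) aborts with a diagnostic.  Time-step bias is
O(dt); tests use dt = 0.002–0.01 in reduced units, where the bias is well
below sampling noise.

## Gaussian accelerated dynamics

Threshold mode `E = Vmax`; `k0 = min(1, (sigma0/sigma_V)
(Vmax-Vmin)/(Vmax-Vavg))`; `k = k0/(Vmax-Vmin)`.  Staging: unbiased
statistics collection (expanding extrema, Welford mean/variance), an
equilibration stage re-deriving parameters every 1,000 steps while
statistics keep accumulating, and production with frozen parameters.
Dual boost is supported for potentials exposing named energy terms and
term gradients (the double well designates its quartic part as the
"dihedral-like" term).  Boosted force:
`grad(U + dV) = (1 - k (E - V)) grad U` below threshold.

Reweighting uses the cumulant expansion to second order per bin, with
bins under a minimum sample count reported NaN.  **The boost cap sigma0
must be scaled to the system.**  A 6 kcal/mol cap is an all-atom-scale
choice; on a toy surface whose entire potential span is ~9 kcal/mol it
saturates `k0 = 1` (full flattening), producing per-bin boost spreads of
~0.9 kcal/mol with skewness ~ -1, and the second-order cumulant then
leaves a systematic 0.25–0.4 kcal/mol distortion (exact exponential
reweighting of the same runs agrees with quadrature to ~0.1 kcal/mol,
isolating the truncation as the cause).  The quantitative reweighting
demonstrations therefore use sigma0 = 0.6 kcal/mol (k0 ~ 0.7), which
still accelerates barrier crossing ~50-fold over unbiased dynamics while
keeping the reweighted profile within ~0.2 kcal/mol of quadrature; the
cap-property and crossing-acceleration demonstrations use the full
6 kcal/mol.  This mirrors the role sigma0 plays in practice: it is the
accuracy/acceleration dial, and its value is meaningful only relative to
the system's potential-energy fluctuations.

## Problem sizes

Defaults are chosen so the full recovery study (two scenarios, 3 x
200,000 frames each) and the GaMD reweighting study (600,000 production
steps) each run in about a minute on one CPU, with unit tests using
10–100x smaller inputs.  At these sizes the recovery errors (populations
within ~0.01, MFPTs within ~5%) are dominated by finite-sampling noise,
well inside the design bands (0.03 / 15%).

## Known limitations

- PCCA+ has no membership-optimization refinement; very weakly metastable
  or strongly overlapping states may need one.
- The reversible MLE provides point estimates only; error bars come from
  whole-trajectory bootstrap, not posterior sampling.
- Second-order reweighting degrades when the boost distribution is
  strongly non-Gaussian within bins (see above); no Gaussian-mixture or
  higher-order correction is implemented.
- Trajectory I/O covers multi-model PDB and an npz container only; no
  compressed MD formats.
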