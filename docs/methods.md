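# Methods

This note records the models, numerical choices and known limitations of
cptk, in the package's own words.  Units throughout: angstrom (Å),
nanosecond (ns), kcal/mol; default temperature 310 K.

## Thermodynamic bookkeeping

β is the inverse thermal energy 1/(k_B T).  k_B T at 310 K is computed
from k_B = 1.38064852 × 10⁻²³ J/K via the Avogadro constant and
4184 J/kcal, giving kT = 0.6160 kcal/mol; every Boltzmann factor in the
package reproduces this value.

## Pore profiling

The pore radius at axial position z is the maximal inscribed-sphere
clearance r(z) = max_c min_a (|c − x_a| − vdW_a) over in-plane centers c,
clipped to [0, r_cap] with r_cap = 30 Å (beyond which a plane counts as
open to bulk and is flagged).  The search is a multi-start Nelder–Mead
ascent seeded from the previous plane's optimum, the axis point, a ring of
perturbed starts and a coarse-grid best; a seeded random-restart fallback
handles occluded planes.  The objective is a minimum of smooth functions
(piecewise smooth, concave near the optimum), for which simplex ascent
from several starts is reliable; the test suite checks it against an
exhaustive 0.05 Å in-plane grid search.  Atoms are considered within an
axial slab of r_cap + max vdW of the query plane.

The channel axis is the normal of the best-fit plane through the per-chain
centroids (for ≥ 3 chains, the least-variance direction of the centroid
cloud — exact for Cn assemblies); single-chain models fall back to the
principal axis of the coordinate covariance.  Sign is fixed
deterministically (largest-magnitude component positive).

Constrictions are local minima of r(z) with prominence ≥ 0.5 Å (default).
A channel is closed for an ion iff min r(z) is *strictly* below the ion's
hydrated radius; exact equality counts as open.  Shipped hydrated radii:
Ca²⁺ 4.12, Cl⁻ 3.32, K⁺ 3.31 Å (Cl⁻ bare Stokes radius 1.21 Å is carried
alongside).  vdW radii are a configurable Bondi table (C 1.70, N 1.55,
O 1.52, S 1.80 …) with a 1.70 Å default for unknown elements.

## Umbrella sampling and WHAM

Each window biases the reaction coordinate q (signed displacement along
the channel axis) with U_i(q) = c/2 (q − q_i)²; the standard protocol uses
c = 20 kcal/mol/Å², anchors 1 Å apart (111 anchors spanning ±55 Å in the
full protocol, inclusive of both ends; an exclusive end reproduces a count
of 110), five replicas per anchor pooled before solving, and 0.5 Å bins.

**Binned likelihood.**  Samples are histogrammed into half-open bins and
the WHAM equations are solved for bin probabilities P_k and window offsets
A_i.  The bias enters through its *exact within-bin average* Boltzmann
factor ⟨e^{−βU_i}⟩_k (Gaussian-mass/erf form), not its bin-center value:
with the standard stiff bias the window width √(kT/c) ≈ 0.18 Å is much
narrower than the bin, and a bin-center evaluation misstates the weight of
tail bins by orders of magnitude (empirically a ~1.5 kcal/mol staircase on
a flat landscape).  The bin-averaged form is the maximum-likelihood
estimator of the piecewise-constant-density model given per-sample biases.
A `bias_eval="center"` option retains the plain convention.

**Within-bin slope refinement.**  Piecewise-constant P is itself
misspecified at this bin width: a window anchored at a bin edge splits its
samples between the two adjacent bins according to the local PMF slope,
and ignoring that slope attenuates every recovered free-energy gradient
(the shipped 5 kcal/mol double-well barrier comes out near 3.6).  The
solver therefore runs a small number (default 4) of outer passes that
estimate each bin's local slope from the quadratic-smoothed current
profile (damped, clipped at ±6 kcal/mol/Å) and fold it into the weight as
an analytically integrable tilted Gaussian.  With the refinement the
double-well barrier is recovered at 5.06 ± 0.10 (mean ± sd over 10 seeds)
and the two channel-like peaks at 5.1 ± 0.24 and 4.1 ± 0.28.

**Solver.**  The self-consistent iteration defines the fixed point and the
convergence flag (max |ΔA_i| < tol, default 10⁻⁷ kcal/mol), but under the
protocol's weak window overlap direct iteration needs ~10⁵ sweeps, so each
pass is warm-started by an L-BFGS minimization of the equivalent convex
log-likelihood F(g) = Σ_k N_k ln Σ_i n_i e^{g_i} W_ik − Σ_i n_i g_i in
g = βA.  All algebra is in log space (log-sum-exp; stable Gaussian-mass
differences via log_ndtr) so arbitrarily stiff biases cannot overflow.
The tests pin the solver to an independent scalar brute-force fixed-point
oracle to 10⁻⁶ kcal/mol on small problems.

Windows whose sampled bins form disconnected groups raise an error naming
the gap (free energies of disconnected groups have no common scale).  The
PMF is anchored min A = 0; P integrates to 1 over the bins.

**Smoothing and barriers.**  The discrete PMF is smoothed by moving-window
quadratic least squares (odd window, default 5 bins; exact on globally
quadratic input; windows wider than the profile degenerate to one global
fit).  Barriers are local maxima of the smoothed profile with prominence
≥ 0.5 kcal/mol, measured relative to the smoothed minimum, each mapped to
residues whose side-chain centroid lies within a ±2 Å axial slab.
Convergence is monitored by re-solving on cumulative time blocks and
reporting max_k |A_block − A_full|.

## Synthetic data

The generators emulate the study conditions, not real experiments:

- **Analytic profiles.**  `double_well_pmf`: A*(q) = h((q/w)² − 1)² with
  h = 5 kcal/mol, w = 10 Å (barrier 5 at q = 0, minima ±10, windows span
  ±11 Å → 23 anchors).  `channel_like_pmf`: Gaussian barriers of 5 and
  4 kcal/mol at z = −12/+12 Å (width 3 Å) on a ±20 Å domain — the scale of
  the reported divalent/monovalent cation peaks at the two major
  constrictions of a closed heptameric channel.
- **Sampler.**  Overdamped Langevin (Euler–Maruyama),
  q ← q − (dt/γ)∇U + √(2kT dt/γ)ξ, with γ = 1 kcal·mol⁻¹·ns·Å⁻² and
  dt = 0.002 ns so that c·dt/γ = 0.04 for the stiffest shipped case; all
  windows are propagated as one vectorized batch; trajectories start at the
  relaxed biased minimum, discard a 10% burn-in, and may be thinned
  (default budgets: 10⁵ steps thinned by 10 → 10⁴ recorded samples per
  window).  Escaping far beyond the profile domain raises a step-size
  error naming dt.  An `method="exact"` path draws i.i.d. samples from the
  stationary law by inverse-CDF on a fine grid (for the flat profile this
  is exactly the N(q_i, kT/c) law) — used for null tests where sampling
  noise, not dynamics, is the point.  Steered seeding moves the anchor at
  constant velocity and snapshots the coordinate at each window anchor.
- **Toy channels.**  Ring stacks of pseudo-atoms (default vdW 1.5 Å,
  C7 symmetry by angular sector, residue index increasing along z) with
  prescribed radius-vs-z: constant (cylinder), linear (cone), and a
  two-waist profile whose accessible radii at z = ∓12 Å are 2.0 and 2.6 Å
  — both narrower than every hydrated ion in the default table, so the
  construction is closed by design.
- **Maps.**  Sum of unit-mass isotropic atom Gaussians (truncated at 4σ)
  plus optional i.i.d. voxel noise; `halves=True` reuses one signal with
  two independent noise draws, the synthetic analogue of half maps from
  split particle stacks.  What this does *not* emulate: CTF envelopes,
  B-factor falloff, solvent background correlations, per-particle
  alignment error.  Passing tests on these fixtures validates the
  estimators' correctness, not their behavior on real reconstructions.

## Map/model validation

- **Model-to-map blur**: "blur width" is the Gaussian σ (3.15 Å default,
  configurable).  For the *map-resolution* emulation in fixtures the FWHM
  convention applies instead (σ = resolution/2.355) — a σ = 3.15 Å blur
  corresponds to a ~7.4 Å map, far coarser than a 3.15 Å-resolution one.
- **FSC**: shells one reciprocal voxel wide; per-shell normalized
  conjugate cross-power; optional real-space mask clamped to [0, 1];
  zero-power shells recorded as 0 and flagged.  Resolution-at-threshold
  interpolates linearly between the bracketing shells; a curve that never
  crosses returns an explicit better-than-Nyquist sentinel, and a curve
  that starts below threshold returns the coarsest shell.
- **Cross-validation**: the test model displaces every atom by a uniform
  random vector of norm ≤ 0.5 Å (uniform in the ball, seeded); the
  overfitting indicator is the maximum per-shell gap between the
  FSC(test, half1) and FSC(test, half2) curves.
- **Per-residue Z-scores**: raw score = Manders-style overlap
  Σ m·e / √(Σm² Σe²) between the full model-derived density and the
  experimental map over the residue's footprint (voxels within 2σ of any
  residue atom), optionally averaged over a sliding residue window
  (default 1); Z-scored against the pooled mean/sd.  A pooled sd of ~0
  (e.g. a map synthesized from the model itself) is flagged and yields
  Z = 0.  Empty footprints are excluded and returned as NaN.
- **Local amplitude scaling**: cubes of 30 Å (default) with stride
  window/2; per-cube radial Fourier amplitudes of the experimental
  subvolume are matched to the reference's; cubes are blended with
  triangular weights.  This is a deliberate single-pass simplification —
  no per-voxel sliding window and no reference B-factor handling.
- **Mean-shift LDPs**: Gaussian kernel of σ = bandwidth (default 2 voxels)
  truncated at 3σ, density-weighted over voxel centers, negative density
  clamped to zero; convergence at step < 10⁻³ Å or 200 iterations;
  converged points merged within 1 voxel by density-weighted centroids.
  Thresholds accept absolute units or "kσ" above the map mean.  For
  backbone tracing of ~3 Å-resolution fixtures a bandwidth of 1 voxel
  follows the density spiral more tightly than the default.

## Dual residue numbering

The tagged construct inserts WSHPQFEK (8 residues) after native residue
172: native i maps to model i for i ≤ 172 and i + 8 above; model indices
173–180 are tag residues with no native equivalent and are rejected by the
inverse mapping.  Reports print dual labels like `E414(422)`.

## Numerical conventions and degenerate inputs

Histogram bins are half-open [lo, hi) with an edge sample counted in the
right-hand bin; the top of the range opens one extra bin so conservation
Σ N_k = Σ n_i holds exactly.  Ties in pore lining atoms break toward the
smallest atom index (stable argsort).  Maps are stored float32 on disk
(MRC/CCP4 2014, orthogonal P1 cells only); grids are normalized to
x-fastest `[ix, iy, iz]` indexing with absolute Å origins.  Empty windows
warn and carry n_i = 0; blocks with empty windows in the convergence scan
are solved on the remaining windows with a warning.

## Problem sizes

The shipped experiments use 23–41 anchors × 5 replicas × 10⁴ recorded
samples per window for PMF recovery (10 seeds), a 574-atom toy channel
profiled at 0.5 Å steps, a 30-residue helix on ~50³ voxel maps, and 8³
grids for the brute-force Fourier oracle — sizes chosen so the whole
validation battery, including the 10-seed recovery studies, completes in
minutes on one CPU while keeping Monte-Carlo error well inside the stated
tolerances.

## Known limitations

- The 1-D Langevin surrogate has no solvent, membrane, ion–protein
  interactions or orthogonal slow degrees of freedom; it validates the
  estimator, not the physics of any specific channel.
- The within-bin slope refinement assumes the PMF is smooth on the bin
  scale; profiles with sub-bin structure would need narrower bins instead.
- No autocorrelation/statistical-inefficiency weighting of window samples
  (thinned Langevin samples are treated as the data they are); error bars
  on A(q) are not reported.
- Pore tracing assumes a straight axis; curved permeation pathways are out
  of scope.
- local_scale does not reproduce reference-model B-factor handling or
  voxel-granular sliding of the full algorithm.
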