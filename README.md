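# cptk — channel-profiling toolkit

Desk-scale computational pipeline for heptameric ion-channel structures of
the pannexin type: given a coordinate model, a cryo-EM density map, and
umbrella-sampling trajectories along the pore axis, it answers three
questions a channel structural biologist asks —

1. **Is the pore open?**  HOLE-style profiling of the maximal
   inscribed-sphere radius r(z) along the symmetry axis, detection of
   constrictions (local minima of r), and a closed/open verdict per ion by
   comparing min r against hydrated ion radii (Ca²⁺ 4.12 Å, Cl⁻ 3.32 Å,
   K⁺ 3.31 Å).
2. **What does an ion feel on the way through?**  WHAM estimation of the
   potential of mean force A(q) from harmonically biased umbrella windows
   U_i(q) = c/2 (q − q_i)², with the standard protocol (c = 20 kcal/mol/Å²,
   0.5 Å bins, 310 K where kT = 0.616 kcal/mol), quadratic smoothing,
   block-convergence analysis, and mapping of PMF peaks onto pore-lining
   residues.
3. **Does the model fit the map?**  Model-to-map Gaussian blurring, masked
   and unmasked Fourier shell correlation with resolution-at-threshold
   (0.143 / 0.5), perturbed-model half-map cross-validation against
   overfitting, per-residue Z-scored local fit (SMOC-style), simplified
   windowed local amplitude scaling (LocScale-style), and mean-shift
   extraction of local dense points (MAINMAST-style) for main-chain
   tracing.

A seeded synthetic-data layer replaces the cluster-scale inputs: analytic
free-energy profiles with a 1-D overdamped Langevin sampler stand in for
biased all-atom MD, ring-stack pseudo-atom channels with known radius
profiles stand in for deposited coordinates, and Gaussian-blurred
(optionally noisy, optionally split into half-map pairs) grids stand in for
experimental reconstructions.  Residue bookkeeping between a native
sequence and a tagged construct (an 8-residue tag after residue 172, the
`E414(422)` dual-numbering convention) is built in.

## The estimator at the core

Pooled window samples are histogrammed into bins of width Δq and the
unbiased bin probabilities P(q_k) and window offsets A_i solve the WHAM
equations

    P(q_k) = N_k / Σ_i n_i exp(β A_i) ⟨exp(−β U_i)⟩_k
    exp(−β A_i) = Σ_k P(q_k) ⟨exp(−β U_i)⟩_k ,     A(q) = −kT ln P(q)

where ⟨·⟩_k is the exact within-bin average of the harmonic bias Boltzmann
factor.  Because the stiff standard bias makes each window (σ = √(kT/c) ≈
0.18 Å) narrower than the bin, the solver additionally re-estimates each
bin's local PMF slope and folds it into the within-bin density model (an
analytic tilted-Gaussian form); without this the recovered free-energy
gradients are systematically attenuated.  See `docs/methods.md`.

The estimator follows the statsmodels convention: `UmbrellaSampling` is
the model object, `fit()` returns a `PMFResult` with `summary()`,
`smoothed()`, `plot()` and the convergence history.

## Worked example

```python
import numpy as np
from cptk.synth import double_well_pmf, sample_windows
from cptk.wham import make_windows, UmbrellaSampling, barrier_report

pmf = double_well_pmf()                    # 5 kcal/mol barrier at q = 0
wins = make_windows(11.0, -11.0, 1.0, replicas=5, force_const=20.0)
sampled = sample_windows(pmf, wins, n_steps=100_000, thin=10, seed=0)
result = UmbrellaSampling(sampled, bin_width=0.5).fit()
print(result.summary())
for peak in barrier_report(result):
    print(f"barrier {peak.height:.2f} kcal/mol at q = {peak.z:+.1f} A")
```

prints

```
WHAM potential of mean force
==================================
bins             : 48 (0.5 A wide)
populated bins   : 48
windows          : 115
temperature      : 310 K (kT = 0.616 kcal/mol)
iterations       : 8 (converged)
barrier height   : 4.971 kcal/mol
q range sampled  : [-11.8, +11.8] A
barrier 4.98 kcal/mol at q = -0.2 A
```

i.e. the 5 kcal/mol barrier built into the synthetic landscape is recovered
from the biased trajectories alone.  The pore side works the same way:

```python
from cptk.synth import two_waist_channel
from cptk.pore import channel_axis, pore_profile, find_constrictions, classify_state

model = two_waist_channel()            # waists of pore radius 2.0 / 2.6 A
profile = pore_profile(model, channel_axis(model), -18, 18, 0.5)
print([(c.z, round(c.radius, 2)) for c in find_constrictions(profile, model)])
v = classify_state(profile)["K+"]
print(f"closed={v['closed']}, min_radius={v['min_radius']:.2f} A, "
      f"margin={v['margin']:.2f} A")
```

```
[(-12.0, 2.0), (12.0, 2.6)]
closed=True, min_radius=2.00 A, margin=1.31 A
```

— a 2 Å constriction excludes every hydrated ion in the default table, so
the toy channel is classified closed, with the margin to hydrated K⁺
reported.

There is also a CLI (`cptk pore …`, `cptk wham …`, `cptk ldp …`,
`cptk mapval …`, `cptk synth …`, `cptk pmf-pipeline`); every random stage
takes `--seed` and identical invocations produce byte-identical outputs.

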