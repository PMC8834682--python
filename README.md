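# flimfret

Quantifying protein–protein interaction in living cells from fluorescence
lifetimes: a simulation, fitting and statistics toolkit for FLIM–FRET with
time-correlated single-photon counting (TCSPC).

## The problem

When a donor fluorophore (e.g. mNeonGreen fused to a transcription factor)
sits within a few nanometers of an acceptor (e.g. mRuby3 fused to its
dimerization partner), Förster resonance energy transfer (FRET) quenches the
donor and shortens its fluorescence lifetime. Intensity-based FRET readouts
conflate two things: how *close* the interacting pair is, and how *much* of
the donor is bound. Lifetime imaging (FLIM) disentangles them. The donor
decay measured by TCSPC is a mixture of an unquenched-donor species (UD,
lifetime τ_UD) and a quenched, acceptor-bound species (QD, lifetime τ_QD),
and bi-exponential reconvolution fitting recovers both lifetimes and the
species amplitudes A_UQ, A_QD. From these:

- FLIM–FRET efficiency (distance readout):
  **E = (τ_UD − τ_QD) / τ_UD**
- donor–acceptor binding ratio (abundance readout):
  **B% = A_QD / (A_UQ + A_QD) · 100**
- apparent FRET efficiency (what intensity methods see), with species
  intensities I_i = A_i·τ_i:
  **E_app = (I_QD / ΣI) · E**
- donor–acceptor distance from the sixth-power transfer law with Förster
  radius R₀ (6.417 nm for mNeonGreen/mRuby3):
  **E = R₀⁶ / (R₀⁶ + r⁶)  ⇔  r = R₀ · ((1−E)/E)^{1/6}**

The package provides every stage of that analysis, plus a synthetic-data
generator that emulates the full live-cell study design (donor-only control,
wild-type and mutant donor+acceptor conditions, nuclear/extranuclear
compartments, a free-acceptor negative control; three independent
experiments, ≥38 cells per condition), so the whole chain is testable
without microscope data:

| module | what it does |
| --- | --- |
| `flimfret.tcspc` | forward model: multi-exponential decay × Gaussian IRF under periodic 40 MHz excitation, uniform background |
| `flimfret.simulate` | per-cell ground truth (lifetimes, binding, intensities) and multinomial photon sampling |
| `flimfret.fitting` | mono/bi-exponential reconvolution by maximum Poisson likelihood, residual diagnostics, AIC + runs-test model selection |
| `flimfret.metrics` | E, E_app, B%, r, A:D ratio per ROI, qc flags, ROI averaging |
| `flimfret.stats` | boxplot summaries, Kruskal–Wallis, Dunn's post hoc (Holm/Bonferroni/Šidák), negative-control background gate |
| `flimfret.io` / `flimfret.pipeline` / `flimfret.cli` | plain-text formats, run configs, manifests, and the `flimfret` CLI |

## Worked example

Simulate a wild-type donor+acceptor condition (39 cells, binding fraction
0.5, UD 2.75 ± 0.14 ns, QD 1.10 ± 0.20 ns, 10⁵ photons/cell), fit each cell
bi-exponentially, and summarize:

```python
import numpy as np
from flimfret import (
    AcquisitionConfig, ConditionDesign, simulate_experiment,
    fit_biexp, flim_fret_efficiency, binding_ratio, donor_acceptor_distance,
)

config = AcquisitionConfig()          # 40 MHz, 256 channels, 25 ns window
wt = ConditionDesign(name="WT+E47", binding_mean=0.5,
                     n_cells=13, n_experiments=3)
truths, hists = simulate_experiment([wt], master_seed=1, config=config)

eff, bind = [], []
for h in hists:
    fit = fit_biexp(h)
    eff.append(100 * flim_fret_efficiency(fit.tau_ud, fit.tau_qd))
    bind.append(binding_ratio(fit.a_qd, fit.a_uq))

e_mean = np.mean(eff)
print(f"n cells                 : {len(hists)}")
print(f"FLIM-FRET efficiency E  : {e_mean:.1f} +/- {np.std(eff, ddof=1):.1f} %")
print(f"binding ratio B%        : {np.mean(bind):.1f} +/- {np.std(bind, ddof=1):.1f} %")
print(f"donor-acceptor distance : {donor_acceptor_distance(e_mean / 100):.3f} nm")
```

```
n cells                 : 39
FLIM-FRET efficiency E  : 59.7 +/- 7.7 %
binding ratio B%        : 55.0 +/- 12.7 %
donor-acceptor distance : 6.009 nm
```

The mean efficiency sits where the generating lifetimes put it
(1 − 1.10/2.75 ≈ 60%), the recovered binding ratio brackets the simulated
50% bound fraction, and a ~60% transfer efficiency corresponds to a
donor–acceptor separation just under the 6.417 nm Förster radius —
nanometer-scale proximity, i.e. direct dimerization.

The same analysis runs end to end from a shell, writing histograms, a fit
log, per-ROI metrics, group comparisons and a reproducibility manifest:

```sh
flimfret run-all --seed 1 --out-dir out/       # built-in 7-condition design
flimfret run-all --config my_run.yaml          # or a custom YAML design
```

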