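# Methods

## Forward model of a TCSPC measurement

A pulsed laser (repetition rate f, default 40 MHz) excites the sample every
T = 1000/f ns (25 ns). Photon arrival times are histogrammed into
`n_channels` equal bins over one period (default 256 bins of 0.0977 ns).
The expected histogram is

    y(t) ∝ (1 − b) · [ IRF ⊛ Σ_i A_i w_i e^(−t/τ_i) ] + b / T

with components i ∈ {UD, QD}, uniform background fraction b, and per-
component periodic wrap factors w_i = Σ_m e^(−mT/τ_i) accounting for
fluorescence excited by preceding pulses (the geometric sum is truncated
once a term falls below 1e-12; for τ = 2.75 ns in a 25 ns window the wrap
adds ≈ 1.1e-4 of the peak). The vector is rescaled to the total photon
count, so photon conservation is exact by construction.

**IRF.** The instrument response is modeled as a Gaussian with FWHM
0.15 ns centered at 2.0 ns — the temporal scale of hybrid photodetectors,
with the peak kept away from the window edge. σ = FWHM/(2√(2 ln 2)). Both
the shape and the defaults are this package's choice; vendor "simulated
IRF" parameterizations are not public, so the Gaussian is a stand-in, not a
claim about any instrument. An IRF-vs-data shift parameter is not fitted
(default 0): the simulator and fitter share the same time origin.

**Grid convention.** The decay is sampled at channel centers; the IRF
kernel is sampled at whole-channel delays (circular, mod-window). With this
pairing the discrete circular convolution keeps the time axis aligned — the
convolved peak sits at `irf_center_ns` exactly, with no half-channel bias —
and moving the IRF center by k whole channels circularly shifts the
expected counts by exactly k channels.

## Synthetic cell populations

The generator emulates the study layout the statistics expect: seven
conditions (donor-only; wild-type and two mutant donors + wild-type
acceptor; an NLS-deficient acceptor split into nuclear and extranuclear
compartments; a free-acceptor negative control), three independent
experiments × 14 cells = 42 cells per condition (study-scale minimum 38;
smaller designs warn).

Per-cell parameters, all drawn from streams keyed by
(master seed, condition, experiment index, cell index) so datasets are
byte-reproducible and enumeration-order independent:

| parameter | family | default (wild-type) |
| --- | --- | --- |
| τ_UD | Normal truncated at 0.5 ns | 2.75 ± 0.14 ns |
| τ_QD | Normal truncated to (0.1 ns, τ_UD) | 1.10 ± 0.20 ns |
| binding fraction B | logit-Normal | mean 0.5, logit-SD 0.5 |
| donor / acceptor intensity | lognormal | log-mean 0, log-SD 0.4 |
| photons per cell | fixed | 10⁵ |

Only the wild-type lifetime summaries are anchored to reported
measurements; mutant binding levels (0.35 / 0.25 / 0.20–0.35) are
illustrative, and the negative control is a low-binding (mean 0.05),
wide-spread population. The distribution families are a modeling choice —
only means and SDs are reported for the real populations. An optional
logistic link (`ad_coupling`, off by default) makes per-cell binding
increase with the cell's log acceptor:donor ratio, reproducing the
expression-stoichiometry confound.

Counts are drawn multinomially from the normalized forward model, so each
histogram sums exactly to the cell's photon budget. The default budget of
10⁵ photons/ROI keeps bi-exponential fits stable while a full 7-condition
run stays at desk scale (~300 fits, well under a minute).

**What the generator does not emulate:** pixel-level images and ROI
segmentation, detector afterpulsing/pile-up/dead time, spectral
bleed-through, photobleaching, and any cell-to-cell correlation within an
experiment. Passing tests therefore demonstrate correctness of the
analysis chain under the stated noise model, not robustness to every
instrumental artifact of real FLIM data.

## Reconvolution fitting

Parameters are estimated by maximum Poisson likelihood: the fit minimizes
the deviance (C-statistic)

    D = 2 Σ_i [ e_i − o_i + o_i ln(o_i/e_i) ]

which handles low-count tail channels correctly where Gaussian weighting
fails; a Neyman weighted least-squares objective (`objective="leastsq"`)
is available for cross-checks. Free parameters: lifetime(s) bounded to
[0.1, 10] ns, QD amplitude fraction in [0, 1], background fraction in
[0, 0.2]; the overall scale is fixed by photon conservation. Optimization
uses bounded L-BFGS-B; an exhaustive grid search backs the optimizer in
the test suite. Standard errors come from the curvature of the deviance at
the optimum (cov = 2 H⁻¹).

**Initialization.** τ from the histogram's background-corrected first
moment past the IRF center; bi-exponential fits start at (1.4 m, 0.6 m)
around that moment m with a 0.5 QD fraction. Overridable via `init`.

**τ_UD free by default.** Measured UD lifetimes shift slightly in
high-binding samples, so the unquenched lifetime is fitted per ROI;
`fix_tau_ud` clamps it (e.g. to the donor-only value) for the alternative
analysis. Note the clamp is misspecified per cell whenever real
between-cell UD variability (SD 0.14 ns) exceeds the fit noise.

**Diagnostics and model selection.** Pearson residuals
(o−e)/√max(e, 1), reduced χ² over (channels − parameters), and a
Wald–Wolfowitz runs test on residual signs. "Evenly distributed residuals"
is operationalized as: accept the bi-exponential model only if it improves
AIC by more than 10 AND the mono fit's runs-test p < 0.05. Histograms
under 1000 photons default to mono with a warning. Bi-exponential fits
whose lifetimes collapse within 0.05 ns are flagged degenerate; callers
fall back to the mono model.

**Identifiability at low binding.** With a true bound fraction near zero
the two-component split is unidentifiable and the free fit can return a
spurious decomposition with substantial amplitudes at nearby lifetimes
(its amplitude-weighted lifetime still equals the true mono lifetime).
Per-ROI model selection is the default guard: when it selects the mono
model for a FRET sample, the ROI is recorded with B% = 0 and E_app = 0
(A_QD = 0 in the defining equations) while E and r — properties of a bound
population that was not detected — stay absent. This keeps
low/undetectable-binding cells in the binding-ratio statistics instead of
silently emptying the negative-control group.

## FRET metrics

E = 1 − τ_QD/τ_UD, B% = 100·A_QD/(A_UQ+A_QD),
E_app = I_QD/(I_UD+I_QD) · E, r = R₀((1−E)/E)^{1/6} with
R₀ = 6.417 nm (mNeonGreen/mRuby3). The species intensity in E_app is taken
as I_i = A_i τ_i — the steady-state intensity of an exponential species;
the raw-amplitude variant is available via `intensity_mode="amplitude"`
for sensitivity checks. E_app ≤ E always, with equality only at full
binding.

Fitted values outside their domain (τ_QD > τ_UD from noise, E at 0 or 1)
are clamped or given inf/0 distance sentinels and qc-flagged rather than
dropped; flagged rows are excluded from group statistics by default, with
exclusion counts carried in the comparisons table. Repeated acquisitions
of one ROI are averaged arithmetically per metric (acquisition → ROI →
condition ordering) before any statistics.

## Group statistics

Per metric and condition: boxplot summaries (median, quartiles, 10th/90th
percentiles; linear-interpolation quantiles), Kruskal–Wallis omnibus with
tie correction, and Dunn's post hoc z-tests on the pooled ranks with tie
correction. Multiplicity adjustment defaults to Holm (uniformly more
powerful than Bonferroni at the same FWER); Bonferroni and Šidák are
selectable and the method is recorded in the output. Cells from the three
experiments are pooled within a condition (no hierarchical model), matching
the boxplot-style reporting the design emulates.

The free-acceptor negative control defines a background gate: a condition
counts as a genuine interaction only if its median exceeds the control
median AND its Dunn-adjusted p against the control is below α = 0.05.
Under a null simulation the full omnibus → Dunn → gate chain keeps the
false-flag rate at or below 0.07 at nominal 0.05.

## Numerical and design notes

- Wrap summation truncated at per-period factor 1e-12; lifetimes with
  e^(−T/τ) > 1e-6 are flagged wrap-sensitive (metadata, not an error).
- Runs test: conditional normal approximation; the all-one-sign case uses
  the unconditional single-run probability 2^(1−n) so pathological
  residual patterns still yield small p.
- Kruskal–Wallis with every value identical returns H = 0, p = 1 instead
  of erroring.
- Degenerate-fit lifetime gap: 0.05 ns; at-bound detection at 1e-4 of the
  parameter range.
- File formats are plain text (tab-separated tables + YAML sidecars);
  vendor TCSPC binaries are out of scope, with `read_histograms` as the
  import hook point.
- Known limitations: at most two decay components; no global multi-ROI
  linked fitting, phasor analysis or anisotropy; no spectral-overlap
  computation of R₀ (taken as an input constant); statistics assume
  independent cells.
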