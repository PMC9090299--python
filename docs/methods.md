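# Methods

## The kinetic model

The early steps of Arabidopsis pre-rRNA maturation are represented as a
linear compartmental cascade over the three species a Northern blot resolves
well: the primary 45S transcript, the 35S produced by endonucleolytic
cleavage at the P site in the 5'ETS, and the P-A3 intermediate of the
ITS1-first pathway.  Synthesis enters the 45S pool at a constant flux σ;
each downstream step is first order.  The branching fraction α splits total
35S removal (rate k35) into productive conversion to P-A3 (α·k35) and
direct degradation ((1−α)·k35) — the model does not distinguish exosome
decay from alternative cleavages, both are "removal without appearing as
P-A3".  The cascade deliberately stops at P-A3: later intermediates
(18S-A3, 27SB, 7S/6S) turn over faster, are fainter on blots, and would add
parameters without adding identifiable structure.  Co-transcriptional
processing and stochastic effects are out of scope; abundances are relative
signal units, not molecule counts.

Temperature treatment is modelled as piecewise-constant parameters over a
schedule of contiguous regimes (heat 0–24 h at 37°C, recovery 24–48 h at
22°C by default), with state continuity at the switches.  The pre-stress
22°C condition enters only through the initial state, which is the baseline
steady state (σ/k45, σ/k35, α·σ/kpa3) — the culture is assumed equilibrated
before the shift.

### Solution

For positive, pairwise-distinct rates the trajectory is the explicit
Bateman-type sum of three exponentials, vectorized over time.  When any two
rates are closer than 1e-6 relative, or any rate is zero, the explicit
formula loses digits to cancellation; those cases are routed to an exact
evaluation via the matrix exponential of the augmented affine system (a
4×4 `expm` per time point).  This replaces hand-written repeated-eigenvalue
limits (t·e^{−kt} branches): one uniform fallback covers every degeneracy,
including triple-equal rates and kpa3 = 0 (allowed in simulation; rejected
by the steady state, which then does not exist).  Agreement with a
fixed-step RK4 integrator is tested to 1e-6 relative over random
log-uniform parameter draws.

## Fitting

Observations are tidy rows (time, species, probe, replicate, value) of
loading-control-normalized intensities.  The model prediction for a row is
`scale[probe] × trajectory(t)[species]`: the per-probe scale absorbs
probe-specific detection efficiency, and all species measured by one probe
share it (they sit on one membrane).

Identifiability fixes two conventions:

* σ(baseline) ≡ 1 signal-unit·h⁻¹.  Model output is linear in the flux
  scale, so one overall scale must be pinned; pinning σ rather than one
  probe's factor makes every probe's scale free, and multiplying one
  probe's observations by c > 0 moves only that probe's scale factor.
* Recovery shares the baseline (22°C) parameters by default
  (`recovery_ties_baseline`).  The t = 0 steady state alone determines only
  α·σ/kpa3, not α and kpa3 separately; the recovery dynamics are what
  identify the baseline branching fraction and P-A3 removal rate.  A
  staged or fully separate recovery parameter set remains available
  (`recovery_ties_baseline=False`), at the cost of that identifiability.

The objective is weighted least squares on the linear signal scale
(weights 1 by default; 1/signal optional for relative error).  Rates are
optimized as logarithms within [1e-6, 100] h⁻¹, α within [1e-6, 1] (the
tiny lower bound keeps the derived ratios defined), scales within
[1e-6, 1e6].  A deterministic multi-start grid (default 8 starts, all rates
at a common value log-spaced over [1e-2, 10^0.5] h⁻¹, α = 0.5, scales
initialized from the t = 0 observations) feeds scipy's trust-region
reflective `least_squares` (tolerances 1e-12); the best start by SSE wins,
ties broken lexicographically on the parameter vector; the scan stops early
once the relative SSE falls below 1e-16 (noiseless data).  The reported SSE
never exceeds the value at the chosen start.  `converged=False` flags an
optimizer that ended without satisfying its tolerances — parameters are
still reported, never silently replaced.

Per-probe fitting (`fit_per_probe`) runs the same machinery on each probe's
rows alone; the spread of the per-probe derived statistics is how
range-style results ("30–90% reduction") are reported.  Whether pooling or
per-probe fitting better matches practice is genuinely open; per-probe is
the default because it is what produces ranges at all.

### Derived statistics

From a baseline and a heat parameter set: the percent reduction of k45,
the percent reduction of the 35S→P-A3 transformation rate α·k35, the fold
change of kpa3, and α·k35 at 37°C converted to s⁻¹ (divide by 3600).  A
fixed literature pulse-labelling constant (2.4×10⁻⁵ s⁻¹) is carried in the
result purely as a reporting comparator, never fitted.

### Recovery study

`run_recovery_study` is the fit's acceptance surface: simulate noisy time
courses from known parameters, refit, and report per-parameter bias, RMSE
and median relative error across replicates, all deterministic given the
seed.  The study default uses 4 optimizer starts (the full 8 change no
conclusion and double the cost).  At the study conditions used in the tests
(lognormal CV 0.10, 12 time points × 3 probes, 100 replicates) the pooled
median relative error is ≈ 19–21%; individual parameters differ widely —
k45 and k35 at baseline are well determined (~9%), while σ and α at 37°C
are the softest (~25–29%).

## Quantification

* Loading-control normalization divides each band by the 5S signal of its
  lane; an optional second step rescales each (probe, species) series to
  its t = 0 value (off by default, since the exact published normalization
  beyond the loading control is not specified).
* The TIS/P fold change is the ratio of primer-extension TIS/P ratios,
  37°C over 22°C, reported exactly and rounded to the nearest integer.
* Transcript end coordinates are classified against a shipped map of the
  45S unit (1-based, TIS = +1): TIS 1; P 1274/1275; P' 1755; 18S
  1836–3639; A2 3661; A3 3830; 5.8S 5' end 3911; 25S 4259–7633.  Intervals
  are represented by their boundary coordinates; the classifier assigns the
  site within tolerance (default 2 nt — the P site itself is a doublet),
  breaking ties by absolute offset then map order, and otherwise returns
  "unassigned" with the nearest site and signed offset.

## Gradient profiles

Baseline correction cuts the trace into consecutive windows (default 30% of
the trace length in samples — wider than any subunit peak), anchors a
piecewise-linear baseline at each window's minimum (linearly extrapolated
at the ends, so a linear drift is removed exactly), optionally pre-smooths
with a boxcar (area-preserving; recommended near the narrowest peak's sigma
for noisy detector traces), re-centres the background at zero via the
median of below-10%-of-maximum samples (window minima are biased low under
noise, which would otherwise leave a pedestal that inflates areas), and
clips at zero.

Peak detection keeps local maxima with prominence above 5% of the trace
maximum; adjacent maxima whose connecting valley stays above 50% of the
lower apex are merged into one region — this is what turns an
under-resolved 60S shoulder and the 80S monosome into the single 60S-80S
region.  Boundaries are the flanking minima; the area is the trapezoidal
integral above the chord joining the boundary points (the valley-to-valley
baseline of chromatographic practice: zero on a clean corrected trace, and
it cancels residual local background under noise).  The two leading regions
in sedimentation order are labelled 40S and 60S-80S.  The subunit ratio is
area(60S-80S)/area(40S); replicate ratios are averaged arithmetically and
reported to two decimals.  Heights are not used; whether published summary
values are heights or areas is unknowable from a figure, and areas are the
parameter-free choice.

Known limitation: with two peaks riding a steep drift, window-minimum
anchors near the inter-peak valley can sit slightly above the true drift
line, biasing the ratio by up to ~1.5%; and at signal-to-noise ≈ 20 a
boundary occasionally lands in a noise dip, so the round-trip invariant is
asserted on the median over seeded replicates, not per trace.

## Composition

Category percentages are 100·count/total rounded to one decimal, with the
rounded set re-checked to sum to 100 ± 0.2.  Weighted spectral counts
(shared-peptide apportioning happens upstream, in the search software) are
summed per RPS/RPL/RPP class within fraction pools; ids missing from the
annotation map are counted under "other", warned about, and excluded from
ribosomal percentages.  A Pearson chi-square (uncorrected) on the 2×k table
is provided for comparing two distributions; it demands matching category
sets and positive expected counts.

## Synthetic data

The generators exist so every stage has an input with the right statistical
structure and no download:

* Time courses follow the study sampling design (heat 0/2/3/4/5/6/8/24 h,
  recovery +2/3/6/8/24 h; probes p23/p43/p6 with detection efficiencies
  1.0/1.4/0.7) with lognormal multiplicative noise (unit-mean factors,
  default CV 0.10 — densitometry noise is multiplicative).  Default true
  parameters: baseline σ=1, k45=0.2, k35=0.28, α=0.8, kpa3=0.3 h⁻¹; heat
  σ=0.6, k45=0.06, k35=0.18, α=0.8, kpa3=0.75 h⁻¹; recovery = baseline.
  These are a fixture choice placing the derived statistics inside the
  ranges the analysis should resolve (70% k45 reduction, 35.7% α·k35
  reduction = 4.0×10⁻⁵ s⁻¹ at 37°C, 2.5-fold kpa3), with the heat flux
  lowered so the 45S pool rises while 35S falls, mirroring blot behaviour.
* Traces are Gaussian mixtures (center, width, area) on a linear drift with
  additive or multiplicative noise.
* Counts are multinomial draws; spectral-count tables split known class
  totals across synthetic protein ids and fractions with Dirichlet weights
  (pooling recovers the totals exactly).  These synthetic spectra stand in
  for search-engine exports and say nothing about real protein inference.

What passing the recovery loop shows — and what it does not: the fit is
consistent and well-conditioned under multiplicative noise on data generated
by its own model family.  Real blots add membrane-position effects, probe
cross-hybridization, saturation, and model misspecification (e.g. time-
varying σ), none of which the generator emulates; recovery error on real
data is therefore a lower bound, not an estimate.

## Problem sizes

Defaults keep everything interactive on one core: 13 time points × 3
species × 3 probes per fit (~0.5 s noiseless, ~0.3 s per replicate in the
recovery study), 100-replicate recovery studies in ~half a minute, traces
of 1001–2001 samples, count tables of ~10² categories.
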