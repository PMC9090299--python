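# rrnapipe

Quantitative analysis of pre-rRNA processing in *Arabidopsis thaliana* under
heat stress: a regime-switching kinetic model of the early processing
intermediates, plus the supporting quantifications around it (densitometry
normalization, primer-extension ratios, sucrose-gradient subunit profiles,
ribosomal-protein composition, nucleolus-morphology distributions, and
processing-site coordinate classification).

## Who this is for

Plant molecular biologists and modellers who quantify ribosome biogenesis:
the package turns band-intensity tables from Northern blots, A254 gradient
traces and weighted spectral counts into normalized observables, and fits a
small mechanistic model that asks *which processing steps slow down or speed
up when seedlings are shifted from 22°C to 37°C, and how they recover*.

## The model

The three abundant precursors of the major (ITS1-first) maturation pathway
are tracked as a linear first-order cascade:

```
d[45S]/dt  = σ        − k45·[45S]
d[35S]/dt  = k45·[45S] − k35·[35S]
d[P-A3]/dt = α·k35·[35S] − kpa3·[P-A3]
```

σ is the Pol I synthesis flux (signal units·h⁻¹); k45 is the rate of the
primary cleavage at the P site in the 5'ETS (45S → 35S); k35 is total 35S
removal, of which a fraction α is converted to the P-A3 intermediate (the
rest is degraded, e.g. by 3'-5' exonucleolytic decay); kpa3 removes P-A3.
Temperature regimes (22°C baseline, 37°C heat, 22°C recovery) each carry
their own parameter set; the trajectory is continuous across regime
switches, and the pre-stress state is the 22°C steady state
(σ/k45, σ/k35, α·σ/kpa3).

The solution is evaluated in closed form (a Bateman-type three-exponential
formula, with an exact matrix-exponential fallback for degenerate rate
combinations) and fitted to loading-control-normalized band intensities by
bounded, multi-start weighted least squares with per-probe scale factors.

## Worked example

```python
from rrnapipe import fit_timecourse, synthetic

table = synthetic.gen_timecourse()          # study-design time course, no noise
fit = fit_timecourse(table, synthetic.default_schedule())
d = fit.derived
print(f"k45 reduction at 37°C: {d.pct_reduction_k45:.1f}%")
print(f"35S→P-A3 reduction:    {d.pct_reduction_35S_to_PA3:.1f}%")
print(f"P-A3 removal fold:     {d.fold_kpa3:.2f}")
print(f"α·k35 (37°C):          {d.alpha_k35_s:.2e} s⁻¹")
```

prints

```
k45 reduction at 37°C: 70.0%
35S→P-A3 reduction:    35.7%
P-A3 removal fold:     2.50
α·k35 (37°C):          4.00e-05 s⁻¹
```

i.e. under the generator's default heat-stress parameters the fit recovers a
70% slowdown of primary P-site cleavage, a 35.7% slowdown of 35S → P-A3
transformation, a 2.5-fold acceleration of P-A3 removal, and a 37°C
transformation rate α·k35 of 4.0×10⁻⁵ s⁻¹ — the derived statistics the
analysis is designed to resolve.

The same stages are available from a shell:

```
rrnapipe simulate timecourse --seed 1 --out out/
rrnapipe fit --table out/timecourse.csv --out out/ --per-probe
rrnapipe simulate trace --out out/
rrnapipe profile --trace out/trace.csv --out out/
```

Every command writes a `provenance.json` (tool version, config hash, seed);
identical config and seed give byte-identical outputs.

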