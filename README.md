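# sipturnover

Turnover analysis of biopolymers from 13C stable-isotope-probing (SIP)
time series in continuously operated enrichment cultures — built for
the question of whether extracellular polymeric substances (EPS) of
polyphosphate-accumulating organisms (PAOs) are degraded faster than
intracellular biomass, or simply share the general decay of the
community.

When a sequencing batch reactor (SBR) held at solids retention time
SRT is switched to a uniformly 13C-labeled carbon source, every
polymer pool accumulates label as old molecules are washed out and
degraded and new, labeled ones are synthesized. The labeling ratio
(LR, labeled fraction of a compound's population) of each compound
follows the exponential cumulative model

    LR(t) = a − e^(−k·t)

where `k` (1/d) is the turnover rate; pure wash-out gives
`k = 1/SRT = mu_imposed`. Measured rates above `1/SRT` reveal biomass
decay through

    mu_actual = mu_imposed + k_decay.

The package provides the full desk pipeline around these two
relations:

* **`isotopes` / `formula`** — isotopologue distributions of sugars
  and tryptic peptides at arbitrary 13C atom fraction (binomial carbon
  + natural-abundance convolution), and two-population native/labeled
  mixture spectra with reproducible noise;
* **`sbr` / `datasets`** — per-cycle simulation of label wash-in
  under wash-out, intrinsic turnover, storage-polymer (PHA/glycogen)
  lags and amino-acid recycling (which makes protein trajectories
  sigmoidal), plus a generator for complete synthetic studies;
* **`lr`** — labeling-ratio estimation from isotope peak clusters,
  a brute-force mixture-decomposition oracle, the two-ion averaging
  rule for negative-mode sugars, and the >10%-incorporation
  detectability rule;
* **`kinetics`** — exponential and Gompertz fits with multi-start
  bounded least squares, group mean trajectories with SD or 95% CI
  bands, and interval-overlap group comparison;
* **`decay`** — growth/decay arithmetic and the summary report.

See `docs/methods.md` for models, defaults, and limitations.

## Worked example

```python
from sipturnover import (PoolSpec, SBRConfig, decay_summary, fit_eq1,
                         simulate_washout, theoretical_lr)

cfg = SBRConfig()   # SRT 7.55 d, 6-h cycles, 32 cycles, 99 atom % 13C

# Wash-out alone predicts ~65% labeling after 8 days:
print(round(theoretical_lr(8, a=1, k=1/cfg.srt_days), 3))   # 0.653

# A polymer decaying at 0.048 1/d labels faster; refit its trajectory:
series = simulate_washout(cfg, PoolSpec(name="eps", k_turnover=0.048))
fit = fit_eq1(series)
print(round(fit.k, 3), round(fit.r_squared, 3))             # 0.181 1.0

# Class-average turnover rates -> growth and decay of the community:
print(decay_summary(7.55, {"sugars": 0.167, "proteins": 0.192}).to_text())
```

which prints

```
0.653
0.181 1.0
imposed growth rate  mu_imposed = 1/SRT(7.55 d) = 0.132 1/d
actual growth rate   mu_actual  = 0.180 1/d  (scheme: mean_of_class_means)
decay rate           k_decay    = 0.048 1/d
equivalent SRT       1/mu_actual = 5.6 d
decay fraction       k_decay/mu_actual = 27%
literature benchmark (activated sludge model, PAO): 0.2 1/d
```

Reading: the reactor imposes a growth rate of 0.132 1/d, but the
polymers' measured turnover implies the community actually grows at
0.180 1/d — the 0.048 1/d difference is biomass decay, about 27% of
all synthesis, equivalent to an SRT of 5.6 days. (The fitted 0.181
for the simulated pool is the discrete-cycle realization of
0.132 + 0.048.)

The `examples/` directory walks through each capability: isotope
patterns, wash-out simulation, LR estimation, kinetic fitting and
group comparison, the decay report, and the end-to-end pipeline.

## Command line

```sh
sipturnover simulate --config config.yaml --out study/
sipturnover fit --in study/ --out results/ --estimator cluster --dispersion ci95
```

`simulate` writes a synthetic study (LR table, spectra, annotations,
manifest; TSV with version/config-hash/seed headers, byte-identical
under a fixed seed). `fit` estimates LRs from the spectra (or uses an
observed-LR column), fits every compound, builds group trajectories
and overlap reports, and writes the decay report. Config presets:
`replica` (reference study conditions), `replica_sugars`,
`decay_recovery`, or an explicit `pools:` list.

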