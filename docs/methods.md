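# Methods

`sipturnover` analyses stable-isotope-probing (SIP) time series from
continuously operated enrichment cultures: how fast are biopolymer
pools — extracellular polysaccharides, glycogen, intracellular and
extracellular proteins — replaced by newly synthesized material when
the carbon feed is switched to a 13C source? This note records the
models, the defaults and why, the numerical choices, and what the
synthetic data do and do not emulate.

## Incorporation model

A sequencing batch reactor (SBR) held at solids retention time SRT
wastes a fraction `dt/SRT` of its biomass per cycle of length `dt` and
regrows it from substrate; at cyclic steady state this imposes a
specific growth rate `mu_imposed = 1/SRT`. After a step switch to
labeled substrate at `t = 0`, the labeling ratio (LR: labeled
molecules over all molecules of a compound) of an inert pool follows
the exponential cumulative curve

    LR(t) = a − exp(−k·t)                                   (fit form)

with `k = 1/SRT` and `a = 1`. A pool that additionally turns over
intrinsically at rate `k_turn` (degradation exactly compensated by
resynthesis, keeping pool mass constant) incorporates label at
`k = 1/SRT + k_turn`. The fit form is the regression model used
throughout; note that for `a < 1` it is slightly negative at small
`t`. The saturating variant `a·(1 − exp(−k·t))`, which coincides with
it at `a = 1` and starts at exactly zero, is provided
(`saturating_lr`, `fit_eq1(form="saturating")`) for users who prefer
an asymptote interpretation of `a`.

Measured turnover rates above `1/SRT` indicate biomass decay: decayed
material must be resynthesized on top of wash-out replacement, so

    mu_actual = mu_imposed + k_decay.

`decay_summary` averages class-level rates into `mu_actual` (default:
mean of class means, each compound class weighing equally; a pooled
per-compound mean is available), subtracts `mu_imposed`, and reports
the equivalent SRT `1/mu_actual` and the decay fraction
`k_decay/mu_actual`. By default the two growth rates are rounded to
the 3-decimal reporting precision *before* the subtraction — that is
how such numbers are quoted (0.180 − 0.132 = 0.048) — with half-up
rounding (banker's rounding would turn 0.1795 into 0.179); the
unrounded values are always retained in the `*_raw` fields. The
activated-sludge-model PAO decay constant (0.2 1/d) is carried in
every report as a literature benchmark, never as a computed value.

## Simulation (`sbr`, `datasets`)

The simulator advances per-cycle difference equations rather than
continuous ODEs: sampling, biomass wasting and storage-polymer cycling
are cycle events in an SBR. Each cycle the pool label relaxes toward
the precursor label by the per-cycle replacement fraction
`f + g = dt/SRT + k_turn·dt`; newly synthesized molecules count as
labeled with the substrate atom fraction (default 0.99), so simulated
LR values live in `[0, label_atom_fraction]`. Agreement with the
continuum closed form is a tested property (within 0.02 absolute LR at
the default 6-h cycles), not an assumption. Biomass is at cyclic
steady state (growth balances removal plus decay); no net biomass
trend, and anaerobic substrate uptake is treated as instantaneous
relative to the cycle. Unlabeled yeast-extract carbon (~1% of feed
COD in the emulated design) is ignored.

Two delay mechanisms sit on the substrate→precursor path:

* **Storage compartments** (PHA/glycogen): a chain of first-order
  exchange pools updated synchronously (shift-register) each cycle,
  the polymer pool reading the post-update terminal compartment. A
  single compartment fully exchanged per cycle passes label through
  within the cycle (anaerobic uptake, aerobic consumption in the same
  cycle), so fully cycled storage delays labeling by at most a few
  hours — `simulate_storage_delay` quantifies the delay as the
  horizontal shift (grid-searched at 0.001-d resolution) minimizing
  the squared difference from the storage-free trajectory.
* **Amino-acid recycling**: a fraction `rho` of the monomer demand for
  new protein is met from a legacy monomer reservoir that relabels
  only at its own exchange rate (default 0.25 per cycle, i.e. a
  relabeling timescale of roughly one day), the rest directly from
  substrate. This is a pure transient: early incorporation is slowed,
  the discrete second difference of the trajectory changes sign
  (a genuine sigmoid, Gompertz-like), and the asymptote and late rate
  are unchanged. A mechanism in which the recycled stream permanently
  tracks the current pool label was considered and rejected: it
  multiplies the asymptotic approach rate by `1 − rho·k/(f+k)`,
  which contradicts the observation that sigmoidal protein series
  end near the wash-out-plus-turnover expectation. The reservoir
  model corresponds to amino acids salvaged from a slowly turning
  legacy protein stock and is the package's own design choice — the
  recycling hypothesis itself specifies no mechanism.

Default pool tables: six monosaccharides with apparent rates 0.146 to
0.326 1/d (glucose fastest, flagged `is_storage_proxy` because
hot-alkaline EPS extraction cannot exclude intracellular glycogen, so
it is excluded from decay estimates); protein pools at apparent rate
0.192 1/d with `rho = 0.5`, one random tryptic peptide (length 8–17,
C-terminal K/R) per protein, ~20% carrying a secretion-signal flag,
and taxa drawn 65/35 between the two dominant PAO genera. Noise:
mean-preserving multiplicative lognormal per spectral channel
(CV 0.05 by default — preserves intensity positivity), plus additive
Gaussian noise (sd 0.02) on the tabulated observed LR.

What the generator does **not** emulate: chromatographic peak
integration, charge states, peptide identification loss at high
enrichment (only its detectability logic is modeled), compositional
drift of the community, and between-compound correlated noise.
Passing tests therefore validate the estimators and kinetics against
the stated forward model, not against instrument physics.

## Isotopologue forward model (`isotopes`)

Carbon contributes a binomial over the carbon count at the chosen 13C
atom fraction; H, N, O, S contribute their natural multinomial
patterns (IUPAC abundances; 36S, natural abundance 1e-4, is folded
into the 32S remainder so each element sums to exactly one; the whole
table is overridable). The molecular pattern is the convolution of
per-element patterns on the nominal mass-shift axis — peak clusters,
not m/z profiles, so peak picking is out of scope — truncated where
the cumulative abundance reaches `1 − 1e-6` and renormalized. The
13C–12C shift constant 1.003355 Da is carried for reporting only.
Patterns are validated to sum to 1 within 1e-9; `carbon_pattern` is
untruncated so its mean is exactly `n_C · fraction`. Correctness is
pinned by two independent oracles in the test suite: atom-by-atom
enumeration of all isotope assignments (formulas ≤ 12 atoms, 1e-9 per
channel) and multinomial count enumeration (glucose).

An observed cluster is the two-population mixture
`scale·[(1−LR)·natural + LR·enriched(RIA)]` with lognormal noise.

## Labeling-ratio estimation (`lr`)

**Cluster estimator.** The native cluster spans the channels in which
the natural pattern retains 99.9% of its mass (an invented boundary
that separates clusters robustly for peptides up to ~60 carbons). The
labeled cluster is the contiguous run around the most intense local
maximum strictly beyond `m_nat + 1` — the gap rule keeps natural
M+1/M+2 peaks out of the labeled cluster. The native population is
quantified by least-squares projection of the native-cluster channels
on the natural pattern (the "compared to the native peak" scaling
generalized to the whole native envelope); the labeled population is
the remaining total intensity, which keeps the estimator accurate even
when the enriched envelope leaks a little below the cluster boundary.
RIA is the intensity-weighted mean shift of the labeled cluster over
the carbon count. No labeled local maximum, or a labeled cluster below
1% of total intensity (an invented guard making "undetected"
meaningful under noise), yields `lr = 0` flagged undetected — not an
error. The estimator is scale invariant.

*Validity domain*: the cluster method needs the enriched envelope to
separate from the natural one, i.e. `n_C · RIA` beyond the native
cluster. For 5–6-carbon sugars at RIA 0.5 the enriched binomial peaks
inside the gap and the method (correctly) reports undetected; the
cluster-vs-mixture agreement (≤ 0.05 LR, noiseless) is therefore
asserted on peptide-scale formulas across RIA 0.5–0.99 and on sugars
at the 0.99 atom fraction the emulated design actually uses.

**Mixture estimator (oracle).** Grid search over RIA ∈ {0.05, …,
1.00} at 0.01 resolution (matching reporting precision, and keeping
the oracle brute-force); at each grid point a non-negative
least-squares fit of (natural, enriched) columns; minimum residual
wins; `lr = w_lab/(w_nat + w_lab)`. Used as the independent
cross-check of the cluster method, and as a robust estimator in its
own right.

**Sugars** are estimated on both negative-mode ions, [M−H]− and
[M−COO]− (read as the deprotonated ion after CO2 loss: one fewer
carbon — the notation is ambiguous for neutral monosaccharides and
this interpretation is flagged in the code), and the two per-ion LR
estimates are averaged; averaging LRs rather than intensities is the
package's reading of the two-ion rule, and a missing ion falls back to
the available one with a flag. **Detectability** follows the >10%
incorporation rule, strict at the boundary.

## Kinetics (`kinetics`)

`fit_eq1` fits `a − exp(−k·t)` by bounded trust-region least squares
(`a ∈ (0, 1.2]`, `k ∈ (0, 5] 1/d` — LR is a fraction and rates far
above the glycogen pool's 0.33 1/d are unphysical here) with
multi-start `k0 ∈ {1, 2, 4}/SRT` and `a0 = max(LR) + (1 − max)/2`;
tight tolerances (1e-15) make the fitted `k` invariant to time-unit
rescaling to ~1e-12. Constant series return `converged=False` with a
"degenerate" reason (R² undefined); optimizer failure likewise never
raises. `fit_gompertz` fits `a·exp(−exp(b − c·t))` (the cited
sigmoid's common parameterization; the rate equivalent is the maximum
specific slope `c/e`) from a 3×3 start grid. On the default sigmoidal
protein simulation the exponential `k` and the Gompertz `c/e` agree
within 30% relative — "similar" operationalized, since no tolerance is
standard.

`group_trajectory` aggregates per timepoint: arithmetic mean, and
either the sample SD (zero for a single member) or the t-based 95%
confidence half-width of the mean (requires ≥ 2 members per timepoint,
validated against a 10,000-draw bootstrap percentile interval in the
tests). `compare_groups` intersects `mean ± band` per timepoint;
"no difference detected" when ≥ 90% of timepoints overlap — the
overlap criterion is qualitative in origin, and 0.9 is the package's
threshold choice. No formal hypothesis tests are attempted.

## Problem sizes and reproducibility

Defaults everywhere are the emulated study conditions: 32 six-hour
cycles, SRT 7.55 d, 99 atom % substrate, 6 sugar + 50 protein pools.
Test-suite simulations use 4–20 protein pools and 40–100 Monte-Carlo
replicates, sizes at which every stochastic tolerance was calibrated
by repeated simulation; all randomness flows through
`numpy.random.default_rng` seeds, and dataset writes are
byte-deterministic under a fixed seed. `scripts/acceptance.py`
recomputes the headline quantities (imposed growth rate, day-8
expected enrichment, actual growth rate, decay rate, equivalent SRT,
decay fraction, and two fit round trips) from the package alone.

## Known limitations

* The per-cycle discretization overestimates the continuous-time rate
  by about 1.7% at 6-h cycles (−ln(1−f)/dt vs 1/SRT); fits on
  simulated data inherit that bias. It is well inside every tolerance
  used, but users comparing against analytic rates should be aware.
* The cluster estimator's native/labeled split assumes one dominant
  enrichment level per compound; multimodal enrichment (subpopulations
  at different RIA) collapses onto an intensity-weighted compromise.
* The recycling reservoir is well mixed with a fixed exchange rate; it
  reproduces the shape and timing of sigmoidal onsets but is not a
  mechanistic proteome-turnover model.
* Formulas are CHNOS-only; phosphorylated or halogenated species are
  out of scope.
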