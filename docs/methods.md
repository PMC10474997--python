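# Methods

## The inference chain

The package treats an eDNA pond survey as a two-layer process: a latent
occupancy layer (which species truly occupy which ponds in which months)
and an observation layer (replicate qPCR reactions on water samples). The
analysis never models the latent layer explicitly; instead it converts
detections into month-to-month *transition states* per species and site —
stay zero `--`, persist `++`, enter `-+`, disappear `+-` — and asks whether
the transition states of different species co-occur across sites more or
less often than chance.

### Detection scoring

A dilution-series standard curve is fitted by ordinary least squares of Cq
against ln(relative concentration). By default each dilution level
contributes its mean Cq over amplifying replicates; fitting on all
replicates is a flag (`use_replicates=True`). Level means are the default
because dropout at low concentrations otherwise weights levels unevenly.
Amplification efficiency is E = 10^(−1/(slope·ln 10)) − 1, identical to the
usual log10-slope convention. The LOD is the lowest concentration at which
≥95% of replicates amplify; the LOQ additionally requires the coefficient
of variation (sample SD / mean, ddof=1) of back-calculated concentrations
to be ≤0.35. Both thresholds are configurable; a series in which no level
qualifies yields null limits rather than an error. A fitted curve with
non-negative slope is returned flagged invalid (with a warning), since
downstream code may still want its diagnostics.

A replicate well is *positive* when its back-calculated quantity strictly
exceeds the LOD. A site-month-species is *detected* when it has ≥2 positive
replicates. The two readings of the replicate rule — two biological samples
or two technical replicates of one sample — are equivalent to the pooled
count by pigeonhole (any two positive wells either share a biological
sample or span two), so the `mode` switch affects only the reported
`basis` field (biological / technical / both). Cq values are valid on
(0, 50] (a 50-cycle protocol); a missing Cq is an empty CSV field, never 0
or 50. Site-months with no wells are *missing* in the detection matrix,
never absent.

### Transitions and the co-occurrence matrix

Transitions exist only between consecutive months. If either month of a
pair is unsampled at a site, the site is dropped from that pair for **all**
species (listwise deletion), keeping every species on a common site set so
that joint counts are well defined. The co-occurrence matrix is
row-conditional: cell (r, c) = (#sites with row event r and column event c)
/ (#sites with r). Rows whose event never occurs are undefined (explicit
NaN, never 0). The matrix is not symmetric; same-species blocks are
reported (their diagonal is 1 by construction) but excluded from testing by
default because their dependence is degenerate.

### Permutation test

The null model permutes each species' transition-state vector across sites
independently, within a month pair. This preserves (i) each species'
transition-type frequencies, hence its temporal autocorrelation between the
two months, and (ii) the site set, while destroying cross-species
association. The two month pairs are tested separately; no cross-pair
pooling.

Because permutation preserves the row counts, tail comparisons are made on
integer joint counts (exact, no float ties). P-values use the add-one
correction p = (1 + #{null ≥ empirical})/(1 + B) with ties counted toward
the tail; the two-sided p doubles the smaller tail, capped at 1. A cell is
flagged `more_than_expected` / `less_than_expected` when its two-sided p is
≤ α (default 0.05) — blue/red in the customary dot-matrix rendering.
Defaults: B = 10,000 permutations, two-sided, cross-species cells only, no
multiple-testing correction (per-cell chance statements); a
Benjamini–Hochberg adjustment across tested cells is available behind
`adjust="bh"`. `check_null_conservation=True` asserts the per-species state
frequencies on every permutation (test mode).

The test is **exact and conditional**: given the per-species margins, the
null distribution of a cell's joint count is discrete (hypergeometric for
two species). Two consequences worth knowing:

- *Conservatism.* With ~30 sites, attainable p-values are coarse; the
  realized per-cell type-I error at α = 0.05 is well below 0.05 (often
  below 0.01, and exactly 0 for cells whose margins cannot produce a tail
  ≤ 0.025). Enumeration at 31 sites shows even the most favorable margins
  (15/15) yield size ≈ 0.032. This is a property of any exact discrete
  test with these conventions, not an implementation artifact.
- *Power.* Rare row or column events (e.g. pond entry, a handful of sites
  per season) give joint counts of 0–7, so single-cell power at 31–60
  sites is modest even under strong simulated interactions.

## Synthetic data generator

`simulate_occupancy` draws month-1 presence per species as
Bernoulli(psi0); thereafter an empty site is colonized with probability γ
and an occupied site goes extinct with probability ε per month. The
predator→prey interaction multiplies a prey's γ by `theta_col` and its ε by
`theta_ext` when **at least one** predator occupied the site in the
preceding month; predators' γ is multiplied by `phi_pred` when at least one
prey was present. Conditioning on the *preceding* month avoids simultaneity
and matches the transition framing; a same-month alternative
(`interaction_timing="same"`, predators updated first) is switchable.
Effective probabilities are clipped to [0, 1] and the number of clipped
draws is recorded in `matrix.meta["n_capped"]` rather than raised.

The observation layer gives each sampled site-month `n_bio` water samples ×
`n_tech` qPCR replicates. Given presence a replicate amplifies with
probability `p_rep` at concentration x ~ LogNormal(conc_mu, conc_sigma) and
Cq = curve(x) + N(0, cq_sd); given absence it amplifies with probability
`p_fp` at LOD/2 — a trace-level signal that the LOD rule screens out, so
false positives never create detections. Predicted Cq beyond 50 cycles is
recorded as no amplification. Site-months in months ≥2 are missing
completely at random with `missing_rate`; month 1 is never missing. One
seed drives three child RNG streams (occupancy, missingness, wells) via
`numpy.random.SeedSequence`, making regeneration bit-identical.

### Default parameter choices

| parameter | default | rationale |
|---|---|---|
| psi0 (prey A1, A2) | 0.258 | guild-level prey prevalence ~45%; per-species = 1−√(1−0.45) |
| psi0 (fish F1, F2) | 0.392 | guild-level fish prevalence ~63%; per-species = 1−√(1−0.63) |
| γ, ε (prey) | 0.3, 0.3 | amphibians move between breeding ponds within a season |
| γ, ε (fish) | 0.15, 0.05 | invasive fish persist once established, spread moderately |
| theta_col / theta_ext / phi_pred | 0.1 / 5 / 2 | strong-avoidance presets; ε×5 caps at 1 (prey cannot persist under predators) |
| n_bio × n_tech | 3 × 3 | three water samples per site-month, qPCR in triplicate |
| p_rep | 0.8 | with 9 replicates, site-level detection of a present species ≈ 0.9999 |
| p_fp | 0.002 | rare trace amplification, always below LOD |
| conc_mu, conc_sigma | 0, 1 | relative amounts around 1, well above the default LOD of 0.01 |
| cq_sd | 0.3 | typical between-replicate Cq scatter |
| missing_rate (paper_like) | 0.15 | a few ponds dry up or become unsampleable after month 1 |

Presets: `null_model` (31 sites, 3 months, all multipliers 1, no
missingness — the calibration scenario), `strong_avoidance` (60 sites, the
multipliers above), `paper_like` (31 sites, multipliers above,
missing_rate 0.15). The reference assay curve is Cq = −1.526·ln(x) + 41.232
with synthetic limits LOD = 0.01, LOQ = 0.05.

### What the generator does and does not emulate

It reproduces the survey design (ponds × consecutive months × replicate
structure), guild-level initial prevalence, detection noise and missing
site-months. It does **not** model spatial structure between ponds, pond
covariates (size, vegetation), disease, per-predator-specific effects,
inhibition, or seasonally varying detectability. Initial occupancy is
grounded in the survey's guild fractions; because colonization accumulates
over months, the *month-pooled* simulated fish prevalence exceeds the
single-number survey fraction — the generator is a stylized testbed, not a
fitted model. Passing tests therefore show that the pipeline recovers
associations that are present in data of this shape and size, not that the
field system has any particular parameter values.

## Numerical and design notes

- Curve fitting: `numpy.polyfit` on level means; R² computed from
  residuals; an all-null series raises, a positive slope warns and flags.
- Undefined proportions (empty rows) are NaN end to end, written as `NA`.
- Month tokens May/June/July ↔ 1/2/3 are accepted interchangeably in
  inputs; ordinals are canonical internally.
- Detection-matrix CSV state tokens are {0, 1, NA}; duplicate
  (species, site, month) keys and unknown tokens are located parse errors.
- Pipeline artifacts carry `#`-comment provenance headers (version, config
  hash, seed); the config hash excludes the output directory so the same
  analysis written elsewhere is recognizably the same run.
- All randomness flows through explicit `numpy.random.Generator` objects;
  every public entry point takes a seed.

## Known limitations

- Single-cell significance at realistic survey sizes is limited by the
  discreteness of the exact permutation null (see above); the test's
  realized size is conservative and its per-cell power against even strong
  simulated interactions is well below 1 at 31–60 ponds. Qualitative
  direction (more/less than chance) is recovered reliably only for cells
  with moderately frequent row and column events.
- The any-predator interaction rule means single-predator cells understate
  the underlying effect when a second predator is prevalent.
- No correction is applied for testing many cells by default; treat
  per-cell flags as descriptive unless `adjust="bh"` is on.
- The transition framework uses detection as truth: a species present but
  undetected in one month appears as a disappearance plus an entry.
  Detection probability at the default replicate design makes this rare
  (~10⁻⁴ per present site-month) but it is not zero.
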