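# Methods

## The spreading random walk

The generative model treats the distal reporter's repression state as a
clamped Gaussian random walk per cell generation. While nucleated, the
spreading de-repression level `s ∈ [0, 1]` experiences a linear restoring
drift toward full repression, `−k_restore·s`, plus zero-mean Gaussian noise
of scale `sigma_s`; while not nucleated, the drift points toward full
de-repression, `+k_loss·(1 − s)`. Nucleation itself is a two-state Markov
chain with per-generation gain/loss probabilities `k_nuc` / `k_denuc`. This
is deliberately the simplest continuous-state model consistent with the
observed phenomenology — dynamic, unstable fluctuation of distal silencing
across generations with a broad intermediate occupancy — and it makes no
claim about nucleosome-level mechanism (read-write feedback, me2/me3
interconversion are out of scope).

Two consequences anchor the model biologically:

* `sigma_s` is the **histone-turnover proxy**. Replication-independent H3
  exchange (measured by RITE tag swaps) is near-euchromatic in strains
  nucleated only by ncRNA elements and essentially absent in ΔK-OFF cells;
  accordingly the ΔREIII-type and ectopic presets carry `sigma_s ≈ 0.16–0.22`
  per generation and the ΔK-OFF preset carries `sigma_s = 0` exactly. With
  zero noise the repressed boundary `s = 0` is absorbing — the model
  guarantees, rather than merely makes improbable, that repressed ΔK-OFF
  lineages never de-repress.
* Reporter distance from the nucleator enters only through `k_restore`
  (spreading strength attenuates with distance); the turnover class of the
  locus sets the noise.

Generations convert to hours at 2.3 hr/generation (≈200 generations in
456 hr of passaging). Equilibrium populations use a 100-generation burn-in
from the fully de-repressed state, comfortably past the ~25 generations a
domain needs to form; a long-chain oracle test (10× burn-in, 10× cells)
confirms stationarity of the repressed mass.

## Fluorescence rendering

Each cell draws one lognormal extrinsic factor `F` (log-SD 0.40) shared
multiplicatively by all three channels — the cell-to-cell variation in
global expression capacity that the euchromatic red reporter exists to
measure. Channels additionally carry independent lognormal noise (log-SD
0.15 for snapshots), a residual promoter leak of 0.2% of full expression
when repressed, and additive lognormal autofluorescence background
(mean 20 a.u.). Forward/side scatter correlate positively with `F`
(∝ √F), so a small-cell scatter gate enriches for dimmer cells. These
defaults put the green–red rank correlation of a heterochromatin-null
population at ρ ≈ 0.86 ungated, in the observed 0.83–0.93 band, and make
red-ratio normalization cut the green coefficient of variation roughly
three-fold.

Time-lapse rendering differs in two ways: per-sample measurement noise is
smaller (log-SD 0.02 — frame-to-frame error of an imaging pipeline rather
than cytometer shot noise) and the rendered level relaxes first-order toward
the state-implied level with a 1.5 hr time constant, emulating fluorophore
maturation and dilution smoothing. Sampling is every 0.5 hr for up to 60 hr;
a configurable 5% of cells is flagged as dying or being ejected before 12 hr
and excluded from analysis, as in the microfluidic protocol.

## Analysis conventions

* **Normalization.** Snapshot channels are divided by red, then scaled by
  the *median* ratio of the matched Δclr4 population (median rather than
  mean: robust to the lognormal tail), putting full de-repression at 1.
  Traces are background-subtracted before the ratio and scaled by the mean
  Δclr4 trace ratio. Normalization is scale-invariant and commutes with
  time restriction (both property-tested).
* **Nucleation clamp.** Cells count as nucleated when raw green falls below
  the no-XFP control's median + 2 sample SD. Sample (n−1) SDs are used
  throughout. Clamping on normalized green is available as an option.
* **State bins.** OFF ≤ an unstained-control-derived bound; ON ≥ the
  matched Δclr4 mean − 3 SD; INTERMEDIATE between, with a guard gap of 2% of
  the full range enforced when both bounds are data-derived. The
  unstained bound is converted to the normalized scale by dividing an upper
  quantile (99.5%) of no-XFP orange by a low quantile (10%) of reference
  red — generous for dim cells, so the OFF bin is not eroded by the
  background-to-red ratio of small cells.
* **Trace cohort statistics** use only cells that survived past 12 hr and
  kept normalized green below 0.5 at every observed timepoint (maintained
  nucleation). Crossing fractions are assessed on per-cell maxima against
  the half-maximal line y = 0.5 and the Δclr4-derived ON cutoff; transient
  de-repression events are maximal runs ≥ threshold that end before the
  trace does, with a configurable minimum duration (default: one sample).
  Cells never reaching a crossing level stay in fraction denominators but
  are censored from onset-delay statistics. Masked timepoints (focus loss)
  are ignored by maxima and run detection. Heatmap export aligns traces by
  nearest sample, never interpolation.
* **Dose-response.** The half-resistance point is read off the normalized
  untreated-ancestry curve by monotone log-linear interpolation (running
  minimum first, to suppress count noise), with 0 µM placed on the log axis
  at half the smallest nonzero concentration; a 4-parameter log-logistic
  least-squares fit is the fallback for sparse or noisy curves, and the two
  agree within 10% on noiseless curves. Memory is summarized as the mean
  normalized separation between ancestries, alongside the full
  per-concentration difference table and the concentration beyond which all
  differences stay below ε = 0.05.
* **Recovery.** The 38 °C arm is divided by the 32 °C arm per timepoint and
  fit with a 4-parameter logistic in time, 5 quantile-derived starts with
  fixed-seed jitter, best RSS kept. t½ is the time the *fitted curve*
  crosses absolute 0.5 (the inflection midpoint is also reported; the two
  coincide when the asymptotes are 0 and 1). Flat series raise a
  "no transition" error; crossings outside the data span are flagged
  extrapolated, and the flag propagates into Δt½.

## What the generators emulate — and what they do not

The dose-response and recovery generators are phenomenological: binomial
counts around a log-logistic in concentration (Hill slope 1.5, midpoint =
the preset's half-resistance) and a logistic in time (slope 0.09/hr,
0.5-crossing at the preset's t½), decoupled from the mechanistic walk,
because only curve-level summaries of those experiments are available to
emulate. Memory enters multiplicatively — the TSA-pretreated arm is the
untreated curve scaled by (1 − memory_offset) — so the two ancestries
converge at high concentration, as observed for the ΔREIII-type locus;
presets that cannot re-nucleate after erasure (ΔK) emit an essentially
empty pretreated arm. The enrichment generator draws two technical
replicates per quantity with 4% lognormal noise around the bin presets
(expression 0.05/0.30/0.80 of the Δclr4 maximum; H3K9me2 0.90/0.49/0.20 of
the dh control; H3K4me3 0.09/0.23/0.44 of the actin control).

Consequently, passing tests demonstrate that the *analysis stages* recover
what the generators inject (parameter-recovery properties: half-resistance
within 15% at n = 5000 per point, t½ within 10% at n = 2000) and that the
calibrated walk reproduces the benchmark cohort fractions. They do not
validate the walk as a mechanistic model of chromatin, nor the generators
against instrument artifacts real data carry (spectral spillover, doublets,
segmentation error, photobleaching) — all deliberately out of scope.

## Calibration

Curve-level preset parameters (half-resistance 2.0 / 0.2 / 3.0 µM for
WT-MAT / ΔREIII / ΔK; recovery t½ 30 and 52 hr so Δt½ = 22 hr; the ΔK
recovery floor of 0.9) are study conditions, set directly. The walk
parameters have no closed form for the cohort statistics, so `k_restore`
and `sigma_s` were fixed once by grid search
(`scripts/calibrate_presets.py`) against the benchmark fractions — ~83%
half-maximal crossing and ~30% fully-ON transit for ΔREIII trace cohorts,
~20% transient loss for WT MAT, ~30% fully repressed clamped cells at 3 kb
with a linear distance decline (0.375/0.30/0.225/0.15 at 1/3/5/7 kb) — and
shipped as a versioned YAML config. Benchmark problem sizes (100-cell trace
cohorts, 10,000-cell populations, 5000/2000 counts per curve point) match
the corresponding experiment scales.

## Known limitations

* The walk's single continuous level cannot represent spatially partial
  domains (e.g. green-ON/orange-OFF collapse patterns seen in rare
  isolates); states are summarized at one distal locus.
* Trace green is binary at the state level (nucleated or not) smoothed by
  maturation; slow nucleation decay within a generation is not modeled.
* FCS ingest is schema-mapped CSV only in practice; no spillover
  compensation or doublet discrimination is performed (inputs are assumed
  compensated, as in the deposited analysis).
* The 20%-transient-loss statistic counts crossings of the y = 0.5 line;
  whether weaker excursions should count is ambiguous, so the threshold is
  exposed as a parameter (`detect_events(threshold=...)`).
* Technical-replicate summaries use mean ± sample SD uniformly, including
  for replicate RNA isolations.
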