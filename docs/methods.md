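# Methods

## Problem setting

A pretrained vocalization classifier applied to a passive acoustic corpus
emits detections: claims that species *k* vocalized at recorder *r* at time
*t*, with confidence score *s* ∈ (0, 1]. Scores below an export floor
(0.80 by default) are discarded at export time and never seen. Classifier
precision varies strongly across species and deployments, so each
(species, dataset) pair is calibrated independently from a small
expert-labeled subsample; nothing learned in one dataset is transferred to
another.

## Precision estimation and threshold choice

The labeling budget is one uniform without-replacement sample of
`n_labels_per_species` detections (default 50) per (species, dataset), drawn
from all exported detections. Precision at a candidate threshold θ is
estimated on the labeled detections with *s* ≥ θ — the one labeled sample is
reused across the grid, not re-drawn per θ, which is the only design
compatible with a fixed labeling budget. Consequences:

* the labeled subset shrinks as θ grows, so high-θ estimates are noisy. A
  grid point with fewer than `min_labeled` (default 5) surviving labels is
  flagged *undefined* and can never be selected; setting `min_labeled=1`
  recovers a guard-free reading.
* estimates at neighbouring grid points are strongly dependent; the
  selection rule ("lowest θ whose estimated precision reaches the target")
  is therefore evaluated left to right on the grid and tested against an
  exhaustive-scan oracle.

The grid is 0.80 to 0.99 inclusive with step 0.01 (20 points), matching the
two-decimal score convention; the target comparison is inclusive
(p̂ ≥ 0.90). Uncertainty is a 95% Wilson score interval (via statsmodels),
chosen over the Wald interval for its coverage near p = 1, where much of the
mass sits in practice; the degenerate counts T_p = 0 and T_p = n are pinned
to exact 0/1 bounds. A pair is *reliable* when a threshold exists; it enters
downstream summaries only if strictly more than `min_detections_post` (20)
detections survive its threshold, counted on the full detection table.

## Filters

Composition order: per-recorder species allowlist → minimum raw count
(strictly more than 50 per species per dataset) → calibrated thresholds.
All boundary comparisons are sharp: 51 raw detections pass and 50 do not;
21 surviving detections pass and 20 do not; a score exactly at the chosen
threshold is kept (consistent with precision being computed on *s* ≥ θ).
Each filter is idempotent, and each dropped detection appears in exactly one
drop-report row with a reason code. The allowlist and minimum-count filters
commute when the allowlist is uniform across a dataset's recorders; a
recorder-specific allowlist can push a species below the raw minimum, which
is why the composition order is fixed and documented rather than left free.

## Synthetic detection streams

The generator produces what the analysis consumes — a detection table with
scores and times plus a complete ground-truth label table — from a
mechanistic description per species:

* **events**: independent inhomogeneous Poisson processes per
  (recorder, species), intensity = base rate (events/recorded hour) ×
  diel kernel × habitat multiplier × presence indicator. Day totals are
  drawn Poisson and event times allocated by the normalized intensity,
  which is distributionally equivalent and fast.
* **diel kernel**: a von Mises mixture on the 24 h circle, normalized to
  mean 1 over the day so base rates keep their units. κ = 0 components are
  uniform.
* **seasonality**: an optional day-of-year residency window (it may wrap the
  year end, as for wintering visitors).
* **migration**: a sharp latitude band of half-width *w* whose center moves
  north at a constant speed (degrees/week) from a start latitude and start
  day. A sharp indicator rather than a gradient keeps front-recovery
  assertions crisp.
* **scores**: Beta-distributed, with separate (α, β) for true and false
  positives; only events with *s* ≥ the export floor are emitted. Because
  emission is a hard floor on an untruncated Beta, true precision at any θ
  has the closed form p(θ) = r_tp·S_tp(θ) / (r_tp·S_tp(θ) + r_fp·S_fp(θ)),
  exposed as `analytic_precision` and used as the oracle throughout the
  tests.
* **habitat multipliers** scale true- and false-positive intensities
  equally, so precision is habitat-invariant and rate ratios across habitats
  equal the multiplier ratios exactly.

Randomness is sub-seeded per (seed, recorder, species) stream via CRC32
keys, so a stream's draw is independent of which other streams exist and
identical seeds give byte-identical CSV output.

What the generator deliberately does not model: song-bout temporal
autocorrelation (events are Poisson), acoustic propagation and
detection-distance effects, score drift within a deployment, and
labeler error (ground-truth labels are exact). Passing tests therefore
demonstrate that the estimation and filtering machinery is correct under
the stated statistical assumptions, not that those assumptions hold for any
particular field dataset.

## Scenario presets

* `precision_ladder` — eight species spanning true floor precision
  ~0.05–1.0. The four low rungs give true and false positives identical
  score distributions, making precision exactly constant in θ (those species
  can never be calibrated); two species concentrate false-positive scores
  just above the floor so precision climbs steeply through 0.90 at interior
  grid points (0.87 and 0.90); two are already above 90% at the floor. The
  crossing parameters were chosen from the closed form so that precision
  clears the target decisively (≈0.93–0.95 at the optimum vs ≤0.85 one step
  below) rather than hugging 0.90, keeping threshold recovery stable at
  realistic label budgets. One recorder, 30 days, ≈1,200–3,100 exported
  events per species — enough for 500-label calibration experiments.
* `diel_triptych` — dawn (0600), midday (1200) and dusk (1800) von Mises
  peaks (κ = 4, 2, 4), 21 days, ≥5,000 true detections per species so the
  circular-mean recovery tolerance of ±1 h is measurable.
* `migration_north` — nine recorders on a 58–70.8° latitude transect,
  one migrant moving north at 1.75°/week with a ±1.6° band, April–mid-June.
* `seasonal_taiwan` — two years, a summer breeder (residency days 105–220),
  a winter visitor (300–80, wrapping), and a year-round resident.
* `habitat_gradient` — twelve recorders across old-growth/secondary/pasture
  with multipliers 2.0/1.0/0.5, 30 days (360 recorder-days).

Sizes were picked so the full test suite and the acceptance script each run
in about a minute on one CPU while keeping every statistical tolerance
measurable.

## Biodiversity summaries

* **Diel profiles** use local wall-clock hours (UTC + per-detection offset;
  the offset is data, no timezone database). Effort correction (dividing
  each hour's count by recorded hours at that hour-of-day) is optional and
  off by default. The profile's peak is summarized by the circular mean.
* **Habitat rates**: the observation unit is the recorder-day,
  rate = detections / recorded hours; habitat means average recorder-day
  rates, and the 90th percentile of pooled rates is stored with the summary
  as the display cap so plots are reproducible from the artifact alone.
  A recorder-day with detections but no effort record is an error rather
  than a silently infinite rate.
* **Migration fronts**: median and 25th/75th percentile latitude per 7-day
  bin; empty bins carry no summaries. A least-squares slope of median
  latitude over time is attached as a convenience diagnostic of front speed.
* **Occurrence matrices**: species × contiguous equal-width bins (7-day
  default) spanning first to last detection; count or presence mode. The
  display row order comes from agglomerative clustering of presence rows
  with Jaccard distance and average linkage — a standard pairing for binary
  occurrence data. Rows are sorted alphabetically before linkage, which
  makes the leaf order invariant to input row order and breaks zero-distance
  ties deterministically.

## Numerical and design notes

* Detection ids, when absent from input, are SHA-1 hashes of
  (source file, start offset to 3 decimals, species), so label sheets join
  back stably across re-reads; species names match exactly after
  whitespace/case normalization (no fuzzy matching — a misjoin is worse
  than a miss).
* CSV writers fix score precision at 6 decimals and offsets at 3; a
  write/read round trip reproduces every field to that stated precision.
* Pipeline run directories contain only deterministic bytes (timings go to
  stderr), so reproducibility can be checked by hashing the directory.
* Replicated calibration experiments (100 simulation seeds) put the
  chosen threshold at the analytic optimum in >95% of (species, replicate)
  cells with 500 labels, and within one grid step in >95% with 50 — the
  one-step slack at the routine budget is the cost of estimating a plateau
  crossing from ~15–30 surviving labels.

## Known limitations

Recall is out of scope by design; all guarantees concern precision of the
kept set. Calibration assumes the labeled sample is exchangeable with the
stream it was drawn from — score drift within a dataset violates this and
is not modeled. The simulator's Poisson assumption understates the variance
of bout-structured singing, so real-data confidence intervals will be
somewhat anti-conservative at fine time scales. The allowlist stage consumes
externally supplied expected-species lists; constructing them (e.g. from
range maps) is outside the package.
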