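# Methods

This note documents the models and conventions behind `lickstruct`: what
each processing stage computes, what the synthetic-data generator does and
does not emulate, the numerical choices, and the design decisions taken
where more than one reasonable convention exists.

## Event detection and lick construction

Raw capacitance samples are converted to touch/release events by a
per-consecutive-sample delta rule: a touch fires when
`value[i] − value[i−1] ≥ Δ` and a release when
`value[i−1] − value[i] ≥ Δ`, with Δ = 12 sensor counts by default (the
threshold used by MPR121-class filtered touch controllers). The rule is
deliberately *not* referenced to a running baseline: a slow drift below Δ
per step emits nothing. A state machine forces polarities to alternate
starting from the untouched state, collapsing repeated same-polarity
triggers to the first and suppressing a release that precedes any touch.
The event timestamp is that of the triggering sample, so detection latency
is bounded by one sample period; firmware latency is assumed zero.

Pairing is conservative — contact time is never invented:

* a release with no preceding touch is dropped (logged);
* on a double touch, the earlier touch is dropped and the one closest to
  the eventual release kept;
* a touch with no release before session end is dropped.

Duration filtering defaults to 5 ms – 10 s. The published inclusion
criteria for lickometer experiments in this paradigm are cited to prior
work without numeric values, so these bounds are declared here: the lower
bound rejects contact glitches shorter than any physiological tongue
contact, and the 10 s ceiling is far above any lick so that genuinely long
spout contacts — which carry the non-bout-duration phenotype — are never
truncated by preprocessing.

## Bout segmentation

Criteria: a bout initiates at the first lick *i* such that licks
*i … i + n − 1* (n = 3) have every consecutive inter-lick interval
≤ 1 s; once initiated, the bout extends while each subsequent interval is
≤ 3 s; it terminates when the gap exceeds 3 s.

Conventions that the criteria sentence leaves open, fixed here and shared
by the brute-force reference implementation used in the tests:

* "within 1 second of each other" is read as *consecutive* inter-lick
  intervals, not a 1-s sliding window over the initiating run — the common
  convention in the lick-microstructure literature;
* boundary comparisons are inclusive: an ILI of exactly 1.0 s can
  initiate, a gap of exactly 3.0 s continues, termination requires a gap
  strictly greater than 3.0 s (matching the "at least 3 seconds" phrasing
  of the quiet period);
* licks immediately preceding the initiating run (e.g. a pair with gaps
  between 1 and 3 s before a fast triple) do **not** retro-join the bout;
  a bout's first lick is the first lick of its initiating run. This keeps
  segmentation a single deterministic forward pass;
* duplicate onsets are invalid input; upstream processing bumps duplicates
  forward by the 1 ms timestamp quantum, logged.

The segmentation is checked bit-identically against an independently
written brute-force enumerator over 1000+ random lick trains whose ILI
mixture (0.05–10 s) straddles both thresholds.

## Microstructure and temporal summaries

Per-session summaries report total licks, total contact time, bout count,
mean licks per bout, mean *total* contact time per bout (the "drinking
time within bouts" measure; the per-lick mean within bouts is reported
separately), percentage of licks in bouts, non-bout lick count, and mean
contact durations by bout membership. Means over empty sets are NaN
sentinels, never zero.

The frontloading split counts licks in the half-open window [0, 1800 s);
a lick at exactly 1800 s is post-frontload. Half-open windows compose
without double counting. Membership in the window is per lick, not per
bout. Cumulative curves count onsets ≤ t (inclusive). Pooled per-group
distributions collect, across sessions, each lick's onset time and its
within-session cumulative index; the two marginals are compared between
genotypes with two-sample Kolmogorov–Smirnov tests.

KDE grids span the data ± 4 bandwidths — wide enough that the truncated
Gaussian tails keep the numerical integral within 1e-3 of unity, which a
3-bandwidth margin does not quite guarantee. The bandwidth rule is
configurable (Scott default, Silverman, or fixed).

## Intake and accumulation

Intake conversion: `(m_pre − m_post)/ρ_sol × f × ρ_EtOH / (body/1000)`
g/kg, with ρ_EtOH = 0.789 g/mL and ρ_sol = 0.97 g/mL for 20 % v/v
(standard ethanol–water density tables; both configurable — the source
experiments report g/kg without stating their conversion).

Blood-ethanol concentration (BEC) units are carried opaquely: the package
never converts them, so accumulation slopes are in BEC-units per g/kg and
the knockout/control slope *ratio* is unit-free. Fits are per-group OLS
with intercept by default (a through-origin option exists); the slope
ratio carries a 95 % percentile bootstrap interval resampling animals
within groups (2000 replicates, seeded).

## Group inference

* **Location tests**: Mann–Whitney U reported as a tie- and
  continuity-corrected normal z, or Welch's t. `method="auto"` runs
  Shapiro–Wilk per group at α = 0.05 and uses the rank test on any
  rejection; experiments in this literature mix the two tests without
  stating a rule, so the selection is explicit and overridable.
* **Mixed models**: intake ~ behavior × genotype with a random intercept
  per animal, fit by REML. The random-intercept-only structure is the
  minimal one consistent with repeated sessions per animal. The
  interaction is tested with a Wald F whose denominator df is
  `n_obs − rank(X)` (residual convention), recorded in the result
  metadata — df conventions differ across software, so printed F/df values
  from other toolchains are not directly comparable. When a noise-free
  design drives the residual variance to zero the Wald statistic is
  reported as infinite with p = 0 (non-zero contrast) or 0 with p = 1
  (zero contrast) rather than NaN.
* **Mixed ANOVA**: two-way mixed design (between = genotype, within =
  bout type) via pingouin, with per-within-level Welch contrasts. Every
  subject must be observed in both bout types; the pipeline drops (and
  reports) animals missing a cell before fitting.
* No multiple-testing correction is applied by default (per-test p-values
  are reported); a Benjamini–Hochberg helper exists but is off.

## The synthetic-data generator

One session is generated as:

1. **Bout anchors** from a piecewise-constant-intensity Poisson process
   over the segments 0–30, 30–120, 120–150 and 150–240 min — the
   frontloading and late-session analysis windows. An anchor closer than
   the termination gap (+0.5 s margin) to the previous bout is dropped, so
   generated bouts can never merge.
2. **Bout contents**: lick count per bout ~ shifted geometric (min 1);
   within-bout ILIs ~ gamma (mean 0.15 s, shape 4 — ≈7 Hz licking, the
   physiological mouse rate) truncated at the 1 s initiation ceiling, so
   every generated bout of ≥ 3 licks is detectable by construction;
   contact durations lognormal, clipped below the gap to the next onset.
3. **Isolated licks** from a homogeneous Poisson process, placed uniformly
   and rejected within the termination gap (+margin) of any existing lick
   (bounded retry budget). They can neither extend a bout nor — being
   pairwise separated — initiate one.

Consequently segmentation recovers the generated bout count *exactly*
(generated bouts of fewer than 3 licks count as non-bout licks), which the
tests exploit over hundreds of seeded sessions.

Intake is Σ licks × per-lick volume (Gaussian per-lick volume noise plus a
session-level g/kg noise term), written back as bottle masses so the
manifest inverts the intake conversion exactly; with all noise disabled
BEC = slope × intake exactly.

### Presets

| parameter | control (wild type) | ADH1-null | anchored contrast |
|---|---|---|---|
| bout rate /h by segment | 16, 5, 5, 5 | 10, 3.5, **8**, 3.5 | fewer bouts; late-session (120–150 min) elevation |
| licks per bout (geometric mean) | 28 | 18 | fewer licks within bouts |
| within-bout ILI | gamma(0.15 s, k=4) | same | — |
| bout lick duration | lognormal(50 ms, σ=0.3) | same | no within-bout duration difference |
| isolated licks /h | 30 | 30 | non-bout lick counts equal |
| non-bout lick duration | lognormal(75 ms, σ=0.4) | lognormal(150 ms, σ=0.4) | ×2 non-bout duration |
| volume per lick (µL) | 1.2 ± 0.25 | same | — |
| BEC slope (units per g/kg) | 25 | 50 | ×2 accumulation |
| BEC noise sd / intake noise sd | 8 / 0.10 | same | — |

Only the ratios and orderings in the last column encode reported
phenotype contrasts; every absolute value is a declared default chosen to
be physiologically plausible for 2–4 h mouse drinking sessions (e.g.
control intake ≈ 3.4 g/kg in 2 h, BEC ≈ 80–100 units). The saccharin
preset uses the control parameters for both genotypes, mirroring the
absence of genotype differences for non-ethanol fluids, and supports the
specificity analyses.

With these defaults a 2-h control session expects ≈ 430 licks and an
ADH1-null session ≈ 220, putting the knockout/control intake ratio near
50 %.

### What the generator does not emulate

Circadian structure beyond the session, day-to-day escalation or learning,
within-bout rate rhythms (bursts inside bouts), sex differences, bottle
leakage/evaporation, and any tissue pharmacokinetics (absorption and
elimination are collapsed into one linear BEC-vs-intake relation per
genotype). Passing tests therefore demonstrate correctness of the
*analysis chain* under a controlled generative model — not that real data
satisfy the model.

## Statistical calibration checks: problem sizes

The mixed-model calibration suite uses 20 animals × 8 sessions per
replicate: the 3-standard-error coverage check relies on normal-based Wald
standard errors, whose between-animal components are systematically
anti-conservative when only a handful of animals per group inform them.
The phenotype-contrast suite runs 100 seeded cohorts of 12 animals per
group — mean orderings (intake, bout count, licks per bout, percentage of
licks in bouts) are required to hold in every cohort, while the two ratio
contrasts (non-bout duration ×2, accumulation slope ×2) are checked on
seed-averaged estimates: a single cohort's slope-ratio estimate at the
default BEC noise has a sampling sd of ≈ 0.24, wider than the ±0.2 band
that the averaged estimate comfortably meets.

## Known limitations

* The on-disk log dialect is a reconstruction; laboratories with existing
  loggers should add a dialect rather than change the defaults.
* Mixed-model degrees of freedom use the residual convention, not
  Satterthwaite/Kenward–Roger; F statistics from software using those will
  differ, particularly at small group counts.
* The delta rule operates on already-filtered sensor readings; no
  additional denoising is attempted, and licks shorter than one sample
  period of the raw trace are undetectable by construction.
* Bout criteria are fixed per run; no hierarchical (burst-within-bout)
  analysis is provided.
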