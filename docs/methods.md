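# Methods

## Cohort data model

One record per founder female: the replicate it belongs to, its last
observed day, whether that day is a death or a censoring, and a sparse map
of day → offspring count. Days are 1-based (day 1 = first 24 h after
introduction of a <24 h neonate) and all observations are daily integers.

Two conventions matter downstream and are fixed package-wide:

- **Death-day attribution.** An animal is "alive on day x" for every
  x ≤ its last day, including the day a death is recorded. Offspring were
  removed daily in the protocols this emulates, so a brood found with a
  dead female must be attributable to her; deaths therefore take
  demographic effect the following day.
- **Censoring.** An individual whose record ends alive is censored on that
  day: it contributes survival information through the day and nothing
  after. Partial life tables are produced by censoring at the horizon, not
  by discarding animals that die later — truncation uses all information
  available up to the horizon.

The CSV dialect is long-format (`species,replicate,individual,day,alive,
offspring`), one row per individual-day; a final `alive=0` row marks the
day the animal was found dead. The death row carries that day's offspring
count (normally 0) so that writing and re-reading any valid cohort is an
exact identity.

## Life-table engine

For a replicate of n founders, `l_x` = (number alive on day x)/n and
`m_x` = (offspring on day x)/(number alive on day x), zero when none are
alive. The seven endpoints follow classical cohort life-table practice;
see the README table for the formulas.

Two estimators of the intrinsic rate r are provided:

- **approximate** (default): r = ln(R0)/T_c with T_c the cohort generation
  time Σx·l_x·m_x / Σl_x·m_x. The weekly Daphniid tables this pipeline
  emulates are internally consistent with this estimator — e.g. a 10-week
  species' week-2 column gives ln(73.13)/10.09 ≈ 0.425, exactly the
  printed r — and it can *decrease* as later reproduction is added, which
  those tables show and which no renewal-equation root can do.
- **lotka**: the exact root of Σ e^(−r·x) l_x m_x = 1. The left side is
  strictly decreasing in r, so the root is unique; it is bracketed
  starting from [−2, 5] d⁻¹ (geometric expansion if needed) and solved by
  Brent's method, then required to satisfy |Σ − 1| < 1e−10. Under this
  method T is reported as ln(R0)/r.

The Euler–Lotka exponent uses the exact age x in days. The birth rate b
uses the stable-age formulation `b = 1/Σ e^(−r(x+1)) L_x` with mid-interval
person-days `L_x = (l_x + l_{x+1})/2` (l beyond the horizon taken as 0);
this is the one endpoint whose exact historical formula cannot be
recovered from printed data, so the identity d = b − r is treated as the
authoritative constraint and is asserted to 1e−12 in the test suite along
with λ = e^r, DT·r = ln 2 and T·r = ln R0.

Degenerate inputs: a truncation with no reproduction yet (R0 = 0) yields
NaN-flagged rates, is excluded from downstream statistics, and triggers a
warning. r = 0 gives DT = ∞; r < 0 sets a declining-population flag and DT
holds the halving-time magnitude ln 2/|r|.

## Weekly truncation

Week-w horizon = day 7w inclusive; W = ⌈max observed day / 7⌉. Week W uses
all data, so the final summary column is bit-identical to a standalone
full-life-cycle analysis (same code path, same floats). Truncation
composes: truncating at week w then v < w equals truncating at v directly.
Cross-replicate summaries report mean ± SEM by default with SD selectable;
published weekly tables use both conventions in different places, so the
choice is surfaced rather than resolved.

## Cutoff inference

Per parameter, replicate values at weeks 1..W−1 are compared to week W
(control) by a two-sided Dunnett test on the pooled one-way ANOVA error
(df = N − k − 1 with k = W − 1 comparison groups). The joint null of the k
statistics is multivariate t with pairwise correlations
n_i n_j/((n_i+n_0)(n_j+n_0)) — ½ under balance. Adjusted p-values
P(max|T| ≥ |t_i|) are estimated from a seeded Monte Carlo sample (default
200 000 draws; the sample is cached per (group sizes, df, draws, seed) and
its standard error ~0.0005 near p = 0.05 is reported per comparison).
Monte Carlo was chosen over table lookup so that any k, any df and any α
are reproducible from a recorded seed; the suite cross-checks it against
an independent implementation of the same test and verifies familywise
error 0.05 ± 0.02 under a simulated global null (k = 8, n = 3).

α defaults to 0.05, the field norm; the stricter 0.005 sometimes quoted in
this literature is selectable. Parameters are analysed independently — no
multiplicity correction across the seven endpoints, mirroring standard
practice. Weeks with undefined replicate values are dropped from the
comparison set with a warning.

The **cutoff point** is the smallest week w such that weeks w..W−1 are all
non-significant (W if none). Because published cutoff statements use two
off-by-one conventions, both fractions are always emitted:
100·(w−1)/W — the "indistinguishable beyond week w−1" reading that
reproduces the classical 4/9 = 44.4 % and 7/10 = 70 % figures — and
100·w/W.

## Synthetic cohorts

The simulator emulates the 3-replicate × 10-female daily-observation
design. Per individual: a continuous Weibull(shape 4, scale 52–58 d)
lifespan rounded up to whole days (recorded dead the next day; censored,
not killed, at the 7·max_week horizon), clutches every 3 days from
maturation (day 6–7), expected clutch size ramping linearly from 55 % of
the peak at first clutch to the peak at day 14–16 and decaying
exponentially thereafter, and realised clutch sizes negative-binomial with
shape 8 (overdispersed; shape → ∞ recovers Poisson). Draw order is fixed
(all lifespans first, vectorised, then clutches), so a seed's survival
trajectories are invariant to the fecundity stressor multiplier; the
stressor hooks (multipliers on survival scale and clutch mean) default to
1 — unexposed controls.

Calibration (`scripts/calibrate_presets.py`): per species, the peak
clutch mean and senescence rate are fit so the expected full-life schedule
hits the species' full-life-cycle (R0, T) — 239.8/24.1 d, 244.3/27.3 d,
237.4/22.7 d — then a fixed-seed 600-replicate simulation nudges the
working targets so the *replicate-mean* λ of 10-female replicates lands on
1.255, 1.224 and 1.275 d⁻¹ respectively (λ is a convex functional of the
schedule, so small-cohort means sit slightly above the expected-schedule
value). The fitted numbers are frozen in `lifetab.simulate`; survival and
timing parameters are fixed life-history choices, with fecundity
senescence included because the weekly R0 increments of real Daphniid
tables decline strongly after mid-life.

What the simulator does **not** reproduce: the week-by-week trajectories
of any real dataset (only full-life-cycle endpoint magnitudes are
calibrated), brood-interval variability, maturation-day jitter,
density-dependence, male/ephippia production, or between-replicate
environmental variance beyond sampling noise. Consequently its replicate
SEMs are of realistic order but not matched to any published table, and
simulated cutoff weeks tend to fall *later* than classically reported ones
(with only sampling noise between replicates, a λ bias of a few percent
remains detectable for longer). Passing tests therefore demonstrate the
pipeline's correctness and the qualitative single b→a convergence of λ,
not the historical cutoff weeks themselves, which the suite reproduces
from the published significance patterns instead.

## Problem sizes

Defaults keep everything interactive: analyses use the 3 × 10 study
design; the Dunnett familywise-error check uses 2 000 simulated null
datasets; oracle-equivalence sweeps use 200 random ≤30-day schedules;
monotonicity checks use 100 simulated 6-female cohorts; preset-calibration
verification uses 200 replicates. The full test suite runs in well under a
minute on one core.

## Known limitations

- The approximate r estimator is biased relative to the Euler–Lotka root
  whenever reproduction is spread over ages; it is the default for
  fidelity to the weekly-table tradition, not for statistical optimality.
- Survivorship uses simple proportions, not Kaplan–Meier: censoring is
  only expected at the analysis horizon itself (as in the emulated
  design). Individuals censored earlier are treated as leaving the risk
  set.
- λ's interpretation assumes continuous exponential growth; under density
  dependence or time-varying vital rates a cutoff tuned to λ may not
  transfer.
- Balanced replicates are assumed by the default Dunnett mode; the
  unbalanced correlation structure is implemented but flagged.
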