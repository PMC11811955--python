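# Methods

This note documents the model, the conventions chosen where the design was
genuinely open, the synthetic data generator, and what the test suite does
and does not establish.

## Health states and their clinical reading

PHQ-9 totals (0–27) are graded healthy (H, score < 5), mild (M, 5–9) and
moderate-to-severe (S, ≥ 10). The thresholds are applied to real-valued
monthly means as half-open intervals [0, 5), [5, 10), [10, 27]; monthly
averaging produces non-integer scores and the classification must stay
total on them. A Markov state is the ordered pair of levels in months t−1
and t. The pair encodes treatment response: HM, MM, HS, MS, SS are
non-response or relapse (treatment change indicated); HH, MH, SH are
remission (score < 5 held ≥ 1 month); SM is response without remission;
HH/MH are stable, SH/SM unstable. Structurally a pair (a, b) can only be
followed by (b, ·), so the 9-state graph has exactly 27 feasible edges and
diameter 2.

Death is an absorbing mass outside the pair states — patients can die in
any month at any severity — rather than a tenth pair, which would have no
meaningful "previous level" semantics.

Observed severity is treated as true severity: the monitoring technology's
sensitivity/specificity is the single accuracy layer in the model, standing
in for both instrument error and irregular use.

## Cohort engine

The cohort is a mass distribution over
pair × line × months-since-change × visit-countdown × engagement ×
on-treatment (9 × 10 × 3 × 8 × 2 × 2 cells) plus dead mass. Event order in
each monthly cycle is fixed: (1) mortality, (2) attendance determination,
(3) per-visit follow-up dropout, (4) treatment change, (5) pair transition,
(6) adverse discontinuation, (7) counter updates and rescheduling. The
sources describe the events narratively without fully serializing them;
this order is a documented commitment, and the individual-level
microsimulation oracle implements the identical order so the two routes are
comparable. Mass conservation is asserted to 1e−10 every cycle.

Conventions worth calling out:

* **Cycle-start accounting, no half-cycle correction.** QALYs and costs for
  month m use the state occupied at the start of the cycle (after
  mortality): utility of the pair's current level ÷ 12, background
  treatment cost for all alive mass, the active line's monthly cost for
  on-treatment mass, the average of the nine line costs for the exhausted
  stratum, the visit fee for realized attendance, and the monitoring fee for
  engaged alive mass under the adaptive strategy. A patient who changes
  lines in month m pays the new line's cost from month m+1.
* **Discounting** is `(1 + r)^(−(m−1)/12)` with r = 0.03/year by default, so
  cycle 1 is undiscounted. Only the annual rate is conventionally stated;
  the month-indexing choice is ours and is stated explicitly.
* **Treatment boost.** At a change to a line with remission probability
  pr_rm and response probability pr_rsp, the changer's transition row for
  that single cycle becomes
  `pr_rm·e(curr,H) + pr_rsp·e(response target) + (1−pr_rm−pr_rsp)·baseline`.
  For curr = S the response target is SM; for curr = M "improvement short of
  remission" coincides with reaching H, so the response mass merges into MH.
  Baseline resumes the following cycle.
* **Lockout.** `months_since_change` is capped at 2; changes require the cap,
  so two changes are never fewer than 2 months apart. The cohort starts with
  the lockout cleared (patients are established on line 1).
* **Adverse discontinuation** is a one-time hazard applied exactly one month
  after a change (the sources state discontinuation becomes possible after
  1 month on a treatment; with the capped counter a recurring hazard would
  instead drain every line indefinitely, which neither source describes).
  A discontinued line is consumed: its cost stops, the patient keeps
  baseline progression and may start the next line at the next eligible
  visit.
* **Follow-up dropout** is stated as an annual probability; it is converted
  to a per-visit probability by a constant-hazard transform over the
  strategy's nominal visits per year (fixed k → 12/k; rule-based → 3, the
  mean of the 2/4/6 schedule; adaptive → 12, the monthly assessment
  cadence), overridable in config. Dropped patients keep background
  treatment and baseline progression, never attend again, and stop paying
  the monitoring fee.
* **Post-exhaustion.** After failing line 9: no further boosts; rule-based
  and fixed strategies book 6-month maintenance visits, adaptive monitoring
  keeps charging its fee but triggers no visits; the exhausted stratum's
  treatment cost is the average of lines 1–9.
* **Adaptive visits during lockout** are attended and costed by default (a
  flagged patient goes to the visit even if no change is yet allowed); a
  config switch (`engine.suppress_lockout_visits`) suppresses them instead,
  since the sources do not resolve this. False-negative misses are
  independent across months — a cohort model cannot carry per-patient
  correlation without expanding the state space, and no per-patient
  persistence is claimed.

The **microsimulation oracle** re-implements the identical rules at the
individual level with explicit sampling, used only to validate the
deterministic engine (agreement within 3 Monte-Carlo standard errors at
100,000 individuals across distinct parameter sets).

## Preparation chain

* Patients with < 6 recorded scores are excluded; the observation span is
  divided into 12 equal segments and scores averaged per segment (records
  whose times are integers in 1–12 are treated as already month-indexed;
  a zero-width span puts its score in month 1).
* **EWMA imputation**: the sources name the method but not its algorithm;
  ours is a forward pass writing the running exponentially weighted average
  (α = 0.5, configurable) of observed values into missing slots, with a
  symmetric backward pass for leading gaps. Imputed values are convex
  combinations of observed ones and therefore never leave the observed
  range.
* **Clustering**: k-means (Euclidean, 20 restarts, fixed seed) on raw
  12-vectors without standardization — all dimensions are the same PHQ-9
  scale. Silhouette scores are reported for k = 2…6, but k = 3 is the
  default even where k = 2 scores marginally higher: three named risk tiers
  (high/medium/low, ordered by descending mean trajectory) are the unit of
  analysis. The cluster count, α and standardization are exposed in config
  because none is externally fixed.
* **Transition estimation**: frequency counts of pair-to-pair transitions,
  normalized per row; structurally infeasible entries are exactly zero.
  Rows never observed default to the (curr, curr) self-loop successor —
  conservative "no information = no movement" — with a uniform-over-three
  alternative in config. Initial distributions are the empirical
  (month-1, month-2) pair frequencies.

## Synthetic cohort generator

The generator emulates the statistical shape of the kind of private EHR
extract such a model would be estimated from: 444 patients split
128 : 192 : 124 into high/medium/low risk groups, 12 monthly scores, 38%
missing completely at random (re-masked until ≥ 6 observed scores remain,
matching the filtering rule), 69% female, mean age 45. Conditioning on
≥ 6 observed scores rejects the most-masked draws, so realized missingness
runs systematically a few points below the nominal 38% (about 34–35%);
this is a property of the guarantee, not a bug.

Generation operates on the pair-state chain directly — 13 latent monthly
levels per patient so that each of the 12 emitted months has a defined
(previous, current) pair — and the PHQ-9 score is a decoration: the group's
per-level mean plus Gaussian noise (sd 1.2), clamped to the level's score
interval. This makes the generating matrices exact ground truth for
downstream estimator tests. The three group chains are built from 3×3
level kernels with a ±0.05 trend-momentum nudge (improving patients are
slightly likelier to keep improving); the kernels were chosen so that all
nine pair states occur at estimable frequency within a 12-month window
while keeping the groups' mean trajectories clearly separated
(≈ 10.4 / 7.2 / 5.1 mean PHQ-9). Initial pairs default to each chain's
stationary distribution.

What the generator does **not** emulate: informative missingness (visit
frequency rising with severity — a real selection concern), score
autocorrelation beyond the two-period chain, item-level PHQ-9 structure,
and demographic effects on progression. Passing tests therefore establish
internal consistency of the pipeline, not external validity on real EHR
data.

## Parameters

All monetary values are abstract currency (2023-USD scale). The shipped
defaults are **documented placeholders**: realistic magnitudes chosen once,
clearly not transcriptions of any proprietary table. The two conventional
anchors are the 0.03 annual discount rate and the $81,630/QALY WTP
threshold (2023 US GDP per capita); the $12/month monitoring fee is a
published exemplar for an automated telephonic assessment service.

| Parameter | Default | Units |
| --- | --- | --- |
| Horizon | 24 | months |
| Monthly mortality | 0.0004 | probability/month |
| Annual follow-up dropout | 0.20 | probability/year |
| Utilities H / M / S | 0.85 / 0.72 / 0.58 | per year |
| Follow-up visit cost | 180 | $/visit |
| Background treatment cost | 40 | $/month |
| Treatment change fee | 0 | $/change |
| Line costs (1→9) | 25 → 130 | $/month |
| pr_rm (1→9) | 0.35 → 0.09 | per change |
| pr_rsp (1→9) | 0.20 → 0.09 | per change |
| Adverse discontinuation (1→9) | 0.06 → 0.14 | one-time |
| Adaptive sensitivity / specificity | 0.85 / 0.85 | — |
| Monitoring fee | 12 | $/month |

Because base-case costs, QALYs, ICERs and cost-effective fractions are
functions of these placeholders, their absolute values carry no external
meaning; the structural outputs (frontier logic, grid topology — a
sensitivity threshold for non-domination, specificity- and cost-driven
gradients, cost-saving cells at near-zero fees) are the reproducible
content. Scenario definitions in `configs/scenarios_example.yaml` (97 per
group: base + 24 one-way + 60 two-way + 12 multi-way) follow standard
deterministic-sensitivity-analysis structure with placeholder ranges.

## Numerical choices

* Mass conservation tolerance 1e−10 per cycle; transition rows validated to
  1e−12.
* Frontier ties (identical cost and QALYs) keep the first-listed strategy;
  extended dominance is removed iteratively until incremental ICERs
  strictly increase, and the construction is verified against brute-force
  mixture-domination search.
* An ICER with zero QALY gain is reported as infinite (never a division
  error); a technology with strictly fewer QALYs than the comparator is
  "dominated" regardless of cost, and "cost-saving" requires no fewer
  QALYs at strictly lower cost.
* Degenerate inputs raise: all-missing series, constant clustering input,
  empty sequence lists, distributions not summing to 1.
* All CSV floats are written with 10 significant digits; one config seed
  derives fixed per-component sub-seeds.

## Known limitations

* Payer perspective only; no productivity or societal costs, no
  net-monetary-benefit curves, and deliberately no probabilistic
  sensitivity analysis — the deterministic grid and scenario sweeps are the
  uncertainty analysis, so no probability-of-cost-effectiveness statements
  can be made.
* No individual covariates beyond the risk-group split; transition matrices
  are time-invariant and line-independent (treatment acts only through the
  one-cycle boost).
* The cohort engine cannot represent per-patient persistence of monitoring
  misses or preference heterogeneity; dropout and accuracy parameters are
  the proxies.
* Simulation-based throughout: conclusions about real monitoring
  technologies require replacing the placeholder parameters and, ideally,
  validating progression assumptions against trial or observational data.
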