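# depmon

Decision-analytic cost-effectiveness modelling of **remote monitoring for
chronic depression**, compared against rule-based and fixed-frequency
follow-up scheduling.

## The problem

Depression care relies on periodic follow-up visits at which treatment can
be modified, but how often to follow up is an open question: too rarely and
non-responders linger on failing regimens; too often and the payer funds
visits that change nothing. Remote monitoring technology (apps, sensors,
periodic PHQ-9 self-assessment reviewed remotely) promises to trigger a
visit exactly when a treatment change is needed — at the price of a monthly
fee, missed detections (imperfect sensitivity) and false alarms (imperfect
specificity). `depmon` is a framework for asking, from a payer's
perspective: *under what accuracy and cost is adaptive remote monitoring
cost-effective?*

## The model

Severity is graded from the PHQ-9 total score (0–27) into three levels —
H (0–4), M (5–9), S (10–27) — and a Markov state is the **pair of levels in
consecutive months** (HH, HM, …, SS). The pair carries clinical meaning:
HM/MM/HS/MS/SS are non-response or relapse (a treatment change is
indicated), HH/MH/SH are remission, SM is response without remission. A
monthly-cycle cohort model runs for 24 months over an expanded state
(pair × treatment line 1–9 × change lockout × visit countdown × engagement
× on-treatment), with events per cycle in fixed order: death, follow-up
attendance, follow-up dropout, treatment change, pair transition, adverse
discontinuation.

A treatment change at a visit gives a **one-cycle health boost**: with the
new line's remission probability `pr_rm` and response probability `pr_rsp`,
a patient in a needs-change pair (e.g. SS with occupancy `p_SS`) moves to
the remission target SH with probability `pr_rm` (mass `pr_rm × p_SS`) and
to SM with probability `pr_rsp`; afterwards the baseline group-specific
transition matrix resumes. Consecutive changes within 2 months are locked
out; failing all nine lines returns the patient to baseline progression.

Five strategies are compared: adaptive remote monitoring
(sensitivity/specificity/monthly fee), rule-based scheduling (next visit in
2/4/6 months by current pair state) and fixed 2-, 4-, 6-month visits.
Outcomes are discounted costs and QALYs (3%/year), ICERs
(Δcost/ΔQALY), efficiency frontiers with strong and extended dominance, and
a dominated / cost-saving / ICER classification against the rule-based
comparator at a willingness-to-pay threshold of $81,630/QALY.

Because the longitudinal EHR data such models are estimated from are
private, the package includes a **synthetic cohort generator** (three
latent risk groups, 12 monthly PHQ-9 scores, ~38% missingness) and the full
**preparation chain**: ≥6-observation filtering, 12-segment monthly
averaging, EWMA imputation, k-means risk-group clustering (silhouette
reported for k = 2…6) and frequency-count estimation of the 9×9 pair-state
transition matrices and initial distributions per group.

## Worked example

```bash
depmon cea --out-dir outputs
```

generates the default synthetic cohort (444 patients, seed 12345), prepares
the three risk groups and writes `outputs/cea_table.csv`:

```
group,strategy,cost,qaly,dominance,icer_vs_next
high,adaptive,4753.07,1.29813,frontier,231086.55
high,rule_based,3134.15,1.28384,extended_dominated,
high,fixed_2,3864.22,1.29428,frontier,71051.49
high,fixed_4,2629.16,1.27690,frontier,46259.92
high,fixed_6,2173.91,1.26706,frontier,
...
```

Reading the high-risk rows: over two years a high-risk patient under
6-monthly visits accrues 1.267 QALYs at $2,174; stepping up the frontier,
4-monthly visits buy extra QALYs at $46,260/QALY and 2-monthly at
$71,051/QALY (both under the $81,630 threshold), while the adaptive
technology at its placeholder accuracy (85%/85%) and $12/month costs
$231,087 per additional QALY — not cost-effective *at these placeholder
parameter values*. Rule-based scheduling is extended-dominated here: a
mixture of fixed schedules attains its QALYs more cheaply. All economic and
treatment-line inputs live in `configs/default.yaml` and are documented
placeholders; substitute your own estimates to analyse a real setting.

The technology question itself is answered by the grid:

```bash
depmon grid --out-dir outputs --plot        # 1089 cells + heat maps
depmon scenarios --out-dir outputs          # 97 scenarios x 3 groups
```

The heat maps show the characteristic structure: below a sensitivity
threshold the technology is QALY-dominated by rule-based care; above it,
cost-effectiveness improves with specificity and falls with the monthly
fee, reaching cost-saving cells when monitoring is (nearly) free and highly
specific.

Other commands: `depmon synth` (trajectories CSV + generating truth),
`depmon prep --input trajectories.csv` (risk-group profiles JSON + prep
report), `depmon simulate --group high --strategy fixed_6` (per-cycle state
snapshots).

## Layout

| Module | Role |
| --- | --- |
| `depmon.model_core` | severity levels, nine pair states, feasibility |
| `depmon.cohort_prep` | filtering, monthly segmentation, EWMA imputation, clustering, matrix estimation |
| `depmon.synthetic_cohort` | synthetic trajectory generator with known truth |
| `depmon.strategies` | adaptive / rule-based / fixed follow-up strategies |
| `depmon.engine` | deterministic cohort engine + microsimulation oracle |
| `depmon.economics` | discounting, accrual, ICERs, frontier, dominance |
| `depmon.sensitivity` | technology grid, heat maps, scenario sweeps |
| `depmon.config`, `depmon.cli` | validated configuration and command line |

See `docs/methods.md` for modelling assumptions, parameter conventions and
limitations.
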