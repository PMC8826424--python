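# Methods

## The evaluative framework

Each analytical finding `E` — a binary evidence condition such as
"diastase number ≤ 8 DN", "caramel ≥ 5 mg/kg" or "syrup marker above
LoQ" — is weighed under a pair of mutually exclusive source-level
propositions: the sample is atypical of a reference set of genuine
products (Hp), or it is a typical product whose composition falls
outside the reference set by chance or for a stated reason (Hd). The
weight of evidence is the likelihood ratio LR = P(E|Hp) / P(E|Hd).

The framework deliberately stops there. Converting an LR into the
probability that a sample is adulterated requires a prior, which is
subjective and belongs to the trier of fact, not the analyst. The report
renderer enforces this: every strength statement uses the
conditional-on-proposition form ("the findings are N times more likely
if [Hp] than if [Hd]") and rendering fails if the output matches a
denylist of transposed-conditional phrasings.

Assumptions worth stating explicitly:

- **P(E|Hp) = 1 for threshold conditions.** A sample genuinely
  non-compliant with a limit meets the corresponding condition with
  certainty. The API accepts numerators below 1 for future soft
  conditions, but the shipped pipeline uses 1.
- **Evidence conditions are binary.** Measurement uncertainty near a
  threshold is *not* used to soften the condition; `mu` is carried as
  disclosure metadata only, because there is no agreed rule for folding
  it into P(E|H). A value of 7.9 DN against a limit of 8 therefore meets
  the condition outright — a known limitation.
- **Only source-level (level I) propositions are computed.** Activity
  and offence levels are representable in the data model for case-file
  completeness but trigger no arithmetic; objectivity is best served by
  starting at level I.

## Probability assignment

P(E|Hd) is the background prevalence of the condition among genuine
samples. Four routes, each recorded as provenance on the assignment:

| method | estimate | default use |
|---|---|---|
| `empirical` | k/n | reference counts with k ≥ 1 |
| `laplace` | (k+1)/(n+2) | zero or tiny counts |
| `jeffreys` | (k+½)/(n+1) | zero or tiny counts |
| `upper_bound` | exact one-sided binomial upper limit at `confidence` (default 95%) | conservative zero-count fallback |
| `asserted` | caller-supplied value | experience-based probabilities; mandatory free-text justification |

An empirical estimate with k = 0 is refused: an observed zero is not a
usable denominator, and the error message directs the caller to a
correction or an assertion. Every count-based assignment carries the
two-sided Clopper–Pearson interval at the same confidence level
(computed from the beta quantile function; cross-checked against
statsmodels in the tests). Interval bounds propagate through the LR by
interval division — the LR interval is (num.lo/den.hi, num.hi/den.lo) —
and through combination by the same max/product rules as the point
values.

LR point values are computed in exact rational arithmetic via the
decimal representation of the inputs, so 1/0.08 is exactly 12.5 and
combinations like 9×9×9 are exactly 729; floats would drift. Display
rounding (default 3 significant figures) is purely a report-layer
concern; JSON output always carries full precision.

## Verbal scales and the conservative demarcation

Two built-in scales (shipped as YAML, user-replaceable in the same
schema) share the band structure Null at LR = 1, then decade bands with
the convention lower < LR ≤ upper: 1–10, 10–100, 100–1000, 1000–10,000,
and unbounded above 10,000. The ENFSI wording runs slight/limited,
moderate, moderately strong, strong, very strong; the literature wording
weak/limited, moderate, strong, very strong, extremely strong.

Band demarcations are treated conservatively: an LR within a factor
`conservative_margin` (default 2) of its band's lower bound is reported
one band lower and flagged. The default of 2 classifies 12.5 as
slight/limited rather than moderate while leaving 50 as moderate. The
rule never downgrades below the lowest support band for LR > 1, never
moves more than one band, and applies uniformly — to both scales and to
the combined LR as well as per-finding LRs (so a combined LR of 125 is
reported one band below its nominal 100–1000 band, with the downgrade
flag set). Scales are defined for the supported proposition only; an LR
below 1 is first replaced by its reciprocal and marked as supporting Hd
(`orient`, an idempotent operation).

## Combining findings

Within a *correlation group* (findings believed dependent) only the
largest LR is counted; group maxima are multiplied across groups. This
is the conservative extreme of dependence handling — no copula or joint
model is attempted, since estimating inter-marker dependence is an open
research problem. Because max ≤ product for LRs ≥ 1, grouping can only
lower the combined LR. All LRs must be oriented the same way before
combining; mixed-direction evidence is rejected rather than silently
multiplied. When no plan is supplied every finding becomes its own
group and the result (and the rendered report) carries an explicit
independence-assumed warning. When intervals are present the max rule
selects by point value and carries that finding's interval through.

## Misleading-evidence simulation

`misleading_evidence_rate` stress-tests a marker panel: how often does a
*genuine* sample (Hd true) nevertheless reach a combined LR ≥ t? Markers
are binary, present in genuine samples with their background
prevalences and with certainty under Hp. Within a correlation group
markers are fully dependent, simulated comonotonically (one shared
uniform per group, marker present iff u < prevalence — identical to a
shared coin when prevalences are equal, and preserving marginals when
they differ); groups are independent. The combined LR of a simulated
sample is the joint-evidence LR: zero if any marker is absent (such a
pattern is impossible under Hp, whose per-marker probability is 1),
otherwise the group-max/cross-group-product of the per-marker LRs
1/prevalence. Under this model the universal bound
P(LR ≥ t | Hd) ≤ 1/t holds for every threshold, and the simulation is
checked against it (and against closed-form cases) within Monte-Carlo
error. Note the contrast with the reporting pipeline, which treats a
finding whose condition is *not* met as inconclusive (LR = 1) rather
than exculpatory: a routine CoA evaluation is not a joint-likelihood
statement over the whole panel, and absence of one marker should not
silently cancel the others in a report. The simulation answers a
different, design-stage question and uses the strict joint model.

## Study design (survey sizing)

With P(E|Hp) = 1, achieving LR ≥ target requires background prevalence
≤ 1/target — 1% for moderate support (LR > 100), 0.1% for
strong-to-very-strong (LR > 1000). `required_reference_size` inverts the
chosen estimator: the smallest n such that the correction or exact upper
bound applied to (observed_k, n) is ≤ 1/target. The bound is strictly
decreasing in n for fixed k, so the search is exponential doubling plus
integer bisection, verified by brute-force scans in the tests. With the
Laplace correction and zero positives, LR 1000 needs n = 998 (≈ the
"1000 genuine samples, none positive" design) and LR 10 needs n = 8;
the exact 95% upper bound is more demanding (n = 2995 for LR 1000). All
three corrections are reported rather than privileging one, since the
choice is a policy matter. A design whose search would exceed 10⁸
samples is returned as an explicit infeasibility result, not an
exception, so reports can state that the target strength cannot be
demonstrated.

## CoA schema and disclosure audit

CoAs have no agreed machine format — their opacity is the problem this
package addresses — so the CSV/JSON schema here is a proposal:
comma-separated, UTF-8, mandatory header, empty string = absent, columns
`parameter, mode, value, units, lod, loq, mu, condition_direction,
condition_threshold, ref_n, ref_k, ref_population, ref_source` (the last
optional; qualitative rows put `detected`/`not_detected` in `value`).
Malformed rows are collected with line numbers rather than aborting the
read.

The disclosure checklist audits each finding for: a quantitative value
(a qualitative "detected" only counts if an LoQ makes it interpretable
as "above LoQ"), an LoD or LoQ, measurement uncertainty, a cited
reference dataset, and a strength assessment. Method-acceptability
metadata (tested, peer-reviewed, error rate known, generally accepted)
cannot be derived from a CoA and defaults to explicit False. A report in
which any finding lacks a strength assessment is badged
intelligence/investigative/technical — explicitly not capable of
supporting a definitive judgement — rather than evaluative. Every
probability assignment is logged with its method, inputs and citation so
the case-file trace is reconstructable from logs alone.

## Synthetic fixtures

`generate_fixture_coa` emulates a CoA from a marker panel: each
parameter is a quantitative marker with condition "≥ 5 mg/kg" and a
reference survey of 1000 genuine samples whose positive count encodes a
prevalence drawn from the configured range (default 5–15%, rounded to
3 decimals so k/1000 is exact). Genuine samples meet each condition with
its background prevalence; adulterated samples meet all conditions. The
generator is fully deterministic given its seed and writes a ground-truth
record alongside the CSV. What it does *not* emulate: correlated
markers, measurement error around thresholds, heterogeneous survey
sizes, or non-compliance mechanisms unrelated to adulteration — so
passing end-to-end tests demonstrate the arithmetic and plumbing, not
robustness to real-world reference-database deficiencies, which remain
the user's responsibility to assess.

## Numerical and testing choices

Exact rational arithmetic for LR points; beta quantiles for all binomial
bounds; integer bisection verified against linear scans; Monte-Carlo
checks sized at 10⁵ replicates (bound checks) and 10⁴ replicates per
grid point (interval coverage over n ∈ {50, 1000} × p ∈ {0.01, 0.1,
0.5}), with assertions allowing 3 binomial standard errors of
Monte-Carlo slack around the analytic guarantees. Group-maximum
tie-breaks are by (value, id) so combination breakdowns are
deterministic. Rendering is pure string assembly with stable key
ordering in JSON, making repeated renders byte-identical.
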