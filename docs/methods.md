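# Methods

## Case/non-case design and counting rules

The unit of analysis is the spontaneous report, never the drug–reaction
pair. A report is a **case** when at least one of its reactions carries a
Preferred Term (PT) matching the case definition — a single PT, or a High
Level Term (HLT) expanded to its member PTs through the two-level
terminology shipped with the package (lookup is case-insensitive; a PT may
belong to several HLTs). A report is **exposed** when at least one drug
entry with role `suspect` matches the exposure definition (ingredient,
class, or class union). Concomitant drugs — e.g. the maintenance
immunosuppressants that co-occur on transplant-rejection reports — are
deliberately not exposures; the requirement is configurable
(`require_suspect=False`) because source databases do not always state
which convention was used upstream.

A report whose suspect drugs span two classes (PD1 + CTLA4 combination
therapy) counts in **both** per-class analyses and once in the union row.
This reproduces the characteristic arithmetic of per-class tables
(152 + 18 + 1 − 12 = 159 in the calibrated example below). The
head-to-head comparison instead excludes dual-exposed reports, because a
report exposed to both arms carries no information about the contrast
(`include_dual=True` restores the inclusive behaviour).

## Information component

For observed count O = a and expected count E = (a+b)(a+c)/N (kept at full
floating precision),

    IC = log2((O + 1/2)/(E + 1/2)),

with the equal-tailed 95% interval taken as the log2 of the 2.5% and 97.5%
quantiles of a Gamma(shape O + 1/2, rate E + 1/2) posterior for the
observed-to-expected ratio. The 1/2 offsets are the usual BCPNN shrinkage:
they keep the measure finite at zero counts and pull small-count
estimates toward zero. The Gamma-quantile formulation, rather than the
older asymptotic variance-correction formula, is the one that remains
accurate at extreme small counts — at O=1, E=9 it puts the upper credible
bound at −1.0 where the asymptotic formula gives about −0.4 — and it is
the formulation this package validates against a Monte-Carlo oracle. The
signal rule is strict: `signal ⟺ IC025 > 0`.

Expected counts are computed against the **full** report universe for
every screen row, including rows for overlapping exposures, so the rows
share a common denominator.

## Reporting odds ratio

ROR = ad/bc with Woolf's log-scale interval, SE = √(1/a+1/b+1/c+1/d), and
a two-sided Wald p from z = ln(ROR)/SE. The 97.5% normal quantile is fixed
at 1.959964 for cross-platform reproducibility. A zero **cell** triggers
the Haldane–Anscombe correction (add 1/2 to all four cells, flagged in the
result); a zero **margin** is an error, since no correction makes the odds
ratio identifiable there.

The test suite compares the Woolf interval against an exact conditional
interval obtained by brute-force enumeration of the noncentral
hypergeometric distribution. The exact oracle uses the **mid-P** tail
convention: the classical conservative convention produces intervals so
much wider than any asymptotic method at cells of 3–5 that the comparison
would be uninformative, while mid-P endpoints track Woolf within 15% on
the log scale across all 81 tables with cells in {3,4,5}.

## Synthetic database and calibration

The generator emulates the structure of a large spontaneous-reporting
database: one record per report with demographics, reporting metadata,
1–5 drugs (a long-tailed multinomial background plus independently drawn
Bernoulli exposure drugs, so exposure margins are analytically
controlled), 1–3 reactions (event-eligible PTs assigned per-report at
configured base rates, plus weighted filler PTs guaranteeing
non-emptiness), calendar dates by year weights, and outcomes. Everything
is driven by one mandatory seed; identical configurations produce
byte-identical files.

Drug–event associations are planted in one of two modes:

* **rate** (default): the conditional event probability given a matching
  exposure is multiplied by the reporting-rate ratio λ; a product above 1
  is rejected at validation. Realized counts carry binomial noise, which
  is what a parameter-recovery study should see. For non-planted pairs,
  assignment is independent of exposure by construction, and the test
  suite audits this with chi-square tests over 100 pairs.
* **count**: exactly `n_events` matching reports, drawn uniformly, receive
  the event, and base-rate draws of the planted event terms are suppressed
  for all exposure-drug reports (conditional-on-target simulation). This
  is the right tool when the purpose of the dataset is to realize a known
  observed/expected table: the marginal signal rows of the published
  screen (e.g. 18 observed vs 9 expected, lower credible bound 0.2) sit
  so close to the decision threshold that Bernoulli noise around the
  target would flip the flag in a third of datasets — a property of the
  published counts themselves, not of any generator.

`paper_calibrated_config()` uses count mode. Its arithmetic, per 100,000
reports: PD1-exposed margin 3,800, of which 600 dual with ipilimumab
(combo probability 600/3800 given PD1, the value implied by the published
expected counts: 38 + 9 + 9 − 50 = 6 expected-overlap per 1,000-report
event margin); ipilimumab-only 300; PDL1 900; union 5,000. The background
rejection rate is set so the total event margin is ~1,000, giving expected
counts ≈ 50/38/9/9 for union/PD1/CTLA4/PDL1. Planted case counts are
140 PD1-only + 12 dual + 6 CTLA4-only + 1 PDL1, realizing observed counts
159/152/18/1 exactly and the published dual-exposure share of cases
(12/159 = 7.5%). The realized observed-to-expected ratios, ≈3.2 / 4.0 /
2.0 / 0.17 per row, are then the planted effect sizes. Organ-specific
rejection PTs are drawn with kidney at 54.7% and liver at 15.7% of cases;
case outcomes use the published distribution (fatal 22.6%, recovered or
recovering 21.4%, sequelae 2.5%).

Time to onset is log-normal, parameterized by the published median
(28 days) and quartile ratio (IQR 16–60): σ = ln(60/16)/(2·z₀.₇₅) ≈ 0.98.
The quoted median and IQR are not exactly consistent with any log-normal
(the IQR is not geometrically centred on the median), so the model keeps
the median and the quartile ratio; the implied quartiles are ≈14.5–54
days.

What the generator does **not** emulate: reporting-delay dynamics,
duplicate reports, country-level reporting heterogeneity, indication
channeling, and drug–drug correlations beyond the explicit combination
rule. Tests passing on this generator therefore demonstrate correctness
of the counting and the statistics, not robustness to those real-data
phenomena.

## Numerical and design choices

* Quantiles in descriptive summaries use linear interpolation between
  order statistics (the common statistical-software default); proportions
  are displayed to one decimal, IC/ROR to one decimal, p to one
  significant figure.
* Ingredient names are normalized by lowercasing, whitespace collapsing
  and stripping a small table of salt suffixes; full WHODrug-style
  normalization is out of scope.
* Partial dates (YYYY-MM) are accepted on input, imputed to mid-month and
  flagged; the interchange format always writes full dates.
* A negative exposure-to-onset interval is treated as an inconsistent
  record: logged, returned as missing, excluded from summaries.
* The drug-class dictionary ships with the three checkpoint-inhibitor
  classes (CTLA4i: ipilimumab; PD1i: cemiplimab, dostarlimab, nivolumab,
  pembrolizumab, retifanlimab, tislelizumab, toripalimab; PDL1i:
  atezolizumab, avelumab, durvalumab). One name that sometimes appears in
  drug listings, "emiplimab", is treated as a typographical variant of
  cemiplimab and is not a separate ingredient (no such INN exists).
* Monte-Carlo oracle tests fix their own seed and use a tolerance of
  max(0.01 log2 units, 4× the analytic standard error of the empirical
  quantile): an MC oracle cannot certify agreement below its own sampling
  resolution, which at shape 1/2 (zero observed reports) is ~0.02 log2
  units per 10⁶ draws on the lower quantile.

## Problem sizes

The test suite generates databases of 10⁵ reports for calibration and
recovery studies (20 seeds each), 3×10⁴ for the pipeline and independence
audits, and uses 10⁶-draw Monte-Carlo oracles; the full suite runs in a
few minutes on one CPU.

## Limitations

Disproportionality measures are reporting associations, not incidence or
causal effects; the package deliberately implements no causality
assessment, no duplicate detection, and no multiple-comparison adjustment
across screen rows (none is conventional for a four-row confirmatory
screen). The comparative ROR requires a non-empty singly-exposed
comparator arm; with a single comparator case its interval spans an order
of magnitude, which the package reports rather than hides.
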