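# Methods

## Signal model and depletion equation

A competitive peptide-binding assay reads out the free reactive groups left
after incubation with a test chemical: Ellman's reagent gives an absorbance
at 405 nm proportional to free thiols (cysteine/glutathione readout), FSE a
fluorescence (Ex 485/Em 528 nm) proportional to free amines (lysine
readout). Three reference controls define the scale on every plate:

* **A** (peptide + solvent + probe): maximum attainable signal,
* **B** (peptide + solvent, no probe): blank,
* **C** (peptide + chemical, no probe): the chemical's own optical
  contribution (color, autofluorescence), measured per substance.

Percent depletion of a mean well signal S is

    depletion% = [1 − (S − C)/(A − B)] × 100,

applied identically to the negative control (lactic acid), positive control
(DNFB) and each test chemical. The expression is invariant under rescaling
of (S − C) and (A − B) by a common positive factor (gain changes of the
reader) and strictly decreasing in S. A run with A ≤ B has no dynamic range
and is rejected outright.

**Order of operations.** Replicate wells are averaged within a run (the
bench protocol uses two wells per chemical), the equation is applied per
run, per-run signed values are averaged across runs (at least three
independent experiments, configurable via `n_min`), and clamping to
[0, 100] happens once, after cross-run averaging. The signed mean is
retained for audit — the bundled reference panel itself contains a negative
printed value (Chlorpromazine, DPRA), showing that published upstream data
were not clamped at source. Clamping before versus after cross-run
averaging differs only when per-run values straddle the bounds; both
orderings are reachable through the public functions, with after-averaging
the default.

**Run QC.** The negative control must stay essentially unreactive and the
positive control clearly reactive. No numeric acceptance band is
standardized for this readout, so the defaults — NC clamped depletion
≤ 10%, PC depletion ≥ 50% — are package choices, configurable and reported
in the run result rather than silently applied.

## The bundled dataset

`data/chemicals.csv` is the published 106-chemical reference panel: index,
name, CAS, human potency category (1–6), and Cys/Lys/mean percent depletion
for the spectrophotometric assay and for the classical DPRA (HPLC-derived
literature values), transcribed at the printed one-decimal precision.
Transcription was validated row-by-row with the internal check
mean ≈ (Cys + Lys)/2 within ±0.1. Exactly one row fails it — Dibenzyl
ether's spectrophotometric mean (printed 47.9 vs computed 87.9) — and is
carried as printed with a `mean_inconsistent` flag, because the published
misclassification rosters are reproduced only by the printed per-column
values. For the same reason classification always consumes the printed
columns as-is: no re-deriving of means, no re-clamping of signed values
(any positive threshold classifies a negative value as non-sensitizer).

Human categories 1–4 bind to `sensitizer`, 5–6 to `non_sensitizer`
(category-5 chemicals sensitize so rarely in the general population that
they are grouped with true non-sensitizers). The panel then contains 71
sensitizers and 35 non-sensitizers, with per-category counts
{1: 6, 2: 20, 3: 24, 4: 21, 5: 22, 6: 13}.

**Mechanistic domains.** `data/domains_s1_synthetic.csv` assigns each
chemical a protein-binding domain (Michael acceptor, Schiff base, SN2,
SNAr, acyl transfer, or no alert) plus optional pre/pro-hapten flags. The
file is a *synthetic reconstruction*: the domains of the 41 chemicals
misclassified by at least one model and the aggregate totals (35 none,
33 Michael acceptor incl. 3 slashed, 17 Schiff base incl. 2 slashed, 10 SN2
incl. 2 slashed, 9 acyl transfer, 2 SNAr) follow the published analysis;
the assignments of the always-correctly-classified chemicals are chemically
plausible placeholders constrained to those totals. Per-domain tallies of
correct classifications depend only on the constrained parts, so they are
insensitive to the placeholder choices. Slashed labels ("Michael
acceptor/none", "None/SN2") normalize to their non-"none" token with an
ambiguity flag — the only convention consistent with the aggregate counts.

## Prediction models

A rule model is a branch (`cys_only`, `mean_only`, `combined_or`), its
threshold(s) and a comparison strictness. Built-ins:

| model | rule |
|---|---|
| `protreact_cys` | Cys% ≥ 13.935 |
| `protreact_mean` | mean% ≥ 9.563 |
| `protreact_combined` | Cys% ≥ 13.935 **or** mean% ≥ 9.563 |
| `dpra_mean` | mean% > 6.38 |
| `dpra_cys` | Cys% > 13.89 (used when co-elution affects the lysine peptide) |

The spectrophotometric rules are inclusive (≥), the DPRA rules strict (>),
exactly as published; the distinction matters only at exact threshold
values but is preserved because it is part of the published model
definitions. DPRA co-elution is an HPLC phenomenon: the package represents
it as branch selection by the caller and does not model detection.
`combined_or` is provided for completeness; no published per-metric values
exist for it, and evaluation grids use the four single-branch columns.

## ROC cut-off derivation

Candidate thresholds are midpoints between consecutive distinct observed
scores, plus one sentinel below the minimum and one above the maximum:
every achievable confusion matrix of the rule `score ≥ t → sensitizer`
appears exactly once, and a derived cut-off is reported together with its
**tie interval** — the half-open interval `(low, high]` of thresholds
inducing the identical classification. Published cut-offs such as 13.935%
were derived from unrounded laboratory data, so a reimplementation on the
one-decimal printed values cannot (and should not) match the third decimal;
the meaningful statement, which the tests assert, is that the derived
cut-off and the published one lie in the same tie interval: on the bundled
panel the Youden-optimal cysteine cut-off is 13.95 with tie interval
(13.7, 14.2] ∋ 13.935, and the mean cut-off 9.55 with (9.5, 9.6] ∋ 9.563.

The optimality criterion is Youden's J = sensitivity + specificity − 1,
equivalent to balanced accuracy (BA = (J+1)/2). Which criterion produced
the published cut-offs is not documented; Youden's J is the standard choice
and reproduces their classifications. Ties on J break toward higher
specificity (the assay's selling point is specificity), then toward the
larger threshold. All three choices are deliberate and fixed.

`YoudenThresholdClassifier` wraps the derivation as an sklearn estimator
(`fit` stores `threshold_`, `tie_interval_`, the achieved operating point
and the full curve; `predict` applies the rule), and
`DepletionRuleClassifier` does the same for fixed-threshold rule models, so
both compose with sklearn model selection.

## Evaluation and concordance

Accuracy = (TP+TN)/n, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
balanced accuracy = (sensitivity+specificity)/2. Reported percentages
round **half-up** to whole percents (74.53 → 75, 73.58 → 74, 77.36 → 77);
with small-integer confusion counts exact .5 cases occur and banker's
rounding would shift them. Metrics with an empty denominator (single-class
truth) are reported as `None`, never as silent zeros, because a zeroed
sensitivity or specificity would silently corrupt balanced accuracy.

The concordance report compares two (assay, rule) pairs on the same
records: correct counts per model and jointly, false-positive/negative
index sets with their intersections, rosters sorted by dataset index, and —
when domain annotations are present for every record — per-domain correct
counts. On the bundled panel with the anchor models (spectrophotometric
Cys-only vs DPRA mean): 79/78 correct, 65 jointly; FP 5/9 with 3 shared;
FN 22/19 with 11 shared; no-alert chemicals 28/35 vs 23/35; acyl transfers
6/9 vs 9/9.

## Synthetic data generators

**Plate simulator.** Inverts the depletion equation: for true depletion d,
the expected test-chemical well signal is `C + (1 − d/100)(A − B)`; i.i.d.
Gaussian noise of configurable SD is added to every well *on the signal
scale* (the instrument measures absorbance/fluorescence; depletion-scale
noise follows by propagation), clipped at zero since signals are
non-negative. Defaults emulate an Ellman's-type absorbance assay: A = 2.0,
B = 0.2, per-substance C uniform in [0.2, 0.4], two replicate wells, three
runs, NC/PC behaving like lactic acid (0.5%) and DNFB (90%). With zero
noise the pipeline recovers targets to < 1e−9 (floating-point only).

**Population simulator.** Labeled scores from two normals clamped to
[0, 100]; defaults, chosen as a well-separated but overlapping pair typical
of reactive vs unreactive chemicals, are 200 sensitizers ~ N(60, 15) vs 200
non-sensitizers ~ N(5, 5). Clamping relocates out-of-range mass to the
endpoints without changing any exceedance probability over thresholds
inside (0, 100), so the population-optimal Youden threshold equals the
closed-form intersection of the two unclamped densities (20.20 for the
defaults) whenever that lies in (0, 100); `analytic_youden_threshold`
computes it and the tests use an independent numeric root-finder as oracle.
Empirical threshold recovery is consistent but slow (the J(t) surface is
flat near its maximum — cube-root asymptotics), so tests assert shrinking
mean error across n ∈ {50, 200, 1000} and exact tie-interval membership in
the separated point-mass case, rather than convergence to a point.

What the generators do *not* emulate: chemical color/interference beyond
the C control, well-position or plate effects, heteroscedastic reader
noise, and non-normal depletion distributions. Green tests on synthetic
data therefore demonstrate correctness of the computational pipeline, not
assay performance on real chemistry — the bundled measured panel covers the
latter end of the argument.

## Numerical choices and limitations

* Half-up rounding only at the reporting boundary; all internal arithmetic
  is double precision.
* Sentinel ROC thresholds sit one unit outside the score range; candidate
  midpoints are exact float midpoints.
* Plate CSV interchange uses a long format
  (`run_id,peptide,role,substance_id,replicate,signal`) with the special
  substance ids `NC`/`PC` attaching interference controls to the run
  controls; a missing control-specific C falls back to the blank B.
* The package does no structure-based reasoning (no SMILES/InChI), no
  potency sub-categorization (hazard is binary), and no statistical tests
  on metric differences or concordance (none are defined for this
  analysis).
* `pandas` would read the literal domain label "None" as missing; all
  loaders disable default NA parsing and handle empty cells explicitly.
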