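# Methods

This note documents the models, numerical choices and known limitations of
`crmscan`, in the order the pipeline runs them.

## Markov backgrounds

A background of order *m* stores k-mer counts for k = 1…m+1, tallied over
the unmasked (uppercase A/C/G/T) portions of the training sequences on both
strands, so the model is strand-symmetric. Conditional probabilities are
maximum-likelihood count ratios; the first *m* positions of a window, where
the left context is short, are scored with the marginal lower-order tables,
which are always trained alongside. A (context, base) pair never observed
in training receives the add-one floor 1/(total+4) so log-odds scores stay
finite; observed contexts keep exact MLE conditionals (which sum to 1).
Training on the pooled input sequences themselves is the default for
classification scans, making a run self-contained; an external sample can
be supplied instead.

## PWM and consensus scanning

PWM probabilities use a symmetric pseudocount (default 0.5) over the site
counts. Log-odds scores are **natural log**; the conventional hit
thresholds in this package (4.6 for density features, 4.5 for positional
profiles) are interpreted on that scale. The base is configurable in the
sense that the score is a plain sum of ln-ratios — rescale thresholds
accordingly if you think in bits. Every window strictly above threshold is
a hit; overlapping and palindromic double matches are all kept (no
deduplication), both strands are scanned by default, and windows containing
N are skipped — a masked position can therefore never sit inside a hit once
a `to_N` mask policy is applied, while the default `keep` policy scans
lowercase letters as ordinary bases. The threshold applies per strand, not
to the best of both strands. Hit densities are count × 1000 / region
length.

## K-mer enrichment

Within one set, each observed k-mer (canonicalized with its reverse
complement when both strands are counted) is tested by the binomial upper
tail of its overlapping count against n_windows × P(k-mer) under the
background chain; k = 6 by default, background order 3. Between two sets,
the A-count of each k-mer is tested against Binomial(c_A + c_B,
w_A/(w_A+w_B)) one-sided — an exact two-sample binomial on window-
normalized counts. Multiple testing is Bonferroni over the canonical k-mer
space by default (2080 hypotheses for k = 6), Benjamini–Hochberg by flag.
These are deliberately simple analogs of oligonucleotide-analysis tools;
the contract on clear planted signals is rank agreement, not p-value
equality with any particular external implementation. Masked and N
positions break words on both the counting and the window-total side, so
counts always sum to the number of scannable windows.

## Positional profiles

Hit position is the midpoint of the matched window (the convention is a
package choice; "position" alone does not fix it). Fractions are clipped to
[0,1] and binned into twenty half-open 5% bins, the last closed at 1.0.
Scaled density divides each bin count by N/20, so the scaled profile
averages exactly 1 and a uniform distribution is the flat line at 1. The
bin count is fixed at 20 to keep profiles comparable across runs.
Smoothing is loess — local quadratic regression with tricube weights —
applied to the *scaled* bin values with span 0.75 by default (the span is a
knob and is recorded in the profile object). Loess is implemented in-house
because the local-regression routine available in the installed stack is
degree-1 only; the test suite checks it against an independent
normal-equations weighted-least-squares oracle at 1e-9. The flatness
control scans background peaks with an unrelated PWM and checks that
|scaled − 1| stays within 3 binomial standard errors in at least 18 of 20
bins; a scan with no hits returns an empty-profile signal rather than a
degenerate profile.

## Bolasso classification

Features are per-kb hit densities, standardized to zero mean and unit
**population** variance over the whole dataset; constant columns are
dropped with a warning and the column means/SDs retained for scoring new
sequences. The model is L1-penalized least squares against ±1 targets with
an unpenalized intercept (fit by centering). A logistic-loss variant was
considered and not implemented: the regression formulation matches the
coefficient semantics the final model reports.

The penalty is chosen **once**, on the full dataset, by stratified 5-fold
CV minimizing squared error, averaged over 5 independent fold splits, and
is then shared across all bootstrap fits — the original bolasso
formulation. Re-tuning inside every resample is available behind a flag but
is noisier: bootstrap duplicates leak across the inner CV folds and bias
the penalty low, which inflates noise-motif selection frequencies (measured
at 0.6–0.8 on pure-null data versus 0.3–0.5 with the shared penalty). The
averaged CV curve matters for the same reason: with a single 5-fold split
on ~60 rows the curve's minimum often lands at a spuriously small penalty.
If the CV-optimal model has more than 50 non-zero coefficients (a cap
guarding against overfitting on small studies) the penalty is increased
along the path until the cap holds. Bootstrap resamples are full-size,
with replacement, unstratified; resamples containing a single class are
redrawn and counted.

The final panel keeps motifs with selection frequency at or above a
confidence threshold found by greedy descent: start at 95%, drop in 5%
steps, refit the panel by ordinary least squares, score by leave-one-out
AUC, and stop at the first non-improvement. Thresholds at which the panel
does not change are skipped, since their AUC is identical by construction.

**LOOCV AUC.** Each decision value comes from an OLS refit without that
row; pooled values are centered by the training fold's label mean before
the Mann–Whitney AUC (ties count half). Without centering, the intercept of
each fold equals the training label mean, which moves *opposite* to the
held-out label and biases the permutation-null AUC down to ~0.33–0.45 — a
known artifact of pooling leave-one-out scores. Centering removes exactly
that label-dependent term; a residual O(p/n) bias from slope overfitting
remains (null mean ≈ 0.47 for a 3-feature panel at n = 61), so
permutation-based calibration should still accompany any small-study AUC.

## Synthetic studies

The default study has 24 positive and 37 negative sequences of 500–1500 bp,
drawn from an order-2 Markov background trained on a 200 kb synthetic
reference with 43% GC (fly-like composition, order-0 source chain — the
reference provides realistic k-mer statistics, not genome structure). The
CEE consensus is planted at 2.86/kb (positive class) versus 1.52/kb
(negative), and 30 random non-degenerate noise 6-mers (excluding the CEE
words, AGATAC, and their reverse complements) are planted at 0.5/kb in both
classes so feature selection faces a realistic null pool. Planted counts
are Poisson — densities are expectations, as in real sequence — with an
exact-count mode for deterministic fixtures. Positions are uniform, or
Beta(5,5) in relative coordinates for center-biased positional controls.
Planting is non-overlapping across all motifs of a sequence, and a truth
table records every instance.

Two features of real data the generator does **not** emulate: measured
densities include background matches of the planted pattern (~1/kb for a
two-word 6-mer scanned on both strands under this background), sitting on
top of the planted rate in both classes; and real enhancer classes have
overdispersed, multi-motif signal, whereas here a single motif carries all
the class contrast with Poisson counting noise. Consequently the
single-feature class separation is capped near AUC ≈ 0.75 in expectation at
these densities and lengths, and per-seed results fluctuate (AUC 0.70–0.94,
CEE confidence 0.3–1.0 over the first ten seeds). Passing tests therefore
demonstrate correct mechanics and honest statistical behavior at the
planted effect size — not that any fixed AUC is reachable on real data.

The gene-landscape generator lays out two-exon genes with wide intergenic
gaps (so every planted peak's category and nearest gene are unambiguous by
construction), annotates a CDS start 300 bp into the 5′ exon (giving each
gene a 5′UTR), and plants peaks cycling through the five categories with
triangular signal contours; peak area is the trapezoidal integral of the
contour.

## Annotation conventions

Distances are measured from the peak summit. The intronic rule (assign to
the nested gene with the nearest TSS) takes precedence over the
nearest-boundary rule; equidistant boundaries tie-break toward a TSS
boundary, then the smaller gene id. When several genes nest the same
intronic summit, the nearest TSS among the containing genes wins — a
declared convention, since nesting is ambiguous in general. 5′UTR calls
require an annotated CDS start; without one the category collapses to
exon, and the precedence order (exon > 5′UTR > promoter > intron >
intergenic) is itself a declared convention. Term enrichment is a flat
hypergeometric upper tail with BH-FDR — a deliberate simplification that
ignores ontology topology; term sizes are restricted to the supplied
universe.

## Problem sizes

The test suite and `scripts/acceptance.py` run the study at its native size
(61 sequences, 31 motifs) with 200 bootstrap resamples per bolasso run and
200 label permutations for the null calibration; k-mer recovery uses 50 ×
1 kb sequences per replicate, positional controls 300–1000 × 800 bp peaks,
and the annotation sweep 500 peaks over 20 genes. The full 1000-resample
bolasso changes selection frequencies by at most a few percent (the
binomial standard error at 200 resamples is ≤ 3.5 points) and is available
everywhere through `n_bootstrap`.
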