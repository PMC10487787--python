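# Methods

## Relative quantification model

Each qPCR measurement is a threshold cycle Ct; one cycle difference
corresponds to a factor of 2 in template under perfect amplification
efficiency. For genes g, h in tumour (T) and control (C) samples the
pairwise relative copy number is

    ΔΔCt(g,h) = (Ct_g,T − Ct_h,T) − (Ct_g,C − Ct_h,C)
    R(g,h)    = E^(−ΔΔCt),   E = 2.0 by default

Replicates are collapsed to an arithmetic mean Ct before pairing; the
per-gene summary (mean, sample SD with n−1 denominator) is taken over the
gene's ratios against every other usable panel gene. Per-replicate ratio
distributions are deliberately not propagated: the scoring rule below acts
on point estimates, and replicate-level scoring is not identifiable from
the published design. An optional per-run efficiency E ≠ 2 is supported
but off by default.

Structural consequences, all enforced by tests:

* reciprocity R(g,h)·R(h,g) = 1 and R(g,g) = 1;
* invariance to per-sample template-dose offsets (they cancel inside each
  ΔCt), so preamplification and loading differences do not bias calls;
* blindness to balanced changes: an alteration shared by every panel gene
  is invisible to purely relative quantification (a known limitation).

## Scoring and calling

A ratio scores 0 inside the closed equivalence band
[lower, upper] = [0.80, 1.25], −1 below, +1 above. The band is the
conventional ±25% copy-number equivalence range; keeping
upper = 1/lower makes score(g,h) = −score(h,g), so the panel's score sums
cancel to zero — a useful internal consistency check. Band boundaries are
inclusive (a ratio of exactly 0.80 scores 0).

Per gene, scores are summed over all partners of *different* genes
(allele-discriminating assays of the same gene never score each other).
With threshold 5 on a 10-gene panel (9 comparisons), a sum ≤ −5 calls a
deletion and ≥ +5 a multiplication; the threshold is a majority-of-partners
rule and is kept fixed, with a warning suggesting rescaling when fewer
than 10 genes are usable. Threshold raising is monotone: it can only
retract calls, never create them.

## Reference validation and absolute copy number

Candidate reference genes (ALB, B2M, BCKDHA, CD36, F5, MPO, TBP, RPPH1 —
different chromosomes, nominally diploid) are scored exactly like targets
in a single pass; any flagged candidate is rejected for that pair. Target
CYP assays are never used as references. At least `min_reference_genes`
(default 3) must survive, otherwise the pair is reported uncallable.

The absolute copy number of gene g is

    CN(g) = ploidy_control × mean{ R(g, r) : r validated reference, r ≠ g }

with ploidy_control = 2; a reference gene never normalizes itself.
Averaging over validated references only (not all nine partners) matters:
flagged genes would otherwise drag the mean.

### Tumour-fraction interpretation

Tumours are heterogeneous, so CN is a population average. Under a
single-copy-event model — a fraction φ of tumour cells carrying exactly
one copy gained or lost, the rest diploid —

    CN = 2 − φ  (loss)    or    CN = 2 + φ  (gain)

so φ = |CN − 2| whenever 1 ≤ CN ≤ 3. CN = 1.6 ⇒ 40% of cells with a
one-copy loss. Outside [1, 3] more than one copy per cell must have
changed and the fraction is omitted. A no-call band |CN − 2| < 0.1
(configurable) suppresses spurious sub-10% fractions arising from noise.

## Functional-gain classification and association

A tumour counts as carrying a *functional* CYP multiplication when the
extra copies should raise paclitaxel-metabolizing capacity:

* **CYP2C8** — in \*1/\*1 patients any CYP2C8 multiplication counts; in
  \*1/\*3 heterozygotes the multiplication must be established on the
  allele-discriminating \*1 assay (multiplying the reduced-activity \*3
  allele does not raise activity). A heterozygote whose total CYP2C8 is
  multiplied without \*1-assay support is classified negative and a
  warning is logged — the attribution is genuinely ambiguous.
* **CYP3A4** — \*1 and \*1B both encode functional enzyme, so any CYP3A4
  multiplication counts.

Association with therapy response (responder / non-responder) uses
Fisher's exact test on the 2×2 table, two-sided by the point-probability
rule (sum of hypergeometric probabilities ≤ that of the observed table,
margins fixed), computed via `scipy.stats.fisher_exact` and cross-checked
in the tests against an independent enumeration oracle. Concordance
between qPCR and sequencing copy numbers is an ordinary least-squares fit
with free intercept (`--through-origin` available), r² the squared Pearson
correlation.

Allele/genotype percentages are reported to one decimal; values are
carried at two decimals and then reduced to one with halves rounded up at
each stage, the way spreadsheet displays round. (With two-category rows of
N = 17 this two-stage path yields e.g. 17.65 → 17.7 for 3/17; a one-stage
nearest rule would give 17.6.)

## Synthetic-data generator

The generator inverts the measurement model. A tumour is a mixture of a
fraction f of tumour cells with configured copy numbers CN_g and 1 − f
diploid stromal cells:

    m_g(T) = f·CN_g + (1 − f)·2,    m_g(C) = 2
    Ct     = B_g + dose − log2(m_g / 2) + ε,   ε ~ N(0, σ²)

Defaults: per-assay baselines B_g are a fixed documented list (22.7–26.4
cycles, typical of post-preamplification genomic DNA), 2 replicates,
σ = 0 unless stated, dose offsets 0, seeds explicit everywhere. Noise is
Gaussian on the cycle scale because Ct is the measured quantity;
template-scale noise is then lognormal. Zero effective template emits a
missing Ct (no amplification). Correlated multi-gene events (e.g. an
arm-level 1q gain carrying F5) set one copy number jointly on a gene set.

What the generator does *not* emulate: amplification-efficiency drift
between assays, inter-chip calibration error, probe cross-reactivity,
stromal copy-number changes, and subclone structure beyond a single
two-population mixture. Passing recovery tests therefore demonstrate the
estimator's correctness under the stated model, not robustness to every
instrument artefact.

The recovery experiment simulates n patient pairs, runs the full caller,
and reports per-gene bias and RMSE of recovered vs true population-average
copy number plus call sensitivity/specificity; pairs failing reference
validation at high noise are counted as uncallable rather than aborting.
Test problem sizes (12–50 simulated pairs, σ ∈ {0.3, 0.1, 0.03}) keep the
suite fast while leaving Monte-Carlo error well inside the asserted
tolerances.

## Numerical and degenerate-input choices

* Missing Ct is never imputed; a gene with no usable replicate in either
  sample of a pair is dropped from that pair's panel (logged), shrinking
  the score denominator.
* No Ct cut-off by default; `max_ct` optionally censors late amplification.
* Band comparisons are plain floating-point `<`/`>` on the closed band;
  sums of ±1 integers are exact.
* Sample SD uses ddof = 1 and is defined as 0 for a single partner.
* A 2×2 table with a zero margin has a single attainable configuration:
  p = 1 and the odds ratio is reported as NaN.
* Constant predictors raise a degenerate-fit error rather than returning
  an unstable slope.

## Known limitations

* Relative quantification cannot detect balanced panel-wide changes or
  genome duplications that scale every gene equally.
* The ±5 score threshold is calibrated to a 10-gene panel; smaller usable
  panels make the rule conservative (warning emitted, not auto-rescaled).
* The tumour-fraction model assumes one event state per tumour; mixtures
  of gains and losses of the same gene in different subclones are
  averaged away.
* Score antisymmetry holds for point-estimate scoring with a reciprocal
  band; published per-site score sums need not cancel exactly if scoring
  was performed at replicate or confidence-interval granularity.
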