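# Methods

## The classification cascade

Endometrial carcinomas are assigned one of four molecular subtypes by a
strict-precedence hierarchy: POLE, then MSI, then CN-high, with CN-low as the
residual class. Every sample receives exactly one label.

**POLE stage.** The POLE-ultramutated phenotype is detected from the somatic
substitution spectrum alone. Substitutions are collapsed onto the six
pyrimidine-centric classes (C>A, C>G, C>T, T>A, T>C, T>G); a purine-reference
call is reverse-complemented, so both strand representations of one somatic
event count in the same class. A sample is POLE when

* total somatic SNVs > 500,
* C>A class fraction > 0.2,
* C>G class fraction < 0.03,

with all three inequalities strict. The C>A/C>G fractions are taken over all
collapsed somatic SNVs — the rule's source leaves the denominator implicit,
and the share-of-all-SNVs reading matches how the POLE spectrum criterion is
used for these tumors elsewhere. Indels and multi-nucleotide substitutions
never enter the spectrum. A zero-SNV sample has both rates defined as 0 and
can never be POLE (it already fails the burden gate). POLE takes precedence
over MSI: roughly a third of POLE tumors are also MSI-high, and they stay
POLE.

**MSI stage.** Remaining samples that are MSI-high are MSI. Status may be
categorical (MSI-high vs MSS/MSI-low) or a numeric score in [0, 1], in which
case the gate is score ≥ 0.5; the tie goes to MSI-high because a single
documented convention is preferable to an undefined boundary. A non-POLE
sample with unknown MSI status is an error rather than a silent CN-low — the
cascade's semantics depend on the gate being evaluable.

**CN stage.** The residue is split by a supervised model of TCGA somatic
copy-number cluster 4 membership (cluster 4 ≙ CN-high; clusters 1–3 ≙ other).
A Gaussian naïve Bayes posterior ≥ 0.5 yields CN-high, else CN-low. The 0.5
cutoff is the canonical NB decision rule and is configurable. By default the
posterior is only computed for samples that reach this stage; a
`full_evidence` switch computes it for every sample for audit purposes.

## Copy-number features

Input is a per-sample segment profile (1-based inclusive intervals, absolute
total copy number) plus a ploidy. A segment is a **gain** when
copy number ≥ ploidy + 0.5 and a **loss** when ≤ ploidy − 0.5. The margins are
relative to sample ploidy so that a whole-genome-duplicated tumor is not
called altered everywhere, which would make the ploidy feature redundant. The
feature vector, in fixed order, is:

| block | count | notes |
|---|---|---|
| gains, losses per sample | 2 | segment counts |
| gains, losses per chromosome | 46 | fixed universe chr1–22, X (no Y: EC is a female malignancy) |
| gains, losses per selected gene | 2k (k ≤ 25) | ≥1 bp overlap of an altered segment |
| ploidy | 1 | passed through |
| altered length per megabase | 1 | altered bases / (3100 Mb) |

The k = 25 "most abundant" genes are those most frequently overlapped by an
altered segment across **training** samples, ties broken by genomic order.
Selection is a fitted quantity: it is re-run inside every cross-validation
training fold, and a held-out sample can never influence the gene list. When
fewer than k genes are ever altered the list truncates.

Segment counts (not base-pair-weighted counts) are used for the gain/loss
features; "length of alterations per megabase" is the per-sample density of
altered bases over a fixed 3100 Mb genome, the only per-sample scalar
consistent with the rest of the feature list.

## The Gaussian naïve Bayes model

Written from scratch in the scikit-learn estimator idiom. Priors are class
frequencies; per class and feature the likelihood is a normal with the biased
sample variance, floored at `1e-9 ×` the largest overall feature variance so
constant features contribute a proper (if sharply peaked) density — flooring
rather than additive smoothing keeps non-degenerate variances untouched.
Posteriors are computed in log space and normalized with log-sum-exp; tests
verify agreement with a direct density-product computation to 1e-10 relative
error. Count features and continuous features share the single Gaussian
likelihood: the features are mutually correlated and counts are not Gaussian,
but this is exactly the model configuration being reproduced, and its CV
performance is measured rather than assumed.

Cross-validation is stratified k-fold (default 5) with a fixed, overridable
shuffle seed (default 13). Reported metrics are accuracy, precision, recall,
F1 and ROC-AUC per fold; the headline averages are **unweighted fold means**,
with pooled out-of-fold metrics also reported because the averaging
convention materially changes the numbers on imbalanced data.

## Evaluation statistics

* **Confusion matrix** with a fixed class order (POLE, MSI, CN-low, CN-high);
  per-class precision/recall/F1 with the zero-denominator convention
  precision = F1 = 0 for an empty predicted column, keeping averages defined.
* **Macro and weighted averages** over reference-class sizes; weighted recall
  over a complete matrix equals accuracy (identity-tested).
* **Chi-square homogeneity** of two class-count vectors: Pearson statistic on
  the 2×k table without continuity correction, df = k−1.
* **Kaplan–Meier** product-limit curves (via lifelines) with right censoring;
  "survival at t" is the step value at the largest event time ≤ t, the
  standard convention for 36-month rates. Table-style row percentages round
  half-up to whole percents.
* **Log-rank**: the omnibus k-group test (df = k−1); with four subtype curves
  and one inserted p-value this is the appropriate reading of a
  "multivariable" log-rank comparison. Two-group results are verified against
  a brute-force observed-minus-expected computation to 1e-10.

## Synthetic cohort generator

The generator produces, per sample: a subtype label, a variant set, a segment
profile with ploidy, MSI status, a CN cluster (4 iff CN-high), and follow-up.
Defaults are fixed at the study conditions: n = 232, subtype mix
7% / 28% / 39% / 26% (POLE/MSI/CN-low/CN-high); the companion CN training set
uses n = 240 with exact apportionment (62/240 ≈ 26% cluster-4 positives).

* **SNV burden** is log-normal per subtype (POLE log-mean ln 3000, MSI
  ln 1200, CN-low ln 60, CN-high ln 90) — the simplest heavy-tailed form for
  an ultramutator phenotype. POLE spectra use C>A 0.30 / C>G 0.01, so the
  POLE rule fires with probability > 0.99; other subtypes get ordinary
  C>T-dominated spectra that cannot fire it.
* **Copy number**: each chromosome (rounded real female-genome lengths,
  ≈ 3029 Mb total) is tiled by 1 + Poisson segments; each segment is altered
  with probability 0.45 (CN-high) or 0.03–0.05 (others), half gains and half
  losses, with ploidy ≈ 3.2 ± 0.3 for CN-high and 2.0 otherwise. CN-high
  altered-genome fraction is therefore ≈ 10× CN-low.
* **MSI-high probability**: 0.97 for MSI, 0.35 for POLE, 0.02 otherwise.
* **Survival**: exponential event times with monthly hazards back-solved from
  36-month survival targets via S(t) = e^(−ht) — POLE 0 (S₃₆ = 1.00), CN-low
  0.00387 (0.87), MSI 0.00585 (0.81), CN-high 0.01419 (0.60) — and
  independent exponential censoring at hazard 0.008 (median follow-up
  ≈ 87 months).

A single master seed (default 7) fans out to per-stage substreams
(labels, genes, variants, copy number, MSI/cluster, survival), so each stage
is reproducible in isolation.

What the generator does **not** emulate: trinucleotide-context signatures,
recurrent focal amplicons or real gene positions, correlated censoring, or
the messiness of real variant calling (the subtypes are generated
well-separated). Passing the end-to-end recovery tests therefore shows the
cascade is implemented correctly and is recoverable under its own model
assumptions — it is not a claim about accuracy on real tumors.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere internally; BED converts on
  read, VCF/SEG positions load unchanged; leading `chr` is stripped.
* Multi-allelic VCF records split into one record per alt allele; duplicate
  (chrom, pos, ref, alt) entries collapse on load; non-PASS records are
  excluded when the dialect carries a filter column.
* SEG input carries absolute copy number by default; a `--seg-log2` switch
  converts log2 ratios via `ploidy × 2^value`. Missing ploidy defaults
  to 2.0.
* Problem sizes in tests and the acceptance script are the study's own
  (n = 232 cohort, n = 240 CV training set); smaller cohorts elsewhere in the
  suite exist purely to exercise code paths.
* The published overall comparison metrics that depend on an unstated
  averaging convention are not asserted anywhere; only quantities exactly
  recomputable from the published matrix are (accuracy 206/232, macro recall
  from the printed cells, row/column percentages, the chi-square p-value).

## Known limitations

* The upstream "standard filtering criteria" of the original variant-calling
  pipeline are proprietary; variant and MSI calls are assumed pre-filtered
  inputs.
* The gain/loss call rule (±0.5 around ploidy) is a package convention — the
  source never defines one — so absolute feature values depend on it even
  though the model is refit to whatever rule is configured.
* Gaussian NB on correlated count features is a deliberately reproduced
  modeling simplification, not a recommendation.
* No secondary rule is applied near the 0.5 CN posterior boundary.
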