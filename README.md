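# ecsubtypes

Whole-exome determination of the four TCGA molecular subtypes of endometrial
carcinoma — **POLE** (ultramutated), **MSI** (microsatellite-unstable),
**CN-low** and **CN-high** (copy-number-driven, serous-like) — from a single
sequencing experiment, for bioinformaticians and translational researchers who
have somatic variant calls, copy-number segments and MSI status but not the
multi-platform data (methylation, mRNA, RPPA) the original TCGA classification
required.

## Method

Samples are assigned hierarchically:

1. **POLE rule.** A sample with more than 500 somatic SNVs, a C>A fraction
   above 0.2 and a C>G fraction below 0.03 (all strict; substitutions
   collapsed to the six pyrimidine-centric classes) is POLE. This is the
   characteristic mutation spectrum of polymerase-ε exonuclease-domain
   mutants, and it takes precedence over everything else.
2. **MSI gate.** Of the remainder, MSI-high samples (categorical status, or a
   score ≥ 0.5) are MSI.
3. **CN stage.** The rest are CN-high when a Gaussian naïve Bayes classifier
   puts their posterior probability of belonging to TCGA somatic copy-number
   cluster 4 at ≥ 0.5, and CN-low otherwise. The NB features are: gains and
   losses per sample, per chromosome (chr1–22, X) and per gene for the 25 most
   frequently altered genes (selected on training data only), plus ploidy and
   total altered length per genome megabase. Gains and losses are called
   relative to sample ploidy with ±0.5 margins.

The evaluation layer reproduces the full comparison protocol: four-class
confusion matrix, per-class and macro/weighted-averaged precision, recall and
F1, a chi-square test of homogeneity between class distributions,
Kaplan–Meier survival curves with 36-month rates, and omnibus (k-group)
log-rank tests. A synthetic cohort generator emulates subtype-specific
mutation burdens and spectra, MSI status, copy-number load, ploidy and
survival, so the entire pipeline is testable without any protected data.

The classifiers follow the scikit-learn estimator idiom
(`fit`/`predict`/`transform`, `get_params`), so the copy-number feature
extractor and the NB model compose with sklearn pipelines and model selection.

## Worked example

```python
import numpy as np
import ecsubtypes as ec

cohort = ec.simulate_cohort()  # n=232, seed 7, 7/28/39/26% subtype mix
sids = sorted(cohort.profiles)
cluster4 = np.array([1 if cohort.clinical[s].cn_cluster == 4 else 0 for s in sids])

clf = ec.SubtypeCascadeClassifier(gene_model=cohort.gene_model)
clf.fit([cohort.profiles[s] for s in sids], cluster4)
calls = clf.classify_cohort(cohort.variants, cohort.clinical, cohort.profiles)

ev = ec.evaluate_cohort(calls, cohort.clinical)
print(ev.confusion.counts)
print(f"accuracy: {ev.metrics.accuracy:.4f}")
print(f"chi-square p: {ev.chi_square.p_value:.4f}")
print(f"log-rank p (predicted subtypes): {ev.logrank['predicted'].p_value:.2e}")
```

prints

```
[[23  0  0  0]
 [ 0 47  2  0]
 [ 0  1 91  1]
 [ 0  1  0 66]]
accuracy: 0.9784
chi-square p: 1.0000
log-rank p (predicted subtypes): 7.27e-15
```

The confusion matrix (rows = generating labels, columns = cascade calls) shows
the cascade recovering 97.8% of the synthetic truth; the chi-square p-value
near 1 says the predicted class distribution is indistinguishable from the
generating one; the tiny log-rank p-value confirms the four predicted groups
have strongly separated survival, with POLE best (36-month survival 1.00) and
CN-high worst.

The same pipeline runs from the shell:

```sh
ecsub simulate --n 232 --seed 7 --out cohort/
ecsub classify --variants cohort/variants --seg cohort/segments.seg \
    --clinical cohort/clinical.tsv --genes cohort/genes.bed \
    --model model.json --out calls.tsv
ecsub evaluate --calls calls.tsv --reference cohort/clinical.tsv --out report/
```

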