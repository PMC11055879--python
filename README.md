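# crisparray

Analysis and design tools for multiplex CRISPR knockout screens, built
around Cas12a guide arrays that knock out one to four (or, experimentally,
seven) genes from a single construct.

Paralogs — duplicated genes with overlapping function — buffer each other's
loss, so single-gene knockout screens systematically miss them. Multiplex
screens knock out gene pairs and families directly and ask whether the
combined phenotype is worse than expected. `crisparray` implements the full
computational path for such screens, for analysts reprocessing published
paralog screens and for groups designing and analyzing their own array
libraries:

- **Counting and normalization** — exact-match counting of array amplicon
  reads, pseudocount + depth scaling, log2 fold change against a
  plasmid/T0 reference, and per-group mode-centering of construct classes.
- **Genetic-interaction scoring** — single mutant fitness (SMF), the
  multiplicative null, delta log fold change and a modified Cohen's D, with
  dual-threshold hit calling.
- **Cross-study meta-analysis** — Jaccard-based platform replicability
  weights, weighted paralog scores, and gold-standard synthetic-lethal
  selection, plus recall of any screen against a gold set.
- **Array null model** — enumeration of essential/non-essential guide-array
  pools, the binary-design-matrix regression that validates additive
  (log-multiplicative) fitness, and per-position guide-efficacy
  diagnostics.
- **Library design** — paralog pair/family selection from sequence-identity
  and expression tables, four-guide array construction, and byte-exact
  synthesis-oligo assembly.
- **Gene-level screen analysis** — fold-change aggregation, essential
  calling, precision-recall QC, and family GI classification including the
  dynamic-range "untestable" rule.
- **Synthetic data** — seeded generators that reproduce the statistical
  structure of all of the above, so the pipeline is testable end to end
  with no downloads.

## The model

For a pair (g1, g2), single mutant fitness is the mean log2 fold change of
constructs pairing each gene with a control guide. Under the multiplicative
null, fitness effects add in log space:

    expected_mean = mu_1 + mu_2
    expected_std  = sqrt(std_1^2 + std_2^2)

The interaction magnitude is the deviation of the observed double-knockout
constructs from that expectation,

    dLFC = observed_mean - expected_mean

and its standardized effect size is a modified Cohen's D,

    S_pooled = sqrt(expected_std^2 + observed_std^2) / 2
    D        = (expected_mean - observed_mean) / S_pooled

(the divisor-outside-the-radical form is the default; the classical pooled
form, exactly sqrt(2) smaller in D, is available via
`pooled_sd_convention="classical"`). A pair is a synthetic-lethal hit when
`dLFC < -1` and `D > 0.8`, both strict.

Across studies, each study's platform weight is the median Jaccard
coefficient of hit sets between its cell-line screens, a pair's paralog
score is the weighted sum of its hits minus the weighted sum of its misses,
and gold-standard candidates have score > 0.25 with hits in more than one
study.

For multi-guide arrays, the additive null is the regression `y ~ A beta`
with A the arrays-by-positions binary matrix of essential guides, fit on
arrays carrying at most two essentials.

## Worked example

Score a simulated screen with two planted synthetic-lethal pairs:

```python
from crisparray.synthetic_data import ScreenSimConfig, simulate_screen
from crisparray.normalization import NormalizationConfig, counts_to_fold_changes
from crisparray.gi_scoring import score_screen, records_to_frame

planted = ((("G050", "G100"), -2.0), (("G051", "G101"), -2.0))
cfg = ScreenSimConfig(sl_pairs=planted, seed=7)
counts, truth = simulate_screen(cfg)
fc, offsets = counts_to_fold_changes(counts, NormalizationConfig())
records, _ = score_screen(fc, control_labels={"CTRL"})
df = records_to_frame(records)
print(f"{len(df)} pairs scored, {df['hit'].sum()} hits")
print(df[df["hit"]].round(2).to_string(index=False))
```

prints

```
150 pairs scored, 2 hits
gene1 gene2  smf1  smf2  observed_lfc  expected_lfc  dlfc  cohens_d
 G050  G100  0.04  0.10         -1.98          0.14 -2.11      6.20
 G051  G101  0.01 -0.05         -2.28         -0.04 -2.24      5.89
```

Both planted pairs — and only they — are recovered: each gene is fit on its
own (SMF near 0), the observed double knockout is ~2 log2 units below the
additive expectation (dLFC ≈ −2, the planted effect), and the separation
between expected and observed construct distributions is large (D ≈ 6).

The same steps are available from the shell:

```
crisparray simulate --seed 7 --out sim/
crisparray normalize --counts sim/counts.tsv --manifest sim/manifest.tsv --out fc.tsv
crisparray score-gi --fc fc.tsv --controls CTRL --out gi.tsv
```

plus `count-reads`, `meta`, `fit-array-model`, `design-library`,
`assemble-oligos`, `qc` and `classify-gi` for the other stages.

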