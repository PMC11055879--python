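# Methods

This note documents the statistical procedures `crisparray` implements, the
choices made where the procedures are underdetermined, what the synthetic
data does and does not emulate, and the problem sizes used by the test
suite and the acceptance script.

## Counts to fold changes

Raw construct × sample read counts are processed per sample: a pseudocount
(default 5 reads) is added to every construct, then counts are scaled so
that the mean normalized reads per construct equals a target depth (default
500; equivalently total = 500·K for K constructs). Log2 fold change is
computed per endpoint replicate against the reference; multiple reference
samples (e.g. two T0s) are averaged in normalized-read space before the
ratio. The pseudocount bounds the fold change of dropout constructs and
the depth scaling removes sequencing-depth differences; log2 fold change is
invariant to any global rescaling of a sample's counts.

**Group mode-centering.** Constructs fall into classes — single-gene
constructs with the control guide in the first slot (N_gene), in the second
slot (gene_N), and two-gene constructs (A_B) — whose fold-change
distributions drift differently (they carry different numbers of cutting
guides, and depth scaling shifts all constructs when essentials drop out).
Each class is therefore shifted additively so its modal LFC is zero: the
mode is where the mass of no-phenotype constructs sits. Two alternative
schemes subtract the mode of designated control constructs from every
value instead (used for library layouts with a single singleton
orientation, or where a dedicated negative-control set anchors the scale);
those schemes also support dropping designated gene families before any
computation (for families whose internal homology produces cross-reactive
guides).

- *Mode estimator*: Gaussian KDE with Silverman bandwidth evaluated on a
  512-point grid over the group's range; the mode is the argmax, ties
  broken toward the value nearest zero. Measured on N(0, 0.3) samples of
  n = 5000, the estimator's RMSE is ≈ 0.03, and a single draw exceeds
  0.05 absolute error ~14% of the time — recovery claims are therefore
  stated on the RMS error across draws, not on every draw.
- *Shift, not scale*: "setting the mode to zero" is implemented as
  subtraction; a multiplicative rescaling cannot in general zero a nonzero
  mode and would distort fold-change differences.
- *Order of operations*: pseudocount → depth scaling → per-replicate LFC →
  group centering → replicate averaging. Centering before averaging keeps
  replicate columns on a common scale; with per-sample shifts this
  ordering commutes with averaging up to estimator noise.
- Missing replicate values are skipped in means and the retained count is
  recorded; nothing is imputed.

## Genetic-interaction scoring

Single mutant fitness (SMF) of gene g is the mean LFC of constructs pairing
g with a control label, pooling both slot orientations; the standard
deviation uses the n−1 (sample) convention. The multiplicative null for a
pair adds means and adds variances. The interaction magnitude is
dLFC = observed − expected over all constructs targeting the pair, and the
standardized separation is a modified Cohen's D with

    S_pooled = sqrt(e_std² + o_std²) / 2        ("as_printed", default)
    S_pooled = sqrt((e_std² + o_std²) / 2)      ("classical")

The two conventions differ by exactly √2 in D. The default follows the
divisor-outside-the-radical form; the classical pooled form is exposed
behind `pooled_sd_convention` since the printed form is plausibly a
typesetting of it. Hits require dLFC < −1 **and** D > 0.8, both strict:
boundary values are misses. Pairs whose SMFs or pair constructs are
missing are *unassayed*, a distinct state from a miss.

## Meta-analysis

Each screen (study × cell line) contributes a hit set and an assayed set.
Within a study, the Jaccard coefficient |A∩B|/|A∪B| is computed for every
unordered pair of cell lines, and the study's platform weight is the median
of these (mean of the two central order statistics for even counts).
Jaccard of two empty hit sets is defined as 0: two screens that find
nothing provide no replicability evidence. Single-screen studies have no
within-study replicability and are excluded with a warning.

A pair's paralog score is Σ weights over screens where it is a hit minus Σ
weights over screens where it is an assayed miss; unassayed screens
contribute nothing. Gold-standard candidates require score > 0.25 (strict)
and hits in ≥ 2 distinct *studies* (not screens). Recall of a screen
against a gold set is |hits ∩ gold| / |assayed ∩ gold|, undefined (reported
missing) when the screen assays no gold pair.

## Additive null model for guide arrays

A pool of n-position arrays enumerates all 2ⁿ essential/non-essential
masks (128 at n = 7; 384 over three pools). Fold changes are anchored by
subtracting the mean of the all-non-essential arrays per sample, then the
model y ~ Aβ is fit by least squares on arrays carrying at most two
essential guides (87 rows over three pools), where A[i,j] = 1 iff array i
is essential at position j. An intercept is included and reported
separately: after anchoring it should be ≈ 0, which is checked as a
diagnostic, not enforced — the intercept-free formulation and ours coincide
on anchored data. Rank deficiency (a position constant within the retained
rows) is a hard error naming the degenerate positions. Predictions sum the
β of a mask's essential positions; R² between predicted and observed is
reported per pool on the popcount ≤ 2 arrays. The three pools are fit
jointly and scored per pool; per-pool fitting is available by subsetting
the design. With noise sd 0.2 at k = 87 the closed-form OLS standard error
per coefficient is 0.0594, so individual coefficients land within ±0.15 of
truth ≈ 98.8% of the time (the joint all-7 event is ≈ 92%).

**Position effects.** Per-position means of single-essential arrays expose
efficacy loss along the array. In the forward/reverse comparison, masks
always index *physical slots*; the reverse pool carries the same guides
with slot j holding the guide whose forward home is n+1−j. A guide's
(forward, reverse) LFC pair deviates from the diagonal exactly when one of
its two physical slots is attenuated — so with attenuation at slots 6–7,
guides homed at forward 6–7 deviate one way and guides homed at forward
1–2 (which land in reverse slots 6–7) deviate the other; guides homed at
3–5 sit on the diagonal.

## Library design

Pair selection applies strict-inequality filters from two named profiles:
the *prototype* profile (mean identity in (30, 99), delta identity < 10,
both genes mean expression > 2 with std < 1.5) and the relaxed *inzolia*
profile (delta and expression-variance filters disabled, family-drop
threshold widened from 10 to 20; the mean-expression floor retained). The
upper identity bound is dropped together with the delta filter in the
relaxed profile — the lower bound still excludes distant homologs — and
both bounds remain configurable, since only the lower bound demonstrably
carries over. Setting both expression thresholds to None disables the
expression lookup entirely, so a fully open profile passes every candidate.

Families grow by the difference-from-top-paralog rule: C joins A's family
when identity(A, top) − identity(A, C) is below the profile threshold.
Directed admissions are closed into families by union–find (the rule is
not symmetric); components larger than 4 keep the four members with the
smallest admission drop, ties alphabetical, making the output deterministic
under input reordering.

Each target gets two four-guide arrays: singles use the same four guides in
two orders (the sibling order is the reversal); pairs interleave two guides
per gene (A,B,A,B / reversed); triples take one guide per gene plus a pad
slot (non-essential gene or non-targeting, by policy) and quads one guide
per gene, with sibling arrays of triples/quads using disjoint guide sets.
Guide ranking is an input — any ranked spacer list works.

Oligo assembly is byte-exact concatenation: 5' amplification primer,
BsmBI site + AGAT overhang (lowercase restriction flanks preserved as
synthesized), four 20-nt spacers interleaved with the three distinct
internal direct repeats (TAATTTCTACTATTGTAGAT, AAATTTCTACTCTAGTAGAT,
TAATTTCTACTGTCGTAGAT), the TTTTTT Pol III terminator, the 3' BsmBI region
and the 3' primer — 212 nt with the prototype primers, 208 nt with the
production primers. Assembly is injective on spacer tuples, and the two
BsmBI cores live only in the restriction segments of the layout (asserted
per segment; a spacer could coincidentally contain the motif, which is a
synthesis QC concern outside the assembler's contract).

## Gene-level screen analysis

Gene (or family) fold change is the mean over clone × replicate values of
the arrays targeting it. Essentials are mean fc < −1 (strict). The PR
curve walks the fc-ascending ranking restricted to reference
essential/non-essential genes; it is invariant to monotone transformations
of the ranking statistic.

Family GI classification uses the sum-of-singles expectation: dLFC < −1 is
synthetic lethal, dLFC > +1 masking/buffering — unless the expectation
falls below the screen's dynamic-range floor, in which case the family is
*untestable*: saturation cannot be distinguished from buffering there. The
floor is the most severe clone-level mean fold change observed anywhere in
the screen, the most conservative available granularity. Untestable takes
precedence over masking only; a family observed *below* threshold relative
to expectation is still synthetic lethal. Triples/quads use the same null
and additionally report each constituent pair's own dLFC; a higher-order
call is flagged explainable-by-pair when some constituent pair's dLFC is
within a configurable margin (default 0.5) of the family's.

## Synthetic data

The generators emulate the statistical structure the pipeline assumes, not
any particular dataset.

*Pooled screen*: 150 genes (10% essential, SMF ~ N(−2, 0.5); the rest
N(0, 0.1)), 150 assayed pairs, 12 constructs per target in each singleton
orientation and per pair, 2 endpoint replicates. A construct's true LFC is
the sum of its targets' SMFs plus any planted interaction plus
N(0, 0.3 · platform_fidelity) guide-intrinsic noise shared across
replicates. Reference counts are lognormal around 500× representation;
endpoint counts are negative-binomial around reference·2^LFC with
dispersion 0.01 (variance m + d·m²; replicate CV ≈ 10%, matching
high-quality screens — dispersion 0 disables sampling entirely so noiseless
configurations round-trip exactly). The sparse composition is deliberate:
mode-centering assumes the modal construct has no phenotype, which holds in
real libraries and must hold in the emulation. Multi-study simulation
shares gene truth across studies, varies platform_fidelity per study, and
plants universal versus background-specific interactions.

*Seven-guide pools*: all 2⁷ masks per pool × 3 pools, LFC = Σ mask·
attenuation·β + N(0, noise); default attenuation (1,1,1,1,1,0.3,0.2)
reproduces the efficacy cliff after position five. Reverse-orientation
pools place each guide in its mirrored physical slot.

*Design inputs*: identity/expression/guide tables with families planted on
known sides of each profile filter (pairs inside all thresholds, pairs
with delta identity 15, third members at drop 12).

Not emulated: guide-specific off-target structure, copy-number artifacts,
chromosomal-position effects, real library compositions, or the count
distributions of any particular published screen — passing tests show the
pipeline's statistical machinery is correct under its stated assumptions,
not that any specific biological dataset would reproduce.

All randomness flows from one seed; identical configurations are
byte-identical.

## Problem sizes and numerical choices

The test suite and acceptance script run on: default-size screens (~5,400
constructs; 3 seeds for specificity/power, one 9-screen 3-study simulation
for meta-analysis recovery), 7-guide pools of 384 arrays, mode-centering at
n = 5000 × 4 draws, 10,000 random oligos for assembly invariants, and 40
simulations of the k = 87 regression. These sizes put Monte-Carlo standard
errors comfortably inside the asserted bands while keeping a full run in
tens of seconds. Degenerate inputs (empty groups, all-zero samples,
missing anchors, rank-deficient designs, zero pooled SD) raise typed
errors rather than propagating NaN; the only silent NaN is the sample SD
of a single construct, which flows into an undefined effect size and a
non-hit.

## Known limitations

- The KDE mode estimator's finite-sample error (≈ 0.03 at n = 5000) is a
  floor on dLFC accuracy shared by all pairs in a screen.
- Whether published analyses centered before or after replicate averaging
  is not documented; we center per-replicate then average (see above).
- Multi-matching reads are dropped with a log message; real multi-hit
  reads essentially require a pathological library.
- Family closure beyond pairs (union–find + smallest-drop truncation) is
  one defensible convention among several; published family counts do not
  pin it down.
- Real-data headline counts from published screens (total hits across
  studies, multi-study pairs, gold-standard counts) depend on the deposited
  datasets and are not asserted anywhere in this package.
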