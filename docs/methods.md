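# Methods

## The problem

Bulk tumor tissue is a mixture of tumor epithelial cells and stromal cells, and
the proportion of tumor epithelial cells (PTEC, "tumor purity" or "tumor
cellularity") varies between sampling sites of the same tumor. Any diagnostic or
prognostic score that sums absolute expression levels of signature genes
therefore inherits that variation: thousands of genes correlate with PTEC simply
because epithelium and stroma express them differently. This package implements
the counter-proposal: statistics built on within-sample **relative expression
orderings (REOs)** — for a gene pair (G_i, G_j), only the sign of the
within-sample difference — and an analysis pipeline demonstrating that REOs are
largely insensitive to PTEC, plus a single-reversal-pair classifier that
exploits this.

A REO is invariant to any strictly increasing transform of one sample, so it is
unaffected by monotone normalization, and — the quantitative question the
pipeline answers — it is unaffected by cell-type mixing whenever the ordering
agrees between the two cell types, and degrades gracefully when it does not.

## Core statistics

**Pairwise REO consistency.** For two expression profiles over the same gene
universe, a pair is consistent when its non-tie orientation is identical in
both. Tied pairs carry no ordering information: they are excluded from the
denominator and reported separately (`n_ties_excluded`). The all-pairs score
streams the upper triangle of the gene × gene comparison in fixed-size row
chunks, so memory stays O(chunk × n) and ~2×10⁸-pair universes are feasible.
The one operation that must *return* a pair set, the rank-difference filter,
materializes its output, so its all-pairs path is O(n²) memory; at the gene
counts used here (≤ 2000) that is a few megabytes.

**Concordance of purity correlation with cell-type contrast.** A gene is
concordant when it is positively Spearman-correlated with PTEC and up-regulated
in epithelium versus stroma (pooled-variance Student's t-test), or negatively
correlated and down-regulated. With k genes significant in both lists (BH FDR
strictly below 10% in each) and s concordant, the score is s/k and its chance
probability is the upper tail of Binomial(k, Pe):

    P = 1 − Σ_{i=0}^{s−1} C(k, i) Pe^i (1 − Pe)^{k−i},   Pe = 0.5 by default,

evaluated through the binomial survival function so it is accurate for k up to
~10⁵. Zero-variance genes are excluded from the correlation (rank correlation
is undefined for them) rather than assigned rho = 0. Degenerate t-tests (zero
pooled variance) get t = 0, p = 1 when the group means agree.

**Mixture model.** A simulated bulk profile at purity Pi ∈ (0, 1) is the convex
combination E = Ee·Pi + Es·(1 − Pi) of the patient's epithelial and stromal
profiles. Mixing defaults to the **linear** intensity scale — cells contribute
transcripts additively — with log2 inputs unlogged before and re-logged after;
`mixing_scale="as_given"` combines values as provided, since processed public
profiles are sometimes mixed on whatever scale they ship in. Pi = 0 and Pi = 1
are rejected in pipeline mode and permitted only as explicit endpoint
identities (returned as copies of the inputs, exact by construction rather than
by floating-point arithmetic).

Because E is linear in Pi and equals Ee at Pi = 1, the sign of E_i − E_j can
agree with that of Ee_i − Ee_j only on an interval containing Pi = 1: the set of
REO-consistent pairs **nests monotonically** as purity rises. This exact
containment is asserted in the tests and is the structural reason consistency
degrades smoothly rather than erratically.

**Small-rank-difference filter.** Pairs with small |R_i − R_j| in the
epithelial reference profile (ascending average-tie ranks) are the ones most
easily flipped by stromal admixture. The filter deletes
⌊fraction · n_pairs⌋ pairs with the smallest absolute rank difference
(default fraction 0.1), breaking ties at the cut lexicographically by (i, j)
so the result is deterministic. The reference is the epithelial profile, not
the mixture, because the practitioner filters on what is measurable in the
reference cohort.

**Reversal-pair signature.** Discovery: (i) keep pairs with the same non-tie
REO in strictly more than 95% of normal samples, and likewise for tumors —
tied samples count in the denominator but toward neither orientation; (ii)
intersect for pairs whose stable orientations are opposite; (iii) per sample,
rank all genes ascending, take Rij = |R_i − R_j|, and score each candidate by
the reversal degree avgRij = (median[Rij(normal)] + median[Rij(tumor)]) / 2
(even-length medians use the midpoint convention); (iv) return the argmax,
breaking exact ties lexicographically. Classification of a new sample uses only
the pair's within-sample ordering: normal orientation ⇒ normal, opposite ⇒
tumor. An exact expression tie is surfaced as `unclassifiable` by default; the
stricter normal-or-else rule is available as `tie_policy="tumor"`. The whole
discovery path depends on the data only through per-sample ranks, so it is
invariant under strictly increasing per-sample transforms (asserted in tests).

## Synthetic data: what it emulates, and what it does not

**Paired cell-type profiles** (`CellPairConfig`, defaults: 2000 genes, 8
patients, target concordance 0.85, stromal log2 noise sd 0.05). The epithelial
profile is log-normal (log2 values ~ Normal(6, 2)), resembling RMA-processed
array intensities; the stromal profile cyclically permutes the values of a
calibrated subset of genes and adds noise. The subset size is found by
bisection until the realized all-pairs consistency of the emitted pair —
measured by the pipeline's own scorer, noise included — is within ±0.02 of the
target, which closes the loop between generator and estimator; unattainable
targets raise with the attainable range. The 0.85 target and 8 patients sit
inside the 82–93% concordance range and cohort sizes reported for
microdissected epithelial/stromal pairs. Concordance is controlled by value
swapping rather than independent resampling because swapping directly targets
the pairwise-REO statistic under study.

**Tumor/normal cohorts** (`CohortConfig`, defaults: 200 genes, 50+50 samples,
one planted reversal pair at maximal rank separation, background reversal rate
0.02, PTEC ~ Uniform(30, 100), log2 noise sd 0.3, stromal discordance 0.15).
Normal samples scatter around a baseline ordering; tumor epithelial samples
swap the planted pairs' values (plus a few background swaps) and are mixed with
a per-sample noisy copy of a cohort stromal profile at the sample's PTEC. The
stromal profile is derived from the *tumor* baseline (with a permuted subset),
so it shares the planted pairs' tumor orientation — tumor stroma is observed to
show differential REOs similar to tumor epithelium relative to normal tissue —
which is what lets a planted reversal survive mixing the way the real signature
does. Noise sd 0.3 on log2 is a typical between-replicate spread for processed
array data; PTEC spanning 30–100% covers the low-cellularity range the
validation binning targets.

What the generators do **not** emulate: cross-patient sharing of the
epithelial/stromal contrast beyond a single pair of cell-type baselines,
platform/batch effects, probe-level structure, count noise of RNA-seq, or
correlated gene modules. Passing tests therefore show that the estimators and
the discovery machinery behave as designed under the stated mixture model —
not that any particular accuracy will be attained on real cohorts.

## Problem sizes and numerical choices

The shipped analyses use 2000-gene, 8-patient cell-pair simulations (≈2×10⁶
gene pairs per score), a 1500-gene concordance experiment with 10 replicate
profiles per cell type and 60 bulk mixtures, 200-gene 50+50 cohorts for
signature work, and 40 seeds for the recovery-rate estimate — sizes chosen so
every experiment reproduces the qualitative structure of the full-scale
analysis while each driver finishes in seconds to tens of seconds.

Other fixed choices: average ranks for ties (keeps rank sums at n(n+1)/2, the
Spearman convention); rows with any missing value dropped at load; duplicate
gene rows collapsed by mean, matching the probe→gene collapse rule (probes
mapping to no gene or to several genes are dropped, the rest averaged per
gene); per-sample PTEC resolved as the arithmetic mean of per-slide tumor-cell
percentages, with the sample dropped if any slide reading is missing; strict
inequalities at both the FDR threshold and the stability threshold; BH
adjustment via the standard step-up procedure (statsmodels implementation).

## Known limitations

* The stability screen's chunked pair enumeration is O(n² · m) time; at the
  ~20k-gene scale of a full transcriptome it is feasible but slow in pure
  NumPy — the shipped analyses work on gene subsets.
* `filter_small_rank_diff` materializes its output pair set (see above).
* The concordance experiment models the epithelium/stroma contrast with a
  single baseline pair; its concordance score is therefore an upper-end
  scenario compared with heterogeneous real cohorts.
* Only two-class (tumor/normal) single-pair signatures are implemented; k-TSP
  ensembles and survival signatures are out of scope.
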