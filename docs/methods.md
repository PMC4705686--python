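# Methods

## Model and procedure

The pipeline has three stages.

**1. Activity scoring.** A compendium is a dense genes × samples matrix of
normalized expression scores on one platform, with every sample annotated
with exactly one free-text context label. Scores are assumed z-score-like:
near zero for unexpressed genes, large for highly expressed ones, and
comparable across samples within one compendium (not across platforms).
The activity of gene set *s* in sample *i* is
`y_si = Σ w_g x_gi / Σ |w_g|`, summed over member genes present in the
compendium. Genes absent from the compendium are excluded from numerator
and denominator alike — the denominator renormalizes, so partial overlap
(routine after cross-species conversion or across platforms) changes the
effective set rather than biasing the scale — and are reported per set. A
set with no present member, or whose present members carry zero total
absolute weight, is an error rather than a silent NaN.

The score is invariant under positive rescaling of a set's weights, and
with unit weights it equals the mean expression of the present members.

**2. Sample selection (POI).** A pattern of interest evaluates to a
boolean mask over samples. Interval POIs use *strict* inequalities (open
intervals) on every bound, so samples lying exactly on a cutoff are not
selected; this matches the "activity > cutoff" reading and makes numeric
and formula POIs agree. Cutoff specifications resolve against the observed
activity distribution: `raw` (the value itself), `sd` (mean + value·SD,
SD with the N−1 denominator), `quantile` (empirical quantile with linear
interpolation between order statistics), and `normal_p` (tail point of a
normal distribution fitted by mean/SD to the activities; the upper side
takes the upper tail). The default POI requires every analyzed set to be
above mean + 1 SD — "all sets highly active", selecting roughly the upper
16% per set for near-normal activities.

Polygon POIs test point-in-polygon in the activity plane of two sets;
polygon *boundaries count as inside* (selection regions are closed, so
vertex-snapped selections keep their edge points), polygons must be simple,
and the mask is the union over polygons. Formula POIs support `+ - * / ^`
(power, right-associative), comparators `< > <= >=`, and `& |`, with
precedence `^` > unary `−` > `* /` > `+ −` > comparators > `&` > `|`. Set
names are sanitized to identifiers by replacing non-alphanumeric characters
with `_`; a collision after sanitization is an error, and a sanitized name
starting with a digit cannot be referenced in a formula. All POI kinds
serialize to JSON (`"poi_version": 1`); interval POIs store their most
recently resolved numeric bounds alongside the specs so a saved POI is
self-documenting.

**3. Context enrichment.** With *N* samples, *K* selected, and a context of
*n_c* samples of which *k_c* are selected, the p-value is the one-sided
Fisher's exact test (hypergeometric upper tail, P(X ≥ k_c)); one-sided
because the question is enrichment — a two-sided test would also flag
depleted contexts the ranking does not report. The Bonferroni factor is the
number of distinct annotated contexts *C* — every context is tested,
including those with k_c = 0 and singleton contexts (no minimum-size
filter; small contexts are simply hard to call significant). The fold
change `f_c = ((k_c + K/N)/(n_c + 1))/(K/N)` is the context's selection
rate over the global rate with a pseudocount, so empty contexts get
exactly 1 and small contexts are shrunk toward the global rate. Reporting
cutoffs are strict (`p_adj < 0.05`, `fold > 1.5` by default). Ranking is by
ascending adjusted p, ties by descending fold change, then label — the
tie-break is a determinism choice, not a statistical one. A POI matching no
samples yields an empty report with a logged warning (fold change is
undefined at K = 0).

The Fisher test assumes independent samples; compendium samples from the
same study are correlated, so adjusted p-values are interpretable as
significance only for a POI fixed in advance, and serve as ranking scores
under interactive exploration.

## Synthetic compendia

`synthesize_compendium` draws baseline scores i.i.d. Normal(0,
baseline_sd²) — default SD 1, matching the near-zero behaviour of
normalized scores for unexpressed genes — and adds a constant `delta` to
the implanted genes in the implanted context's samples. It emulates the one
property the method relies on (context-consistent signal standing out of a
comparable-scale background) and deliberately omits several features of
real compendia: inter-gene correlation, study/batch structure within a
context, heavy-tailed score distributions, and context-specific variance.
A green recovery test therefore establishes that the pipeline finds clean
implanted signal at the stated effect size and sample counts — not that it
is robust to correlated noise, which the Fisher test does not model.

The recovery benchmark uses N = 1000 samples in 20 contexts of 50, one
50-gene implant at delta = 1 (one baseline SD — a modest signal), and a
gene universe of 2000 (chosen so the implant is a small fraction of the
universe while 100 seeded replicates run in seconds). Under the default
POI the implanted context ranks first in ≥95/100 seeds; with 50% of the
set replaced by random genes it still passes default cutoffs in ≥80/100
(observed: 100/100 for both), while at 90% replacement recovery visibly
degrades (examples/04).

## Numerical and design choices

- SDs use the N−1 denominator throughout (resolution of `sd` and
  `normal_p` cutoffs, `activity_moments`).
- `perturb_gene_set` rounds the replacement count half-up
  (`int(f·n + 0.5)`), replaces members sampled uniformly without
  replacement, and carries each displaced member's weight to its
  replacement, keeping the weight multiset (hence Σ|w|) constant across
  noise levels.
- Cross-species conversion expands one-to-many homologs (each target
  inherits the source weight) rather than taking the first hit; duplicate
  targets keep the first-seen weight, with the conflict logged and
  reported. Removing genes shared between input sets is an explicit
  utility (`remove_shared_genes`), never applied silently.
- Heat-map sample ordering is the leaf order of complete-linkage
  hierarchical clustering on Euclidean distances between sample activity
  vectors (scipy linkage; deterministic for fixed input, with scipy's
  internal tie-breaking).
- Compendium I/O writes scores at 12 significant digits; round-tripping is
  exact to ≥10 digits. Missing values are rejected, not imputed.
  Identifiers and labels may not contain tab or newline (no quoting).
- Randomness: every stochastic routine (synthesis, perturbation) takes an
  explicit integer seed and is bit-reproducible; no global RNG state.

## Limitations

- Enrichment treats samples as exchangeable; correlation-aware inference
  (rotation/competitive tests) is out of scope.
- Expression values are consumed pre-normalized; no normalization,
  probe-to-gene mapping, or cross-platform merging is attempted.
- Formula POIs cannot reference sets whose sanitized names start with a
  digit; rename such sets before use.
- Plotting is a convenience export (histogram / scatter / clustered heat
  map); failures there never affect tabular outputs.
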