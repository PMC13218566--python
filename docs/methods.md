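# Methods

## The assignment model

`themecast` treats an article the way item-response analysis treats a
person: its keywords are item-level observations, clusters of co-occurring
keywords are "item testlets" (coherent thematic units), and the article's
theme is the testlet that best summarizes it. The summary statistic is the
mode: with *f_i(k)* the number of article *i*'s keywords falling in cluster
*k*, the assigned theme is the smallest cluster id attaining
max_k *f_i(k)*. The smallest-id tie rule applies to *every* tie pattern,
not only the all-equal case; this subsumes the weaker rule (first-of-max)
while remaining deterministic, and is the convention the whole package
relies on (cluster ids are assigned in founding order, so "smallest id"
means "earliest, largest-leader cluster"). Blank and missing keyword
entries are dropped before counting; an article with no mapped keyword gets
a missing theme and is excluded from proportion denominators (denominators
are reported alongside).

## Clustering

The co-word graph connects two canonical terms when at least one document
contains both; the edge weight is the number of such documents and each
node carries its document frequency and document set.

**Leader-following clustering (FLCA).** The literature describes
leader-based co-word clustering without a full normative definition, so
this package fixes one, chosen for determinism and for honoring the
"leader" concept: visit terms by descending document frequency
(alphabetical tie-break); a term joins the existing cluster whose leader is
most Jaccard-similar to it (similarity of document sets) when that
similarity reaches the threshold τ, otherwise it founds a new cluster and
becomes its provisional leader. After the pass, leaders are recomputed as
each cluster's highest-frequency member. With `target_clusters` set, the
smallest cluster (ties: latest-founded) is repeatedly merged into the
cluster with the most similar leader (ties: smallest id) until the target
is reached, and ids are renumbered 1..K in founding order. Everything is
tie-broken lexicographically; there is no randomness anywhere in the path
from corpus to theme.

τ defaults to 0.1: within a coherent subfield, two keywords typically share
well over 10% of their joint document set, while unrelated keywords share
almost none, so 0.1 acts as a noise floor rather than a tuning knob.

**Louvain comparison.** For robustness analyses the same graph can be
partitioned by Louvain modularity optimization (networkx implementation,
seeded); communities are numbered by descending size and given leaders by
the same rule, so FLCA and Louvain solutions are directly comparable via
plurality collapse, chance-corrected κ at the coarse granularity, and the
top-k concordance curve (an article agrees at level k when its fine theme
is among the k most frequent fine themes of its coarse community).

## Core themes

The journal h-index is the largest h with h articles at ≥ h citations. A
theme is *core* when at least one of its articles belongs to the journal's
h-core (citations ≥ journal h). This operationalizes "themes contributing
to the h-index" as h-core membership — a convention of this package, since
the phrase admits several readings. Themes are ranked by (theme h-index,
article count, label).

## Agreement and stability

Cohen κ is unweighted, computed from the confusion matrix over the union
label set (Pe from marginal products), with the conventional qualitative
bands (≤0.20 slight, ≤0.40 fair, ≤0.60 moderate, ≤0.80 substantial, else
almost perfect; negative poor). A pre-built confusion matrix can be passed
directly, so published interrater tables can be re-evaluated verbatim.

Stability is summarized on the theme-proportion simplex. The
Jensen–Shannon distance is the square root of the JS divergence with
base-2 logarithms, hence bounded in [0, 1]; Spearman correlation is
computed on proportion vectors over the union theme set (absent themes at
0, average-rank ties). Bootstrap stability resamples themed articles with
replacement at the original size against the full-sample reference
distribution; holdout robustness splits them at a prespecified fraction
(default 0.3) and compares train against holdout. Both are seeded and
reproduce bit-identically. Because the holdout comparison involves two
disjoint finite samples (the smaller of which carries most of the
variance) while the bootstrap compares one resample to the fixed
full-sample reference, the mean holdout JS distance systematically exceeds
the mean bootstrap JS distance on the same corpus — the drift ordering the
validation tests assert.

## The numeric branch and mapping power

A person×item panel is converted to "keywords" in three steps: each item is
binarized at its own mean (strictly greater than; constant items become
all-zero with a warning), positive cells become `Y<item>` tokens, and
N-type tokens are discarded. The Y-token co-word graph is clustered with
FLCA into two testlets and each person gets the modal testlet. Mapping
power is Cohen κ between those person themes and an external binary label
after choosing, between the two possible theme↔label bijections, the one
with higher observed agreement; MP is therefore invariant to theme
relabeling and label flipping. Persons with no positive cell have no
tokens, get a missing theme, and are excluded and counted.

The differential-selection step mirrors two-group expression screening:
per item a Welch two-sample t-test and a fold change
log10((mean_case + c)/(mean_ref + c)) with pseudocount c = 0.5 (handles
zero means in sparse presence data; the "case" group is the lexically
larger label). Direction is the sign of the log fold change; items with
equal group means belong to neither pool. The top-10 up and down items by
p-value and, separately, by |log10FC| are selected, and their union is the
core term set fed to the binarized dual-heatmap export. Negative group
means (possible only on scales the ratio was not meant for) are floored at
zero with a warning rather than producing undefined logarithms. Welch's
test is used uniformly for continuous and 0/1 inputs; no multiplicity
correction is applied (selection, not inference). Paired t-tests between
per-person testlet mean scores flag zero-variance differences as
degenerate instead of erroring.

## Leadership scoring

For an entity's sorted top-three partner counts n1 ≥ n2 ≥ n3 > 0, the
dominance ratio is r = (n1/n2)/(n2/n3) and the advantage coefficient
r/(1+r) ∈ (0, 1), banded as super (≥0.8), quasisuper (≥0.7), strong
(≥0.6), moderate (≥0.5), weak otherwise, with a dominance flag at ≥0.7.
The coefficient is scale-invariant in the counts. Only this printed,
verifiable formula is implemented; the Kano export is reduced to its
underlying coordinates (entity, article count, citation count, band)
because axis conventions vary across renderings.

## Synthetic data: what it emulates and what it does not

The corpus generator plants one theme per article: keywords are drawn
without replacement from the theme's 12-term vocabulary (disjoint across
themes) and each is replaced by a random other-theme term with probability
`noise` (default 0.05). Citations are discretized lognormal (μ=1.0,
σ=1.2 on the log scale) so h-indices are non-degenerate; countries and
years carry theme-correlated biases so flow and summary outputs are
non-trivial. With 6 keywords per article over a 12-term vocabulary, two
same-theme terms co-occur in roughly a quarter of the theme's articles,
holding each theme's component together under the leader pass at τ=0.1,
while zero noise keeps themes disconnected — which is what makes exact
recovery of the planted partition provable rather than merely observed.

The two-domain panel gives group 0 a mean shift of d·sd on the first
domain's items and baseline on the second (group 1 mirrored), Gaussian
noise sd = 1, 20 persons per group, 10 items per domain, d = 5 by default.
The expression generator plants 10 up- and 10 down-shifted features
(effect 3 on a log-like scale, baseline 5) in a 31-versus-52 two-group
layout, a shape typical of a primary-versus-metastatic tumor comparison.

What the generators do *not* emulate: real keyword synonymy and polysemy,
skewed theme sizes, multi-topic articles, citation dynamics, batch effects
or correlated features. Passing tests on these corpora therefore
demonstrate the pipeline's correctness and determinism under planted
structure, not its thematic validity on real literature — the latter is
what the interrater-κ machinery is for.

## Numerical choices and degenerate inputs

- Strict ">" in both binarization rules; equality maps to 0.
- Jaccard on empty document sets is 0; κ with Pe = 1 is 1 when Po = 1
  (single-label degeneracy) and NaN otherwise.
- JS distance of identical distributions is exactly 0 (NaN from the
  underlying routine is mapped to 0).
- Bootstrap/holdout with fewer than two distinct themes warn and record
  Spearman as missing; holdout repetitions with an empty partition are
  skipped and counted.
- Problem sizes in the test suite (corpora of 120–200 articles, 100-seed
  mapping-power sweeps, 20–60 resampling repetitions) are chosen so the
  planted-structure guarantees are comfortably in their asymptotic regime
  while the whole suite stays fast enough to run habitually.

## Known limitations

- The leader pass is greedy: once a cluster exists, a borderline term joins
  it rather than founding a competitor. On mean-split panels this matters
  when group separation is weak: stray flips (a person crossing an item's
  mean) connect the two domains' tokens, and when that stray similarity
  reaches τ the second domain's first token is absorbed before it can found
  its own cluster. Empirically the two-testlet recovery is essentially
  certain at d = 5, holds in ~95% of seeds at d = 4, and degrades at d = 3;
  users analyzing weakly separated panels should raise τ or inspect the
  cluster composition.
- Single-theme assignment underrepresents genuinely multi-topic articles;
  candidate frequencies are retained on every assignment so weighted or
  probabilistic extensions can be layered on.
- Abstract keyword extraction is frequency-based (unigrams + bigrams, no
  lemmatization or concept mapping); it is deterministic but vocabulary-
  sensitive.
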