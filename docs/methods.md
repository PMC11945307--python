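# Methods

## Model

`dagenrich` performs over-representation analysis on a rooted `is_a` DAG
of ontology terms under the true-path rule. Throughout, *N* is the number
of genes in the true-path-expanded annotation universe, *n* the number of
interest genes inside that universe, and, per term *t*, *m* its expanded
gene count and *r* its overlap with the interest list. The classic
per-term statistic is the hypergeometric upper tail P(X ≥ r),
X ~ Hypergeometric(N, m, n).

The weighted model replaces *m* and *r* by floors of weight sums over a
per-(term, gene) **weight ledger** w ∈ (0, 1]:

* initialization: `w(t, g) = max(1 − weight_step · d(t, g), min_init_weight)`,
  where d(t, g) is the origin distance — the minimum number of levels the
  annotation was inherited upward to reach *t* (0 for a direct
  annotation, minimized over all annotated descendants);
* traversal: levels are processed from the deepest to the root
  (lexicographic term order within a level — the levels of a DAG share no
  edges, so within-level order cannot change the result through the
  graph, only through deterministic tie-breaking). For a node *t* whose
  score p(t) passes the significance threshold, each already-scored,
  significant child *c* is compared via the dynamic weight
  `w_d = log p(c) / log p(t)` (natural logarithm):
  * `w_d > 1` (child locally dominant): the weights of *c*'s genes at *t*
    and at every ancestor of *t* are divided by `w_d · penal`;
  * after re-scoring *t* and exhausting dominant children, each remaining
    (dominated) child has its own gene weights multiplied by `w_d` and
    divided by `penal`, and its score is recomputed and re-recorded;
* penalty: `penal = max(scale · log(xmin) / (log p(t) + log p(c)), 1)`,
  xmin the smallest positive normalized double (≈ 2.225e−308). Because
  the denominator is the joint log-magnitude of the two p-values, the
  penalty is strong for weakly significant pairs (both p near the
  threshold give penal ≈ 7.69) and inert for deeply significant pairs
  (both ≤ 1e−36 clamp to 1), exactly where `w_d` alone discriminates well.

Scores are clamped to [xmin, 1]; scores of exactly 1 are nudged to
1 − 1e−16 *inside the weight formulas only*, so logarithms stay finite
while reported p-values are untouched. Benjamini–Hochberg adjustment is
applied once, over all recorded node scores, at the end.

### Termination and monotonicity

Every refinement pass either finds no dominant child (and exits) or
permanently removes at least one child from the comparison set, so the
per-node refinement terminates after at most (number of children) passes;
`max_refine_iters` (default 50) is a pure safety cap, and if it ever
tripped the dominated-child factor is additionally clamped at 1. All
ledger mutations go through guarded operations that forbid any weight
increase and floor weights at xmin, so the ledger is monotone
non-increasing after initialization by construction.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `threshold` | 0.01 | raw-p cutoff driving the traversal (BH-adjusted values are reported but do not steer it) |
| `weight_step` | 0.1 | initial-weight decay per inherited level |
| `min_init_weight` | 0.5 | floor of initial weights |
| `penalty_scale` | 0.1 | scale factor of the penalty formula |
| `min_genes`, `max_genes` | off | per-term expanded-gene bounds; terms outside are skipped entirely. Recommended 10 / 2000 on real ontology-scale data; off for small fixtures. The root term annotates the whole background and is uninformative (its plain p is identically 1), so analyses that compare against ORA exclude it via `max_genes = N − 1` |
| `reweight` | on | debug flag; off together with `weight_step=0, min_init_weight=1` reduces the run to classic ORA exactly |

Defaults reproduce the double-weighting model as specified; the reduction
configuration is exported as `CLASSIC_PARAMS`.

## Design choices where the procedure was underdetermined

* **Origin distance** uses level difference (level(descendant) −
  level(ancestor)), not edge counts of a particular path; with multiple
  inheritance these can differ, and levels are the model's only distance
  notion. When one gene reaches an ancestor via several annotated
  descendants the minimum distance (maximum weight) is kept, favoring the
  strongest evidence.
* **Ties in the dynamic weight** (`w_d == 1`) leave the child in the
  dominated set — ties favor the parent.
* A child moved to the dominant set is removed permanently; it does not
  re-enter comparison in later refinement passes.
* A dominated child's re-recorded score **overwrites** its earlier entry
  in the final table.
* Weight division propagates to the processed node and its ancestors
  only, never to its other descendants.
* Scores recorded at deeper levels are not globally recomputed when later
  sibling processing shares genes; only the explicit dominated-child
  update touches an already-recorded node.
* The floors of the weighted counts m_w and r_w are taken independently
  (with a 1e−9 guard against float drift in the sums).
* BH is applied once over all recorded nodes, not per level.

## Synthetic fixtures: what they emulate, and what not

`generate_ontology` builds a rooted DAG of prescribed depth: level sizes
grow geometrically (`branching`) and are rescaled to the term budget;
each non-root term takes one parent one level up (so the target depth is
achieved exactly) and a second strictly shallower parent with probability
`multi_parent_prob` (default 0.3), giving diamond motifs.
`generate_annotations` draws direct gene counts per term from a truncated
discrete power law (`tail_exponent`), reproducing the 1-to-thousands
spread and strong right skew of real disease-gene annotation tables.

The standard study fixtures use `tail_exponent = 1.45`, chosen so the
mean direct genes-per-term (≈ 50) and direct terms-per-gene (≈ 13.5)
match the density of a current disease-ontology annotation corpus
(≈ 190k pairs over ≈ 4.4k terms and ≈ 15k genes) at the reduced scale of
500 terms / 2,000 genes. The generators do **not** reproduce a real
ontology's exact level census or degree distribution, annotation noise,
or gene-gene correlation; passing studies demonstrate the algorithmic
properties (decorrelation, recovery direction, robustness) under
realistic structure, not performance guarantees on any particular real
corpus.

## Study protocols and problem sizes

* **Recovery (accuracy) study** — 500-term / 2,000-gene fixture, 10
  implanted "known" terms sampled from the middle 50% of the
  direct-annotation-size ordering (ranks strictly above the 25th
  percentile up to the 75th; ties broken by term id), interest lists
  built from the known terms' direct or true-path-expanded gene sets with
  genes carrying ≥ 30 direct annotations removed, 20 repetitions.
  Recovery = |top-k significant terms ∩ known|. The weighted-vs-ORA
  comparison is made on expanded-mode interest lists — the regime where
  inherited annotations crowd the ranking — and the direct-vs-expanded
  comparison on the weighted method itself. Only terms at or below the
  raw-p threshold count as recovered.
* **Perturbation (robustness) study** — 150-term / 600-gene fixture,
  interest from 30 known terms (direct mode); noise added (or genes
  removed) at 0–30% in 5% steps, 100 repetitions per level; measured as
  the overlap of the perturbed top-100 significant list with the
  unperturbed one. Monte-Carlo tolerance for the monotone-decline check
  on 100-rep means is fixed a priori at 0.5 overlap counts between
  consecutive levels.
* Per-repetition seeds derive deterministically from the master seed, so
  every report is bit-reproducible.

These sizes keep the full test suite under roughly a minute and the
acceptance script under half a minute on one CPU.

## Text annotation

The dictionary matcher is a deliberately simple exact-phrase scanner:
names and synonyms are case-folded and whitespace-normalized, strings
shorter than 3 characters discarded, surface-string collisions resolved
to the lexicographically smallest term id, and text scanned
case-insensitively at word boundaries with longest-match suppression of
nested shorter matches. It is not a tokenizing concept recognizer; it
exists so annotation corpora can be built and round-tripped in tests.

## Known limitations

* Only `is_a` edges are used; other relationship types are ignored.
* The interest-list size strongly influences which levels of the DAG
  reach significance (very large lists favor large general terms), so
  per-term gene-count bounds are recommended on real data.
* The penalty formula's strength depends on the absolute magnitude of the
  p-values, hence on study size: small backgrounds put typical p-values
  in the strongly penalized regime. This is a property of the model, not
  of this implementation.
* With multiple inheritance, level-difference distances may undercount
  the edges actually traversed by an annotation path.
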