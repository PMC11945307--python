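# dagenrich

DAG-aware, double-weighted over-representation analysis for ontology
gene-set enrichment.

## The problem

Ontologies such as the Disease Ontology or Gene Ontology organize terms in a
rooted directed acyclic graph connected by `is_a` edges, and annotations
obey the **true-path rule**: a gene annotated to a term is implicitly
annotated to every ancestor of that term. Classic over-representation
analysis (ORA) tests each term independently with the hypergeometric upper
tail

```
p = 1 − Σ_{k=0}^{r−1} C(m,k) · C(N−m, n−k) / C(N,n)
```

where *N* is the annotated background, *m* the term's gene count, *n* the
interest-list size and *r* their overlap. Because ancestors inherit the
genes of a genuinely enriched term, they come out "enriched" too — the
over-enrichment (inheritance) problem. `dagenrich` counteracts it with a
double weighting of annotated genes:

* **Initial weights** — direct annotations weigh 1; inherited annotations
  lose 0.1 per level climbed, floored at 0.5.
* **Dynamic re-weighting** — nodes are visited bottom-up by level. For a
  node *t* and child *c*, the dynamic weight `w_d = log p(c) / log p(t)`
  decides the locally more significant term; the loser's genes are
  down-weighted by `w_d` together with a penalty factor
  `max(0.1 · log(xmin) / (log p(t) + log p(c)), 1)` that bites when the
  two p-values are similar (`xmin` = smallest positive normalized double).

Each node's significance score is the hypergeometric tail computed on
floors of weight sums instead of raw counts, and Benjamini–Hochberg
adjustment is applied once at the end. The package also ships the
annotation plumbing (OBO parsing, true-path expansion, leaf pruning,
dictionary-based text annotation), a seeded synthetic-fixture generator,
and the two evaluation protocols used to characterize such methods:
known-term recovery simulation and perturbation robustness.

## Worked example

`examples/run_enrichment.py` implants signal in one deep term of a
30-term synthetic ontology and compares the weighted traversal with plain
ORA:

```
ontology: 30 terms, depth 5; background 93 genes
implanted term: T:000019 (level 5), interest list 25 genes

weighted traversal, top 5 (term, level, p, p_adjust, geneRatio):
    term                  name  level            p     p_adjust geneRatio bgRatio
T:000019 synthetic term 000019      5 3.325490e-23 9.643921e-22     25/25   25/93
T:000014 synthetic term 000014      4 8.116820e-11 1.176939e-09     25/25   26/93
T:000023 synthetic term 000023      5 2.688172e-01 1.000000e+00      1/25    1/93
...
plain ORA, top 5:
T:000019 ... 3.325490e-23
T:000014 ... 8.646274e-22
T:000004 ... 8.800780e-05
T:000002 ... 2.606095e-03
```

The implanted term T:000019 ranks first under both methods, but under
plain ORA its whole ancestor chain (T:000014, T:000004, T:000002) is
dragged into significance purely by inherited genes. The weighted
traversal leaves the direct parent at p ≈ 8e−11 (eleven orders of
magnitude weaker) and pushes the higher ancestors out of significance
entirely, while the specific term's p-value is untouched.

The other example scripts cover free-text dictionary annotation
(`text_annotation.py`), the recovery simulation (`recovery_study.py`),
and the robustness study (`perturbation_study.py`).

## Command line

```bash
dagenrich make-fixture --preset small --seed 1 --out fx/
dagenrich run --obo fx/ontology.obo --annotations fx/annotations.tsv \
              --genes fx/interest.txt --out result.tsv
dagenrich simulate --obo fx/ontology.obo --annotations fx/annotations.tsv \
              --k 5 --reps 10 --seed 7 --out sim.tsv
dagenrich perturb --obo fx/ontology.obo --annotations fx/annotations.tsv \
              --genes fx/interest.txt --kind noise --reps 20 --seed 7 --out rob.tsv
```

`dagenrich run --classic` runs plain per-term ORA on the same inputs for
comparison. Result tables are TSV with columns
`DOID  DOTerm  level  p  p_adjust  geneRatio  bgRatio  genes`.

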