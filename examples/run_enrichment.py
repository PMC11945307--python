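"""Run weighted DAG enrichment next to plain ORA on a small synthetic ontology.

Builds a seeded 30-term ontology with heavy-tailed annotations, implants
signal in one deep term (its direct genes become the interest list), and
prints both result tables. Under plain ORA the implanted term's ancestors
look enriched because they inherit its genes; the weighted traversal keeps
the specific term on top while pushing the ancestors' p-values up.
"""

from dagenrich import (
    EnrichmentParams,
    classic_ora,
    implant_interest,
    make_fixture,
    run_enrichment,
)

graph, annotations, config = make_fixture("small", seed=3)
signal = max(
    graph.nodes,
    key=lambda t: (graph.level[t] >= 4) * len([1 for _, tt in annotations.direct if tt == t]),
)
interest = implant_interest(graph, annotations, {signal: float("inf")},
                            background_rate=0.0, seed=1)
print(f"ontology: {graph.n_nodes} terms, depth {graph.max_level}; "
      f"background {len(annotations.background)} genes")
print(f"implanted term: {signal} (level {graph.level[signal]}), "
      f"interest list {len(interest)} genes\n")

params = EnrichmentParams(max_genes=len(annotations.background) - 1)
weighted = run_enrichment(graph, annotations, interest, params)
plain = classic_ora(graph, annotations, interest, params)

print("weighted traversal, top 5 (term, level, p, p_adjust, geneRatio):")
print(weighted.to_dataframe().head(5).to_string(index=False))
print("\nplain ORA, top 5:")
print(plain.to_dataframe().head(5).to_string(index=False))
print(
    f"\nimplanted term rank: weighted={weighted.rank(signal)}, ORA={plain.rank(signal)}. "
    "Ancestor rows sit lower (larger p) in the weighted table: that is the "
    "decorrelation of inherited annotations at work."
)
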