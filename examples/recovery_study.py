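"""Known-term implantation study: can the method find what was planted?

Samples known terms from the middle 50% of the annotation-size ordering,
builds the interest list from their gene sets, reruns enrichment, and
counts recovered known terms among the top-ranked significant results —
for the weighted method and plain ORA side by side. Run at reduced scale
here so it finishes in seconds.
"""

from dagenrich import SimulationDesign, make_fixture, run_recovery_study

graph, annotations, _ = make_fixture("perturb", seed=0)
print(f"fixture: {graph.n_nodes} terms, {len(annotations.background)} genes\n")

for mode in ("expanded", "direct"):
    design = SimulationDesign(k_known=10, mode=mode, n_reps=10, seed=7)
    report = run_recovery_study(graph, annotations, design)
    print(f"interest-set mode = {mode} (10 known terms, 10 repetitions):")
    print(report.summary.to_string(index=False))
    print()

print(
    "mean_overlap counts known terms recovered among the top-k significant "
    "results (out of 10). Direct-mode interest lists are cleaner than "
    "true-path-expanded ones, so their recovery fractions are higher; the "
    "weighted method matches or beats plain ORA where inherited annotations "
    "crowd the ranking."
)
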