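"""Map free-text functional descriptions to ontology terms by dictionary lookup.

Builds a disease-name dictionary from term names and synonyms (case-folded,
length >= 3) and scans sentences with a longest-match word-boundary rule,
the way gene-function text corpora are turned into gene-term annotations.
"""

from dagenrich import Term, annotate_text, build_dictionary

terms = [
    Term("D:1", name="carcinoma"),
    Term("D:2", name="colorectal carcinoma"),
    Term("D:3", name="alzheimer's disease", synonyms=["AD", "alzheimer dementia"]),
    Term("D:4", name="old concept", obsolete=True),
]
dictionary = build_dictionary(terms)
print(f"dictionary entries: {sorted(dictionary.entries)}")
print("(note: the 2-letter synonym and the obsolete term were excluded)\n")

sentences = [
    "GENE1 is overexpressed in colorectal carcinoma tissue",
    "variant implicated in Alzheimer's Disease progression",
    "no disease concept mentioned here",
]
for sentence in sentences:
    hits = annotate_text(dictionary, sentence)
    print(f"{sentence!r} -> {sorted(hits)}")
print(
    "\nThe first sentence maps only to the specific term D:2: the nested "
    "'carcinoma' match is suppressed by the longest-match rule."
)
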