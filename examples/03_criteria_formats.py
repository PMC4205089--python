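"""Classify eligibility-text formats and segment criteria.

Shows the two recognized macro-formats (the suggested inclusion/exclusion
layout and the extended cancer-trial topic layout), the per-domain adherence
table, and what segmentation extracts from one block.
"""

from ctgaudit import classify_format, format_table, segment_criteria
from ctgaudit.synthetic_data import default_corpus_spec, generate_corpus

corpus, truth = generate_corpus(default_corpus_spec(seed=1))

print(format_table(corpus))
# percent_suggested: trials following "Inclusion Criteria" then "Exclusion
# Criteria" with a bulleted list; percent_either additionally counts the
# extended topic-heading layout.  The overall row pools all 437 trials.

rec = next(r for r in corpus.records
           if truth.trials[r.nct_id].format_label == "extended")
print(f"\n--- {rec.nct_id} (extended format) ---")
print(rec.eligibility_text)
print("\nsegmented criteria:")
for c in segment_criteria(rec.eligibility_text, classify_format(rec.eligibility_text)):
    tag = " [negated]" if c.negated else ""
    print(f"  {c.role.value:<9} depth={c.indent_depth} {c.text!r}{tag}")
# Extended-format items are all inclusion criteria; items phrased "No ..."
# carry the negation flag.
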